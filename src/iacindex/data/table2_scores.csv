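country_id,rank,score_hours,score_density,score_drink_driving,score_pricing,score_marketing,total
Turkey,1,1.1,1.0,2.6,2.3,7.0,13.9
Vietnam,2,0.6,2.0,1.7,6.1,1.4,11.8
Thailand,3,1.3,1.0,3.0,2.2,2.8,10.3
Mongolia,4,0.7,1.0,2.1,3.2,2.7,9.7
St Kitts and Nevis,5,1.5,2.0,0.9,1.5,2.2,8.0
Chile,6,1.4,0.5,3.2,1.9,0.7,7.6
South Africa,7,1.0,1.0,2.3,1.5,0.9,6.7
Scotland,8,1.1,1.5,0.4,1.9,1.6,6.5
Australia,9,0.6,0.0,2.6,1.2,1.4,5.8
England,10,0.7,0.0,0.9,2.3,1.3,5.1
Netherlands,11,0.7,0.5,1.8,1.1,1.0,5.0
New Zealand,12,0.4,0.0,1.8,1.5,1.4,5.0
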