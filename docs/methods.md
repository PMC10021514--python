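# Methods

## The composite index

The index scores a cohort of countries on five alcohol-policy domains.
Every measure is first normalised to a score in [0, 1] with one fixed
direction convention — higher = more restrictive environment — and
measures whose natural direction runs the other way (trading hours,
marketing modes in use, the price side of affordability) are inverted
inside their scorer. Normalised scores are then multiplied by integer
effectiveness weights and summed.

Per-domain scoring rules and the reasoning behind the open choices:

- **Trading hours/days.** Four sub-scores: on- and off-premise daily
  hours, mapped linearly by (24 − h)/24, and on- and off-premise 7-day
  opening (0 if allowed, 1 if not), averaged without weighting. The
  published scheme states only that hours map to "0–1"; the linear map is
  the simplest monotone map attaining both endpoints, and the unweighted
  mean is the neutral aggregation. Both live in one helper so a binned
  alternative can replace them at a single point. The impact score applies
  the identical rule to actual opening hours/days.
- **Outlet density.** Count of six binary restrictions / 6. No impact
  measure: outlet-density data are not available for enough countries, so
  the domain contributes stringency only (the API reserves the slot).
- **Pricing.** Stringency is the tax share of price, weighted by each
  beverage's market share: Σ_b share_b · tax%_b/100. Tax share is already
  a proportion of a bounded quantity, so it is used directly — keeping
  pricing stringency cohort-independent — rather than min–max scaled.
  Impact is affordability: share-weighted mid-price of 15 ml absolute
  alcohol divided by per-capita GDP (prices and GDP must share a currency;
  the ratio is then unit-free and needs no FX layer), min–max scaled over
  the cohort so the least affordable country scores 1.
- **Marketing.** Stringency: five modes scored 0 (no regulation or
  self-regulation) / 1 (partial ban) / 2 (total ban), plus one point for a
  potency differential, over the maximum of 11. Impact: the number of the
  25 observed marketing modes *not* present, divided by 25 — affine in the
  presence count with slope −1/25.
- **Drink driving.** Stringency: BAC category (no limit 0; ≥ 0.05% 1;
  [0.03, 0.05) 2; [0, 0.03) 3 — half-open intervals, consistent with
  "0.05% or above" being the weakest real limit) plus sobriety-checkpoint,
  random-breath-testing and zero-tolerance-for-professional-drivers flags,
  over 6. "No limit" is a distinct category from a limit of 0.0, which is
  itself the strictest possible limit; the record type keeps them apart.
  Impact: the % of vehicles stopped for random breath testing per year,
  min–max scaled over the cohort.

Cohort-relative min–max scaling (affordability, RBT%) is the standard
composite-indicator normalisation for open-ended measures; its documented
consequence is that those two scores — and hence a country's total — can
change when the cohort changes. A cohort with zero spread in one of these
measures is degenerate; the scaler then returns 0.5 (centre of the scale)
with a warning rather than dividing by zero.

## Weighting and ranking

Default scheme: nine integer weights in [1, 5], one per stringency score
and one per impact score. A domain's points are w_S·s + w_M·m and can
exceed 5 (the published country table contains a marketing domain score
of 7.0, which is only reachable with separate stringency and impact
weights). The alternative per-domain scheme weights the unweighted mean
of a domain's available components by a single weight, giving the literal
0–25 total range at maximum weights. The baseline weight values — pricing
5, marketing 4, hours 3, density 3, drink driving 2, identically in both
blocks — follow the effectiveness-evidence ordering of the domains (the
"best buys": pricing, marketing, availability; drink-driving prevention a
"good buy" aimed at harm rather than consumption). They are a
configurable starting point (`weights.yaml`), not an empirical claim.

Totals are computed on unrounded scores; one-decimal rounding happens only
at report time. Ranks are competition ranks on descending totals (ties
share the smallest applicable rank); output ordering breaks ties by
country id, which affects presentation only.

## Missing data

A missing RBT percentage is imputed with the cohort median of observed
values — robust at cohort sizes around a dozen and exactly reproducible —
and every imputation is logged (country, value) so the choice is
auditable. Imputation is idempotent and never mutates its input.

## Sensitivity analysis

The grid perturbs each of the nine weights one unit up and down and takes
the full Cartesian product: 3⁹ = 19,683 combinations, enumerated in
lexicographic order. Bounds are deliberately **not** clipped (a baseline
weight of 5 yields candidates 4/5/6): clipping would collapse boundary
combinations and the enumeration would no longer have exactly 3^K
members. Per combination, the Pearson correlation between index totals
and recorded APC is computed in one vectorised pass (totals = C·Wᵀ for
the n×9 component matrix C); combinations producing zero-variance totals
get an undefined correlation, excluded from summaries with a warning.

The final weights are the combination with the most negative correlation
(strongest protective association). Ties break by smallest L1 distance to
the baseline — keeping the data-driven choice anchored to the expert
prior — then lexicographically, so selection is deterministic and
independent of grid ordering. Correlation spread is summarised by the
five-number summary and IQR, with quartiles by linear interpolation
between order statistics (values are reported to two decimals, so the
convention matters). Robustness is further probed by leave-one-country-out
correlations (requires n ≥ 4) and by rank stability: each country's rank
distribution across the grid, its mode (ties toward the smaller rank),
and whether the mode equals the baseline rank.

## Association analysis

The correlation table reports, per domain and for the whole index, the
Pearson correlation with recorded APC of the weighted stringency score,
the weighted impact score, and their sum, plus the correlation between
the stringency-only and impact-only totals. Stringency-only and
impact-only totals are formed by zeroing the complementary weight block
rather than re-normalising, which keeps all three columns on one additive
scale and makes "combined = stringency" exact when impact weights vanish.
Degenerate (constant) series are flagged as unavailable rather than
raised, so a single pathological domain does not abort the table. With a
dozen countries the analysis reports correlations only; no p-values, no
regression adjustment.

## Synthetic cohort generator

The generator encodes the index's core assumption — one latent
restrictiveness dimension driving both policy and consumption — as an
explicit, controllable truth. Per country: latent u ~ Uniform(0, 1);
every raw measure in a signal-carrying domain moves monotonically with u
(legal hours shrink from 24 toward 10/14 h, density restrictions
accumulate 0→6, tax rates rise toward 50–70%, marketing bans tighten
mode-by-mode through staggered thresholds while observed modes disappear,
the BAC limit steps through none → 0.08 → 0.04 → 0.02, breath-testing
intensity grows to 60%); non-signal domains draw an independent latent.
Impact measures are the convex blend coupling·(stringency-implied value)
+ (1 − coupling)·(independent draw). Consumption is
APC = max(0, a − b·u + ε), ε ~ Normal(0, noise_sd), floored at zero with
a warning.

Defaults are chosen to emulate the study setting and are not tuned:
12 countries; baseline APC a = 12 litres and effect b = 9 litres, spanning
roughly the 3–12 litre range seen across diverse countries; noise 1
litre; coupling 0.8, reflecting the observed tight correlation between
legislation and environment. Mid-prices are set proportional to GDP with
a common per-beverage coefficient so that affordability is *exactly*
monotone in the latent factor — a deliberate simplification that makes
the noiseless limit (noise 0, coupling 1) perfectly anti-monotone, the
anchor for sign-recovery checks. What the generator does **not**
reproduce: real countries' parameter values and currencies, correlated
domain adoption beyond the single factor, beverage-specific price
structure, measurement error in the policy records, and reverse causation
from consumption to policy. Passing tests therefore demonstrate the
machinery is correct under the stated model, not that the empirical
associations hold in new data; the published 12-country table enters only
as a verbatim fixture.

## Numerical and degenerate-input conventions

- Correlations require n ≥ 3 and non-constant inputs; violations raise
  errors naming the offending variable (cohort-level) or are flagged as
  unavailable (table cells).
- The published domain-score fixture is one-decimal data: recomputed
  component sums match printed totals within ±0.1 (six of twelve rows
  differ by exactly 0.1 through rounding), and two countries' components
  sum to identical totals, producing a genuine shared rank of 11 under
  competition ranking where the source listed 11 and 12 from unrounded
  internal values that were never published.
- Score-passthrough inputs carry only weighted per-domain points; when an
  analysis needs the nine components, each domain's points are split as
  d/(w_S + w_M) against the baseline weights (d/w_S for density), which
  reproduces the points exactly under the baseline and may exceed 1 if the
  source used heavier weights.
- All randomness flows through a single integer seed
  (`numpy.random.default_rng`); the analysis modules themselves are fully
  deterministic.

## Known limitations

- Cohort-relative scores make totals non-portable across cohorts; fix the
  cohort before comparing countries.
- The weight-selection rule optimises an in-sample correlation over 19,683
  candidates with n ≈ 12 countries; it is a robustness probe and a
  transparent tie to expert priors, not an out-of-sample estimator.
- The sub-score rules for trading hours (linear map, unweighted mean) are
  the package's own documented choices where the published scheme leaves
  the mapping open; alternative binnings plug in at one function each.
- Tax design scoring beyond the tax-share measure is not implemented.
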