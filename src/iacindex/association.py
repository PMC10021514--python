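"""Correlations of policy scores with recorded alcohol consumption.

Builds the per-domain and total correlation table: for each policy
domain, the Pearson correlation with recorded APC of (a) the weighted
stringency score alone, (b) the weighted impact score alone, and
(c) their sum (the combined index contribution); plus the same three
columns for the whole-index totals, and the correlation between the
stringency-only and impact-only totals.

Stringency-only and impact-only totals are formed by zeroing the
complementary weight block, not by re-normalising — the additive
structure keeps all three columns on one scale. With only a dozen
countries the table reports correlations without p-values.

A negative correlation means more restrictive policy or environment is
associated with lower recorded consumption.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .index import COMPONENTS, IMPACT_COMPONENTS, STRINGENCY_COMPONENTS, WeightVector
from .scoring import DOMAINS

__all__ = ["AssociationTable", "pearson_r", "build_association_table"]

#: Presentation order of the table rows.
ROW_ORDER = ("pricing", "hours", "density", "marketing", "drink_driving", "total")

ROW_LABELS = {
    "pricing": "Pricing",
    "hours": "Hours and days of sale",
    "density": "Outlet density",
    "marketing": "Marketing",
    "drink_driving": "Drink driving",
    "total": "Total",
}


def pearson_r(x: Sequence[float], y: Sequence[float], xname: str = "x", yname: str = "y") -> float:
    """Sample Pearson correlation with explicit degeneracy errors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    for name, v in ((xname, x), (yname, y)):
        if np.ptp(v) == 0:
            raise ValueError(f"{name} is constant; correlation undefined")
    r, _ = stats.pearsonr(x, y)
    return float(r)


def _safe_r(x: np.ndarray, y: np.ndarray) -> Optional[float]:
    """r, or None when x is degenerate (flagged rather than raised)."""
    if np.ptp(x) == 0:
        return None
    r, _ = stats.pearsonr(x, y)
    return float(r)


@dataclass(frozen=True)
class AssociationTable:
    """Correlation-with-APC table plus the stringency-vs-impact correlation.

    ``rows`` maps each domain (and ``"total"``) to a dict with keys
    ``stringency``, ``impact`` and ``combined``; entries are ``None``
    where the correlation is unavailable (density impact) or degenerate
    in the data.
    """

    rows: dict[str, dict[str, Optional[float]]]
    stringency_vs_impact: Optional[float]

    def to_dataframe(self, decimals: Optional[int] = None) -> pd.DataFrame:
        def fmt(v):
            if v is None:
                return np.nan
            return round(v, decimals) if decimals is not None else v

        data = {
            ROW_LABELS[k]: {
                "Policy Stringency": fmt(self.rows[k]["stringency"]),
                "Impact": fmt(self.rows[k]["impact"]),
                "IAC Policy Index": fmt(self.rows[k]["combined"]),
            }
            for k in ROW_ORDER
        }
        return pd.DataFrame(data).T[["Policy Stringency", "Impact", "IAC Policy Index"]]


def build_association_table(
    components: np.ndarray,
    apc: Sequence[float],
    weights: WeightVector,
) -> AssociationTable:
    """Correlate weighted stringency, impact and combined scores with APC.

    ``components`` is the n x 9 normalised component matrix in canonical
    column order (see :data:`iacindex.index.COMPONENTS`).
    """
    C = np.asarray(components, dtype=float)
    y = np.asarray(apc, dtype=float)
    if C.shape[0] != y.shape[0]:
        raise ValueError("components and APC must have the same number of countries")
    if C.shape[0] < 3:
        raise ValueError("need at least 3 countries")
    if np.ptp(y) == 0:
        raise ValueError("recorded APC is constant; correlations undefined")

    w = weights.as_array()
    col = {name: i for i, name in enumerate(COMPONENTS)}

    rows: dict[str, dict[str, Optional[float]]] = {}
    for d in DOMAINS:
        s = w[col[f"{d}_stringency"]] * C[:, col[f"{d}_stringency"]]
        if d == "density":
            i_part = None
            combined = s
        else:
            i_part = w[col[f"{d}_impact"]] * C[:, col[f"{d}_impact"]]
            combined = s + i_part
        rows[d] = {
            "stringency": _safe_r(s, y),
            "impact": None if i_part is None else _safe_r(i_part, y),
            "combined": _safe_r(combined, y),
        }

    s_mask = np.array([name in STRINGENCY_COMPONENTS for name in COMPONENTS], dtype=float)
    i_mask = np.array([name in IMPACT_COMPONENTS for name in COMPONENTS], dtype=float)
    stringency_total = C @ (w * s_mask)
    impact_total = C @ (w * i_mask)
    combined_total = C @ w
    rows["total"] = {
        "stringency": _safe_r(stringency_total, y),
        "impact": _safe_r(impact_total, y),
        "combined": _safe_r(combined_total, y),
    }
    svi = None
    if np.ptp(stringency_total) > 0 and np.ptp(impact_total) > 0:
        svi = float(stats.pearsonr(stringency_total, impact_total)[0])
    return AssociationTable(rows=rows, stringency_vs_impact=svi)
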