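"""Assembly of normalised domain scores into weighted index totals and ranks.

Two weighting schemes are supported:

* **nine-component** (default): separate integer effectiveness weights
  for each of the five stringency scores and four impact scores. A
  domain's points are ``w_stringency * stringency + w_impact * impact``
  and can exceed 5 (e.g. a marketing domain score of 7.0 under weights
  4 + 4). This is the scheme the 3^9 weight-sensitivity grid perturbs.
* **per-domain**: one weight per domain applied to the unweighted mean
  of that domain's available components, giving the literal 0–25 point
  range when all five weights are at the maximum of 5.

Ranks use competition ranking (ties share the smallest applicable rank,
"1, 2, 2, 4"); output ordering breaks ties by country id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import yaml

from .scoring import DOMAINS, DomainScore

__all__ = [
    "STRINGENCY_COMPONENTS",
    "IMPACT_COMPONENTS",
    "COMPONENTS",
    "WeightVector",
    "DomainWeightVector",
    "IndexResult",
    "DEFAULT_WEIGHTS",
    "domain_weighted_score",
    "sum_domain_scores",
    "assemble_index",
    "assemble_from_domain_points",
    "components_from_domain_points",
    "component_matrix",
    "max_possible_total",
    "load_weights",
    "dump_weights",
]

STRINGENCY_COMPONENTS = tuple(f"{d}_stringency" for d in DOMAINS)
IMPACT_COMPONENTS = tuple(f"{d}_impact" for d in DOMAINS if d != "density")

#: Canonical component order: five stringency weights then four impact weights.
COMPONENTS = STRINGENCY_COMPONENTS + IMPACT_COMPONENTS


@dataclass(frozen=True)
class WeightVector:
    """Nine integer effectiveness weights (five stringency + four impact).

    Weights are bounded to [1, 5] at construction; the sensitivity grid
    intentionally steps outside those bounds, so grid-derived vectors
    are built with ``check_bounds=False``.
    """

    hours_stringency: int
    density_stringency: int
    pricing_stringency: int
    marketing_stringency: int
    drink_driving_stringency: int
    hours_impact: int
    pricing_impact: int
    marketing_impact: int
    drink_driving_impact: int
    check_bounds: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self):
        for name in COMPONENTS:
            w = getattr(self, name)
            if not isinstance(w, (int, np.integer)) or isinstance(w, bool):
                raise TypeError(f"{name} must be an integer, got {w!r}")
            if self.check_bounds and not 1 <= w <= 5:
                raise ValueError(f"{name} = {w} outside [1, 5]")

    def as_tuple(self) -> tuple[int, ...]:
        return tuple(getattr(self, name) for name in COMPONENTS)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.as_tuple(), dtype=float)

    @classmethod
    def from_tuple(cls, values: Sequence[int], check_bounds: bool = True) -> "WeightVector":
        if len(values) != len(COMPONENTS):
            raise ValueError(f"expected {len(COMPONENTS)} weights, got {len(values)}")
        return cls(**dict(zip(COMPONENTS, (int(v) for v in values))), check_bounds=check_bounds)

    def stringency_weight(self, domain: str) -> int:
        return getattr(self, f"{domain}_stringency")

    def impact_weight(self, domain: str) -> int:
        if domain == "density":
            raise KeyError("density has no impact weight")
        return getattr(self, f"{domain}_impact")


@dataclass(frozen=True)
class DomainWeightVector:
    """One integer weight per domain (the 0–25 range scheme)."""

    hours: int
    density: int
    pricing: int
    marketing: int
    drink_driving: int

    def __post_init__(self):
        for d in DOMAINS:
            w = getattr(self, d)
            if not isinstance(w, (int, np.integer)) or isinstance(w, bool):
                raise TypeError(f"{d} weight must be an integer, got {w!r}")
            if not 1 <= w <= 5:
                raise ValueError(f"{d} weight = {w} outside [1, 5]")

    def as_tuple(self) -> tuple[int, ...]:
        return tuple(getattr(self, d) for d in DOMAINS)


Weights = Union[WeightVector, DomainWeightVector]

#: Package baseline: effectiveness ordering pricing > marketing > availability
#: (hours, density) > drink driving, applied symmetrically to both blocks.
DEFAULT_WEIGHTS = WeightVector(
    hours_stringency=3,
    density_stringency=3,
    pricing_stringency=5,
    marketing_stringency=4,
    drink_driving_stringency=2,
    hours_impact=3,
    pricing_impact=5,
    marketing_impact=4,
    drink_driving_impact=2,
)


@dataclass(frozen=True)
class IndexResult:
    country_id: str
    domain_points: dict[str, float]
    total: float
    rank: int


def domain_weighted_score(score: DomainScore, weights: Weights) -> float:
    """Weighted points for one domain of one country."""
    if isinstance(weights, DomainWeightVector):
        w = getattr(weights, score.domain)
        if score.impact is None:
            return w * score.stringency
        return w * (score.stringency + score.impact) / 2.0
    ws = weights.stringency_weight(score.domain)
    value = ws * score.stringency
    if score.impact is not None:
        value += weights.impact_weight(score.domain) * score.impact
    return value


def sum_domain_scores(values: Sequence[float]) -> float:
    """Total index points from five per-domain point values."""
    if len(values) != len(DOMAINS):
        raise ValueError(f"expected {len(DOMAINS)} domain values, got {len(values)}")
    return float(sum(values))


def _competition_ranks(totals: list[float]) -> list[int]:
    # rank 1 = highest total; ties share the smallest applicable rank
    order = sorted(totals, reverse=True)
    return [order.index(t) + 1 for t in totals]


def assemble_index(
    cohort_scores: Mapping[str, Mapping[str, DomainScore]], weights: Weights
) -> list[IndexResult]:
    """Compute weighted totals and ranks for a scored cohort.

    Output is sorted by descending total, ties by country id. Ranks are
    independent of input ordering.
    """
    points = {
        cid: {d: domain_weighted_score(scores[d], weights) for d in DOMAINS}
        for cid, scores in cohort_scores.items()
    }
    return assemble_from_domain_points(points)


def assemble_from_domain_points(
    points: Mapping[str, Mapping[str, float]]
) -> list[IndexResult]:
    """Rank a cohort from pre-computed per-domain point values.

    This is the score-passthrough path: it accepts published domain
    scores directly (already weighted), sums and ranks them.
    """
    ids = sorted(points)
    totals = [sum_domain_scores([points[c][d] for d in DOMAINS]) for c in ids]
    ranks = _competition_ranks(totals)
    results = [
        IndexResult(cid, dict(points[cid]), tot, rk)
        for cid, tot, rk in zip(ids, totals, ranks)
    ]
    results.sort(key=lambda r: (-r.total, r.country_id))
    return results


def component_matrix(
    cohort_scores: Mapping[str, Mapping[str, DomainScore]]
) -> tuple[list[str], np.ndarray]:
    """Countries (sorted) and their n x 9 matrix of normalised components.

    Column order matches :data:`COMPONENTS`, so ``matrix @ w`` gives the
    nine-component weighted totals for weight array ``w``.
    """
    ids = sorted(cohort_scores)
    rows = []
    for cid in ids:
        scores = cohort_scores[cid]
        row = [scores[d].stringency for d in DOMAINS]
        row += [scores[d].impact for d in DOMAINS if d != "density"]
        rows.append(row)
    return ids, np.asarray(rows, dtype=float)


def components_from_domain_points(
    points: Mapping[str, Mapping[str, float]], weights: WeightVector
) -> tuple[list[str], np.ndarray]:
    """Recover a component matrix from published per-domain point values.

    Published tables report only the weighted domain points, not the
    stringency/impact split. The point value ``d`` is apportioned so the
    baseline weights reproduce it exactly: both components are set to
    ``d / (w_s + w_i)`` (density: ``d / w_s``). Recovered components may
    exceed 1 when the publication used heavier weights than the baseline.
    """
    ids = sorted(points)
    rows = []
    for cid in ids:
        per_pair = {
            d: points[cid][d]
            / (weights.stringency_weight(d) + (0 if d == "density" else weights.impact_weight(d)))
            for d in DOMAINS
        }
        row = [per_pair[d] for d in DOMAINS]
        row += [per_pair[d] for d in DOMAINS if d != "density"]
        rows.append(row)
    return ids, np.asarray(rows, dtype=float)


def max_possible_total(weights: Weights) -> float:
    """Index total when every normalised component equals 1.

    Per-domain weights all at 5 give the maximum possible score of 25.
    """
    return float(sum(weights.as_tuple()))


# ---------------------------------------------------------------------------
# weights configuration files

def load_weights(path) -> Weights:
    """Load a validated weights config (``weights.yaml``).

    The file holds ``scheme: nine_component | per_domain`` plus the
    named integer weights for that scheme.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "scheme" not in cfg:
        raise ValueError(f"weights file {path} must define a 'scheme'")
    scheme = cfg["scheme"]
    if scheme == "nine_component":
        missing = [k for k in COMPONENTS if k not in cfg]
        if missing:
            raise ValueError(f"weights file {path} missing: {missing}")
        return WeightVector(**{k: int(cfg[k]) for k in COMPONENTS})
    if scheme == "per_domain":
        missing = [d for d in DOMAINS if d not in cfg]
        if missing:
            raise ValueError(f"weights file {path} missing: {missing}")
        return DomainWeightVector(**{d: int(cfg[d]) for d in DOMAINS})
    raise ValueError(f"unknown scheme {scheme!r} in {path}")


def dump_weights(weights: Weights, path) -> None:
    if isinstance(weights, DomainWeightVector):
        cfg = {"scheme": "per_domain", **dict(zip(DOMAINS, weights.as_tuple()))}
    else:
        cfg = {"scheme": "nine_component", **dict(zip(COMPONENTS, weights.as_tuple()))}
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
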