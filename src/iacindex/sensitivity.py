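"""Effectiveness-weight sensitivity analysis.

Perturbs each of the nine effectiveness weights one unit up and one
unit down around a baseline, enumerating the full Cartesian grid
(3^9 = 19,683 combinations for nine varied weights), and quantifies:

* the Pearson correlation of the index total with recorded APC under
  every combination, summarised by quartiles and the IQR;
* the data-driven final weight choice (the combination with the
  strongest protective, i.e. most negative, correlation);
* leave-one-country-out correlations under fixed weights;
* rank stability — whether each country's rank under the baseline
  weights is also its modal rank across the grid.

The grid deliberately does **not** clip at the [1, 5] construction
bounds: perturbing a weight of 5 yields 6. Clipping would collapse
boundary combinations and the enumeration would no longer have
exactly 3^K members.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .index import COMPONENTS, WeightVector

__all__ = [
    "RankStabilityEntry",
    "SensitivityReport",
    "enumerate_weight_grid",
    "grid_correlations",
    "select_final_weights",
    "summarize_correlations",
    "leave_one_out",
    "rank_stability",
    "run_sensitivity",
]


def enumerate_weight_grid(
    baseline: WeightVector, vary: Optional[Sequence[str]] = None
) -> np.ndarray:
    """All combinations of each varied weight at {w-1, w, w+1}.

    Returns a (3^K, 9) integer array in deterministic lexicographic
    order over the canonical component order; non-varied components
    stay at their baseline value. No clipping, no deduplication.
    """
    vary = tuple(COMPONENTS) if vary is None else tuple(vary)
    unknown = [v for v in vary if v not in COMPONENTS]
    if unknown:
        raise ValueError(f"unknown weight components: {unknown}")
    base = baseline.as_tuple()
    choices = [
        (w - 1, w, w + 1) if name in vary else (w,)
        for name, w in zip(COMPONENTS, base)
    ]
    return np.asarray(list(itertools.product(*choices)), dtype=int)


def _pearson_columns(totals: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each column of ``totals`` against ``y``; NaN where degenerate."""
    tc = totals - totals.mean(axis=0, keepdims=True)
    yc = y - y.mean()
    t_norm = np.sqrt((tc**2).sum(axis=0))
    y_norm = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (tc.T @ yc) / (t_norm * y_norm)
    r[t_norm == 0] = np.nan
    return r


def grid_correlations(
    components: np.ndarray, grid: np.ndarray, apc: np.ndarray
) -> np.ndarray:
    """Pearson r(total, APC) for every weight combination in the grid.

    ``components`` is the n x 9 matrix of normalised scores (canonical
    column order), ``grid`` the m x 9 weight array. Combinations whose
    totals have zero variance get NaN (excluded from summaries, with a
    warning).
    """
    components = np.asarray(components, dtype=float)
    apc = np.asarray(apc, dtype=float)
    n = components.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 countries for correlations, got {n}")
    if apc.shape[0] != n:
        raise ValueError("APC vector length does not match cohort size")
    if np.ptp(apc) == 0:
        raise ValueError("recorded APC is constant across the cohort")
    totals = components @ np.asarray(grid, dtype=float).T  # n x m
    r = _pearson_columns(totals, apc)
    if np.isnan(r).any():
        warnings.warn(
            f"{int(np.isnan(r).sum())} weight combinations produced "
            "zero-variance totals; their correlations are undefined",
            stacklevel=2,
        )
    return r


def select_final_weights(
    grid: np.ndarray, correlations: np.ndarray, baseline: WeightVector
) -> WeightVector:
    """The combination with the most negative correlation with APC.

    Ties break by smallest L1 distance to the baseline (keeping the
    data-driven choice anchored to the expert priors), then by
    lexicographic order of the weight tuple — fully deterministic and
    independent of grid ordering.
    """
    r = np.asarray(correlations, dtype=float)
    finite = np.isfinite(r)
    if not finite.any():
        raise ValueError("no weight combination produced a defined correlation")
    best_r = r[finite].min()
    candidates = np.flatnonzero(finite & (r == best_r))
    base = np.asarray(baseline.as_tuple())
    key = lambda i: (int(np.abs(grid[i] - base).sum()), tuple(int(w) for w in grid[i]))
    winner = min(candidates, key=key)
    return WeightVector.from_tuple(grid[winner], check_bounds=False)


def summarize_correlations(correlations: Iterable[float]) -> dict[str, float]:
    """Five-number summary plus IQR; quartiles by linear interpolation."""
    r = np.asarray([v for v in correlations if np.isfinite(v)], dtype=float)
    if r.size == 0:
        raise ValueError("no defined correlations to summarise")
    q1, med, q3 = np.percentile(r, [25, 50, 75])  # linear interpolation
    return {
        "min": float(r.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(r.max()),
        "iqr": float(q3 - q1),
        "n": int(r.size),
    }


def leave_one_out(
    components: np.ndarray,
    weights: WeightVector,
    apc: np.ndarray,
    countries: Sequence[str],
) -> dict[str, float]:
    """r(total, APC) with each country omitted in turn, fixed weights."""
    components = np.asarray(components, dtype=float)
    apc = np.asarray(apc, dtype=float)
    n = components.shape[0]
    if n < 4:
        raise ValueError(f"leave-one-out needs at least 4 countries, got {n}")
    if len(countries) != n or apc.shape[0] != n:
        raise ValueError("countries, components and APC must align")
    totals = components @ weights.as_array()
    out: dict[str, float] = {}
    for i, cid in enumerate(countries):
        mask = np.arange(n) != i
        r, _ = stats.pearsonr(totals[mask], apc[mask])
        out[cid] = float(r)
    return out


@dataclass(frozen=True)
class RankStabilityEntry:
    country_id: str
    baseline_rank: int
    modal_rank: int
    modal_equals_baseline: bool
    rank_counts: dict[int, int]


def rank_stability(
    components: np.ndarray,
    grid: np.ndarray,
    baseline: WeightVector,
    countries: Sequence[str],
) -> list[RankStabilityEntry]:
    """Distribution of each country's rank across all grid combinations.

    Ranks are competition ranks on descending totals. The modal rank
    breaks ties toward the smallest rank.
    """
    components = np.asarray(components, dtype=float)
    totals = components @ np.asarray(grid, dtype=float).T  # n x m
    ranks = stats.rankdata(-totals, method="min", axis=0).astype(int)
    base_totals = components @ baseline.as_array()
    base_ranks = stats.rankdata(-base_totals, method="min").astype(int)
    entries = []
    for i, cid in enumerate(countries):
        vals, counts = np.unique(ranks[i], return_counts=True)
        modal = int(vals[np.argmax(counts)])  # np.unique sorts: ties -> smallest rank
        entries.append(
            RankStabilityEntry(
                country_id=cid,
                baseline_rank=int(base_ranks[i]),
                modal_rank=modal,
                modal_equals_baseline=modal == int(base_ranks[i]),
                rank_counts={int(v): int(c) for v, c in zip(vals, counts)},
            )
        )
    return entries


@dataclass(frozen=True)
class SensitivityReport:
    baseline: tuple[int, ...]
    varied: tuple[str, ...]
    grid_size: int
    correlations: np.ndarray = field(repr=False)
    grid: np.ndarray = field(repr=False)
    summary: dict[str, float]
    selected_weights: tuple[int, ...]
    selected_r: float
    baseline_r: float
    leave_one_out: dict[str, float]
    rank_stability: list[RankStabilityEntry]

    def to_dict(self) -> dict:
        """JSON-ready view (without the full per-combination table)."""
        return {
            "baseline_weights": dict(zip(COMPONENTS, self.baseline)),
            "varied_components": list(self.varied),
            "grid_size": self.grid_size,
            "correlation_summary": self.summary,
            "selected_weights": dict(zip(COMPONENTS, self.selected_weights)),
            "selected_correlation": self.selected_r,
            "baseline_correlation": self.baseline_r,
            "leave_one_out": self.leave_one_out,
            "rank_stability": [
                {
                    "country_id": e.country_id,
                    "baseline_rank": e.baseline_rank,
                    "modal_rank": e.modal_rank,
                    "modal_equals_baseline": e.modal_equals_baseline,
                    "rank_counts": {str(k): v for k, v in sorted(e.rank_counts.items())},
                }
                for e in self.rank_stability
            ],
        }


def run_sensitivity(
    components: np.ndarray,
    apc: np.ndarray,
    countries: Sequence[str],
    baseline: WeightVector,
    vary: Optional[Sequence[str]] = None,
) -> SensitivityReport:
    """Full sensitivity pipeline on a scored cohort."""
    grid = enumerate_weight_grid(baseline, vary)
    r = grid_correlations(components, grid, apc)
    selected = select_final_weights(grid, r, baseline)
    summary = summarize_correlations(r)
    base_arr = np.asarray(baseline.as_tuple())
    base_idx = int(np.flatnonzero((grid == base_arr).all(axis=1))[0])
    return SensitivityReport(
        baseline=baseline.as_tuple(),
        varied=tuple(COMPONENTS) if vary is None else tuple(vary),
        grid_size=int(grid.shape[0]),
        correlations=r,
        grid=grid,
        summary=summary,
        selected_weights=selected.as_tuple(),
        selected_r=float(r[np.flatnonzero((grid == np.asarray(selected.as_tuple())).all(axis=1))[0]]),
        baseline_r=float(r[base_idx]),
        leave_one_out=leave_one_out(components, baseline, apc, countries),
        rank_stability=rank_stability(components, grid, baseline, countries),
    )
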