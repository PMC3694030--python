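"""Dataset-level descriptive statistics over pooled response rates.

Covers three analyses: ORR trends stratified by the number of agents in
the combination (median with an empirical 5th-95th percentile band),
comparison of the ORR distributions of monoclonal-antibody and
non-antibody combinations (two-sample Kolmogorov-Smirnov), and a Fisher
exact test for enrichment of antibodies among synergistic pairs.

The "90% confidence interval" of the per-size trend is the empirical
5-95 percentile band across combinations (nearest-rank quantiles), not a
sampling interval for the median.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .trial_io import AgentRegistry, Combination, TrialValidationError, flag_monoclonal

__all__ = [
    "StratumSummary",
    "stratify_by_size",
    "ks_two_sample",
    "fisher_exact",
    "mab_enrichment",
]


@dataclass(frozen=True)
class StratumSummary:
    """ORR summary for combinations of one size: median and 5-95 band."""

    num_agents: int
    n_combinations: int
    median_orr: float
    ci90_low: float
    ci90_high: float


def _nearest_rank(values: np.ndarray, q: float) -> float:
    # type-1 (inverted CDF) empirical quantile
    return float(np.quantile(values, q, method="inverted_cdf"))


def stratify_by_size(pooled: Sequence[tuple[Combination, float]]) -> list[StratumSummary]:
    """Per-size median and empirical 90% band of posterior-mean ORRs.

    ``pooled`` holds one (combination, ORR percent) pair per distinct
    combination. Empty strata are omitted.
    """
    if not pooled:
        raise TrialValidationError("no pooled combinations")
    by_size: dict[int, list[float]] = {}
    for combo, orr in pooled:
        by_size.setdefault(combo.size, []).append(orr)
    out = []
    for size in sorted(by_size):
        vals = np.asarray(by_size[size], dtype=float)
        out.append(
            StratumSummary(
                num_agents=size,
                n_combinations=len(vals),
                median_orr=_nearest_rank(vals, 0.5),
                ci90_low=_nearest_rank(vals, 0.05),
                ci90_high=_nearest_rank(vals, 0.95),
            )
        )
    return out


def ks_two_sample(xs: Sequence[float], ys: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value).

    D is the supremum distance between the two empirical CDFs.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise TrialValidationError("both samples must be non-empty")
    res = stats.ks_2samp(xs, ys, method="asymp")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise TrialValidationError("table must be 2x2")
    if np.any(arr < 0):
        raise TrialValidationError("counts must be non-negative")
    if arr.sum() == 0:
        raise TrialValidationError("at least one count must be positive")
    _, p = stats.fisher_exact(arr.astype(int), alternative="two-sided")
    return float(p)


def mab_enrichment(
    synergy_pairs: Iterable[Combination],
    all_pairs: Iterable[Combination],
    registry: AgentRegistry,
) -> tuple[np.ndarray, float]:
    """Test whether monoclonal antibodies are enriched among synergistic pairs.

    Cross-tabulates (pair contains >= 1 mAb) against (pair in the synergy
    catalog) over all evaluable pairs and applies the Fisher exact test.
    Returns (2x2 counts, two-sided p). Table layout: rows = mAb yes/no,
    columns = synergistic yes/no.
    """
    synergy = set(synergy_pairs)
    counts = np.zeros((2, 2), dtype=int)
    for pair in all_pairs:
        has_mab = any(flag_monoclonal(a, registry) for a in pair.agents)
        is_syn = pair in synergy
        counts[0 if has_mab else 1, 0 if is_syn else 1] += 1
    return counts, fisher_exact(counts)
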