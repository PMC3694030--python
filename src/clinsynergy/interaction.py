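"""Non-interaction null model for two-agent combinations.

Under Bliss independence, a patient responds to a two-agent combination
iff they respond to at least one of the agents, so the null response
probability is ``q_ij = 1 - (1 - p_i)(1 - p_j)`` with ``p_i``, ``p_j``
the pooled single-agent response probabilities. Observing ``n`` responses
in ``N`` combination patients, the evidence for synergy is the upper
binomial tail ``P(X >= n | N, q)`` and for antagonism the lower tail
``P(X <= n | N, q)``; both tails include the observed count, so
``p_synergy + p_antagonism = 1 + P(X = n)`` exactly.

A pair is labeled synergistic when ``p_synergy < alpha`` and the observed
pooled ORR exceeds the null expectation ``ORR_1``, antagonistic in the
mirror case, and non-interacting otherwise. No multiple-testing
correction is applied by default (raw 0.05 thresholds); an optional
Benjamini-Hochberg flag is available for catalog building.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .pooling import partition_trials, pool_equivalent, resolve_discordant
from .trial_io import Combination, TrialRecord, TrialValidationError, group_by_combination

__all__ = [
    "InteractionResult",
    "null_combination_prob",
    "p_synergy",
    "p_antagonism",
    "expected_orr1",
    "classify_pair",
    "build_catalog",
]

LABEL_SYNERGISTIC = "synergistic"
LABEL_ANTAGONISTIC = "antagonistic"
LABEL_NON_INTERACTING = "non-interacting"
LABEL_NOT_EVALUABLE = "not evaluable"


def _check_prob(x, name: str):
    arr = np.asarray(x, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise TrialValidationError(f"{name} must lie in [0, 1]")
    return arr


def null_combination_prob(p_i, p_j):
    """Bliss null: q = 1 - (1 - p_i)(1 - p_j). Symmetric; accepts arrays."""
    p_i = _check_prob(p_i, "p_i")
    p_j = _check_prob(p_j, "p_j")
    out = 1.0 - (1.0 - p_i) * (1.0 - p_j)
    return float(out) if out.ndim == 0 else out


def _check_counts(n, N):
    n = np.asarray(n)
    N = np.asarray(N)
    if np.any(N < 1):
        raise TrialValidationError("N must be >= 1")
    if np.any((n < 0) | (n > N)):
        raise TrialValidationError("n must lie in [0, N]")
    return n, N


def p_synergy(n, N, q):
    """Upper tail P(X >= n | N, q), inclusive of the observed count."""
    n, N = _check_counts(n, N)
    q = _check_prob(q, "q")
    out = stats.binom.sf(n - 1, N, q)
    return float(out) if np.ndim(out) == 0 else out


def p_antagonism(n, N, q):
    """Lower tail P(X <= n | N, q), inclusive of the observed count."""
    n, N = _check_counts(n, N)
    q = _check_prob(q, "q")
    out = stats.binom.cdf(n, N, q)
    return float(out) if np.ndim(out) == 0 else out


def expected_orr1(p_i_mean: float, p_j_mean: float) -> float:
    """Expected combination ORR (percent) under non-interaction."""
    return 100.0 * null_combination_prob(p_i_mean, p_j_mean)


@dataclass
class InteractionResult:
    """Null-model test outcome for one agent pair."""

    pair: Combination
    q_null: float | None
    orr1: float | None
    orr0: float | None
    n_pooled: int | None
    N_pooled: int | None
    p_synergy: float | None
    p_antagonism: float | None
    label: str
    reason: str = ""

    @property
    def evaluable(self) -> bool:
        return self.label != LABEL_NOT_EVALUABLE


def _pooled_retained(trials: Sequence[TrialRecord], log_bf_threshold: float):
    """Partition/resolve a same-combination trial list; None if excluded."""
    part = partition_trials(trials, log_bf_threshold)
    retained = resolve_discordant(part)
    if not retained:
        return None
    return pool_equivalent(retained)


def classify_pair(
    dataset: Sequence[TrialRecord],
    pair: Combination,
    alpha_level: float = 0.05,
    log_bf_threshold: float | None = None,
    _groups=None,
) -> InteractionResult:
    """Classify one two-agent combination against the non-interaction null.

    Single-agent response probabilities come from pooled trials testing
    each agent alone; the pair's pooled counts come from trials testing
    exactly that pair. Missing single-agent or pair data yields a
    "not evaluable" result rather than an exception.
    """
    from .pooling import DEFAULT_LOG_BF_THRESHOLD

    if pair.size != 2:
        raise TrialValidationError("classify_pair requires a combination of exactly 2 agents")
    if log_bf_threshold is None:
        log_bf_threshold = DEFAULT_LOG_BF_THRESHOLD
    groups = _groups if _groups is not None else group_by_combination(dataset)

    def not_evaluable(reason: str) -> InteractionResult:
        return InteractionResult(
            pair=pair, q_null=None, orr1=None, orr0=None, n_pooled=None,
            N_pooled=None, p_synergy=None, p_antagonism=None,
            label=LABEL_NOT_EVALUABLE, reason=reason,
        )

    single_means = []
    for agent in pair.agents:
        key = Combination((agent,))
        if key not in groups:
            return not_evaluable(f"no single-agent trials for {agent}")
        post = _pooled_retained(groups[key], log_bf_threshold)
        if post is None:
            return not_evaluable(f"single-agent trials for {agent} excluded as discordant")
        single_means.append(post.mean)

    if pair not in groups:
        return not_evaluable("no trials testing the pair")
    pair_post = _pooled_retained(groups[pair], log_bf_threshold)
    if pair_post is None:
        return not_evaluable("pair trials excluded as discordant")

    q = null_combination_prob(single_means[0], single_means[1])
    n_pooled = int(round(pair_post.alpha))
    N_pooled = int(round(pair_post.alpha + pair_post.beta_param))
    p_syn = p_synergy(n_pooled, N_pooled, q)
    p_ant = p_antagonism(n_pooled, N_pooled, q)
    orr0 = pair_post.orr
    orr1 = 100.0 * q

    label = LABEL_NON_INTERACTING
    if p_syn < alpha_level and orr0 > orr1:
        label = LABEL_SYNERGISTIC
    elif p_ant < alpha_level and orr0 < orr1:
        label = LABEL_ANTAGONISTIC

    return InteractionResult(
        pair=pair, q_null=q, orr1=orr1, orr0=orr0,
        n_pooled=n_pooled, N_pooled=N_pooled,
        p_synergy=p_syn, p_antagonism=p_ant, label=label,
    )


def build_catalog(
    dataset: Sequence[TrialRecord],
    alpha_level: float = 0.05,
    bh_correction: bool = False,
    log_bf_threshold: float | None = None,
):
    """Classify every evaluable pair; return (synergistic, antagonistic, all).

    The synergy and antagonism catalogs are each sorted by their p-value
    ascending, mirroring how the published tables are printed. When
    ``bh_correction`` is set, labels are re-thresholded by the
    Benjamini-Hochberg step-up rule within each one-sided family.
    """
    groups = group_by_combination(dataset)
    pairs = sorted((c for c in groups if c.size == 2), key=lambda c: c.agents)
    results = [
        classify_pair(dataset, pair, alpha_level=alpha_level,
                      log_bf_threshold=log_bf_threshold, _groups=groups)
        for pair in pairs
    ]
    evaluable = [r for r in results if r.evaluable]

    if bh_correction and evaluable:
        from statsmodels.stats.multitest import multipletests
        for attr, label, direction in (
            ("p_synergy", LABEL_SYNERGISTIC, 1), ("p_antagonism", LABEL_ANTAGONISTIC, -1),
        ):
            pvals = [getattr(r, attr) for r in evaluable]
            reject, *_ = multipletests(pvals, alpha=alpha_level, method="fdr_bh")
            for r, rej in zip(evaluable, reject):
                effect_ok = (r.orr0 - r.orr1) * direction > 0
                if rej and effect_ok:
                    r.label = label
                elif r.label == label and not rej:
                    r.label = LABEL_NON_INTERACTING

    synergy = sorted(
        (r for r in evaluable if r.label == LABEL_SYNERGISTIC), key=lambda r: r.p_synergy
    )
    antagonism = sorted(
        (r for r in evaluable if r.label == LABEL_ANTAGONISTIC), key=lambda r: r.p_antagonism
    )
    return synergy, antagonism, results
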