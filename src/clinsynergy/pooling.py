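"""Beta-posterior pooling of response rates and the trial-equivalence partition.

For a trial with ``n`` responders out of ``N`` patients, the response
probability ``p`` has a conjugate beta posterior with ``alpha = n`` and
``beta = N - n``; pooling statistically equivalent trials of the same
combination sums the counts, so ``mean(p) = sum(n_i) / sum(N_i)`` and the
pooled overall response rate is ``ORR_0 = 100 * mean(p)``.

Whether trials of one combination ARE equivalent is decided by Bayesian
model selection over set partitions of the trials: each candidate group is
scored by its beta-binomial marginal likelihood under a Beta(1, 1) prior,
and a multi-group partition is accepted only when its total log evidence
beats the single-group model by more than a log-Bayes-factor threshold
(default ``log 10``, a "strong evidence" bar). For up to 8 trials every
set partition is scored exhaustively; beyond that a greedy agglomerative
merge from singletons is used. Ties break toward fewer groups.

Combinations whose trials split into discordant groups are resolved by
dropping the minority group(s); when every group holds a single trial the
combination is excluded outright.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations as _itercombos
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.special import betaln, gammaln
from scipy import stats

from .trial_io import Combination, TrialRecord, TrialValidationError

__all__ = [
    "BetaPosterior",
    "EquivalencePartition",
    "posterior_from_counts",
    "pool_equivalent",
    "partition_trials",
    "resolve_discordant",
    "TrialPartitioner",
    "DEFAULT_LOG_BF_THRESHOLD",
]

DEFAULT_LOG_BF_THRESHOLD = math.log(10.0)
EXHAUSTIVE_LIMIT = 8


@dataclass(frozen=True)
class BetaPosterior:
    """Posterior over a response probability: Beta(alpha, beta_param).

    ``alpha`` is the pooled responder count and ``beta_param`` the pooled
    non-responder count. The boundary cases n=0 and n=N make this density
    improper; the mean ``n/N`` is still reported exactly, and sampling or
    quantile computation substitutes the Jeffreys posterior
    Beta(n + 1/2, N - n + 1/2), which is always proper.
    """

    alpha: float
    beta_param: float

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta_param)

    @property
    def orr(self) -> float:
        """Overall response rate in percent."""
        return 100.0 * self.mean

    def _proper(self) -> tuple[float, float]:
        if self.alpha > 0 and self.beta_param > 0:
            return self.alpha, self.beta_param
        return self.alpha + 0.5, self.beta_param + 0.5

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        a, b = self._proper()
        return rng.beta(a, b, size=size)

    def quantile(self, q) -> np.ndarray:
        a, b = self._proper()
        return stats.beta.ppf(q, a, b)


def posterior_from_counts(n: int, N: int) -> BetaPosterior:
    """Beta posterior for a single trial: alpha = n, beta = N - n."""
    if N < 1:
        raise TrialValidationError("sample size must be >= 1")
    if not 0 <= n <= N:
        raise TrialValidationError(f"n={n} outside [0, {N}]")
    return BetaPosterior(alpha=float(n), beta_param=float(N - n))


def _check_same_combination(trials: Sequence[TrialRecord]) -> Combination:
    if not trials:
        raise TrialValidationError("empty trial list")
    combos = {t.combination for t in trials}
    if len(combos) != 1:
        raise TrialValidationError(f"mixed combinations in pool: {sorted(map(str, combos))}")
    return next(iter(combos))


def pool_equivalent(trials: Sequence[TrialRecord]) -> BetaPosterior:
    """Pool same-combination trials: alpha = sum(n_i), beta = sum(N_i - n_i)."""
    _check_same_combination(trials)
    n = sum(t.n_responders for t in trials)
    big_n = sum(t.sample_size for t in trials)
    return BetaPosterior(alpha=float(n), beta_param=float(big_n - n))


# ---------------------------------------------------------------------------
# Partition scoring


def _group_log_evidence(ns: np.ndarray, Ns: np.ndarray, a0: float, b0: float) -> float:
    """Log beta-binomial marginal likelihood of one group under Beta(a0, b0).

    prod_i C(N_i, n_i) * B(sum n + a0, sum(N - n) + b0) / B(a0, b0)
    """
    log_binom = float(np.sum(gammaln(Ns + 1) - gammaln(ns + 1) - gammaln(Ns - ns + 1)))
    return log_binom + betaln(ns.sum() + a0, (Ns - ns).sum() + b0) - betaln(a0, b0)


def _set_partitions(items: Sequence[int]) -> Iterator[list[list[int]]]:
    """All set partitions of ``items`` (order of groups/members irrelevant)."""
    if len(items) == 1:
        yield [[items[0]]]
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i, group in enumerate(smaller):
            yield smaller[:i] + [group + [first]] + smaller[i + 1:]
        yield [[first]] + smaller


@dataclass
class EquivalencePartition:
    """Selected grouping of same-combination trials into response-rate classes."""

    combination: Combination
    trials: list[TrialRecord]
    groups: list[list[int]]            # disjoint index sets covering all trials
    group_posteriors: list[BetaPosterior]
    log_evidence: float                # score of the selected partition
    log_evidence_single: float         # score of the one-group model

    @property
    def equivalent(self) -> bool:
        return len(self.groups) == 1

    @property
    def log_bayes_factor(self) -> float:
        """Evidence for heterogeneity: selected partition vs single group."""
        return self.log_evidence - self.log_evidence_single


def _score_partition(groups: list[list[int]], ns: np.ndarray, Ns: np.ndarray,
                     a0: float, b0: float) -> float:
    return sum(_group_log_evidence(ns[g], Ns[g], a0, b0) for g in groups)


def _greedy_partition(ns: np.ndarray, Ns: np.ndarray, a0: float, b0: float) -> tuple[list[list[int]], float]:
    """Agglomerative merging from singletons, used beyond the exhaustive regime."""
    groups = [[i] for i in range(len(ns))]
    score = _score_partition(groups, ns, Ns, a0, b0)
    while len(groups) > 1:
        best = None
        for i, j in _itercombos(range(len(groups)), 2):
            merged = groups[:i] + groups[i + 1:j] + groups[j + 1:] + [groups[i] + groups[j]]
            s = _score_partition(merged, ns, Ns, a0, b0)
            # >= : prefer merging (fewer groups) on ties
            if best is None or s >= best[0]:
                best = (s, merged)
        if best[0] >= score:
            score, groups = best[0], best[1]
        else:
            break
    return groups, score


def partition_trials(
    trials: Sequence[TrialRecord],
    log_bayes_factor_threshold: float = DEFAULT_LOG_BF_THRESHOLD,
    prior: tuple[float, float] = (1.0, 1.0),
) -> EquivalencePartition:
    """Decide whether same-combination trials share one response rate.

    Returns the best-scoring partition; multiple groups are declared only
    when the best multi-group partition beats the single-group model by
    more than ``log_bayes_factor_threshold`` in log evidence.
    """
    combo = _check_same_combination(trials)
    a0, b0 = prior
    ns = np.array([t.n_responders for t in trials], dtype=float)
    Ns = np.array([t.sample_size for t in trials], dtype=float)
    k = len(trials)

    single = [list(range(k))]
    score_single = _score_partition(single, ns, Ns, a0, b0)

    if k == 1:
        best_groups, best_score = single, score_single
    elif k <= EXHAUSTIVE_LIMIT:
        best_groups, best_score = single, score_single
        for part in _set_partitions(list(range(k))):
            if len(part) == 1:
                continue
            s = _score_partition(part, ns, Ns, a0, b0)
            if s > best_score or (s == best_score and len(part) < len(best_groups)):
                best_groups, best_score = [sorted(g) for g in part], s
    else:
        best_groups, best_score = _greedy_partition(ns, Ns, a0, b0)

    if len(best_groups) > 1 and best_score - score_single <= log_bayes_factor_threshold:
        best_groups, best_score = single, score_single

    best_groups = sorted((sorted(g) for g in best_groups), key=lambda g: g[0])
    posteriors = [pool_equivalent([trials[i] for i in g]) for g in best_groups]
    return EquivalencePartition(
        combination=combo,
        trials=list(trials),
        groups=best_groups,
        group_posteriors=posteriors,
        log_evidence=best_score,
        log_evidence_single=score_single,
    )


def resolve_discordant(partition: EquivalencePartition) -> list[TrialRecord]:
    """Retain trials after resolving discordant response-rate classes.

    One group: everything is retained. Multiple groups each holding a
    single trial: no trial is internally corroborated, so the combination
    is excluded (empty list). Otherwise the group(s) with the minimal
    trial count are dropped — ties drop all tied minimal groups, and if
    that empties the combination it is excluded.
    """
    if partition.equivalent:
        return list(partition.trials)
    sizes = [len(g) for g in partition.groups]
    if all(s == 1 for s in sizes):
        return []
    smallest = min(sizes)
    retained_idx = [i for g, s in zip(partition.groups, sizes) if s > smallest for i in g]
    return [partition.trials[i] for i in sorted(retained_idx)]


class TrialPartitioner:
    """Estimator-style wrapper around the equivalence partition.

    Parameters
    ----------
    log_bayes_factor_threshold : float
        Log evidence margin a multi-group partition must exceed.
    prior : (float, float)
        Beta prior pseudo-counts used in the group marginal likelihood.
    """

    def __init__(self, log_bayes_factor_threshold: float = DEFAULT_LOG_BF_THRESHOLD,
                 prior: tuple[float, float] = (1.0, 1.0)):
        self.log_bayes_factor_threshold = log_bayes_factor_threshold
        self.prior = prior

    def get_params(self, deep: bool = True) -> dict:
        return {
            "log_bayes_factor_threshold": self.log_bayes_factor_threshold,
            "prior": self.prior,
        }

    def set_params(self, **params) -> "TrialPartitioner":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, trials: Sequence[TrialRecord]) -> "TrialPartitioner":
        part = partition_trials(trials, self.log_bayes_factor_threshold, self.prior)
        self.partition_ = part
        self.groups_ = part.groups
        self.equivalent_ = part.equivalent
        self.log_evidence_ = part.log_evidence
        self.retained_trials_ = resolve_discordant(part)
        return self

    def fit_predict(self, trials: Sequence[TrialRecord]) -> np.ndarray:
        """Group label per trial, aligned with the input order."""
        self.fit(trials)
        labels = np.empty(len(trials), dtype=int)
        for gi, g in enumerate(self.groups_):
            labels[g] = gi
        return labels


def pooling_report(groups: dict[Combination, list[TrialRecord]],
                   log_bayes_factor_threshold: float = DEFAULT_LOG_BF_THRESHOLD):
    """Per-combination pooling summary after partition/resolution.

    Returns (report_rows, retained_trials). Each row records the trial
    count, group structure, retained count and pooled posterior of the
    retained trials (blank when the combination is excluded).
    """
    rows = []
    retained_all: list[TrialRecord] = []
    for combo in sorted(groups, key=lambda c: c.agents):
        trials = groups[combo]
        part = partition_trials(trials, log_bayes_factor_threshold)
        retained = resolve_discordant(part)
        retained_all.extend(retained)
        if retained:
            post = pool_equivalent(retained)
            alpha, beta_param, orr = post.alpha, post.beta_param, post.orr
        else:
            alpha = beta_param = orr = float("nan")
        rows.append(
            {
                "combination": str(combo),
                "num_agents": combo.size,
                "num_trials": len(trials),
                "num_groups": len(part.groups),
                "group_sizes": ";".join(str(len(g)) for g in part.groups),
                "retained_trials": len(retained),
                "alpha": alpha,
                "beta": beta_param,
                "ORR_0": orr,
            }
        )
    return rows, retained_all
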