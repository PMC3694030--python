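"""Two-agent approximation to combination response rates.

The response probability of a combination ``c`` over agents ``i`` is
modeled linearly as

    p_c = sum_i s_ci h_i + sum_{i<j} s_ci s_cj J_ij

where ``s_ci`` indicates membership of agent ``i`` in combination ``c``,
``h_i`` is the single-agent response rate, and ``J_ij`` is a pairwise
correction. Expanding the Bliss (non-interacting) composition
``p_c = 1 - prod_i (1 - h_i)`` to second order shows the non-interacting
value of a pairwise term is ``J0_ij = -h_i h_j``; the deviation
``delta_J_ij = J_ij + h_i h_j`` therefore quantifies synergy (positive)
or antagonism (negative) directly from the fit.

The model is a weighted linear least squares over one row per distinct
(already pooled) combination. Weights default to the pooled sample size
(a binomial-precision proxy), so large pooled trials constrain the fit
more. Rank-deficient systems take the minimum-norm solution, and
variables with no support (an agent or pair absent from every remaining
combination) are flagged un-estimable rather than silently zeroed.

``TwoAgentModel`` follows the scikit-learn estimator protocol: ``fit``
takes combinations with observed response probabilities, fitted
parameters land in trailing-underscore attributes, and ``predict``
returns clipped probabilities for arbitrary combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations as _pairs
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .trial_io import Combination, TrialValidationError

__all__ = [
    "DesignMatrix",
    "TwoAgentModel",
    "build_design",
    "fit_two_agent",
    "loocv",
]

NOT_PREDICTABLE = float("nan")


@dataclass
class DesignMatrix:
    """Binary combination-by-variable design for the 2-agent model.

    Variables are ordered deterministically: single-agent terms ``h`` for
    every agent (alphabetical), then pairwise terms ``J`` for every agent
    pair co-occurring in at least one combination (lexicographic).
    """

    combinations: list[Combination]
    agents: list[str]
    pairs: list[tuple[str, str]]
    matrix: np.ndarray  # shape (n_combinations, n_agents + n_pairs)

    @property
    def variables(self) -> list[str]:
        return [f"h[{a}]" for a in self.agents] + [f"J[{a}|{b}]" for a, b in self.pairs]

    @property
    def n_variables(self) -> int:
        return self.matrix.shape[1]

    def row_for(self, combo: Combination) -> np.ndarray | None:
        """Design row for an arbitrary combination; None if any variable
        (agent or internal pair) is absent from the design."""
        row = np.zeros(self.n_variables, dtype=float)
        agent_idx = {a: i for i, a in enumerate(self.agents)}
        pair_idx = {p: len(self.agents) + i for i, p in enumerate(self.pairs)}
        for a in combo.agents:
            if a not in agent_idx:
                return None
            row[agent_idx[a]] = 1.0
        for a, b in _pairs(combo.agents, 2):
            key = (a, b) if a < b else (b, a)
            if key not in pair_idx:
                return None
            row[pair_idx[key]] = 1.0
        return row


def build_design(combinations: Sequence[Combination]) -> DesignMatrix:
    """Construct the design over the distinct combinations given.

    A pairwise variable exists only for agent pairs that co-occur in at
    least one combination; a row for a size-k combination has k single
    terms and k(k-1)/2 pair terms set.
    """
    seen = set()
    for c in combinations:
        if c in seen:
            raise TrialValidationError(f"combination {c} appears more than once (pool first)")
        seen.add(c)
    agents = sorted({a for c in combinations for a in c.agents})
    pair_set = set()
    for c in combinations:
        for a, b in _pairs(c.agents, 2):
            pair_set.add((a, b) if a < b else (b, a))
    pairs = sorted(pair_set)

    agent_idx = {a: i for i, a in enumerate(agents)}
    pair_idx = {p: len(agents) + i for i, p in enumerate(pairs)}
    A = np.zeros((len(combinations), len(agents) + len(pairs)), dtype=float)
    for r, c in enumerate(combinations):
        for a in c.agents:
            A[r, agent_idx[a]] = 1.0
        for a, b in _pairs(c.agents, 2):
            A[r, pair_idx[(a, b) if a < b else (b, a)]] = 1.0
    return DesignMatrix(combinations=list(combinations), agents=agents, pairs=pairs, matrix=A)


class TwoAgentModel(RegressorMixin, BaseEstimator):
    """Weighted least-squares fit of the 2-agent approximation.

    Parameters
    ----------
    weighting : {"pooled_n", "uniform"}
        "pooled_n" weights each combination by its pooled sample size
        (requires ``sample_weight`` at fit time or defaults to uniform);
        "uniform" ignores weights.
    clip : bool
        Clip predicted probabilities to [0, 1] (reported ORRs always are).

    Attributes
    ----------
    design_ : DesignMatrix
    h_ : dict mapping agent -> fitted single-agent response probability
    J_ : dict mapping (a, b) -> fitted pairwise correction
    delta_J_ : dict mapping (a, b) -> J_ab + h_a * h_b
    fitted_p_ : ndarray of in-sample fitted probabilities (clipped)
    residuals_ : ndarray, fitted (unclipped) minus observed
    unestimable_ : set of variable labels with zero column support
    """

    def __init__(self, weighting: str = "pooled_n", clip: bool = True):
        self.weighting = weighting
        self.clip = clip

    def fit(self, X: Sequence[Combination], y, sample_weight=None) -> "TwoAgentModel":
        """Fit to distinct combinations ``X`` with observed probabilities ``y``."""
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise TrialValidationError("X and y lengths differ")
        if np.any((y < 0) | (y > 1)):
            raise TrialValidationError("observed probabilities must lie in [0, 1]")
        design = build_design(list(X))
        A = design.matrix
        if sample_weight is None or self.weighting == "uniform":
            w = np.ones(len(y))
        else:
            w = np.asarray(sample_weight, dtype=float)
            if w.shape != y.shape:
                raise TrialValidationError("sample_weight shape mismatch")
            if np.any(w <= 0):
                raise TrialValidationError("weights must be positive")
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)

        support = A.sum(axis=0)
        labels = design.variables
        self.unestimable_ = {labels[m] for m in np.nonzero(support == 0)[0]}

        n_a = len(design.agents)
        self.design_ = design
        self.coef_ = coef
        self.h_ = dict(zip(design.agents, coef[:n_a]))
        self.J_ = dict(zip(design.pairs, coef[n_a:]))
        self.delta_J_ = {
            (a, b): self.J_[(a, b)] + self.h_[a] * self.h_[b] for a, b in design.pairs
        }
        raw = A @ coef
        self.residuals_ = raw - y
        self.fitted_p_ = np.clip(raw, 0.0, 1.0) if self.clip else raw
        return self

    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise TrialValidationError("model is not fitted")

    def predict(self, X: Sequence[Combination]) -> np.ndarray:
        """Predicted response probability per combination (NaN = not predictable)."""
        self._check_fitted()
        out = np.empty(len(X), dtype=float)
        unest = self.unestimable_
        labels = self.design_.variables
        for i, combo in enumerate(X):
            row = self.design_.row_for(combo)
            if row is None or any(labels[m] in unest for m in np.nonzero(row)[0]):
                out[i] = NOT_PREDICTABLE
                continue
            val = float(row @ self.coef_)
            out[i] = min(max(val, 0.0), 1.0) if self.clip else val
        return out

    def predict_orr2(self, combination: Combination) -> float:
        """Predicted ORR (percent, clipped to [0, 100]); NaN when not predictable."""
        p = self.predict([combination])[0]
        return 100.0 * p if np.isfinite(p) else NOT_PREDICTABLE

    def rank_pairs(self) -> list[tuple[tuple[str, str], float]]:
        """All co-occurring pairs ranked by predicted pair ORR, descending.

        Ties break alphabetically on the pair. Pairs never co-tested have
        no J variable and are absent by construction.
        """
        self._check_fitted()
        ranked = []
        for a, b in self.design_.pairs:
            orr2 = self.predict_orr2(Combination((a, b)))
            if np.isfinite(orr2):
                ranked.append(((a, b), orr2))
        return sorted(ranked, key=lambda t: (-t[1], t[0]))

    def bootstrap_pair_orr(
        self, X, y, sample_weight=None, n_boot: int = 200, seed: int = 0
    ) -> dict[tuple[str, str], dict[str, float]]:
        """Nonparametric bootstrap (resampling combinations) of pair ORR_2.

        Returns per-pair median and a central 90% interval, for rankings
        that acknowledge parameter uncertainty.
        """
        self._check_fitted()
        rng = np.random.default_rng(seed)
        X = list(X)
        y = np.asarray(y, dtype=float)
        w = None if sample_weight is None else np.asarray(sample_weight, dtype=float)
        samples: dict[tuple[str, str], list[float]] = {p: [] for p in self.design_.pairs}
        n = len(X)
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            # resampled rows may duplicate combinations; aggregate by mean
            agg: dict[Combination, list[int]] = {}
            for i in idx:
                agg.setdefault(X[i], []).append(i)
            Xb = list(agg)
            yb = np.array([y[list(v)].mean() for v in agg.values()])
            wb = None if w is None else np.array([w[list(v)].sum() for v in agg.values()])
            m = TwoAgentModel(weighting=self.weighting, clip=self.clip)
            try:
                m.fit(Xb, yb, sample_weight=wb)
            except np.linalg.LinAlgError:  # pragma: no cover
                continue
            for pair in samples:
                if pair in m.design_.pairs:
                    val = m.predict_orr2(Combination(pair))
                    if np.isfinite(val):
                        samples[pair].append(val)
        out = {}
        for pair, vals in samples.items():
            if vals:
                arr = np.asarray(vals)
                out[pair] = {
                    "median": float(np.median(arr)),
                    "q05": float(np.quantile(arr, 0.05)),
                    "q95": float(np.quantile(arr, 0.95)),
                    "n_boot": len(vals),
                }
        return out


def fit_two_agent(
    combinations: Sequence[Combination],
    observed_p: Sequence[float],
    weights: Sequence[float] | None = None,
    weighting: str = "pooled_n",
) -> TwoAgentModel:
    """Thin functional wrapper over :class:`TwoAgentModel`."""
    return TwoAgentModel(weighting=weighting).fit(combinations, observed_p, sample_weight=weights)


@dataclass
class LoocvResult:
    """Leave-one-out cross-validation of the 2-agent approximation."""

    combinations: list[Combination]
    orr0: np.ndarray               # observed pooled ORR per combination
    orr2: np.ndarray               # held-out prediction (NaN = not predictable)
    underestimation: dict[str, float] = field(default_factory=dict)
    n_not_predictable: int = 0

    def frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "combination": [str(c) for c in self.combinations],
                "num_agents": [c.size for c in self.combinations],
                "ORR_0": self.orr0,
                "ORR_2": self.orr2,
            }
        )


def loocv(
    combinations: Sequence[Combination],
    observed_p: Sequence[float],
    weights: Sequence[float] | None = None,
    weighting: str = "pooled_n",
) -> LoocvResult:
    """Hold out each combination, refit, and predict its ORR.

    Reports the fraction of combinations whose held-out prediction falls
    below the observed pooled estimate (``ORR_2 < ORR_0``), stratified by
    combination size (1, 2, >= 3). A held-out combination whose variables
    lose identification after removal is counted as not predictable and
    excluded from the fractions.
    """
    combos = list(combinations)
    y = np.asarray(observed_p, dtype=float)
    w = None if weights is None else np.asarray(weights, dtype=float)
    n = len(combos)
    orr2 = np.full(n, np.nan)
    if n >= 2:
        for i in range(n):
            keep = [j for j in range(n) if j != i]
            model = TwoAgentModel(weighting=weighting).fit(
                [combos[j] for j in keep], y[keep],
                sample_weight=None if w is None else w[keep],
            )
            orr2[i] = model.predict_orr2(combos[i])
    orr0 = 100.0 * y

    strata = {"1": lambda k: k == 1, "2": lambda k: k == 2, "3+": lambda k: k >= 3}
    fractions: dict[str, float] = {}
    for name, sel in strata.items():
        mask = np.array([sel(c.size) for c in combos]) & np.isfinite(orr2)
        if mask.sum() > 0:
            fractions[name] = float(np.mean(orr2[mask] < orr0[mask]))
    return LoocvResult(
        combinations=combos,
        orr0=orr0,
        orr2=orr2,
        underestimation=fractions,
        n_not_predictable=int(np.sum(~np.isfinite(orr2))),
    )
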