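"""Canned validation experiments for the inference pipeline.

These are the study protocols used to characterize the methodology on
synthetic data with known ground truth: type-I calibration of the
null-model test, the power-surface sweep over sample sizes, parameter
recovery of the 2-agent approximation, and the leave-one-out lower-bound
behavior under injected higher-order synergy. Each function is
deterministic given its seed and returns plain numbers, so the same
protocols back both the test suite and the reproduction script.
"""

from __future__ import annotations

from itertools import combinations as _pairs

import numpy as np

from .interaction import classify_pair
from .pooling import pool_equivalent
from .power import mean_band_width, simulate_null_discrimination
from .synthetic import generate_trials, generate_truth
from .trial_io import Combination, TrialRecord, group_by_combination
from .two_agent import TwoAgentModel, loocv

__all__ = [
    "null_calibration",
    "power_band_widths",
    "noiseless_recovery_error",
    "rmse_h_by_trial_size",
    "loocv_lower_bound",
]


def null_calibration(
    n_datasets: int = 2000,
    N_pair: int = 200,
    N_single_total: int = 1000,
    seed: int = 0,
    alpha_level: float = 0.05,
) -> dict[str, float]:
    """Type-I behavior of the pair test when the pair responds at the null.

    Each replicate dataset holds two single-agent trials per agent
    (pooling to ``N_single_total`` patients, so the plug-in null
    probability is well estimated) and one pair trial of ``N_pair``
    patients whose true response probability is exactly the Bliss null.
    Returns the label rates over replicates; with a calibrated test the
    synergy rate stays at or below ``alpha_level`` (the exact tail is
    conservative under discreteness).
    """
    rng = np.random.default_rng(seed)
    half = N_single_total // 2
    labels = {"synergistic": 0, "antagonistic": 0, "non-interacting": 0,
              "not evaluable": 0}
    pair = Combination(("a", "b"))
    for _ in range(n_datasets):
        p1, p2 = rng.uniform(size=2)
        q = 1.0 - (1.0 - p1) * (1.0 - p2)
        trials = []
        for agent, p in (("a", p1), ("b", p2)):
            for k in range(2):
                trials.append(
                    TrialRecord(f"{agent}{k}", (agent,), int(rng.binomial(half, p)), half, "sim")
                )
        trials.append(TrialRecord("ab", ("a", "b"), int(rng.binomial(N_pair, q)), N_pair, "sim"))
        res = classify_pair(trials, pair, alpha_level=alpha_level)
        labels[res.label] += 1
    evaluable = n_datasets - labels["not evaluable"]
    return {
        "synergy_rate": labels["synergistic"] / evaluable,
        "antagonism_rate": labels["antagonistic"] / evaluable,
        "non_interacting_rate": labels["non-interacting"] / evaluable,
        "n_datasets": n_datasets,
        "n_evaluable": evaluable,
    }


def power_band_widths(
    sample_sizes=(100, 500, 1000), reps: int = 100_000, seed: int = 0
) -> dict[int, float]:
    """Mean width of the non-discriminable diagonal band at each sample size."""
    return {
        N: mean_band_width(simulate_null_discrimination(N, reps=reps, seed=seed))
        for N in sample_sizes
    }


def _bliss(hs) -> float:
    p = 1.0
    for h in hs:
        p *= 1.0 - h
    return 1.0 - p


def noiseless_recovery_error(n_agents: int = 6, seed: int = 0) -> float:
    """Max |parameter error| refitting an exactly linear full-rank system."""
    rng = np.random.default_rng(seed)
    agents = [f"a{i}" for i in range(n_agents)]
    h = dict(zip(agents, rng.uniform(0.1, 0.5, n_agents)))
    J = {p: float(rng.uniform(-0.1, 0.1)) for p in _pairs(agents, 2)}
    X = [Combination((a,)) for a in agents] + [Combination(p) for p in _pairs(agents, 2)]
    y = []
    for c in X:
        val = sum(h[a] for a in c.agents) + sum(J[p] for p in _pairs(c.agents, 2))
        y.append(val)
    m = TwoAgentModel().fit(X, np.clip(y, 0, 1))
    errs = [abs(m.h_[a] - h[a]) for a in agents]
    errs += [abs(m.J_[p] - J[p]) for p in _pairs(agents, 2)]
    return float(max(errs))


def rmse_h_by_trial_size(
    trial_sizes=(10, 100, 1000),
    n_agents: int = 10,
    n_trials: int = 120,
    seed: int = 0,
) -> dict[int, float]:
    """RMSE of recovered single-agent rates vs per-trial sample size.

    Trials cover singles and pairs only, where the 2-agent model is exact,
    so the error is purely binomial-noise-driven and shrinks with N.
    """
    truth = generate_truth(n_agents, mab_fraction=0.0, interaction_density=0.0, seed=seed)
    out: dict[int, float] = {}
    for N in trial_sizes:
        ds = generate_trials(
            truth, n_trials, size_distribution={1: 0.5, 2: 0.5},
            N_range=(N, N), seed=seed + 1,
        )
        X, y, w = [], [], []
        for combo, tl in group_by_combination(ds.trials).items():
            post = pool_equivalent(tl)
            X.append(combo)
            y.append(post.mean)
            w.append(post.alpha + post.beta_param)
        m = TwoAgentModel().fit(X, y, sample_weight=w)
        errs = [m.h_[a] - truth.agents[a] for a in m.h_]
        out[N] = float(np.sqrt(np.mean(np.square(errs))))
    return out


def loocv_lower_bound(
    n_agents: int = 6,
    higher_order_boost: float = 1.25,
    pooled_n_by_size={1: 2000, 2: 1000, 3: 200},
    seed: int = 0,
) -> dict[str, float]:
    """LOOCV underestimation with positive synergy injected above pair order.

    Singles and pairs follow the exactly linear model and carry large
    pooled samples (as in pooled trial data, where low-order regimens are
    tested most), pinning the single-agent and pairwise terms. Triples
    respond at ``higher_order_boost`` times their Bliss composition —
    structure the pairwise model cannot express — so their held-out
    predictions fall below the observed rates: the lower-bound regime.
    Held-out pairs behave oppositely (their only anchoring row is the one
    removed, leaving the boosted triples to set the pairwise term), so
    the lower bound is read off the size-3 stratum.
    """
    rng = np.random.default_rng(seed)
    agents = [f"a{i}" for i in range(n_agents)]
    h = dict(zip(agents, rng.uniform(0.15, 0.4, n_agents)))
    X = [Combination((a,)) for a in agents]
    X += [Combination(p) for p in _pairs(agents, 2)]
    X += [Combination(p) for p in _pairs(agents, 3)]
    y, w = [], []
    for c in X:
        p = _bliss([h[a] for a in c.agents])
        if c.size >= 3:
            p = min(0.99, p * higher_order_boost)
        N = pooled_n_by_size[c.size]
        y.append(rng.binomial(N, p) / N)
        w.append(N)
    res = loocv(X, y, w)
    finite = np.isfinite(res.orr2)
    out = {f"size_{k}": v for k, v in res.underestimation.items()}
    out["overall"] = float(np.mean(res.orr2[finite] < res.orr0[finite]))
    out["n_combinations"] = int(finite.sum())
    return out
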