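"""Synthetic trial datasets with known ground truth.

Emulates the structure of a pooled Phase II response-rate dataset: a
roster of agents with latent single-agent response probabilities ``h``,
sparse pairwise interactions expressed as multiplicative deviations from
the Bliss null (a pair with offset ``epsilon`` responds at
``min(1, q * (1 + epsilon))``), and trials with heterogeneous sample
sizes whose responder counts are binomial draws from the combination's
true response probability. For combinations of three or more agents the
true probability composes the Bliss null over all agents and then applies
every internal pairwise multiplier — higher-order structure a purely
pairwise model cannot fully capture, mirroring the regime where the
2-agent approximation behaves as a lower bound.

Optional per-combination class overrides assign alternating response
probabilities across trials of one combination, creating the
heterogeneous response-rate classes the equivalence partition is meant
to detect.

What this generator does NOT emulate: publication bias, patient dropout,
response-measurement error, or dose/schedule covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations as _pairs
from typing import Mapping, Sequence

import numpy as np

from .trial_io import AgentRegistry, Combination, TrialRecord, TrialValidationError

__all__ = ["SyntheticTruth", "SyntheticDataset", "generate_truth", "generate_trials"]


@dataclass
class SyntheticTruth:
    """Ground-truth parameters behind a synthetic dataset."""

    agents: dict[str, float]                       # name -> true h
    mab_agents: frozenset[str]
    interactions: dict[tuple[str, str], float]     # sorted pair -> epsilon
    class_overrides: dict[Combination, tuple[float, ...]] = field(default_factory=dict)
    seed: int = 0

    def registry(self) -> AgentRegistry:
        reg = AgentRegistry()
        for name in self.agents:
            reg.register(name, is_monoclonal_antibody=name in self.mab_agents)
        return reg

    def true_probability(self, combination: Combination) -> float:
        """Bliss composition of h's with pairwise multipliers, clipped to [0, 1]."""
        if combination in self.class_overrides:
            raise TrialValidationError(
                f"{combination} uses class overrides; probability is per-trial"
            )
        return self._bliss_with_interactions(combination)

    def _bliss_with_interactions(self, combination: Combination) -> float:
        p = 1.0
        for a in combination.agents:
            if a not in self.agents:
                raise TrialValidationError(f"agent {a!r} not in truth")
            p *= 1.0 - self.agents[a]
        q = 1.0 - p
        for a, b in _pairs(combination.agents, 2):
            eps = self.interactions.get((a, b) if a < b else (b, a), 0.0)
            q *= 1.0 + eps
        return float(min(1.0, max(0.0, q)))


@dataclass
class SyntheticDataset:
    """Generated trials plus the truth and configuration that produced them."""

    trials: list[TrialRecord]
    truth: SyntheticTruth
    provenance: dict


def generate_truth(
    num_agents: int,
    mab_fraction: float = 0.2,
    interaction_density: float = 0.1,
    epsilon_range: tuple[float, float] = (-0.5, 0.5),
    seed: int = 0,
    h_range: tuple[float, float] = (0.05, 0.5),
) -> SyntheticTruth:
    """Draw a ground truth: h per agent, mAb flags, sparse pairwise offsets.

    ``h ~ Uniform(h_range)`` per agent; a ``mab_fraction`` share of agents
    is flagged as monoclonal antibodies (their names get the INN ``-mab``
    suffix); each agent pair independently carries an interaction with
    probability ``interaction_density``, with offset
    ``epsilon ~ Uniform(epsilon_range)``.
    """
    if num_agents < 1:
        raise TrialValidationError("num_agents must be >= 1")
    if not 0.0 <= mab_fraction <= 1.0 or not 0.0 <= interaction_density <= 1.0:
        raise TrialValidationError("fractions must lie in [0, 1]")
    if epsilon_range[0] > epsilon_range[1] or h_range[0] > h_range[1]:
        raise TrialValidationError("ranges must be (low, high) with low <= high")
    rng = np.random.default_rng(seed)
    n_mab = int(round(mab_fraction * num_agents))
    mab_idx = set(rng.choice(num_agents, size=n_mab, replace=False).tolist())
    names = [
        f"agent{i:03d}mab" if i in mab_idx else f"agent{i:03d}"
        for i in range(num_agents)
    ]
    hs = rng.uniform(h_range[0], h_range[1], size=num_agents)
    agents = dict(zip(names, hs.tolist()))
    mabs = frozenset(names[i] for i in mab_idx)

    interactions: dict[tuple[str, str], float] = {}
    for a, b in _pairs(sorted(names), 2):
        if rng.uniform() < interaction_density:
            interactions[(a, b)] = float(rng.uniform(*epsilon_range))
    return SyntheticTruth(
        agents=agents, mab_agents=mabs, interactions=interactions, seed=seed
    )


def generate_trials(
    truth: SyntheticTruth,
    num_trials: int,
    size_distribution: Mapping[int, float] | Sequence[float] | None = None,
    N_range: tuple[int, int] = (20, 100),
    seed: int = 0,
    cancer_types: Sequence[str] = ("synthetic",),
) -> SyntheticDataset:
    """Sample trials: combination size, agents, sample size, binomial outcome.

    ``size_distribution`` gives weights over combination sizes (default
    favors small combinations, sizes 1-4); sizes exceeding the agent
    roster are rejected. Trials of a combination with class overrides
    cycle through the override probabilities in generation order.
    """
    if num_trials < 0:
        raise TrialValidationError("num_trials must be >= 0")
    names = sorted(truth.agents)
    if size_distribution is None:
        size_distribution = {1: 0.45, 2: 0.35, 3: 0.15, 4: 0.05}
    if not isinstance(size_distribution, Mapping):
        size_distribution = {i + 1: w for i, w in enumerate(size_distribution)}
    sizes = sorted(size_distribution)
    weights = np.array([size_distribution[s] for s in sizes], dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise TrialValidationError("size weights must be non-negative with positive sum")
    if max(sizes) > len(names):
        raise TrialValidationError(
            f"size {max(sizes)} exceeds the {len(names)}-agent roster"
        )
    weights = weights / weights.sum()
    lo, hi = N_range
    if lo < 1 or hi < lo:
        raise TrialValidationError("N_range must be (low, high) with 1 <= low <= high")

    rng = np.random.default_rng(seed)
    trials: list[TrialRecord] = []
    override_cursor: dict[Combination, int] = {}
    clipped = 0
    for t in range(num_trials):
        size = int(rng.choice(sizes, p=weights))
        chosen = tuple(sorted(rng.choice(names, size=size, replace=False).tolist()))
        combo = Combination(chosen)
        if combo in truth.class_overrides:
            opts = truth.class_overrides[combo]
            k = override_cursor.get(combo, 0)
            p = float(opts[k % len(opts)])
            override_cursor[combo] = k + 1
        else:
            p_raw = truth._bliss_with_interactions(combo)
            p = p_raw
            if p_raw >= 1.0:
                clipped += 1
        N = int(rng.integers(lo, hi + 1))
        n = int(rng.binomial(N, p))
        trials.append(
            TrialRecord(
                trial_id=f"t{t:05d}",
                agents=chosen,
                n_responders=n,
                sample_size=N,
                cancer_type=str(cancer_types[t % len(cancer_types)]),
            )
        )
    provenance = {
        "num_trials": num_trials,
        "size_distribution": {int(s): float(w) for s, w in zip(sizes, weights)},
        "N_range": [int(lo), int(hi)],
        "seed": int(seed),
        "truth_seed": int(truth.seed),
        "n_clipped_probabilities": clipped,
    }
    return SyntheticDataset(trials=trials, truth=truth, provenance=provenance)
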