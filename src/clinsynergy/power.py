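"""Monte-Carlo characterization of the null-model test's discrimination power.

Each replicate simulates a two-drug trial triple at sample size ``N``:
true response probabilities ``p1, p2, p12 ~ Uniform(0, 1)``, observed
counts ``n1, n2, n12 ~ Binomial(N, .)``, plug-in estimates
``p0_k = n_k / N`` and the estimated null probability
``q0_12 = 1 - (1 - p0_1)(1 - p0_2)``. The tail p-values at
``(n12, N, q0_12)`` decide whether the replicate would have been called
non-interacting. Replicates are tallied on a (ORR_1, ORR_0) grid — i.e.
``(q0_12, n12/N)`` — with configurable bin width, so the fraction of
non-interacting calls per bin maps out the region around the diagonal
where the test cannot discriminate. A replicate above the diagonal is
non-interacting when ``p_synergy >= 0.05``, below when
``p_antagonism >= 0.05``; points exactly on the diagonal count as
non-interacting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PowerGrid", "simulate_null_discrimination", "white_region_width"]


@dataclass
class PowerGrid:
    """Binned tallies of simulated (ORR_1, ORR_0) pairs at one sample size."""

    sample_size: int
    bin_width: float
    totals: np.ndarray            # [i_orr1, i_orr0] replicate counts
    non_interacting: np.ndarray   # same shape, replicates deemed non-interacting
    reps: int
    seed: int
    alpha_level: float = 0.05

    @property
    def n_bins(self) -> int:
        return self.totals.shape[0]

    def fraction(self) -> np.ndarray:
        """Per-bin fraction of non-interacting calls (NaN where empty)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.totals > 0, self.non_interacting / self.totals, np.nan)

    def to_frame(self) -> pd.DataFrame:
        edges = np.arange(self.n_bins) * self.bin_width
        i, j = np.nonzero(self.totals)
        return pd.DataFrame(
            {
                "bin_orr1": edges[i],
                "bin_orr0": edges[j],
                "total": self.totals[i, j],
                "non_interacting": self.non_interacting[i, j],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def simulate_null_discrimination(
    N: int,
    reps: int = 100_000,
    seed: int = 0,
    bin_width: float = 0.01,
    alpha_level: float = 0.05,
    chunk: int = 1_000_000,
) -> PowerGrid:
    """Run the replicate simulation and tally the discrimination grid."""
    if N < 1 or reps < 1:
        raise ValueError("N and reps must be >= 1")
    n_bins = int(round(1.0 / bin_width))
    totals = np.zeros((n_bins, n_bins), dtype=np.int64)
    non_int = np.zeros((n_bins, n_bins), dtype=np.int64)
    rng = np.random.default_rng(seed)

    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        p1 = rng.uniform(size=m)
        p2 = rng.uniform(size=m)
        p12 = rng.uniform(size=m)
        n1 = rng.binomial(N, p1)
        n2 = rng.binomial(N, p2)
        n12 = rng.binomial(N, p12)
        p0_1 = n1 / N
        p0_2 = n2 / N
        p0_12 = n12 / N
        q0 = 1.0 - (1.0 - p0_1) * (1.0 - p0_2)

        p_syn = stats.binom.sf(n12 - 1, N, q0)
        p_ant = stats.binom.cdf(n12, N, q0)
        above = p0_12 > q0
        below = p0_12 < q0
        noninteracting = np.ones(m, dtype=bool)      # on-diagonal counts as null
        noninteracting[above] = p_syn[above] >= alpha_level
        noninteracting[below] = p_ant[below] >= alpha_level

        i = np.minimum((q0 / bin_width).astype(int), n_bins - 1)
        j = np.minimum((p0_12 / bin_width).astype(int), n_bins - 1)
        np.add.at(totals, (i, j), 1)
        np.add.at(non_int, (i, j), noninteracting.astype(np.int64))
        done += m

    return PowerGrid(
        sample_size=N, bin_width=bin_width, totals=totals,
        non_interacting=non_int, reps=reps, seed=seed, alpha_level=alpha_level,
    )


def white_region_width(grid: PowerGrid, orr1_slice: float,
                       threshold: float = 0.5) -> float:
    """Width (ORR_0 units) of the non-discriminable band at a given ORR_1.

    Scans the grid column nearest ``orr1_slice`` outward from the diagonal
    and measures the contiguous run of bins whose non-interacting fraction
    is at least ``threshold``. Returns NaN when the slice holds no data.
    """
    frac = grid.fraction()
    i = min(int(orr1_slice / grid.bin_width), grid.n_bins - 1)
    col = frac[i, :]
    if np.all(np.isnan(col)):
        return float("nan")
    j0 = i  # diagonal bin
    ok = col >= threshold
    if not (np.isnan(col[j0]) or ok[j0]):
        return 0.0
    lo = j0
    while lo - 1 >= 0 and (ok[lo - 1] or np.isnan(col[lo - 1])):
        lo -= 1
    hi = j0
    while hi + 1 < grid.n_bins and (ok[hi + 1] or np.isnan(col[hi + 1])):
        hi += 1
    return (hi - lo + 1) * grid.bin_width


def mean_band_width(grid: PowerGrid, slices=None) -> float:
    """Mean white-band width over interior ORR_1 slices (diagnostic summary)."""
    if slices is None:
        slices = np.arange(0.1, 0.91, 0.05)
    widths = [white_region_width(grid, s) for s in slices]
    widths = [w for w in widths if not np.isnan(w)]
    return float(np.mean(widths)) if widths else float("nan")
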