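# Methods

This note records the statistical model behind `clinsynergy`, the
parameters that matter, the numerical choices, and the limits of what
the synthetic-data experiments demonstrate.

## Data model and pooling

The unit of data is a trial arm: a set of agents, `n` responders out of
`N` patients, and a cancer-type label. Responses are modeled as
binomial, `n ~ Binom(N, p)`, giving the conjugate beta posterior for the
response probability with `alpha = n`, `beta = N − n`. This is the
Haldane-prior posterior: its mean is exactly `n/N`, which is the
quantity every downstream step consumes. At the boundaries (`n = 0` or
`n = N`) that density is improper; the reported mean is unaffected, and
any sampling or quantile computation substitutes the Jeffreys posterior
`Beta(n + 1/2, N − n + 1/2)`, which is always proper. Pooling trials of
one combination sums the counts, so the pooled mean is `Σn_i / ΣN_i`.

### Equivalence partition

Whether trials of one combination share a single response rate is a
Bayesian model-selection problem over set partitions of the trial list.
A group `g` is scored by its beta-binomial marginal likelihood under a
proper uniform prior `Beta(a0=1, b0=1)`:

    log m(g) = Σ_{i∈g} log C(N_i, n_i)
             + log B(Σn_i + a0, Σ(N_i − n_i) + b0) − log B(a0, b0)

and a partition by the sum of its group scores. All set partitions are
searched exhaustively up to 8 trials (Bell(8) = 4,140); beyond that a
greedy agglomerative merge from singletons is used, merging while the
score does not decrease. A multi-group partition is accepted only when
it beats the single-group score by more than a log-Bayes-factor
threshold, default `log 10` ("strong" evidence); ties break toward
fewer groups. The threshold is a tunable (`log_bf_threshold`) because
it directly trades sensitivity to dose/subtype heterogeneity against
pooling power.

Discordant combinations are resolved conservatively: if every group
holds a single trial, no report corroborates any other and the
combination is excluded; otherwise the group(s) with the fewest trials
are dropped (all of them when tied — if that empties the combination it
is excluded).

Simulation behavior (seeded tests): four trials drawn from one `p = 0.3`
at `N = 100` are declared equivalent in ≥ 90% of replicates, and trials
split between `p = 0.1` and `p = 0.7` are split into two groups in
≥ 90% of replicates.

## The non-interaction null and the pair test

Under Bliss independence the pair null is
`q_ij = 1 − (1 − p_i)(1 − p_j)`, with `p_i`, `p_j` the pooled
single-agent posterior means (only trials testing the agent alone are
used; pair pooling uses only exact-pair trials, consistent with the
null's derivation). The synergy and antagonism evidence are exact
binomial tails at the pooled pair counts, both inclusive of the
observed count, so `p_syn + p_ant = 1 + Binom(n; N, q)` holds to
machine precision (asserted at 1e-12 in tests). Labels require both the
tail (`< 0.05` by default) and the matching effect direction
(`ORR_0 > ORR_1` for synergy). No multiple-testing correction is
applied by default, matching how such catalogs are conventionally
printed at raw thresholds; a Benjamini-Hochberg flag exists for modern
use and defaults off.

### Calibration and the plug-in limitation

The test is exact in `q`, but `q` is a plug-in built from estimated
single-agent means, and that estimation noise inflates both tails. This
is a real limitation of the method, not of the implementation: with
single agents pooling only ~200 patients each, the measured
synergy-label rate at the null is ~7.5% rather than ≤ 5%. The
calibration experiment therefore uses study conditions in which each
single agent pools 1,000 patients (two trials of 500) against a pair
trial of `N = 200` — the regime the method assumes, where single-agent
rates are far better determined than the pair count. Under those
conditions the synergy-label rate over 2,000 replicate datasets is
~4%, within the nominal level. Two one-sided α = 0.05 tests bound the
total false-label rate at 10%; exact computation at `N = 200` puts it
near 8.5% (discreteness at that size is mild), so the null-recovery
tests assert the provable ≥ 90% non-interacting rate.

## Power surface

The discrimination power of the pair test is mapped by simulation: per
replicate, `p1, p2, p12 ~ Uniform(0, 1)`, counts `n1, n2, n12 ~
Binom(N, ·)`, plug-in estimates `p0_k = n_k/N`, estimated null
`q0 = 1 − (1 − p0_1)(1 − p0_2)`, and the tails evaluated at
`(n12, N, q0)`. Replicates are tallied on a (ORR₁, ORR₀) grid with
0.01-wide bins; a replicate above the diagonal counts as non-interacting
when `p_synergy ≥ 0.05`, below when `p_antagonism ≥ 0.05`, and exactly
on the diagonal always (the diagonal is the null itself, so this
tie-break is the conservative choice). The summary statistic is the
width of the contiguous band around the diagonal where the
non-interacting fraction is ≥ 0.5. The default is 10⁵ replicates per
sample size — band widths at 0.01 granularity are stable well below
that — and the sweep over N ∈ {100, 500, 1000} shows the band narrowing
strictly (≈ 0.15 → 0.07 → 0.05 in ORR units), i.e. larger trials let
the test discriminate smaller interaction effects. Grids are bit-
reproducible given (seed, chunk size); the seed is stored in the grid.

## 2-agent approximation

The linear model `p_c = Σ s_ci h_i + Σ s_ci s_cj J_ij` is fit by
weighted least squares over one row per pooled combination. The design
has one `h` variable per agent (alphabetical) and one `J` variable per
agent pair co-occurring in at least one combination (lexicographic), so
a size-k row has k + k(k−1)/2 ones. Choices:

- **Weights** `w_c` = pooled sample size `ΣN`, the binomial-precision
  proxy — larger pooled samples constrain the fit more. A `uniform`
  mode exists for sensitivity checks. The solution is invariant to
  weight rescaling.
- **No box constraints** on `h` or `J`; the solver stays linear and
  deterministic (`numpy.linalg.lstsq`, minimum-norm on rank-deficient
  systems). Predictions are clipped to [0, 1] afterward.
- **Un-estimable variables** (zero column support) are flagged, and any
  prediction touching them returns a not-predictable marker (NaN)
  rather than a silent zero.
- Expanding the no-interaction composition `p_c = 1 − Π(1 − h_i)` to
  second order gives `J⁰_ij = −h_i h_j`, so `ΔJ_ij = J_ij + h_i h_j` is
  the interaction score; its sign tracks injected multiplicative
  interactions of size |ε| = 0.3 in ≥ 80% of replicates at N = 500.
- Point estimates are reported; an optional nonparametric bootstrap
  (resampling combinations, default 200 replicates, seeded) supplies
  medians and 90% intervals for pair rankings.

### Leave-one-out cross-validation

Each combination's row is removed, the model refit, and its ORR₂
predicted; rows whose variables lose identification are counted
separately. The lower-bound experiment injects positive synergy above
pair order: singles and pairs are exactly linear with large pooled
samples (2,000 / 1,000), triples respond at 1.25 × their Bliss
composition with small pooled samples (200). Held-out triples are then
under-predicted in 70–100% of cases across seeds (~80% typically) —
the lower-bound regime. Held-out pairs in this synthetic design behave
oppositely: a pair's only anchoring row is the one removed, so its `J`
is set by the boosted triples and the pair is over-predicted. That is
an artifact of making pairs exactly linear, so the lower-bound claim is
read off the stratum that actually carries the injected synergy.

## Cohort statistics

Trend summaries stratify pooled combinations by size and report the
median with an empirical 5th–95th percentile band using nearest-rank
(type-1) quantiles; this "90% interval" is a spread across
combinations, not a sampling interval, and is named accordingly in
outputs. Whether medians are taken over combinations (default) or over
trials is a flag. Distribution comparisons (e.g. monoclonal-antibody
vs other combinations) use the two-sample Kolmogorov-Smirnov test with
the asymptotic p-value; enrichment of antibodies among synergistic
pairs uses Fisher's exact test on the (has mAb) × (synergistic) table
over all evaluable pairs. Monoclonal antibodies are identified by an
explicit registry flag, falling back to the INN `-mab` name suffix.

## Synthetic data

The generator emulates the structure of a pooled Phase II dataset:
per-agent latent rates `h ~ Uniform(0.05, 0.5)` (the range typical of
single-agent response rates), a configurable fraction of agents flagged
as monoclonal antibodies, sparse pairwise interactions applied
multiplicatively on the Bliss null (`p_pair = min(1, q(1 + ε))`), trial
sizes uniform on a configurable range (default 20–100 patients,
Phase II scale), and binomial outcomes. Combinations of size ≥ 3
compose the Bliss null over all agents and then apply every internal
pairwise multiplier — deliberately creating structure above pair order
so the 2-agent approximation's lower-bound behavior is exercised.
Per-combination class overrides cycle alternative response
probabilities across trials to create the heterogeneous classes the
equivalence partition detects. Identical seeds reproduce datasets
byte-for-byte.

Not emulated: publication bias, dropout, RECIST measurement error, dose
or schedule covariates. Passing tests on this generator therefore show
the machinery is correct and calibrated under its stated assumptions;
they do not show robustness to the reporting biases of real trial
literatures.

## Reference catalogs

`clinsynergy.reference` embeds published catalogs of 15 synergistic and
20 antagonistic two-agent combinations (with expected ORR₁, observed
ORR₀, tail p-values and standard-of-care annotations) plus the
headline figures of the pooled analysis they came from. Quantities that
would require the full curated trial-level dataset — which is not
redistributed — are marked `desk_scale=False`; the catalog-derived
counts (e.g. one antibody-containing pair among the synergistic 15, one
standard-of-care pair among the antagonistic 20) are recomputed from
the embedded tables by the package's own registry logic.

## Known limitations

- The plug-in null ignores uncertainty in the single-agent means; both
  tails inflate when single-agent pooled samples are small (see
  calibration above).
- Pooling is unadjusted: no dose, schedule or covariate modeling, and
  no random-effects heterogeneity beyond the discrete partition.
- The 2-agent model truncates at pair order by construction; positive
  higher-order structure appears as systematic under-prediction rather
  than as an estimable term.
- The KS p-value is asymptotic; exact small-sample KS is out of scope.
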