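import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import betaln, gammaln

from clinsynergy import (
    TrialValidationError,
    TrialPartitioner,
    partition_trials,
    pool_equivalent,
    posterior_from_counts,
    resolve_discordant,
)


def _log_marginal(counts, a0=1.0, b0=1.0):
    """Independent oracle: log beta-binomial marginal likelihood of one group."""
    n = sum(c[0] for c in counts)
    f = sum(c[1] - c[0] for c in counts)
    log_binom = sum(
        gammaln(N + 1) - gammaln(k + 1) - gammaln(N - k + 1) for k, N in counts
    )
    return log_binom + betaln(n + a0, f + b0) - betaln(a0, b0)


class TestPosterior:
    @pytest.mark.parametrize(
        "n,N,mean", [(30, 100, 0.30), (0, 50, 0.0), (13, 20, 0.65), (50, 50, 1.0)]
    )
    def test_mean_is_n_over_N(self, n, N, mean):
        post = posterior_from_counts(n, N)
        assert post.mean == pytest.approx(mean)
        assert post.orr == pytest.approx(100 * mean)

    def test_invalid_counts(self):
        with pytest.raises(TrialValidationError):
            posterior_from_counts(5, 4)
        with pytest.raises(TrialValidationError):
            posterior_from_counts(0, 0)

    def test_degenerate_counts_still_sample_properly(self):
        rng = np.random.default_rng(0)
        draws = posterior_from_counts(0, 50).sample(1000, rng)
        assert np.all((draws >= 0) & (draws <= 1))
        assert draws.mean() < 0.05  # Jeffreys substitute stays near 0


class TestPoolEquivalent:
    def test_pooled_counts(self, make_trials):
        trials = [make_trials("t1", ("a",), 10, 50), make_trials("t2", ("a",), 20, 50)]
        post = pool_equivalent(trials)
        assert (post.alpha, post.beta_param) == (30.0, 70.0)
        assert post.orr == pytest.approx(30.0)

    def test_single_trial_matches_posterior_from_counts(self, make_trials):
        post = pool_equivalent([make_trials("t1", ("a",), 13, 20)])
        assert post == posterior_from_counts(13, 20)

    def test_extreme_trials_average(self, make_trials):
        trials = [make_trials("t1", ("a",), 0, 10), make_trials("t2", ("a",), 10, 10)]
        assert pool_equivalent(trials).mean == pytest.approx(0.5)

    def test_mixed_combinations_rejected(self, make_trials):
        trials = [make_trials("t1", ("a",), 1, 10), make_trials("t2", ("b",), 1, 10)]
        with pytest.raises(TrialValidationError):
            pool_equivalent(trials)
        with pytest.raises(TrialValidationError):
            pool_equivalent([])

    @given(
        counts=st.lists(
            st.tuples(st.integers(0, 50), st.integers(1, 50)).map(
                lambda t: (min(t), max(t)) if t[1] >= 1 else t
            ),
            min_size=1,
            max_size=6,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_pooled_mean_is_ratio_of_sums(self, counts):
        from clinsynergy import TrialRecord

        counts = [(min(n, N), max(N, 1)) for n, N in counts]
        trials = [
            TrialRecord(f"t{i}", ("a",), n, N, "ct") for i, (n, N) in enumerate(counts)
        ]
        post = pool_equivalent(trials)
        assert post.mean == pytest.approx(
            sum(n for n, _ in counts) / sum(N for _, N in counts)
        )


class TestPartition:
    def test_clearly_different_rates_split(self, make_trials):
        # oracle: two-group evidence must beat one group by > log 10
        counts = [(10, 100), (70, 100)]
        lone = _log_marginal(counts)
        split = _log_marginal([counts[0]]) + _log_marginal([counts[1]])
        assert split - lone > math.log(10)

        trials = [make_trials(f"t{i}", ("a",), n, N) for i, (n, N) in enumerate(counts)]
        part = partition_trials(trials)
        assert len(part.groups) == 2
        assert not part.equivalent

    def test_similar_rates_stay_together(self, make_trials):
        counts = [(30, 100), (32, 100)]
        lone = _log_marginal(counts)
        split = _log_marginal([counts[0]]) + _log_marginal([counts[1]])
        assert split - lone <= math.log(10)

        trials = [make_trials(f"t{i}", ("a",), n, N) for i, (n, N) in enumerate(counts)]
        part = partition_trials(trials)
        assert part.equivalent
        assert part.group_posteriors[0].mean == pytest.approx(62 / 200)

    def test_single_trial_is_equivalent(self, make_trials):
        part = partition_trials([make_trials("t1", ("a",), 5, 20)])
        assert part.equivalent

    @pytest.mark.parametrize("k", [2, 4, 8])
    def test_identical_copies_never_split(self, make_trials, k):
        trials = [make_trials(f"t{i}", ("a",), 30, 100) for i in range(k)]
        assert partition_trials(trials).equivalent

    def test_groups_cover_and_are_disjoint(self, make_trials):
        trials = [
            make_trials(f"t{i}", ("a",), n, 100)
            for i, n in enumerate([10, 12, 70, 72, 40])
        ]
        part = partition_trials(trials)
        flat = sorted(i for g in part.groups for i in g)
        assert flat == list(range(5))

    def test_greedy_regime_matches_structure(self, make_trials):
        # 10 trials > exhaustive limit: two well-separated clusters
        counts = [(10, 100)] * 5 + [(70, 100)] * 5
        trials = [make_trials(f"t{i}", ("a",), n, N) for i, (n, N) in enumerate(counts)]
        part = partition_trials(trials)
        assert sorted(len(g) for g in part.groups) == [5, 5]

    def test_recovery_homogeneous(self, make_trials):
        # trials from one p: declared equivalent in >= 90% of replicates
        rng = np.random.default_rng(42)
        hits = 0
        reps = 100
        for r in range(reps):
            ns = rng.binomial(100, 0.3, size=4)
            trials = [make_trials(f"t{i}", ("a",), int(n), 100) for i, n in enumerate(ns)]
            hits += partition_trials(trials).equivalent
        assert hits / reps >= 0.90

    def test_recovery_two_classes(self, make_trials):
        rng = np.random.default_rng(43)
        hits = 0
        reps = 100
        for r in range(reps):
            ns = [rng.binomial(100, 0.1), rng.binomial(100, 0.1),
                  rng.binomial(100, 0.7), rng.binomial(100, 0.7)]
            trials = [make_trials(f"t{i}", ("a",), int(n), 100) for i, n in enumerate(ns)]
            hits += len(partition_trials(trials).groups) == 2
        assert hits / reps >= 0.90


class TestResolveDiscordant:
    def test_majority_group_retained(self, make_trials):
        counts = [(30, 100), (31, 100), (29, 100), (80, 100)]
        trials = [make_trials(f"t{i}", ("a",), n, N) for i, (n, N) in enumerate(counts)]
        part = partition_trials(trials)
        assert sorted(len(g) for g in part.groups) == [1, 3]
        retained = resolve_discordant(part)
        assert len(retained) == 3
        assert all(t.n_responders < 50 for t in retained)

    def test_all_singleton_groups_exclude_combination(self, make_trials):
        trials = [
            make_trials("t0", ("a",), 5, 100),
            make_trials("t1", ("a",), 95, 100),
        ]
        part = partition_trials(trials)
        assert len(part.groups) == 2
        assert resolve_discordant(part) == []

    def test_equivalent_partition_retains_all(self, make_trials):
        trials = [make_trials(f"t{i}", ("a",), 30, 100) for i in range(4)]
        assert len(resolve_discordant(partition_trials(trials))) == 4

    def test_retained_size_zero_or_at_least_max_group(self, make_trials):
        rng = np.random.default_rng(7)
        for r in range(20):
            ns = rng.integers(0, 101, size=5)
            trials = [make_trials(f"t{i}", ("a",), int(n), 100) for i, n in enumerate(ns)]
            part = partition_trials(trials)
            retained = resolve_discordant(part)
            assert len(retained) == 0 or len(retained) >= max(len(g) for g in part.groups)


class TestTrialPartitioner:
    def test_estimator_protocol(self, make_trials):
        trials = [make_trials(f"t{i}", ("a",), n, 100) for i, n in enumerate([10, 12, 70])]
        est = TrialPartitioner()
        labels = est.fit_predict(trials)
        assert len(labels) == 3
        assert labels[0] == labels[1] != labels[2]
        assert est.equivalent_ is False
        params = est.get_params()
        est2 = TrialPartitioner().set_params(**params)
        assert est2.get_params() == params
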