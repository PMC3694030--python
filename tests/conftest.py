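import numpy as np
import pytest

from clinsynergy import AgentRegistry, Combination, TrialRecord


@pytest.fixture
def registry():
    reg = AgentRegistry()
    reg.register("docetaxel", synonyms=["taxotere"])
    reg.register("doxorubicin", synonyms=["adriamycin"])
    reg.register("rituximab", is_monoclonal_antibody=True)
    reg.register("alpha-interferon", is_monoclonal_antibody=False)
    reg.register("radiation")
    return reg


def make_trial(trial_id, agents, n, N, cancer_type="ct"):
    return TrialRecord(
        trial_id=trial_id,
        agents=tuple(agents),
        n_responders=n,
        sample_size=N,
        cancer_type=cancer_type,
    )


@pytest.fixture
def make_trials():
    return make_trial


@pytest.fixture
def trials_csv(tmp_path):
    """A small valid trials CSV on disk."""
    path = tmp_path / "trials.csv"
    path.write_text(
        "trial_id,agents,n_responders,sample_size,cancer_type\n"
        "t1,docetaxel;doxorubicin,13,20,breast\n"
        "t2,docetaxel,5,40,breast\n"
        "t3,doxorubicin,8,35,lung\n"
    )
    return path


def pair_dataset(p1, p2, p12, N_single, N_pair, seed, n_single_trials=2):
    """Trials for agents a, b alone and the pair, at the given probabilities."""
    rng = np.random.default_rng(seed)
    trials = []
    each = N_single // n_single_trials
    for agent, p in (("a", p1), ("b", p2)):
        for k in range(n_single_trials):
            trials.append(
                make_trial(f"{agent}{k}", (agent,), int(rng.binomial(each, p)), each)
            )
    trials.append(make_trial("ab", ("a", "b"), int(rng.binomial(N_pair, p12)), N_pair))
    return trials


@pytest.fixture
def make_pair_dataset():
    return pair_dataset
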