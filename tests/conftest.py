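import numpy as np
import pytest

from cagepheno import hmm as hmm_mod
from cagepheno import synth
from cagepheno.experiments import separated_state_config, simulate_separated_runs


@pytest.fixture(scope="session")
def small_cohort():
    """6-mouse aging cohort with faults, used across QC/feature tests."""
    cfg = synth.CohortConfig(n_mice=6, study_length=4.0, run_length_days=3,
                             seed=11)
    return synth.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def sep3():
    """Well-separated 3-state runs with planted analyzer offsets, plus a
    fitted robust HMM (shared by several recovery tests)."""
    config = separated_state_config(n_states=3, run_length_days=2)
    offsets = {"a0": np.array([0.5, -0.3, 0.2, -0.4, 0.3]),
               "a1": np.array([-0.5, 0.3, -0.2, 0.4, -0.3])}
    runs = simulate_separated_runs(config, 5, 2, offsets, seed=7)
    model = hmm_mod.fit_robust_hmm(runs, 3, n_restarts=2, max_iter=40, seed=0)
    return {"config": config, "offsets": offsets, "runs": runs, "model": model}
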