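"""Shared helpers for the numbered analysis drivers.

Each driver rebuilds its upstream stages deterministically from the same
seed, so the scripts can be run independently and in any order.
"""

from pathlib import Path

from cagepheno import hmm as hmm_mod
from cagepheno import qc as qc_mod
from cagepheno import synth

SEED = 7
RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"


def demo_config(n_mice: int = 40) -> synth.CohortConfig:
    return synth.CohortConfig(n_mice=n_mice, study_length=6.0,
                              run_length_days=3, seed=SEED)


def get_cohort(with_genetics: bool = False):
    import numpy as np
    return synth.simulate_cohort(demo_config(), with_genetics=with_genetics,
                                 h2_targets=np.full(14, 0.3))


def get_cleaned_runs(cohort):
    res = qc_mod.qc_pipeline(cohort["runs"])
    return res["runs"], res["reports"]


def get_states(cleaned_runs, n_states: int = 6):
    model = hmm_mod.fit_robust_hmm(cleaned_runs, n_states, n_restarts=2,
                                   max_iter=30, seed=SEED)
    sequences = [hmm_mod.decode(model, r) for r in cleaned_runs]
    return model, sequences


def outdir() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS
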