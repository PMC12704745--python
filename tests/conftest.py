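import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)

from bodymeta import (DesignSpec, SDTObserverParams, DDMObserverParams,
                      simulate_sdt_dataset, simulate_ddm_trials)


@pytest.fixture(scope="session")
def sdt_trials_small():
    """300 trials from a single mid-sensitivity observer (one condition)."""
    design = DesignSpec(asynchrony_levels_ms=(52,), trials_per_condition=300,
                        n_subjects=1, seed=0)
    params = SDTObserverParams(dprime_by_condition={(52, 6): 1.2},
                               criterion_c=0.15, mratio_true=0.8)
    return simulate_sdt_dataset(design, params, seed=404)


@pytest.fixture(scope="session")
def sdt_trials_large():
    """20,000 trials from an ideal-confidence observer (d' = 1.4)."""
    design = DesignSpec(asynchrony_levels_ms=(52,), trials_per_condition=20_000,
                        n_subjects=1, seed=0)
    params = SDTObserverParams(dprime_by_condition={(52, 6): 1.4},
                               criterion_c=0.2, mratio_true=1.0)
    return simulate_sdt_dataset(design, params, seed=77)


@pytest.fixture(scope="session")
def ddm_trials_single():
    """2,000 speeded trials, one condition (v = 1, a = 1.8, t0 = 0.35)."""
    params = DDMObserverParams(drift_by_condition={(88, 15): 1.0},
                               boundary=1.8, start_point=0.5,
                               nondecision_t0=0.35, postdecision_drift=1.0,
                               postdecision_duration=1.0,
                               confidence_cutpoints=(-0.3, 0.9))
    return simulate_ddm_trials(params, 2_000, seed=555)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)
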