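import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import foragerl as frl


@pytest.fixture(scope="session")
def small_cohort():
    """Six subjects, short (180-s) blocks: fast, fully processed cohort."""
    gen = frl.GeneratorParams()
    cohort, truth = frl.simulate_cohort(
        6, gen, seed=42, plan_overrides={"duration_s": 180.0})
    cohort = frl.preprocess_physiology(cohort)
    cohort = frl.add_objective_rates(cohort)
    return cohort, truth


@pytest.fixture(scope="session")
def one_subject():
    """One full-length simulated session under default conditions."""
    gen = frl.GeneratorParams()
    plan = frl.make_session_plan("BD")
    df = frl.simulate_subject(gen.group_mean, gen.model, gen, plan,
                              np.random.default_rng(5))
    return frl.preprocess_physiology(df)
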