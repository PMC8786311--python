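import warnings

import numpy as np
import pytest

from riskrl import inference, models, recovery, synth, task

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def machines():
    return task.build_machines()


@pytest.fixture(scope="session")
def machine_by_id(machines):
    return {m.machine_id: m for m in machines}


@pytest.fixture(scope="session")
def sequence_seed1():
    return task.generate_trial_sequence(1)


@pytest.fixture(scope="session")
def rstd_params():
    return models.ModelParams("RSTD", alpha_pos=0.4, alpha_neg=0.2, beta=8.0)


@pytest.fixture(scope="session")
def rstd_session(rstd_params, sequence_seed1):
    return recovery.simulate_agent("RSTD", rstd_params, sequence_seed1, seed=5)


@pytest.fixture(scope="session")
def small_cohort():
    """Eight-subject default-parameter cohort, shared across tests."""
    return synth.generate_cohort(synth.CohortConfig(n_subjects=8, seed=3))


@pytest.fixture(scope="session")
def fitted_cohort(small_cohort):
    """The small cohort with RSTD fits and PE-annotated memory records."""
    from riskrl import memory

    subjects = small_cohort
    for s in subjects:
        if s.fit is None:
            s.fit = inference.fit_map("RSTD", s.session, n_restarts=5, seed=50 + s.subject_id)
            _, s.memory_records = memory.annotate_with_pe(s.fit, s.session, s.memory_records)
    return subjects


def random_reward_stream(rng, n):
    """Reward stream in [0, 1] mixing the task's discrete levels and noise."""
    levels = np.array([0.0, 0.25, 0.5, 1.0])
    discrete = rng.choice(levels, size=n)
    noise = rng.random(n)
    pick = rng.random(n) < 0.5
    return np.where(pick, discrete, noise)
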