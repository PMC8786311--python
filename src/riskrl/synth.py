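"""Synthetic cohorts with the statistical structure the analyses assume.

A cohort is a set of simulated subjects ages 8-27 whose risk-sensitive
learning parameters vary with age: the negative learning rate has an
inverted-u bump peaking in mid-adolescence (so the asymmetry index is
u-shaped over age, lowest for adolescents), the positive rate is flat, and
the softmax inverse temperature is log-normal. Each subject plays the full
183-trial task as an RSTD agent; recognition memory is then generated from
the subject's true learning trace with a logistic model in which hit
probability depends on PE magnitude, PE valence, the subject's true
asymmetry index (through a three-way interaction), and memory-test
position, while foils are endorsed at a subject-specific false-alarm rate.

All generator constants are invented plumbing chosen to produce
qualitatively paper-like structure at realistic sample sizes; none is an
empirical estimate. Pavlovian prediction streams (two scene categories of
unequal mean value, explicit value reports with Gaussian noise) are
generated for the Experiment-2-style least-squares model.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from . import inference, models, recovery, sessions, task
from .memory import MemoryRecord

__all__ = [
    "MemoryCoefs",
    "CohortConfig",
    "SubjectData",
    "generate_cohort",
    "generate_memory_responses",
    "generate_prediction_dataset",
]


@dataclass(frozen=True)
class MemoryCoefs:
    """Generating coefficients of the memory model, on the z-scored
    predictor scale."""

    b0: float = 0.1
    b_mag: float = 0.2
    b_val: float = 0.0
    b_int: float = 0.15  # AI x valence x magnitude
    b_trial: float = -0.2


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings for one synthetic cohort.

    alpha_neg follows base + bump * (1 - ((age - peak)/span)^2) + noise,
    clipped to [0, 1]; bump > 0 makes adolescents (age ~ peak) the most
    negatively-biased learners, hence the u-shape in AI over age.
    """

    n_subjects: int = 62
    age_min: float = 8.0
    age_max: float = 27.0
    alpha_neg_base: float = 0.2
    alpha_neg_bump: float = 0.3
    alpha_neg_peak: float = 17.0
    alpha_neg_span: float = 9.0
    alpha_noise_sd: float = 0.05
    alpha_pos_mean: float = 0.25
    beta_log_mean: float = float(np.log(4.0))
    beta_log_sd: float = 0.3
    memory: MemoryCoefs = field(default_factory=MemoryCoefs)
    fa_beta_a: float = 4.0
    fa_beta_b: float = 12.0
    confidence_definite: float = 0.7  # cosmetic split of old/new into 1/2 or 3/4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if not self.age_min < self.age_max:
            raise ValueError("invalid age range")
        if not 0.0 <= self.confidence_definite <= 1.0:
            raise ValueError("confidence_definite must be a probability")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SubjectData:
    """One simulated (or ingested) participant."""

    subject_id: int
    age: float
    true_params: models.ModelParams | None
    session: sessions.Session
    memory_records: list[MemoryRecord] = field(default_factory=list)
    fa_rate: float | None = None
    fit: inference.FitResult | None = None  # filled by the fitting stage

    @property
    def true_ai(self) -> float | None:
        if self.true_params is None or self.true_params.model_name != "RSTD":
            return None
        return models.asymmetry_index(self.true_params.alpha_pos, self.true_params.alpha_neg)


def _draw_subject_params(age: float, config: CohortConfig, rng: np.random.Generator) -> models.ModelParams:
    rel = (age - config.alpha_neg_peak) / config.alpha_neg_span
    alpha_neg = (
        config.alpha_neg_base
        + config.alpha_neg_bump * (1.0 - rel**2)
        + rng.normal(0.0, config.alpha_noise_sd)
    )
    alpha_pos = config.alpha_pos_mean + rng.normal(0.0, config.alpha_noise_sd)
    beta = float(np.exp(rng.normal(config.beta_log_mean, config.beta_log_sd)))
    return models.ModelParams(
        "RSTD",
        alpha_pos=float(np.clip(alpha_pos, 0.0, 1.0)),
        alpha_neg=float(np.clip(alpha_neg, 0.0, 1.0)),
        beta=float(np.clip(beta, *models.BETA_BOUNDS)),
    )


@dataclass
class _Norm:
    """Grand (cohort-level) standardization constants for the generator."""

    mag_mean: float
    mag_sd: float
    val_mean: float
    val_sd: float
    ai_mean: float
    ai_sd: float
    trial_mean: float
    trial_sd: float


def _cohort_norm(subjects: list[SubjectData], traces) -> _Norm:
    mags, vals, ais, trials = [], [], [], []
    n_items = 2 * task.N_TRIALS
    for subj in subjects:
        trace = traces[subj.subject_id]
        ai = subj.true_ai
        for step in trace:
            mags.append(abs(step.delta))
            vals.append(step.valence)
            ais.append(ai)
        trials.extend(range(1, n_items + 1))

    def ms(x):
        arr = np.asarray(x, dtype=float)
        sd = arr.std()
        return float(arr.mean()), float(sd if sd > 0 else 1.0)

    return _Norm(*ms(mags), *ms(vals), *ms(ais), *ms(trials))


def generate_memory_responses(
    subject: SubjectData,
    trace: models.LearningTrace,
    coefs: MemoryCoefs,
    rng: np.random.Generator,
    norm: _Norm | None = None,
    confidence_definite: float = 0.7,
) -> list[MemoryRecord]:
    """Old/new responses for one subject's 183 old images plus 183 foils.

    Hit probability is logistic in z-scored |PE|, PE valence, the
    AI x valence x |PE| product, and memory-test position; foils are
    endorsed at the subject's false-alarm rate. Confidence is a fixed
    cosmetic split of old/new responses into definite vs maybe.
    """
    if len(trace) == 0:
        raise ValueError("subject has no learning trace")
    if subject.fa_rate is None:
        raise ValueError("subject has no false-alarm rate")
    steps = trace.by_trial()
    n_old = len(trace)
    items = [("old", t) for t in sorted(steps)] + [
        ("foil", i) for i in range(1, task.N_TRIALS + 1)
    ]
    order = rng.permutation(len(items))
    ai = subject.true_ai if subject.true_ai is not None else 0.0
    records: list[MemoryRecord] = []
    for mem_trial, idx in enumerate(order, start=1):
        kind, key = items[idx]
        if norm is None:
            z_mag = z_val = z_ai = z_trial = 0.0
        else:
            z_trial = (mem_trial - norm.trial_mean) / norm.trial_sd
        if kind == "old":
            step = steps[key]
            if norm is not None:
                z_mag = (abs(step.delta) - norm.mag_mean) / norm.mag_sd
                z_val = (step.valence - norm.val_mean) / norm.val_sd
                z_ai = (ai - norm.ai_mean) / norm.ai_sd
            eta = (
                coefs.b0
                + coefs.b_mag * z_mag
                + coefs.b_val * z_val
                + coefs.b_int * z_ai * z_val * z_mag
                + coefs.b_trial * z_trial
            )
            p_old = 1.0 / (1.0 + np.exp(-eta))
        else:
            p_old = subject.fa_rate
        said_old = rng.random() < p_old
        definite = rng.random() < confidence_definite
        response = (1 if definite else 2) if said_old else (4 if definite else 3)
        records.append(
            MemoryRecord(
                subject_id=subject.subject_id,
                image_id=f"img_{key:03d}" if kind == "old" else f"foil_{key:03d}",
                truly_old=kind == "old",
                response=response,
                mem_trial_number=mem_trial,
                trial=key if kind == "old" else None,
            )
        )
    assert sum(r.truly_old for r in records) == n_old
    return records


def generate_cohort(config: CohortConfig) -> list[SubjectData]:
    """Simulate a full cohort: ages, parameters, task play, and memory.

    Reproducible given config.seed. Memory predictors are standardized
    grand, across the cohort's old items, before responses are drawn.
    """
    rng = np.random.default_rng(config.seed)
    subjects: list[SubjectData] = []
    traces: dict[int, models.LearningTrace] = {}
    for sid in range(1, config.n_subjects + 1):
        age = float(rng.uniform(config.age_min, config.age_max))
        params = _draw_subject_params(age, config, rng)
        sequence = task.generate_trial_sequence(int(rng.integers(2**31)))
        session = recovery.simulate_agent("RSTD", params, sequence, int(rng.integers(2**31)))
        subj = SubjectData(
            subject_id=sid,
            age=age,
            true_params=params,
            session=session,
            fa_rate=float(rng.beta(config.fa_beta_a, config.fa_beta_b)),
        )
        traces[sid] = sessions.replay(params, session)
        subjects.append(subj)
    norm = _cohort_norm(subjects, traces)
    for subj in subjects:
        subj.memory_records = generate_memory_responses(
            subj,
            traces[subj.subject_id],
            config.memory,
            rng,
            norm=norm,
            confidence_definite=config.confidence_definite,
        )
    return subjects


def generate_prediction_dataset(
    n_subjects: int,
    n_trials: int = 60,
    seed: int = 0,
    category_means: tuple[float, float] = (0.65, 0.35),
    outcome_sd: float = 0.17,
    report_noise_sd: float = 0.05,
) -> dict[int, list[inference.PredictionRecord]]:
    """Pavlovian prediction streams for the explicit-prediction model.

    Two scene categories with distinct mean values (rescaled [0, 1]); each
    subject carries valenced learning rates drawn from Beta(2, 2) and
    reports the model value plus Gaussian noise.
    """
    if n_trials < 20:
        raise ValueError("need at least 20 trials")
    rng = np.random.default_rng(seed)
    data: dict[int, list[inference.PredictionRecord]] = {}
    for sid in range(1, n_subjects + 1):
        alpha_pos = float(rng.beta(2.0, 2.0))
        alpha_neg = float(rng.beta(2.0, 2.0))
        values = {"A": 0.5, "B": 0.5}
        records = []
        cats = rng.permuted(["A", "B"] * (n_trials // 2 + 1))[:n_trials]
        for t, cat in enumerate(cats, start=1):
            mean = category_means[0] if cat == "A" else category_means[1]
            shown = float(np.clip(rng.normal(mean, outcome_sd), 0.0, 1.0))
            stated = float(np.clip(values[cat] + rng.normal(0.0, report_noise_sd), 0.0, 1.0))
            delta = shown - values[cat]
            rate = alpha_pos if delta > 0 else alpha_neg
            records.append(
                inference.PredictionRecord(
                    trial=t,
                    scene_category=cat,
                    shown_value=shown,
                    stated_prediction=stated,
                    generating_pe=delta,
                )
            )
            values[cat] = values[cat] + rate * delta
        data[sid] = records
    return data
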