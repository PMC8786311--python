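"""Agent simulation, parameter recovery, model recovery, and posterior
predictive checks.

Recovery works by simulate-and-refit: draw parameters uniformly within the
fitting bounds, let each synthetic agent play a fresh seeded session of the
183-trial task, refit by MAP, and correlate generating with recovered
values (Pearson; Spearman kept as a secondary diagnostic). Model recovery
fits competing models to the same simulated subjects and scores pairwise
BIC contests. The posterior predictive check re-simulates each subject at
their MAP parameters on their own trial sequence and correlates the
simulated with the observed equal-EV risky-choice proportion across
subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import inference, models, sessions, task
from .models import BETA_BOUNDS, PARAM_FIELDS, RHO_BOUNDS, ModelParams

__all__ = [
    "simulate_agent",
    "draw_uniform_params",
    "RecoveryResult",
    "run_parameter_recovery",
    "ConfusionRow",
    "run_model_recovery",
    "posterior_predictive_check",
]


def simulate_agent(
    model_name: str,
    params: ModelParams,
    sequence: task.TrialSequence,
    seed: int,
) -> sessions.Session:
    """Play one session: softmax choices on free trials, forced trials taken
    as offered, outcomes drawn from the bag-of-eight schedule, values updated
    per the model. Fully reproducible given the seed."""
    if params.model_name != model_name:
        raise ValueError(f"params are for {params.model_name}, not {model_name}")
    rng = np.random.default_rng(seed)
    machines = task.machine_map()
    state = models.initialize_values(list(machines.values()))
    schedule = task.OutcomeSchedule(machines=machines)
    records: list[task.ChoiceRecord] = []
    for spec in sequence:
        if spec.trial_type == "forced":
            chosen = spec.offered[0]
        else:
            first, second = spec.offered
            p_first = models.choice_prob(params.beta, state.q[first], state.q[second])
            chosen = first if rng.random() < p_first else second
        outcome = task.next_outcome(schedule, chosen, rng)
        agency = "free" if spec.is_free_choice else "forced"
        state, _ = models.update_value(params, state, chosen, outcome / task.MAX_POINTS, agency)
        records.append(
            task.ChoiceRecord(
                trial=spec.index,
                chosen=chosen,
                outcome_points=outcome,
                image_id=f"img_{spec.index:03d}",
            )
        )
    return sessions.Session(sequence, tuple(records))


def draw_uniform_params(model_name: str, rng: np.random.Generator) -> ModelParams:
    """Parameters drawn uniformly within the fitting bounds."""
    values = {}
    for name in PARAM_FIELDS[model_name]:
        if name.startswith("alpha"):
            values[name] = rng.uniform(0.0, 1.0)
        elif name == "beta":
            values[name] = rng.uniform(*BETA_BOUNDS)
        else:
            values[name] = rng.uniform(*RHO_BOUNDS)
    return ModelParams(model_name, **values)


@dataclass
class RecoveryResult:
    """Generating-vs-recovered correlations for one model."""

    model_name: str
    n_subjects: int
    seed: int
    pearson: dict[str, float] = field(default_factory=dict)
    spearman: dict[str, float] = field(default_factory=dict)
    generating: dict[str, np.ndarray] = field(default_factory=dict)
    recovered: dict[str, np.ndarray] = field(default_factory=dict)


def _simulate_cohort_uniform(
    model_name: str, n_subjects: int, seed: int
) -> tuple[list[ModelParams], list[sessions.Session]]:
    """Uniform-parameter agents, each on an independent fresh sequence."""
    rng = np.random.default_rng(seed)
    truths, sims = [], []
    for i in range(n_subjects):
        params = draw_uniform_params(model_name, rng)
        sequence = task.generate_trial_sequence(int(rng.integers(2**31)))
        session = simulate_agent(model_name, params, sequence, int(rng.integers(2**31)))
        truths.append(params)
        sims.append(session)
    return truths, sims


def run_parameter_recovery(
    model_name: str,
    n_subjects: int = 500,
    seed: int = 0,
    n_restarts: int = 10,
) -> RecoveryResult:
    """Simulate-and-refit recovery for one model.

    Each subject's parameters are drawn uniformly within the fitting bounds
    and the same model is refit by MAP; correlations are computed over
    converged fits only.
    """
    truths, sims = _simulate_cohort_uniform(model_name, n_subjects, seed)
    result = RecoveryResult(model_name, n_subjects, seed)
    fields = PARAM_FIELDS[model_name]
    gen = {f: [] for f in fields}
    rec = {f: [] for f in fields}
    for i, (params, session) in enumerate(zip(truths, sims)):
        fit = inference.fit_map(model_name, session, n_restarts=n_restarts, seed=seed + 7919 * i)
        if not fit.converged:
            continue
        for f in fields:
            gen[f].append(getattr(params, f))
            rec[f].append(getattr(fit.map_params, f))
    for f in fields:
        g, r = np.asarray(gen[f]), np.asarray(rec[f])
        result.generating[f], result.recovered[f] = g, r
        result.pearson[f] = float(stats.pearsonr(g, r).statistic)
        result.spearman[f] = float(stats.spearmanr(g, r).statistic)
    return result


@dataclass
class ConfusionRow:
    """Pairwise BIC win proportions for one generating model."""

    generating_model: str
    n_subjects: int
    seed: int
    win_proportion: dict[str, float] = field(default_factory=dict)
    bics: dict[str, np.ndarray] = field(default_factory=dict)


def run_model_recovery(
    generating_model: str,
    n_subjects: int = 300,
    seed: int = 0,
    comparison_models: tuple[str, ...] = ("TD", "RSTD", "FourLR", "Utility"),
    n_restarts: int = 10,
) -> ConfusionRow:
    """Simulate under one model, fit all candidates, score pairwise BIC wins.

    win_proportion[m] is the fraction of simulated subjects for whom the
    generating model's BIC beats model m's BIC.
    """
    truths, sims = _simulate_cohort_uniform(generating_model, n_subjects, seed)
    fit_models = tuple(dict.fromkeys((generating_model,) + tuple(comparison_models)))
    row = ConfusionRow(generating_model, n_subjects, seed)
    bics = {m: np.empty(n_subjects) for m in fit_models}
    for i, session in enumerate(sims):
        for m in fit_models:
            fit = inference.fit_map(m, session, n_restarts=n_restarts, seed=seed + 7919 * i)
            bics[m][i] = fit.bic
    row.bics = bics
    for m in comparison_models:
        if m == generating_model:
            continue
        row.win_proportion[m] = float(np.mean(bics[generating_model] < bics[m]))
    return row


def _equal_ev_risky_proportion(session: sessions.Session) -> float:
    """Proportion of equal-EV risky trials on which the probabilistic
    machine was chosen; NaN if all such trials were missed."""
    picked, total = 0, 0
    risky = {pair[0] for pair in task.EQUAL_EV_PAIRS}
    for spec, rec in zip(session.sequence, session.records):
        if spec.trial_type != "risky_equal" or rec.missed:
            continue
        total += 1
        picked += rec.chosen in risky
    return picked / total if total else math.nan


@dataclass
class PPCResult:
    """Posterior-predictive correspondence between simulated and observed
    risky-choice proportions."""

    r: float
    observed: np.ndarray
    simulated: np.ndarray
    n_sims: int
    degenerate: bool = False
    skipped_subjects: tuple[int, ...] = ()


def posterior_predictive_check(
    fits: dict[int, inference.FitResult],
    data: dict[int, sessions.Session],
    n_sims: int = 10,
    seed: int = 0,
) -> PPCResult:
    """Simulate each subject at MAP parameters on their own sequence and
    correlate mean simulated equal-EV risky-choice proportion with the
    observed one across subjects."""
    rng = np.random.default_rng(seed)
    observed, simulated, skipped = [], [], []
    for subject_id, session in sorted(data.items()):
        fit = fits.get(subject_id)
        if fit is None:
            skipped.append(subject_id)
            continue
        obs = _equal_ev_risky_proportion(session)
        sim_props = [
            _equal_ev_risky_proportion(
                simulate_agent(
                    fit.model_name, fit.map_params, session.sequence, int(rng.integers(2**31))
                )
            )
            for _ in range(n_sims)
        ]
        observed.append(obs)
        simulated.append(float(np.mean(sim_props)))
    observed_arr, simulated_arr = np.asarray(observed), np.asarray(simulated)
    degenerate = (
        len(observed_arr) < 2
        or np.std(observed_arr) == 0.0
        or np.std(simulated_arr) == 0.0
    )
    r = math.nan if degenerate else float(stats.pearsonr(observed_arr, simulated_arr).statistic)
    return PPCResult(r, observed_arr, simulated_arr, n_sims, degenerate, tuple(skipped))
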