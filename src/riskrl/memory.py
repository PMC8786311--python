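"""Recognition-memory scoring and the PE-modulated memory regressions.

After the bandit task, subjects judge 183 task images and 183 novel foils
as old or new on a 1-4 confidence scale. Responses 1-2 count as "old".
Signal detection gives hit rate, false-alarm rate, and d' = z(hit) - z(fa).

The central analysis links incidental memory to the learning model: each
old image inherits the prediction error delta of its trial from a replay
at the subject's MAP parameters, and a mixed-effects logistic regression
predicts recognition accuracy from the subject's asymmetry index (AI), PE
valence, PE magnitude, and their full factorial interaction, controlling
for linear and quadratic age, false-alarm rate, and memory-test position.
The three-way AI x valence x magnitude term is the quantity of interest:
a positive coefficient means positively-biased learners preferentially
remember images paired with large positive surprises, and vice versa.

The mixed model is estimated with statsmodels' binomial mixed GLM under
diffuse priors via mean-field variational Bayes (the estimator that scales
to cohort-sized tables; its posterior standard deviations are mildly
anti-conservative), with uncorrelated random intercept and slopes by
subject; on failure a declared simplification ladder is walked and logged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import inference, models, sessions, task

__all__ = [
    "MemoryRecord",
    "SignalDetection",
    "signal_detection",
    "annotate_with_pe",
    "build_memory_table",
    "MemoryRegressionResult",
    "fit_memory_glmm",
    "marginal_means",
    "subset_analyses",
]


@dataclass(frozen=True)
class MemoryRecord:
    """One memory-test item: truth, response, and (for old items) the
    learning context it came from."""

    subject_id: int
    image_id: str
    truly_old: bool
    response: int  # 1 definitely old ... 4 definitely new
    mem_trial_number: int
    trial: int | None = None  # linked choice trial (old items only)
    agency: str | None = None  # free | forced
    pe: float | None = None
    machine_type: str | None = None  # probabilistic | deterministic

    def __post_init__(self) -> None:
        if self.response not in (1, 2, 3, 4):
            raise ValueError(f"response {self.response} not in 1..4")
        if not self.truly_old and self.trial is not None:
            raise ValueError("foils carry no linked trial")

    @property
    def said_old(self) -> bool:
        return self.response <= 2

    @property
    def correct(self) -> bool:
        return self.said_old if self.truly_old else not self.said_old

    @property
    def pe_magnitude(self) -> float | None:
        return None if self.pe is None else abs(self.pe)

    @property
    def pe_valence(self) -> int | None:
        """Sign of the PE; exact zero counts as negative (fixed tie-break)."""
        if self.pe is None:
            return None
        return 1 if self.pe > 0 else -1


@dataclass(frozen=True)
class SignalDetection:
    hit_rate: float
    false_alarm_rate: float
    d_prime: float
    n_old: int
    n_new: int


def signal_detection(records: list[MemoryRecord]) -> SignalDetection:
    """Hit/false-alarm rates over binarized responses and d'.

    Extreme rates are replaced by 1/(2N) and 1 - 1/(2N) before the
    standard-normal quantile transform.
    """
    old = [r for r in records if r.truly_old]
    new = [r for r in records if not r.truly_old]
    if not old or not new:
        raise ValueError("need both old items and foils")
    hit = sum(r.said_old for r in old) / len(old)
    fa = sum(r.said_old for r in new) / len(new)

    def corrected(rate: float, n: int) -> float:
        if rate <= 0.0:
            return 1.0 / (2 * n)
        if rate >= 1.0:
            return 1.0 - 1.0 / (2 * n)
        return rate

    d_prime = float(
        stats.norm.ppf(corrected(hit, len(old))) - stats.norm.ppf(corrected(fa, len(new)))
    )
    return SignalDetection(hit, fa, d_prime, len(old), len(new))


def annotate_with_pe(
    fit: inference.FitResult,
    session: sessions.Session,
    memory_records: list[MemoryRecord],
) -> tuple[models.LearningTrace, list[MemoryRecord]]:
    """Replay the session at MAP parameters and let each old image inherit
    the prediction error, agency, and machine type of its trial."""
    if fit.asymmetry_index is None:
        raise ValueError("PE annotation requires a valenced-model fit")
    trace = sessions.replay(fit.map_params, session)
    by_trial = trace.by_trial()
    machines = task.machine_map()
    spec_by_trial = {spec.index: spec for spec in session.sequence}
    enriched: list[MemoryRecord] = []
    for rec in memory_records:
        if not rec.truly_old:
            enriched.append(rec)
            continue
        step = by_trial.get(rec.trial)
        if step is None:
            raise ValueError(f"image {rec.image_id} links to trial {rec.trial} with no trace")
        spec = spec_by_trial[rec.trial]
        machine_type = "probabilistic" if not machines[step.chosen].deterministic else "deterministic"
        enriched.append(
            MemoryRecord(
                subject_id=rec.subject_id,
                image_id=rec.image_id,
                truly_old=True,
                response=rec.response,
                mem_trial_number=rec.mem_trial_number,
                trial=rec.trial,
                agency="free" if spec.is_free_choice else "forced",
                pe=step.delta,
                machine_type=machine_type,
            )
        )
    return trace, enriched


def _zscore(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=0)
    if sd == 0:
        return x - x.mean()
    return (x - x.mean()) / sd


def build_memory_table(
    subjects: list,  # SubjectData-like: needs .subject_id, .age, .fit, .memory_records
    z_within_subject: bool = False,
) -> pd.DataFrame:
    """Trial-level regression table: one row per truly-old image with a PE.

    Continuous predictors are z-scored grand (across all included rows) by
    default; ``z_within_subject`` switches to per-subject standardization of
    the within-subject predictors. Foil behavior enters through each
    subject's false-alarm-rate covariate, not as rows.
    """
    rows = []
    for subj in subjects:
        fit = getattr(subj, "fit", None)
        if fit is None or fit.asymmetry_index is None:
            continue  # excluded: no valenced-model fit
        sd = signal_detection(subj.memory_records)
        for rec in subj.memory_records:
            if not rec.truly_old or rec.pe is None:
                continue
            rows.append(
                {
                    "subject_id": subj.subject_id,
                    "image_id": rec.image_id,
                    "correct": int(rec.correct),
                    "ai": fit.asymmetry_index,
                    "pe": rec.pe,
                    "pe_valence": rec.pe_valence,
                    "pe_mag": rec.pe_magnitude,
                    "age": subj.age,
                    "fa_rate": sd.false_alarm_rate,
                    "mem_trial": rec.mem_trial_number,
                    "agency": rec.agency,
                    "machine_type": rec.machine_type,
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    within = ["pe_valence", "pe_mag", "mem_trial"]
    between = ["ai", "age", "fa_rate"]
    for col in between:
        table[f"{col}_z"] = _zscore(table[col])
    if z_within_subject:
        for col in within:
            table[f"{col}_z"] = table.groupby("subject_id")[col].transform(_zscore)
    else:
        for col in within:
            table[f"{col}_z"] = _zscore(table[col])
    table["age_z2"] = table["age_z"] ** 2
    return table


@dataclass
class MemoryRegressionResult:
    """Fixed effects of the memory mixed model, plus the convergence ladder."""

    coefficients: pd.DataFrame  # term, estimate, se, z, p, odds_ratio, ci_low, ci_high
    random_structure: str
    ladder_log: list[str] = field(default_factory=list)
    n_observations: int = 0
    converged: bool = True
    separation: bool = False
    cov_params: np.ndarray | None = None
    formula: str = ""

    def term(self, name: str) -> pd.Series:
        match = self.coefficients[self.coefficients["term"] == name]
        if match.empty:
            raise KeyError(name)
        return match.iloc[0]


MAIN_FORMULA = (
    "correct ~ ai_z * pe_valence_z * pe_mag_z + age_z + age_z2 + fa_rate_z + mem_trial_z"
)
# within-subject predictors eligible for random slopes
_SLOPE_TERMS = ("pe_valence_z", "pe_mag_z", "pe_valence_z:pe_mag_z", "mem_trial_z")


def _fe_table(names, means, sds) -> pd.DataFrame:
    z = means / sds
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "term": names,
            "estimate": means,
            "se": sds,
            "z": z,
            "p": p,
            "odds_ratio": np.exp(means),
            "ci_low": np.exp(means - 1.959963984540054 * sds),
            "ci_high": np.exp(means + 1.959963984540054 * sds),
        }
    )


def _fit_bayes_mixed(table: pd.DataFrame, formula: str, vc_terms: tuple[str, ...]):
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    vc_formulas = {"subject": "0 + C(subject_id)"}
    for term in vc_terms:
        key = term.replace(":", "_x_")
        vc_formulas[key] = f"0 + C(subject_id):({term})"
    model = BinomialBayesMixedGLM.from_formula(
        formula, vc_formulas, table, vcp_p=3.0, fe_p=3.0
    )
    fit = model.fit_vb()
    names = model.exog_names
    means = np.asarray(fit.fe_mean)
    sds = np.asarray(fit.fe_sd)
    if not np.all(np.isfinite(means)) or not np.all(np.isfinite(sds)):
        raise RuntimeError("non-finite fixed-effect estimates")
    cov = np.diag(sds**2)
    return _fe_table(names, means, sds), cov


def _fit_glm_cluster(table: pd.DataFrame, formula: str):
    import statsmodels.formula.api as smf

    model = smf.logit(formula, data=table)
    fit = model.fit(disp=0, cov_type="cluster", cov_kwds={"groups": table["subject_id"]})
    return _fe_table(list(fit.params.index), fit.params.values, fit.bse.values), np.asarray(
        fit.cov_params()
    )


def fit_memory_glmm(
    table: pd.DataFrame,
    formula: str = MAIN_FORMULA,
    slope_terms: tuple[str, ...] = _SLOPE_TERMS,
) -> MemoryRegressionResult:
    """Mixed-effects logistic regression of recognition accuracy.

    Random effects by subject: intercept plus uncorrelated slopes for the
    within-subject predictors. Non-convergence walks a declared ladder —
    uncorrelated slopes (the estimator fits no slope correlations), then
    intercept only, then a plain logistic GLM with cluster-robust standard
    errors — and records each step.
    """
    if table.empty:
        raise ValueError("empty regression table")
    outcome = formula.split("~")[0].strip()
    vals = set(table[outcome].unique())
    if not vals <= {0, 1}:
        raise ValueError("outcome must be binary")
    if len(vals) == 1:
        return MemoryRegressionResult(
            coefficients=pd.DataFrame(),
            random_structure="none",
            ladder_log=["separation: outcome has a single level; no estimates"],
            n_observations=len(table),
            converged=False,
            separation=True,
            formula=formula,
        )

    ladder: list[str] = []
    attempts = [
        ("intercept + uncorrelated slopes", lambda: _fit_bayes_mixed(table, formula, slope_terms)),
        ("intercept only", lambda: _fit_bayes_mixed(table, formula, ())),
        ("no random effects (cluster-robust GLM)", lambda: _fit_glm_cluster(table, formula)),
    ]
    for structure, attempt in attempts:
        try:
            coefficients, cov = attempt()
        except Exception as exc:  # noqa: BLE001 - any estimator failure steps the ladder
            ladder.append(f"{structure}: failed ({type(exc).__name__}: {exc})")
            continue
        ladder.append(f"{structure}: converged")
        return MemoryRegressionResult(
            coefficients=coefficients,
            random_structure=structure,
            ladder_log=ladder,
            n_observations=len(table),
            converged=True,
            cov_params=cov,
            formula=formula,
        )
    return MemoryRegressionResult(
        coefficients=pd.DataFrame(),
        random_structure="none",
        ladder_log=ladder,
        n_observations=len(table),
        converged=False,
        formula=formula,
    )


def marginal_means(
    result: MemoryRegressionResult,
    ai_levels=(-1.0, 0.0, 1.0),
    valence_levels=(-1.0, 1.0),
    magnitude_levels=(-1.0, 0.0, 1.0),
) -> pd.DataFrame:
    """Fixed-effects-only predicted recognition probabilities on a grid of
    (z-scored) AI, PE valence, and PE magnitude; other covariates at their
    z-means (0). CIs propagate the coefficient covariance."""
    if not result.converged:
        raise ValueError("cannot compute marginal means from a failed fit")
    terms = list(result.coefficients["term"])
    beta = result.coefficients["estimate"].to_numpy()
    cov = result.cov_params if result.cov_params is not None else np.zeros((len(beta), len(beta)))
    rows = []
    for ai in ai_levels:
        for val in valence_levels:
            for mag in magnitude_levels:
                x = np.zeros(len(terms))
                filled = {
                    "Intercept": 1.0,
                    "ai_z": ai,
                    "pe_valence_z": val,
                    "pe_mag_z": mag,
                    "ai_z:pe_valence_z": ai * val,
                    "ai_z:pe_mag_z": ai * mag,
                    "pe_valence_z:pe_mag_z": val * mag,
                    "ai_z:pe_valence_z:pe_mag_z": ai * val * mag,
                }
                for i, t in enumerate(terms):
                    x[i] = filled.get(t, 0.0)
                eta = float(x @ beta)
                se = float(np.sqrt(x @ cov @ x))
                expit = lambda v: 1.0 / (1.0 + math.exp(-v))
                rows.append(
                    {
                        "ai": ai,
                        "pe_valence": val,
                        "pe_mag": mag,
                        "prob": expit(eta),
                        "ci_low": expit(eta - 1.959963984540054 * se),
                        "ci_high": expit(eta + 1.959963984540054 * se),
                    }
                )
    return pd.DataFrame(rows)


AGENCY_FORMULA = (
    "correct ~ ai_z * pe_valence_z * pe_mag_z * agency_free"
    " + age_z + age_z2 + fa_rate_z + mem_trial_z"
)


def subset_analyses(table: pd.DataFrame) -> dict[str, MemoryRegressionResult]:
    """The two follow-up models: the main regression restricted to
    probabilistic-machine rows, and an agency-moderated model on all rows."""
    prob = table[table["machine_type"] == "probabilistic"]
    if prob.empty:
        raise ValueError("no probabilistic-machine rows")
    results = {"probabilistic_only": fit_memory_glmm(prob, MAIN_FORMULA)}
    agency_table = table.copy()
    agency_table["agency_free"] = (agency_table["agency"] == "free").astype(int)
    results["agency"] = fit_memory_glmm(agency_table, AGENCY_FORMULA)
    return results
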