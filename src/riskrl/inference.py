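"""MAP parameter estimation, BIC, and model comparison.

Fitting maximizes likelihood x prior. Priors follow the shape-scale
(MATLAB ``gampdf``) convention for the Gamma family:

* learning rates  ~ Beta(2, 2) on [0, 1]
* inverse temperature beta ~ Gamma(shape 2, scale 3) on [1e-6, 30]
* utility curvature rho    ~ Gamma(shape 1.5, scale 1.5) on [0, 2.5]

The optimizer works in an unconstrained space (scaled logit per bounded
parameter, mirroring the original unconstrained-optimizer-with-priors
setup) while prior densities are evaluated on the natural scale, so the
reported optimum is the natural-scale MAP. The session likelihood is
evaluated by a numba-compiled replay kernel; a plain-Python reference of
the same computation lives in :mod:`riskrl.sessions` and the test suite
asserts the two agree.

BIC = -2 log L(MAP) + k ln(n) with n = non-missed free choices (the trials
passed through the softmax; forced trials update values but add no choice
likelihood). A group-level comparison declares no winner when the median
BIC difference is 6 or less.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import minimize

from . import models, sessions
from .models import BETA_BOUNDS, MODEL_NAMES, N_PARAMS, PARAM_FIELDS, RHO_BOUNDS, ModelParams

__all__ = [
    "PriorSpec",
    "default_priors",
    "log_prior",
    "negative_log_posterior",
    "negative_log_likelihood",
    "FitResult",
    "fit_map",
    "compute_bic",
    "ModelComparison",
    "PredictionRecord",
    "fit_explicit_prediction",
    "BIC_DECISION_THRESHOLD",
]

BIC_DECISION_THRESHOLD = 6.0

_MODEL_CODE = {"TD": 0, "RSTD": 1, "FourLR": 2, "Utility": 3}


# ---------------------------------------------------------------------------
# priors


@dataclass(frozen=True)
class PriorSpec:
    """Prior for one parameter: family, hyperparameters, support."""

    family: str  # "beta" | "gamma"
    a: float  # Beta a / Gamma shape
    b: float  # Beta b / Gamma scale (or rate if gamma_rate)
    lo: float
    hi: float
    gamma_rate: bool = False  # shape-rate convention instead of shape-scale

    def logpdf(self, x: float) -> float:
        if not self.lo <= x <= self.hi:
            return -math.inf
        if self.family == "beta":
            if x <= 0.0 or x >= 1.0:
                return -math.inf
            return (
                math.lgamma(self.a + self.b)
                - math.lgamma(self.a)
                - math.lgamma(self.b)
                + (self.a - 1.0) * math.log(x)
                + (self.b - 1.0) * math.log1p(-x)
            )
        if self.family == "gamma":
            if x <= 0.0:
                return -math.inf
            scale = 1.0 / self.b if self.gamma_rate else self.b
            return (
                (self.a - 1.0) * math.log(x)
                - x / scale
                - self.a * math.log(scale)
                - math.lgamma(self.a)
            )
        raise ValueError(f"unknown family {self.family!r}")

    @property
    def mode(self) -> float:
        if self.family == "beta":
            return (self.a - 1.0) / (self.a + self.b - 2.0)
        scale = 1.0 / self.b if self.gamma_rate else self.b
        return max((self.a - 1.0) * scale, self.lo + 1e-6)


def default_priors(model_name: str, gamma_rate: bool = False) -> dict[str, PriorSpec]:
    """The fitting priors, keyed by parameter field name."""
    rate_prior = PriorSpec("beta", 2.0, 2.0, 0.0, 1.0)
    beta_prior = PriorSpec("gamma", 2.0, 3.0, *BETA_BOUNDS, gamma_rate=gamma_rate)
    rho_prior = PriorSpec("gamma", 1.5, 1.5, *RHO_BOUNDS, gamma_rate=gamma_rate)
    out: dict[str, PriorSpec] = {}
    for name in PARAM_FIELDS[model_name]:
        if name.startswith("alpha"):
            out[name] = rate_prior
        elif name == "beta":
            out[name] = beta_prior
        elif name == "rho":
            out[name] = rho_prior
    return out


def log_prior(params: ModelParams, priors: dict[str, PriorSpec] | None = None) -> float:
    """Sum of log prior densities over the model's free parameters."""
    priors = priors or default_priors(params.model_name)
    return sum(priors[name].logpdf(getattr(params, name)) for name in priors)


# ---------------------------------------------------------------------------
# likelihood kernel


@njit(cache=True)
def _nll_kernel(model_code, rates, beta, rho, chosen, other, reward, is_free):
    """Negative log choice likelihood of one session replay.

    rates: TD/Utility use rates[0]; RSTD uses rates[0]/rates[1] for
    positive/non-positive prediction errors; FourLR appends the forced-trial
    pair in rates[2]/rates[3]. Zero prediction errors take the negative rate.
    """
    q = np.full(5, 0.5)
    nll = 0.0
    for i in range(chosen.shape[0]):
        c = chosen[i]
        if c < 0:  # missed: no likelihood, no update
            continue
        if is_free[i]:
            x = -beta * (q[c] - q[other[i]])
            if x > 35.0:
                nll += x
            else:
                nll += math.log1p(math.exp(x))
        r = reward[i]
        target = r**rho if model_code == 3 else r
        delta = target - q[c]
        if model_code == 0 or model_code == 3:
            rate = rates[0]
        elif model_code == 1:
            rate = rates[0] if delta > 0.0 else rates[1]
        else:  # FourLR
            if is_free[i]:
                rate = rates[0] if delta > 0.0 else rates[1]
            else:
                rate = rates[2] if delta > 0.0 else rates[3]
        q[c] = q[c] + rate * delta
    return nll


def _kernel_args(params: ModelParams) -> tuple[int, np.ndarray, float, float]:
    name = params.model_name
    code = _MODEL_CODE[name]
    rates = np.zeros(4)
    if name in ("TD", "Utility"):
        rates[0] = params.alpha
    elif name == "RSTD":
        rates[0], rates[1] = params.alpha_pos, params.alpha_neg
    else:
        rates[:] = (
            params.alpha_pos_free,
            params.alpha_neg_free,
            params.alpha_pos_forced,
            params.alpha_neg_forced,
        )
    rho = params.rho if name == "Utility" else 1.0
    return code, rates, float(params.beta), float(rho)


def negative_log_likelihood(params: ModelParams, session: sessions.Session) -> float:
    """-ln P(free choices | params) over one session."""
    arrays = session.to_arrays()
    code, rates, beta, rho = _kernel_args(params)
    return float(
        _nll_kernel(
            code, rates, beta, rho,
            arrays["chosen"], arrays["other"], arrays["reward"], arrays["is_free"],
        )
    )


def negative_log_posterior(
    params: ModelParams,
    session: sessions.Session,
    priors: dict[str, PriorSpec] | None = None,
) -> float:
    """-ln [P(choices | params) P(params)]: the MAP objective."""
    return negative_log_likelihood(params, session) - log_prior(params, priors)


# ---------------------------------------------------------------------------
# reparameterization


def _sigmoid(u: np.ndarray) -> np.ndarray:
    out = np.empty_like(u)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-u[pos]))
    eu = np.exp(u[~pos])
    out[~pos] = eu / (1.0 + eu)
    # keep strictly interior so prior log-densities stay finite
    return np.clip(out, 1e-12, 1.0 - 1e-12)


def _bounds_for(model_name: str) -> list[tuple[float, float]]:
    out = []
    for name in PARAM_FIELDS[model_name]:
        if name.startswith("alpha"):
            out.append((0.0, 1.0))
        elif name == "beta":
            out.append(BETA_BOUNDS)
        else:
            out.append(RHO_BOUNDS)
    return out


def _to_natural(u: np.ndarray, bounds: list[tuple[float, float]]) -> np.ndarray:
    s = _sigmoid(u)
    return np.array([lo + (hi - lo) * si for (lo, hi), si in zip(bounds, s)])


def _to_unconstrained(x: np.ndarray, bounds: list[tuple[float, float]]) -> np.ndarray:
    frac = np.array(
        [min(max((xi - lo) / (hi - lo), 1e-9), 1 - 1e-9) for (lo, hi), xi in zip(bounds, x)]
    )
    return np.log(frac / (1.0 - frac))


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """A MAP fit: parameters, fit quality, and provenance."""

    model_name: str
    map_params: ModelParams
    neg_log_posterior: float
    log_likelihood_at_map: float
    n_modeled_choices: int
    bic: float
    asymmetry_index: float | None
    n_restarts: int
    converged: bool
    seed: int | None = None
    restart_objectives: tuple[float, ...] = ()
    unidentifiable: bool = False


def _fit_ai(params: ModelParams) -> float | None:
    if params.model_name in ("RSTD", "ExplicitPrediction"):
        return models.asymmetry_index(params.alpha_pos, params.alpha_neg)
    if params.model_name == "FourLR":
        return models.asymmetry_index(params.alpha_pos_free, params.alpha_neg_free)
    return None


def fit_map(
    model_name: str,
    session: sessions.Session,
    n_restarts: int = 10,
    seed: int = 0,
    priors: dict[str, PriorSpec] | None = None,
) -> FitResult:
    """Fit one choice model to one session by MAP with seeded multistart.

    Gradient-based (L-BFGS with finite differences) search in the
    unconstrained reparameterization; the first start point is the vector
    of prior modes, the rest are Gaussian jitters around it. Deterministic
    given the seed.
    """
    if model_name not in _MODEL_CODE:
        raise ValueError(f"cannot MAP-fit model {model_name!r}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    priors = priors or default_priors(model_name)
    bounds = _bounds_for(model_name)
    fields = PARAM_FIELDS[model_name]
    arrays = session.to_arrays()
    chosen, other = arrays["chosen"], arrays["other"]
    reward, is_free = arrays["reward"], arrays["is_free"]
    code = _MODEL_CODE[model_name]
    prior_list = [priors[name] for name in fields]
    rate_slice = [i for i, name in enumerate(fields) if name.startswith("alpha")]
    beta_idx = fields.index("beta")
    rho_idx = fields.index("rho") if "rho" in fields else None

    def objective(u: np.ndarray) -> float:
        nat = _to_natural(u, bounds)
        rates = np.zeros(4)
        for j, idx in enumerate(rate_slice):
            rates[j] = nat[idx]
        rho = nat[rho_idx] if rho_idx is not None else 1.0
        nll = _nll_kernel(code, rates, nat[beta_idx], rho, chosen, other, reward, is_free)
        lp = 0.0
        for p, x in zip(prior_list, nat):
            lp += p.logpdf(x)
        return nll - lp

    rng = np.random.default_rng(seed)
    u_mode = _to_unconstrained(np.array([p.mode for p in prior_list]), bounds)
    best = None
    objectives = []
    any_converged = False
    for restart in range(n_restarts):
        u0 = u_mode if restart == 0 else u_mode + rng.normal(0.0, 2.0, len(fields))
        res = minimize(objective, u0, method="L-BFGS-B", options={"ftol": 1e-8, "maxiter": 500})
        objectives.append(float(res.fun))
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    nat = _to_natural(best.x, bounds)
    map_params = ModelParams.from_vector(model_name, nat)
    nll = negative_log_likelihood(map_params, session)
    n = session.n_modeled_choices
    k = N_PARAMS[model_name]
    bic = -2.0 * (-nll) + k * math.log(n) if n > 0 else math.nan
    return FitResult(
        model_name=model_name,
        map_params=map_params,
        neg_log_posterior=float(best.fun),
        log_likelihood_at_map=-nll,
        n_modeled_choices=n,
        bic=bic,
        asymmetry_index=_fit_ai(map_params),
        n_restarts=n_restarts,
        converged=any_converged,
        seed=seed,
        restart_objectives=tuple(objectives),
    )


def compute_bic(fit: FitResult) -> float:
    """BIC = -2 log L + k ln(n), n = modeled (non-missed free) choices."""
    if fit.n_modeled_choices <= 0:
        raise ValueError("BIC undefined with zero modeled choices")
    k = N_PARAMS[fit.model_name]
    return -2.0 * fit.log_likelihood_at_map + k * math.log(fit.n_modeled_choices)


# ---------------------------------------------------------------------------
# model comparison


@dataclass
class ModelComparison:
    """Per-subject BICs by model, with a ΔBIC > 6 decision rule."""

    bics: dict[str, np.ndarray] = field(default_factory=dict)
    threshold: float = BIC_DECISION_THRESHOLD

    def add(self, model_name: str, subject_bics: np.ndarray) -> None:
        self.bics[model_name] = np.asarray(subject_bics, dtype=float)

    def median_bic(self) -> dict[str, float]:
        return {m: float(np.median(b)) for m, b in self.bics.items()}

    def delta_bic(self) -> dict[str, float]:
        med = self.median_bic()
        best = min(med.values())
        return {m: v - best for m, v in med.items()}

    def winner(self) -> str | None:
        """Best model by median BIC, or None when the margin is <= 6."""
        med = self.median_bic()
        ordered = sorted(med, key=med.get)
        if len(ordered) < 2:
            return ordered[0] if ordered else None
        if med[ordered[1]] - med[ordered[0]] <= self.threshold:
            return None
        return ordered[0]


# ---------------------------------------------------------------------------
# Experiment-2-style explicit prediction fitting


@dataclass(frozen=True)
class PredictionRecord:
    """One Pavlovian prediction trial: scene category, outcome, report."""

    trial: int
    scene_category: str
    shown_value: float  # rescaled to [0, 1]
    stated_prediction: float
    generating_pe: float | None = None


def _explicit_sse(
    alpha_pos: float, alpha_neg: float, records: list[PredictionRecord]
) -> tuple[float, float]:
    """Sum of squared (model value - stated prediction); also max |PE|."""
    values: dict[str, float] = {}
    sse = 0.0
    max_abs_pe = 0.0
    for rec in records:
        v = values.setdefault(rec.scene_category, 0.5)
        sse += (v - rec.stated_prediction) ** 2
        delta = rec.shown_value - v
        max_abs_pe = max(max_abs_pe, abs(delta))
        rate = alpha_pos if delta > 0 else alpha_neg
        values[rec.scene_category] = v + rate * delta
    return sse, max_abs_pe


def fit_explicit_prediction(
    records: list[PredictionRecord],
    n_restarts: int = 10,
    seed: int = 0,
    prior_penalty: bool = False,
) -> FitResult:
    """Least-squares fit of the valenced prediction model to stated values.

    Two scene-category value estimates start at the midpoint of the rescaled
    value range (0.5) and update with valenced learning rates against the
    model's own running estimate. No inverse temperature: the objective is
    the squared gap between model value and the participant's stated
    prediction. Optionally adds a Beta(2, 2) log-density penalty on the rates.
    """
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.scene_category] = counts.get(rec.scene_category, 0) + 1
    if not counts or min(counts.values()) < 2:
        raise ValueError("need at least 2 trials per scene category")
    ordered = sorted(records, key=lambda r: r.trial)
    rate_prior = PriorSpec("beta", 2.0, 2.0, 0.0, 1.0)
    bounds = [(0.0, 1.0), (0.0, 1.0)]

    def objective(u: np.ndarray) -> float:
        ap, an = _to_natural(u, bounds)
        sse, _ = _explicit_sse(ap, an, ordered)
        if prior_penalty:
            sse -= rate_prior.logpdf(ap) + rate_prior.logpdf(an)
        return sse

    rng = np.random.default_rng(seed)
    best = None
    objectives = []
    converged = False
    for restart in range(n_restarts):
        u0 = np.zeros(2) if restart == 0 else rng.normal(0.0, 2.0, 2)
        res = minimize(objective, u0, method="L-BFGS-B", options={"ftol": 1e-10})
        objectives.append(float(res.fun))
        converged = converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    ap, an = _to_natural(best.x, bounds)
    _, max_abs_pe = _explicit_sse(ap, an, ordered)
    params = ModelParams("ExplicitPrediction", alpha_pos=ap, alpha_neg=an)
    return FitResult(
        model_name="ExplicitPrediction",
        map_params=params,
        neg_log_posterior=float(best.fun),
        log_likelihood_at_map=math.nan,
        n_modeled_choices=len(ordered),
        bic=math.nan,
        asymmetry_index=models.asymmetry_index(ap, an),
        n_restarts=n_restarts,
        converged=converged,
        seed=seed,
        restart_objectives=tuple(objectives),
        unidentifiable=max_abs_pe < 1e-12,
    )
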