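"""Value-update and choice rules for the candidate learning models.

All models estimate machine values Q on the rescaled reward scale
(points / 80, so rewards lie in [0, 1]) with Q initialized at 0.5, and
update the chosen machine by a learning-rate-scaled prediction error
delta = target - Q. They differ in how the learning rate and the update
target are chosen:

* TD      — one learning rate alpha; target is the reward r.
* RSTD    — risk-sensitive TD: alpha_pos when delta > 0, alpha_neg
            otherwise. Asymmetric rates make the learner systematically
            over- or under-value variable-outcome machines, so the
            asymmetry index AI = (a+ - a-)/(a+ + a-) indexes revealed
            risk preference.
* FourLR  — RSTD with separate valenced rates for free and forced trials.
* Utility — one rate, but the target is the exponentiated utility r**rho;
            rho < 1 concave (risk-averse), rho > 1 convex (risk-seeking).

Choice on two-option trials is softmax in the value difference with
inverse temperature beta. Forced-trial outcomes update values but
contribute no choice likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .task import MachineSpec

__all__ = [
    "MODEL_NAMES",
    "PARAM_FIELDS",
    "N_PARAMS",
    "ModelParams",
    "ValueState",
    "TraceStep",
    "LearningTrace",
    "initialize_values",
    "update_value",
    "choice_prob",
    "asymmetry_index",
]

MODEL_NAMES = ("TD", "RSTD", "FourLR", "Utility", "ExplicitPrediction")

# free parameters per model, in canonical vector order
PARAM_FIELDS: dict[str, tuple[str, ...]] = {
    "TD": ("alpha", "beta"),
    "RSTD": ("alpha_pos", "alpha_neg", "beta"),
    "FourLR": ("alpha_pos_free", "alpha_neg_free", "alpha_pos_forced", "alpha_neg_forced", "beta"),
    "Utility": ("alpha", "beta", "rho"),
    "ExplicitPrediction": ("alpha_pos", "alpha_neg"),
}

N_PARAMS = {name: len(fields) for name, fields in PARAM_FIELDS.items()}

BETA_BOUNDS = (1e-6, 30.0)
RHO_BOUNDS = (0.0, 2.5)


@dataclass(frozen=True)
class ModelParams:
    """Free parameters of one model; only the fields the model uses are set."""

    model_name: str
    alpha: float | None = None
    alpha_pos: float | None = None
    alpha_neg: float | None = None
    alpha_pos_free: float | None = None
    alpha_neg_free: float | None = None
    alpha_pos_forced: float | None = None
    alpha_neg_forced: float | None = None
    beta: float | None = None
    rho: float | None = None

    def __post_init__(self) -> None:
        if self.model_name not in PARAM_FIELDS:
            raise ValueError(f"unknown model {self.model_name!r}")
        for name in PARAM_FIELDS[self.model_name]:
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"{self.model_name} requires parameter {name}")
            if name.startswith("alpha") and not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
            if name == "beta" and not BETA_BOUNDS[0] <= value <= BETA_BOUNDS[1]:
                raise ValueError(f"beta={value} outside {BETA_BOUNDS}")
            if name == "rho" and not RHO_BOUNDS[0] <= value <= RHO_BOUNDS[1]:
                raise ValueError(f"rho={value} outside {RHO_BOUNDS}")

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in PARAM_FIELDS[self.model_name]], dtype=float)

    @classmethod
    def from_vector(cls, model_name: str, vector: np.ndarray) -> "ModelParams":
        fields = PARAM_FIELDS[model_name]
        if len(vector) != len(fields):
            raise ValueError(f"{model_name} expects {len(fields)} parameters")
        return cls(model_name, **dict(zip(fields, map(float, vector))))

    def learning_rate(self, delta: float, agency: str = "free") -> float:
        """Rate applied to a prediction error of this sign/agency.

        Exactly-zero delta dispatches to the negative ("not better than
        expected") rate; documented tie-break, fixed across the package.
        """
        name = self.model_name
        if name in ("TD", "Utility"):
            return self.alpha
        if name in ("RSTD", "ExplicitPrediction"):
            return self.alpha_pos if delta > 0 else self.alpha_neg
        if name == "FourLR":
            if agency == "free":
                return self.alpha_pos_free if delta > 0 else self.alpha_neg_free
            return self.alpha_pos_forced if delta > 0 else self.alpha_neg_forced
        raise ValueError(name)


@dataclass
class ValueState:
    """Current machine-value estimates Q, on the rescaled [0, 1] scale."""

    q: dict[str, float]

    def copy(self) -> "ValueState":
        return ValueState(dict(self.q))


def initialize_values(machines: list[MachineSpec]) -> ValueState:
    """Every machine starts at Q = 0.5 (equivalent to 40 points)."""
    if not machines:
        raise ValueError("no machines to initialize")
    return ValueState({m.machine_id: 0.5 for m in machines})


def update_value(
    params: ModelParams,
    state: ValueState,
    chosen: str,
    reward: float,
    agency: str = "free",
) -> tuple[ValueState, float]:
    """Apply one outcome: returns the new state and the prediction error.

    The prediction error is computed against the model's target (reward, or
    reward**rho for the Utility model); only the chosen machine's value moves.
    """
    if not 0.0 <= reward <= 1.0:
        raise ValueError(f"reward {reward} outside [0, 1]")
    if chosen not in state.q:
        raise KeyError(f"machine {chosen!r} not in value state")
    target = reward ** params.rho if params.model_name == "Utility" else reward
    delta = target - state.q[chosen]
    rate = params.learning_rate(delta, agency)
    new_state = state.copy()
    new_state.q[chosen] = state.q[chosen] + rate * delta
    return new_state, delta


def choice_prob(beta: float, q_chosen: float, q_other: float) -> float:
    """Softmax probability of the chosen option among two.

    Computed from the value difference (equivalent to subtracting the max
    before exponentiation), so it is invariant to shifting both values and
    never overflows.
    """
    return 1.0 / (1.0 + math.exp(-beta * (q_chosen - q_other)))


def asymmetry_index(alpha_pos: float, alpha_neg: float) -> float:
    """AI = (a+ - a-)/(a+ + a-); positive means good surprises dominate.

    Defined as 0 at (0, 0): the singularity is removable and exact zeros
    are measure-zero under the fitting priors.
    """
    if not (0.0 <= alpha_pos <= 1.0 and 0.0 <= alpha_neg <= 1.0):
        raise ValueError("learning rates must lie in [0, 1]")
    total = alpha_pos + alpha_neg
    if total == 0.0:
        return 0.0
    return (alpha_pos - alpha_neg) / total


@dataclass(frozen=True)
class TraceStep:
    """One trial of a replayed session."""

    trial: int
    agency: str
    chosen: str
    q_pre: float
    delta: float
    q_post: float

    @property
    def valence(self) -> int:
        """Sign of the prediction error; exact zero counts as negative."""
        return 1 if self.delta > 0 else -1


@dataclass
class LearningTrace:
    """Per-trial values and prediction errors replayed under fixed parameters."""

    steps: list[TraceStep] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.steps)

    def __iter__(self):
        return iter(self.steps)

    def by_trial(self) -> dict[int, TraceStep]:
        return {s.trial: s for s in self.steps}
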