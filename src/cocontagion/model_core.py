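"""Core model definitions: parameters, compartment states, and ODE right-hand sides.

The model partitions a closed community into eight behavioural compartments:

====  ==========================================================
S     susceptible to both violent and racist behaviour
V     violence-infected (actively spreading violent behaviour)
U     negotiated (in formal mediation after violence)
R     racism-infected (actively spreading racist ideology)
Ivr   co-infected with both violence and racism
R1    recuperated from violence
R2    recuperated from racism
R3    recuperated from the co-infection
====  ==========================================================

Both behaviours spread by social contact, so the model is formally a
two-pathogen co-infection compartmental system.  New susceptibles enter at a
constant recruitment rate Lambda and every compartment is drained at the
natural exit rate mu, so the total population N obeys dN/dt = Lambda - mu*N
exactly (a conservation identity that is also the package's main integration
oracle).

The forces of infection are

    lambda_v = beta1 * (V + theta2 * Ivr)
    lambda_r = beta2 * (R + theta1 * Ivr)

i.e. co-infected individuals transmit each behaviour like singly infected
ones, up to the modification factors theta1/theta2.
"""

from __future__ import annotations

import dataclasses
import math
from typing import NamedTuple, Sequence, Union

import numpy as np

from .errors import InvalidParameterError, UnknownParameterError

__all__ = [
    "ModelParameters",
    "FullState",
    "ViolenceState",
    "RacismState",
    "PARAM_FIELDS",
    "STATE_LABELS",
    "force_of_infection_violence",
    "force_of_infection_racism",
    "rhs_full",
    "rhs_violence",
    "rhs_racism",
]

#: Compartment order used everywhere (state vectors, Jacobians, CSV columns).
STATE_LABELS = ("S", "V", "U", "R", "Ivr", "R1", "R2", "R3")


@dataclasses.dataclass(frozen=True)
class ModelParameters:
    """The sixteen nonnegative rate and modification constants of the model.

    Rates are per year; modification factors are dimensionless.

    Parameters
    ----------
    Lambda : recruitment rate of susceptibles (persons/year).
    mu : natural exit rate from the community (1/year); must be positive.
    beta1 : violence transmission rate (1/(person * year)).
    beta2 : racism transmission rate (1/(person * year)).
    beta_mod : modification factor for racism-infected acquiring violence.
    kappa : modification factor for violence-infected acquiring racism.
    delta : negotiation rate of violence-infected (1/year).
    epsilon : recuperation rate of negotiated individuals (1/year).
    alpha : return rate of violence-recuperated to susceptible (1/year).
    sigma : recuperation rate of racism-infected (1/year).
    rho : return rate of racism-recuperated to susceptible (1/year).
    omega : violence-only control rate acting on the co-infected (1/year).
    phi : recuperation rate from co-infection (1/year).
    theta : return rate of co-infection-recuperated to susceptible (1/year).
    theta1 : modification factor of co-infected on racism transmission.
    theta2 : modification factor of co-infected on violence transmission.
    """

    Lambda: float
    mu: float
    beta1: float
    beta2: float
    beta_mod: float
    kappa: float
    delta: float
    epsilon: float
    alpha: float
    sigma: float
    rho: float
    omega: float
    phi: float
    theta: float
    theta1: float = 1.0
    theta2: float = 1.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise InvalidParameterError(
                    f"parameter {f.name!r} must be a number, got {value!r}",
                    field=f.name,
                )
            value = float(value)
            object.__setattr__(self, f.name, value)
            if not math.isfinite(value) or value < 0.0:
                raise InvalidParameterError(
                    f"parameter {f.name!r} must be finite and >= 0, got {value}",
                    field=f.name,
                )
        if self.mu <= 0.0:
            raise InvalidParameterError(
                f"parameter 'mu' must be > 0 (the population equilibrium is "
                f"Lambda/mu), got {self.mu}",
                field="mu",
            )

    def to_dict(self) -> dict[str, float]:
        """Flat ASCII-keyed mapping, suitable for JSON serialization."""
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, mapping: dict[str, float]) -> "ModelParameters":
        """Build from a flat mapping; unknown keys are an error."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise UnknownParameterError(
                f"unknown parameter key(s): {', '.join(unknown)}",
                field=unknown[0],
            )
        missing = sorted(
            known
            - set(mapping)
            - {f.name for f in dataclasses.fields(cls) if f.default is not dataclasses.MISSING}
        )
        if missing:
            raise InvalidParameterError(
                f"missing parameter key(s): {', '.join(missing)}", field=missing[0]
            )
        return cls(**mapping)

    def replace(self, **changes: float) -> "ModelParameters":
        """A copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)


class FullState(NamedTuple):
    """The eight compartment counts (persons) in the fixed model order."""

    S: float
    V: float
    U: float
    R: float
    Ivr: float
    R1: float
    R2: float
    R3: float

    @property
    def N(self) -> float:
        return float(sum(self))

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "FullState":
        if len(y) != 8:
            raise ValueError(f"full state needs 8 components, got {len(y)}")
        return cls(*map(float, y))


class ViolenceState(NamedTuple):
    """Compartments of the violence-only submodel (S, V, U, R1)."""

    S: float
    V: float
    U: float
    R1: float

    @property
    def N(self) -> float:
        return float(sum(self))

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "ViolenceState":
        if len(y) != 4:
            raise ValueError(f"violence state needs 4 components, got {len(y)}")
        return cls(*map(float, y))

    def embed(self) -> FullState:
        """Embedding into the full state space with racism compartments at 0."""
        return FullState(S=self.S, V=self.V, U=self.U, R=0.0, Ivr=0.0,
                         R1=self.R1, R2=0.0, R3=0.0)


class RacismState(NamedTuple):
    """Compartments of the racism-only submodel (S, R, R2)."""

    S: float
    R: float
    R2: float

    @property
    def N(self) -> float:
        return float(sum(self))

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "RacismState":
        if len(y) != 3:
            raise ValueError(f"racism state needs 3 components, got {len(y)}")
        return cls(*map(float, y))

    def embed(self) -> FullState:
        """Embedding into the full state space with violence compartments at 0."""
        return FullState(S=self.S, V=0.0, U=0.0, R=self.R, Ivr=0.0,
                         R1=0.0, R2=self.R2, R3=0.0)


StateLike = Union[FullState, Sequence[float], np.ndarray]


def force_of_infection_violence(state: StateLike, p: ModelParameters) -> float:
    """Per-susceptible rate of acquiring violent behaviour (1/year).

    lambda_v = beta1 * (V + theta2 * Ivr): singly violence-infected and
    co-infected individuals both transmit, the latter scaled by theta2.
    """
    s = FullState.from_array(state) if not isinstance(state, FullState) else state
    return p.beta1 * (s.V + p.theta2 * s.Ivr)


def force_of_infection_racism(state: StateLike, p: ModelParameters) -> float:
    """Per-susceptible rate of acquiring racist behaviour (1/year).

    lambda_r = beta2 * (R + theta1 * Ivr).
    """
    s = FullState.from_array(state) if not isinstance(state, FullState) else state
    return p.beta2 * (s.R + p.theta1 * s.Ivr)


def rhs_full(t: float, y: StateLike, p: ModelParameters) -> np.ndarray:
    """Time derivative of the full 8-compartment system (persons/year).

    The componentwise sum equals Lambda - mu*N identically: every
    between-compartment flow appears once with each sign.
    """
    S, V, U, R, Ivr, R1, R2, R3 = (float(v) for v in y)
    lam_v = p.beta1 * (V + p.theta2 * Ivr)
    lam_r = p.beta2 * (R + p.theta1 * Ivr)
    return np.array([
        p.Lambda + p.alpha * R1 + p.rho * R2 + p.theta * R3
        - (lam_v + lam_r + p.mu) * S,
        lam_v * S - (p.delta + p.kappa * lam_r + p.mu) * V,
        p.delta * V - (p.epsilon + p.mu) * U,
        lam_r * S + p.omega * Ivr - (p.sigma + p.beta_mod * lam_v + p.mu) * R,
        p.beta_mod * lam_v * R + p.kappa * lam_r * V - (p.phi + p.omega + p.mu) * Ivr,
        p.epsilon * U - (p.alpha + p.mu) * R1,
        p.sigma * R - (p.rho + p.mu) * R2,
        p.phi * Ivr - (p.theta + p.mu) * R3,
    ])


def rhs_violence(t: float, y: StateLike, p: ModelParameters) -> np.ndarray:
    """Time derivative of the violence-only submodel (S, V, U, R1).

    Obtained from the full system on the face R = Ivr = R2 = R3 = 0, where
    the force of infection reduces to lambda_v = beta1 * V.
    """
    S, V, U, R1 = (float(v) for v in y)
    lam_v = p.beta1 * V
    return np.array([
        p.Lambda + p.alpha * R1 - (lam_v + p.mu) * S,
        lam_v * S - (p.delta + p.mu) * V,
        p.delta * V - (p.epsilon + p.mu) * U,
        p.epsilon * U - (p.alpha + p.mu) * R1,
    ])


def rhs_racism(t: float, y: StateLike, p: ModelParameters) -> np.ndarray:
    """Time derivative of the racism-only submodel (S, R, R2).

    The face V = U = Ivr = R1 = R3 = 0 of the full system, with
    lambda_r = beta2 * R.
    """
    S, R, R2 = (float(v) for v in y)
    lam_r = p.beta2 * R
    return np.array([
        p.Lambda + p.rho * R2 - (lam_r + p.mu) * S,
        lam_r * S - (p.sigma + p.mu) * R,
        p.sigma * R - (p.rho + p.mu) * R2,
    ])
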