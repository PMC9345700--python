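"""Basic reproduction numbers via next-generation matrices.

The next-generation matrix (NGM) method linearizes the infection subsystem at
the infection-free equilibrium S0 = Lambda/mu, splitting the linearization
into a new-infection matrix F and a transition matrix V; R0 is the spectral
radius of F V^-1.

Both submodels have a single infectious class, so their NGMs are scalars with
closed forms

    R0_v = beta1 * Lambda / (mu * (delta + mu))
    R0_r = beta2 * Lambda / (mu * (sigma + mu))

The full model has three infectious classes (V, R, Ivr).  Its 3x3 NGM is
upper-triangular with a zero last row, so its nonzero eigenvalues are exactly
the two submodel R0s and the full-model threshold is their maximum.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import InvalidParameterError
from .model_core import ModelParameters

__all__ = [
    "NGM",
    "r0_violence",
    "r0_racism",
    "r0_full",
    "build_ngm_violence",
    "build_ngm_racism",
    "build_ngm_full",
]


@dataclasses.dataclass(frozen=True)
class NGM:
    """A next-generation matrix pair (F, V) and its spectral radius.

    F holds rates of new infections, Vm rates of transition out of the
    infectious classes, both evaluated at the infection-free equilibrium.
    ``spectral_radius`` is the dominant eigenvalue magnitude of F Vm^-1,
    i.e. the basic reproduction number of the linearized subsystem.
    """

    F: np.ndarray
    Vm: np.ndarray
    spectral_radius: float
    labels: tuple[str, ...]

    @property
    def K(self) -> np.ndarray:
        """The next-generation matrix itself, F Vm^-1."""
        return self.F @ np.linalg.inv(self.Vm)


def _spectral_radius(F: np.ndarray, Vm: np.ndarray) -> float:
    if abs(np.linalg.det(Vm)) == 0.0:
        raise InvalidParameterError(
            "transition matrix V is singular: some infectious class has a "
            "zero total exit rate"
        )
    eigvals = np.linalg.eigvals(F @ np.linalg.inv(Vm))
    return float(np.max(np.abs(eigvals)))


def r0_violence(p: ModelParameters) -> float:
    """Closed-form basic reproduction number of the violence submodel.

    R0_v = beta1 * Lambda / (mu * (delta + mu)): the transmission rate in a
    wholly susceptible population of size Lambda/mu, times the mean time
    1/(delta+mu) spent in the violence-infected class.
    """
    return p.beta1 * p.Lambda / (p.mu * (p.delta + p.mu))


def r0_racism(p: ModelParameters) -> float:
    """Closed-form basic reproduction number of the racism submodel.

    R0_r = beta2 * Lambda / (mu * (sigma + mu)).
    """
    return p.beta2 * p.Lambda / (p.mu * (p.sigma + p.mu))


def r0_full(p: ModelParameters) -> float:
    """Basic reproduction number of the full co-contagion model.

    max(R0_v, R0_r): the full NGM is block-triangular in (V, R, Ivr), so the
    co-infected class contributes no additional eigenvalue.
    """
    return max(r0_violence(p), r0_racism(p))


def build_ngm_violence(p: ModelParameters) -> NGM:
    """1x1 NGM of the violence submodel: F = beta1*Lambda/mu, V = delta+mu."""
    F = np.array([[p.beta1 * p.Lambda / p.mu]])
    Vm = np.array([[p.delta + p.mu]])
    return NGM(F=F, Vm=Vm, spectral_radius=_spectral_radius(F, Vm), labels=("V",))


def build_ngm_racism(p: ModelParameters) -> NGM:
    """1x1 NGM of the racism submodel: F = beta2*Lambda/mu, V = sigma+mu."""
    F = np.array([[p.beta2 * p.Lambda / p.mu]])
    Vm = np.array([[p.sigma + p.mu]])
    return NGM(F=F, Vm=Vm, spectral_radius=_spectral_radius(F, Vm), labels=("R",))


def build_ngm_full(p: ModelParameters) -> NGM:
    """3x3 NGM of the full model over the infectious classes (V, R, Ivr).

    At the infection-free equilibrium S0 = Lambda/mu:

        F = [[beta1*S0, 0,        beta1*theta2*S0],
             [0,        beta2*S0, beta2*theta1*S0],
             [0,        0,        0              ]]
        V = diag(delta+mu, sigma+mu, phi+omega+mu)

    The last row of F is zero because co-infection arises only from an
    already-infected host (a sequential second acquisition, never a direct
    double transmission), so the spectral radius of F V^-1 equals
    max(R0_v, R0_r) regardless of theta1, theta2.
    """
    S0 = p.Lambda / p.mu
    F = np.array([
        [p.beta1 * S0, 0.0, p.beta1 * p.theta2 * S0],
        [0.0, p.beta2 * S0, p.beta2 * p.theta1 * S0],
        [0.0, 0.0, 0.0],
    ])
    Vm = np.diag([p.delta + p.mu, p.sigma + p.mu, p.phi + p.omega + p.mu])
    return NGM(F=F, Vm=Vm, spectral_radius=_spectral_radius(F, Vm),
               labels=("V", "R", "Ivr"))
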