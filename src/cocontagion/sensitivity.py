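"""Normalized forward sensitivity indices of the reproduction numbers.

The normalized forward sensitivity index (elasticity) of an output X with
respect to a parameter p is

    SI(p) = (dX/dp) * (p / X)

— the fractional change in X per fractional change in p.  For the closed-form
reproduction numbers the indices have exact analytic values; a central
finite-difference path is provided as an independent oracle.

For R0_v = beta1*Lambda / (mu*(delta+mu)):

    SI(beta1) = SI(Lambda) = +1
    SI(delta) = -delta/(delta+mu)
    SI(mu)    = -1 - mu/(delta+mu)

and symmetrically for R0_r with (beta2, sigma).  Every other parameter has
index exactly 0.  The full-model threshold max(R0_v, R0_r) is not
differentiable at a tie, so its report delegates to the strictly larger
submodel R0 and refuses ties explicitly.
"""

from __future__ import annotations

import dataclasses

from .errors import CocontagionError, InvalidParameterError
from .model_core import ModelParameters
from .reproduction import r0_full, r0_racism, r0_violence

__all__ = [
    "SensitivityReport",
    "SensitivityTieError",
    "sensitivity_index",
    "finite_difference_si",
    "sensitivity_report",
    "TARGETS",
]

TARGETS = ("r0_violence", "r0_racism", "r0_full")

_TARGET_FN = {
    "r0_violence": r0_violence,
    "r0_racism": r0_racism,
    "r0_full": r0_full,
}

_PARAM_NAMES = tuple(f.name for f in dataclasses.fields(ModelParameters))


class SensitivityTieError(CocontagionError):
    """max(R0_v, R0_r) is tied: its sensitivity is not well defined."""


@dataclasses.dataclass(frozen=True)
class SensitivityReport:
    """Indices of one reproduction number w.r.t. every model parameter.

    ``indices`` maps parameter name -> dimensionless index, ordered by
    decreasing |index|; parameters the target does not depend on are
    exactly 0.
    """

    target: str
    indices: dict[str, float]
    method: str

    def to_dict(self) -> dict:
        return {"target": self.target, "method": self.method,
                "indices": dict(self.indices)}


def _resolve_full_target(p: ModelParameters) -> str:
    """Which submodel R0 realizes max(R0_v, R0_r); ties are an error."""
    rv, rr = r0_violence(p), r0_racism(p)
    if rv == rr:
        raise SensitivityTieError(
            f"R0_v = R0_r = {rv:.6g}: the max is not differentiable at a tie; "
            "request r0_violence or r0_racism explicitly"
        )
    return "r0_violence" if rv > rr else "r0_racism"


def sensitivity_index(target: str, p: ModelParameters, name: str) -> float:
    """Analytic normalized forward sensitivity index SI(name) of a target R0.

    Requires target(p) > 0 for the normalization to be defined.
    """
    if target not in TARGETS:
        raise ValueError(f"unknown target {target!r}; choose from {TARGETS}")
    if name not in _PARAM_NAMES:
        raise InvalidParameterError(f"unknown parameter {name!r}", field=name)
    if _TARGET_FN[target](p) == 0.0:
        raise InvalidParameterError(
            f"{target}(p) = 0: sensitivity index undefined"
        )
    if target == "r0_full":
        target = _resolve_full_target(p)
    if target == "r0_violence":
        if name in ("beta1", "Lambda"):
            return 1.0
        if name == "delta":
            return -p.delta / (p.delta + p.mu)
        if name == "mu":
            return -1.0 - p.mu / (p.delta + p.mu)
        return 0.0
    # r0_racism
    if name in ("beta2", "Lambda"):
        return 1.0
    if name == "sigma":
        return -p.sigma / (p.sigma + p.mu)
    if name == "mu":
        return -1.0 - p.mu / (p.sigma + p.mu)
    return 0.0


def finite_difference_si(
    target: str,
    p: ModelParameters,
    name: str,
    h_rel: float = 1e-6,
) -> float:
    """Central-difference oracle for :func:`sensitivity_index`.

    (X(p*(1+h)) - X(p*(1-h))) / (2*h*X(p)) for the named parameter; requires
    the parameter to be positive (the index normalizes by it).
    """
    if target not in TARGETS:
        raise ValueError(f"unknown target {target!r}; choose from {TARGETS}")
    if name not in _PARAM_NAMES:
        raise InvalidParameterError(f"unknown parameter {name!r}", field=name)
    value = getattr(p, name)
    if value <= 0.0:
        raise InvalidParameterError(
            f"parameter {name!r} must be > 0 for a normalized index, "
            f"got {value}", field=name,
        )
    fn = _TARGET_FN[target]
    base = fn(p)
    if base == 0.0:
        raise InvalidParameterError(
            f"{target}(p) = 0: sensitivity index undefined"
        )
    if target == "r0_full":
        # refuse ties the same way the analytic path does
        _resolve_full_target(p)
    up = fn(p.replace(**{name: value * (1.0 + h_rel)}))
    dn = fn(p.replace(**{name: value * (1.0 - h_rel)}))
    return (up - dn) / (2.0 * h_rel * base)


def sensitivity_report(
    target: str,
    p: ModelParameters,
    method: str = "analytic",
    h_rel: float = 1e-6,
) -> SensitivityReport:
    """Indices for every model parameter, sorted by decreasing magnitude.

    ``method`` selects the analytic closed forms or the finite-difference
    oracle; for parameters currently at 0 the finite-difference path falls
    back to the analytic value (the normalization degenerates there).
    """
    if method not in ("analytic", "finite_difference"):
        raise ValueError(f"unknown method {method!r}")
    indices: dict[str, float] = {}
    for name in _PARAM_NAMES:
        if method == "finite_difference" and getattr(p, name) > 0.0:
            indices[name] = finite_difference_si(target, p, name, h_rel)
        else:
            indices[name] = sensitivity_index(target, p, name)
    ordered = dict(
        sorted(indices.items(), key=lambda kv: (-abs(kv[1]), kv[0]))
    )
    return SensitivityReport(target=target, indices=ordered, method=method)
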