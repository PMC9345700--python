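"""Time integration, scenario runs, parameter sweeps and invariant checks.

The ODE systems are non-stiff, so the default integrator is an adaptive
explicit Runge-Kutta 4(5) pair (scipy's RK45) run at tight tolerances
(rtol 1e-8, atol 1e-10).  Two structural facts make cheap, strong
correctness oracles:

* the total population obeys the scalar linear ODE dN/dt = Lambda - mu*N,
  whose solution N(t) = Lambda/mu + (N(0) - Lambda/mu) e^{-mu t} is known in
  closed form;
* the nonnegative orthant is forward-invariant, so any trajectory started
  from a nonnegative state must stay nonnegative up to solver tolerance.

Both are enforced on every run: breaches beyond tolerance raise rather than
being clipped silently.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Callable, Sequence

import numpy as np
import scipy.integrate

from .errors import ConvergenceError, InvariantViolationError
from .model_core import (
    FullState,
    ModelParameters,
    STATE_LABELS,
    rhs_full,
    rhs_racism,
    rhs_violence,
)
from .reproduction import r0_full, r0_racism, r0_violence

__all__ = [
    "Trajectory",
    "Scenario",
    "SweepRow",
    "default_initial_state",
    "integrate",
    "run_scenario",
    "sweep_r0",
    "control_effect",
    "check_invariants",
]

logger = logging.getLogger(__name__)

MODELS: dict[str, tuple[Callable, tuple[str, ...]]] = {
    "full": (rhs_full, STATE_LABELS),
    "violence": (rhs_violence, ("S", "V", "U", "R1")),
    "racism": (rhs_racism, ("S", "R", "R2")),
}

#: Negative values above this (i.e. closer to 0) are solver noise and get
#: clipped; anything below it aborts the run with diagnostics.
UNDERSHOOT_TOL = -1e-9


@dataclasses.dataclass(frozen=True)
class Trajectory:
    """A time grid with aligned state rows from one integration run."""

    times: np.ndarray
    states: np.ndarray
    params: ModelParameters
    model: str = "full"
    n_clipped: int = 0

    @property
    def labels(self) -> tuple[str, ...]:
        return MODELS[self.model][1]

    @property
    def N(self) -> np.ndarray:
        """Total population over time."""
        return self.states.sum(axis=1)

    def final_state(self) -> np.ndarray:
        return self.states[-1].copy()

    def column(self, label: str) -> np.ndarray:
        return self.states[:, self.labels.index(label)]


@dataclasses.dataclass(frozen=True)
class Scenario:
    """A named experiment: parameters, initial state, horizon, and optional
    per-member overrides for a family of runs (e.g. a control-rate sweep)."""

    name: str
    params: ModelParameters
    initial_state: tuple[float, ...] | None = None
    t_end: float = 50.0
    overrides: tuple[tuple[str, float], ...] = ()

    def __post_init__(self):
        if self.t_end <= 0:
            raise ValueError(f"t_end must be > 0, got {self.t_end}")


def default_initial_state(
    p: ModelParameters, seed_size: float = 1.0
) -> FullState:
    """A lightly seeded community near its demographic equilibrium.

    The population sits at Lambda/mu with ``seed_size`` persons in each of
    the three infected classes (V, R, Ivr) and the rest susceptible.
    """
    S = p.Lambda / p.mu - 3.0 * seed_size
    if S < 0:
        raise ValueError(
            f"seed of 3*{seed_size} persons exceeds the population Lambda/mu"
        )
    return FullState(S=S, V=seed_size, U=0.0, R=seed_size, Ivr=seed_size,
                     R1=0.0, R2=0.0, R3=0.0)


def integrate(
    model: str,
    y0: Sequence[float],
    p: ModelParameters,
    t_end: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_report: int = 201,
) -> Trajectory:
    """Integrate one of the three systems and return a checked trajectory.

    States are reported on an even grid of ``n_report`` times (>= 200 by
    default).  After integration the positivity and population-bound
    invariants are verified; tiny negative undershoot (within solver
    tolerance) is clipped to 0 and counted, larger undershoot raises
    :class:`InvariantViolationError` with diagnostics.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODELS)}")
    rhs, labels = MODELS[model]
    y0 = np.asarray(y0, dtype=float)
    if y0.shape != (len(labels),):
        raise ValueError(
            f"model {model!r} needs {len(labels)} components, got {y0.shape}"
        )
    if np.min(y0) < 0:
        raise ValueError(f"initial state must be nonnegative, got {y0}")
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")

    t_eval = np.linspace(0.0, t_end, max(int(n_report), 2))
    sol = scipy.integrate.solve_ivp(
        rhs, (0.0, t_end), y0, args=(p,), method="RK45",
        rtol=rtol, atol=atol, t_eval=t_eval,
    )
    if not sol.success:
        raise ConvergenceError(f"ODE solver failed: {sol.message}")

    states = sol.y.T.copy()
    worst = float(states.min())
    if worst < UNDERSHOOT_TOL:
        idx = np.unravel_index(np.argmin(states), states.shape)
        raise InvariantViolationError(
            f"positivity breached: {labels[idx[1]]} = {worst:.3g} at "
            f"t = {t_eval[idx[0]]:.4g}",
            diagnostics={
                "worst_value": worst,
                "time": float(t_eval[idx[0]]),
                "compartment": labels[idx[1]],
                "rtol": rtol,
                "atol": atol,
            },
        )
    clipped = int(np.count_nonzero(states < 0))
    if clipped:
        logger.info("clipped %d state entries in [%.1e, 0) to 0",
                    clipped, UNDERSHOOT_TOL)
    states = np.clip(states, 0.0, None)

    traj = Trajectory(times=t_eval, states=states, params=p, model=model,
                      n_clipped=clipped)
    N = traj.N
    bound = max(N[0], p.Lambda / p.mu) * (1.0 + 1e-6)
    if N.max() > bound:
        t_bad = float(t_eval[int(np.argmax(N))])
        raise InvariantViolationError(
            f"population bound breached: N = {N.max():.6g} > {bound:.6g} "
            f"at t = {t_bad:.4g}",
            diagnostics={"worst_value": float(N.max()), "time": t_bad,
                         "bound": bound},
        )
    return traj


def run_scenario(scenario: Scenario, **integrate_kwargs) -> Trajectory:
    """Integrate the full model for a scenario (overrides applied first)."""
    p = scenario.params
    for name, value in scenario.overrides:
        p = p.replace(**{name: value})
    y0 = scenario.initial_state
    if y0 is None:
        y0 = default_initial_state(p)
    logger.info("scenario %s: params=%s t_end=%s", scenario.name,
                p.to_dict(), scenario.t_end)
    return integrate("full", y0, p, scenario.t_end, **integrate_kwargs)


@dataclasses.dataclass(frozen=True)
class SweepRow:
    """One grid point of a reproduction-number sweep."""

    value: float
    r0_violence: float
    r0_racism: float
    r0_full: float
    error: str | None = None


def sweep_r0(
    p: ModelParameters, name: str, values: Sequence[float]
) -> list[SweepRow]:
    """Reproduction numbers along a one-parameter grid.

    A grid value that yields invalid parameters is recorded as an error row
    (NaN reproduction numbers), not a fatal failure.
    """
    rows: list[SweepRow] = []
    for v in values:
        try:
            q = p.replace(**{name: float(v)})
        except (ValueError, TypeError) as exc:
            rows.append(SweepRow(value=float(v), r0_violence=math.nan,
                                 r0_racism=math.nan, r0_full=math.nan,
                                 error=str(exc)))
            continue
        rows.append(SweepRow(value=float(v), r0_violence=r0_violence(q),
                             r0_racism=r0_racism(q), r0_full=r0_full(q)))
    return rows


def control_effect(
    p: ModelParameters,
    name: str,
    values: Sequence[float],
    y0: Sequence[float] | None = None,
    t_end: float = 50.0,
    **integrate_kwargs,
) -> list[tuple[float, Trajectory]]:
    """Full-model trajectories across a grid of one control rate.

    ``name`` must be one of the co-infection control rates (omega: violence-
    only control from the co-infected class; phi: recuperation from
    co-infection).  All runs share the same initial state and horizon, so
    the trajectories differ only through the control value.
    """
    if name not in ("omega", "phi"):
        raise ValueError(f"control parameter must be 'omega' or 'phi', got {name!r}")
    values = [float(v) for v in values]
    if any(b <= a for a, b in zip(values, values[1:])):
        raise ValueError("control values must be strictly ascending")
    if y0 is None:
        y0 = default_initial_state(p)
    out = []
    for v in values:
        q = p.replace(**{name: v})
        out.append((v, integrate("full", y0, q, t_end, **integrate_kwargs)))
    return out


def check_invariants(traj: Trajectory) -> dict[str, dict]:
    """Per-invariant pass/fail report for a computed trajectory.

    Checks positivity, the demographic bound N(t) <= max(N(0), Lambda/mu),
    and agreement of N(t) with its closed-form solution
    Lambda/mu + (N(0) - Lambda/mu) e^{-mu t}.
    """
    p = traj.params
    report: dict[str, dict] = {}

    worst = float(traj.states.min())
    idx = np.unravel_index(np.argmin(traj.states), traj.states.shape)
    report["positivity"] = {
        "passed": worst >= UNDERSHOOT_TOL,
        "worst_value": worst,
        "time": float(traj.times[idx[0]]),
        "compartment": traj.labels[idx[1]],
    }

    N = traj.N
    bound = max(N[0], p.Lambda / p.mu) * (1.0 + 1e-6)
    report["population_bound"] = {
        "passed": bool(N.max() <= bound),
        "worst_value": float(N.max()),
        "time": float(traj.times[int(np.argmax(N))]),
        "bound": bound,
    }

    N_exact = p.Lambda / p.mu + (N[0] - p.Lambda / p.mu) * np.exp(-p.mu * traj.times)
    err = np.abs(N - N_exact)
    report["population_closed_form"] = {
        "passed": bool(err.max() <= 1e-6 * max(N[0], 1.0)),
        "worst_value": float(err.max()),
        "time": float(traj.times[int(np.argmax(err))]),
    }
    return report
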