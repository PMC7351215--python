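"""Per-cycle bounded least-squares identification of the arterial parameters.

For every buffered cardiac cycle the five-element model is run forward
with the Euler-discretised state recursion

    X[k+1] = X[k] + h (A X[k] + B U[k]),    Yhat[k] = C X[k]

and the parameter vector Theta = (Rsa0, Rsa, Csa1, Csa2, Lsa) is sought
that minimises the integral-style squared output error

    J(Theta) = sum_k h * (Y[k] - Yhat[k])^2

subject to the physiological box Theta_lb <= Theta <= Theta_ub.  The
minimisation is an active-set-style bound-constrained least-squares
solve (trust-region reflective) terminating on the KKT first-order
conditions; the Jacobian of the residuals is computed analytically by a
forward-sensitivity recursion of the same Euler predictor, not by finite
differences.

On-line operation chains cycles: the first cycle is initialised either
from an explicit guess or from the genetic-algorithm cold start, and
every later cycle is warm-started from the previous estimate, which
keeps the local solver inside the right basin and makes tracking of
slowly varying parameters possible.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from . import _kernels
from .cardio_sim import HemoTrace
from .signals_io import CycleBuffer, segment_cycles, DEFAULT_SMOOTHING
from .windkessel import (
    DEFAULT_BOUNDS,
    DivergenceError,
    ParamBounds,
    WindkesselParams,
)

__all__ = [
    "IdentConfig",
    "IdentResult",
    "cost",
    "identify_cycle",
    "run_online",
    "initial_state",
]

#: Residual value substituted past a diverged predictor sample (keeps the
#: optimiser's objective finite while making divergence strongly penalised).
_RESID_CAP = 1e6


@dataclass(frozen=True)
class IdentConfig:
    """Solver settings for the per-cycle identification."""

    bounds: ParamBounds = field(default_factory=lambda: DEFAULT_BOUNDS)
    tol: float = 1e-4  # relative cost-change termination tolerance
    max_iter: int = 100
    x0_policy: str = "enddiastolic"
    warm_start: bool = True

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class IdentResult:
    """Outcome of one per-cycle identification."""

    theta_hat: WindkesselParams
    cost: float
    n_iter: int
    converged: bool
    cycle_index: int
    elapsed: float  # wall-clock seconds
    t_end: float = 0.0  # trace time at end of the cycle


def initial_state(cycle: CycleBuffer, policy: str = "enddiastolic", theta=None):
    """Initial predictor state X1 for a cycle and its parameter gradient.

    Returns ``(x0, S0)`` with ``S0 = dX1/dTheta`` of shape (3, 5).

    "enddiastolic" (default)
        Cycles are anchored at end-diastole where the aortic flow is ~0
        and the inertance carries a slowly varying discharge flow, so
        ``p_sa ~ p_ao = Y1`` — but the compliances are still discharging
        through the peripheral resistance, splitting the outflow
        quasi-statically in proportion to their capacities:
        ``Q_Csa1(0) = -Csa1/(Csa1+Csa2) * (Y1 - p_sv,1)/Rsa``.
        This component depends on Theta, hence the non-zero S0.
    "pressure-only"
        The simpler ``[Y1, Y1, 0]`` (ignores the diastolic run-off; its
        residual transient biases the slow parameters noticeably).
    "zero"
        The origin; for open-loop synthetic cycles started at rest.
    """
    S0 = np.zeros((3, 5))
    if policy == "pressure-only":
        return np.array([cycle.Y[0], cycle.Y[0], 0.0]), S0
    if policy == "zero":
        return np.zeros(3), S0
    if policy != "enddiastolic":
        raise ValueError(f"unknown initial-state policy {policy!r}")
    if theta is None:
        raise ValueError("enddiastolic policy needs theta")
    _, R, C1, C2, _ = np.asarray(theta, dtype=float)
    Y1 = cycle.Y[0]
    psv1 = cycle.U[0, 2]
    g = (Y1 - psv1) / R
    frac = C1 / (C1 + C2)
    x0 = np.array([Y1, Y1, -frac * g])
    S0[2, 1] = frac * g / R
    S0[2, 2] = -C2 / (C1 + C2) ** 2 * g
    S0[2, 3] = frac / (C1 + C2) * g
    return x0, S0


def _residuals(theta: np.ndarray, cycle: CycleBuffer, policy: str, want_jac: bool):
    theta = np.asarray(theta, dtype=float)
    x0, S0 = initial_state(cycle, policy, theta)
    resid, jac, bad = _kernels.euler_predict(
        theta, cycle.U, cycle.Y, cycle.h, x0, S0, want_jac
    )
    if bad >= 0:
        resid = resid.copy()
        resid[bad:] = _RESID_CAP * np.sqrt(cycle.h)
        jac = jac.copy()
        jac[bad:] = 0.0
    return resid, jac, bad


def cost(theta, cycle: CycleBuffer, x0_policy: str = "enddiastolic") -> float:
    """The identification cost J(Theta) = sum_k h (Y_k - Yhat_k)^2.

    Raises :class:`DivergenceError` (with the offending theta attached)
    if the Euler predictor blows up for this parameter set.
    """
    if isinstance(theta, WindkesselParams):
        theta = theta.as_array()
    theta = np.asarray(theta, dtype=float)
    x0, S0 = initial_state(cycle, x0_policy, theta)
    resid, _, bad = _kernels.euler_predict(
        theta, cycle.U, cycle.Y, cycle.h, x0, S0, False
    )
    if bad >= 0:
        raise DivergenceError(step=bad, theta=theta)
    return float(resid @ resid)


def identify_cycle(
    cycle: CycleBuffer,
    theta_init: WindkesselParams,
    config: IdentConfig | None = None,
) -> IdentResult:
    """Bound-constrained least-squares fit of one cycle.

    ``theta_init`` must already satisfy the bounds — out-of-box starts
    raise instead of being clipped silently.
    """
    config = config or IdentConfig()
    if isinstance(theta_init, WindkesselParams):
        t0 = theta_init.as_array()
    else:
        t0 = np.asarray(theta_init, dtype=float)
    lb = config.bounds.lb.as_array()
    ub = config.bounds.ub.as_array()
    if np.any(t0 < lb) or np.any(t0 > ub):
        raise ValueError(
            f"theta_init {t0} violates bounds [{lb}, {ub}]; no silent clipping"
        )
    tic = time.perf_counter()
    res = least_squares(
        lambda th: _residuals(th, cycle, config.x0_policy, False)[0],
        t0,
        jac=lambda th: _residuals(th, cycle, config.x0_policy, True)[1],
        bounds=(lb, ub),
        method="trf",
        ftol=config.tol,
        xtol=1e-12,
        gtol=1e-10,
        x_scale=ub - lb,
        max_nfev=config.max_iter,
    )
    elapsed = time.perf_counter() - tic
    return IdentResult(
        theta_hat=WindkesselParams.from_array(res.x),
        cost=float(2.0 * res.cost),  # least_squares cost is 0.5 * sum r^2
        n_iter=int(res.nfev),
        converged=bool(res.status > 0),
        cycle_index=cycle.cycle_index,
        elapsed=elapsed,
        t_end=cycle.t_end,
    )


def run_online(
    trace: HemoTrace,
    config: IdentConfig | None = None,
    cold_start="ga",
    heart_rate: float = 60.0,
    mode: str = "fixed",
    smoothing: int | None = DEFAULT_SMOOTHING,
    ga_config=None,
    seed=None,
) -> list[IdentResult]:
    """On-line identification over a whole trace, one result per cycle.

    cold_start
        ``"ga"`` (genetic-algorithm global search on the first cycle),
        or an explicit :class:`WindkesselParams`/array used directly.
    """
    config = config or IdentConfig()
    cycles = segment_cycles(trace, mode=mode, heart_rate=heart_rate,
                            smoothing=smoothing)
    if isinstance(cold_start, str) and cold_start == "ga":
        from .ga_init import GAConfig, ga_initialize

        gacfg = ga_config or GAConfig(seed=seed)
        theta = ga_initialize(cycles[0], config.bounds, gacfg)
    elif isinstance(cold_start, WindkesselParams):
        theta = cold_start
    else:
        theta = WindkesselParams.from_array(cold_start)

    results = []
    for cyc in cycles:
        result = identify_cycle(cyc, theta, config)
        results.append(result)
        if config.warm_start:
            theta = result.theta_hat
    return results


def results_to_frame(results: list[IdentResult]):
    """Tabulate identification results (one row per cycle)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "cycle": [r.cycle_index for r in results],
            "t_end": [r.t_end for r in results],
            "Rsa0": [r.theta_hat.Rsa0 for r in results],
            "Rsa": [r.theta_hat.Rsa for r in results],
            "Csa1": [r.theta_hat.Csa1 for r in results],
            "Csa2": [r.theta_hat.Csa2 for r in results],
            "Lsa": [r.theta_hat.Lsa for r in results],
            "cost": [r.cost for r in results],
            "n_iter": [r.n_iter for r in results],
            "converged": [r.converged for r in results],
        }
    )
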