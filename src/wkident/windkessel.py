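"""Five-element Windkessel model of the systemic arterial tree.

The model lumps the arterial system into a characteristic resistance
``Rsa0`` at the aortic root, a proximal compliance ``Csa1``, an inertance
``Lsa``, a distal compliance ``Csa2`` and a peripheral resistance ``Rsa``
draining into the venous bed.  It is a MISO system: inputs are the aortic
flow ``Q_ao``, its time derivative and the systemic venous pressure
``p_sv``; the single output is the aortic pressure ``p_ao``.

State-space realisation (1-based row/col indexing used in docs and tests)::

    X = [p_ao, p_sa, Q_Csa1]^T        U = [Q_ao, dQ_ao/dt, p_sv]^T

    A = [[-Rsa0/Lsa,  Rsa0/Lsa,   1/Csa1 ],
         [ 0,        -1/(Rsa*Csa2), -1/Csa2],
         [-1/Lsa,     1/Lsa,       0      ]]

    B = [[0,      Rsa0, 0          ],
         [1/Csa2, 0,    1/(Rsa*Csa2)],
         [0,      1,    0          ]]

    C = [1, 0, 0]

where ``p_sa`` is the pressure at the distal compliance node and
``Q_Csa1`` the flow into the proximal compliance branch.

Units throughout: pressures mmHg, flows mL/s, resistances mmHg*s/mL,
compliances mL/mmHg, inertance mmHg*s^2/mL, time s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WindkesselParams",
    "ParamBounds",
    "StateVector",
    "InputSample",
    "StateSpaceMatrices",
    "NORMAL_PARAMS",
    "DEFAULT_BOUNDS",
    "PARAM_NAMES",
    "build_state_space",
    "partial_matrices",
    "simulate_discrete",
    "dc_gain",
    "transfer_function",
    "DivergenceError",
]

#: Canonical ordering of the parameter vector Theta.
PARAM_NAMES = ("Rsa0", "Rsa", "Csa1", "Csa2", "Lsa")


class DivergenceError(RuntimeError):
    """Raised when the forward-Euler recursion produces a non-finite state.

    Attributes ``step`` (index of the offending sample, 0-based) and
    ``theta`` (the parameter vector in use, if known) aid diagnosis.
    """

    def __init__(self, step: int, theta=None):
        self.step = step
        self.theta = theta
        msg = f"discrete simulation diverged at step {step}"
        if theta is not None:
            msg += f" for theta={np.asarray(theta)}"
        super().__init__(msg)


@dataclass(frozen=True)
class WindkesselParams:
    """The identified parameter vector Theta, in fixed order.

    Rsa0
        Characteristic (proximal) systemic resistance [mmHg*s/mL].
    Rsa
        Peripheral systemic arterial resistance [mmHg*s/mL].
    Csa1
        Proximal arterial compliance [mL/mmHg].
    Csa2
        Distal arterial compliance [mL/mmHg].
    Lsa
        Arterial inertance [mmHg*s^2/mL].
    """

    Rsa0: float
    Rsa: float
    Csa1: float
    Csa2: float
    Lsa: float

    def __post_init__(self):
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0.0:
                raise ValueError(f"parameter {name} must be finite and > 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.Rsa0, self.Rsa, self.Csa1, self.Csa2, self.Lsa])

    @classmethod
    def from_array(cls, theta) -> "WindkesselParams":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (5,):
            raise ValueError(f"theta must have shape (5,), got {theta.shape}")
        return cls(*theta)


#: Normal (healthy adult) parameter values.
NORMAL_PARAMS = WindkesselParams(Rsa0=0.1, Rsa=1.0, Csa1=0.9, Csa2=0.25, Lsa=0.0003)


@dataclass(frozen=True)
class ParamBounds:
    """Elementwise box bounds on Theta used by the constrained identifier."""

    lb: WindkesselParams
    ub: WindkesselParams

    def __post_init__(self):
        if not np.all(self.lb.as_array() < self.ub.as_array()):
            raise ValueError("lower bounds must be strictly below upper bounds")

    def contains(self, theta: WindkesselParams, atol: float = 0.0) -> bool:
        t = theta.as_array()
        return bool(
            np.all(t >= self.lb.as_array() - atol)
            and np.all(t <= self.ub.as_array() + atol)
        )


#: Physiological search box: intentionally somewhat wider than the
#: normal physiological range.
DEFAULT_BOUNDS = ParamBounds(
    lb=WindkesselParams(0.01, 0.5, 0.1, 0.1, 0.00001),
    ub=WindkesselParams(0.5, 2.0, 2.0, 2.0, 0.1),
)


@dataclass(frozen=True)
class StateVector:
    """One state sample X = [p_ao, p_sa, Q_Csa1]^T."""

    pao: float
    psa: float
    QCsa1: float

    def as_array(self) -> np.ndarray:
        return np.array([self.pao, self.psa, self.QCsa1])


@dataclass(frozen=True)
class InputSample:
    """One input sample U = [Q_ao, dQ_ao/dt, p_sv]^T."""

    Qao: float
    dQao_dt: float
    psv: float

    def as_array(self) -> np.ndarray:
        return np.array([self.Qao, self.dQao_dt, self.psv])


@dataclass(frozen=True)
class StateSpaceMatrices:
    """The (A, B, C) realisation of the five-element model."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray


def build_state_space(theta: WindkesselParams) -> StateSpaceMatrices:
    """Assemble the continuous-time state-space matrices for ``theta``.

    Raises ``ValueError`` for non-positive parameters (enforced by the
    ``WindkesselParams`` constructor).
    """
    if not isinstance(theta, WindkesselParams):
        theta = WindkesselParams.from_array(theta)
    R0, R, C1, C2, L = theta.as_array()
    A = np.array(
        [
            [-R0 / L, R0 / L, 1.0 / C1],
            [0.0, -1.0 / (R * C2), -1.0 / C2],
            [-1.0 / L, 1.0 / L, 0.0],
        ]
    )
    B = np.array(
        [
            [0.0, R0, 0.0],
            [1.0 / C2, 0.0, 1.0 / (R * C2)],
            [0.0, 1.0, 0.0],
        ]
    )
    C = np.array([[1.0, 0.0, 0.0]])
    return StateSpaceMatrices(A=A, B=B, C=C)


def partial_matrices(theta: WindkesselParams):
    """Partial derivatives (dA/dTheta_i, dB/dTheta_i) for i = 1..5.

    Obtained by differentiating each (A, B) entry with respect to the
    five parameters; dC/dTheta = 0.  Returns two arrays of shape
    (5, 3, 3) ordered as ``PARAM_NAMES``.
    """
    if not isinstance(theta, WindkesselParams):
        theta = WindkesselParams.from_array(theta)
    R0, R, C1, C2, L = theta.as_array()
    dA = np.zeros((5, 3, 3))
    dB = np.zeros((5, 3, 3))
    # d/dRsa0
    dA[0] = [[-1 / L, 1 / L, 0], [0, 0, 0], [0, 0, 0]]
    dB[0] = [[0, 1, 0], [0, 0, 0], [0, 0, 0]]
    # d/dRsa
    dA[1, 1, 1] = 1.0 / (R * R * C2)
    dB[1, 1, 2] = -1.0 / (R * R * C2)
    # d/dCsa1
    dA[2, 0, 2] = -1.0 / (C1 * C1)
    # d/dCsa2
    dA[3, 1, 1] = 1.0 / (R * C2 * C2)
    dA[3, 1, 2] = 1.0 / (C2 * C2)
    dB[3, 1, 0] = -1.0 / (C2 * C2)
    dB[3, 1, 2] = -1.0 / (R * C2 * C2)
    # d/dLsa
    dA[4] = [
        [R0 / L**2, -R0 / L**2, 0],
        [0, 0, 0],
        [1 / L**2, -1 / L**2, 0],
    ]
    return dA, dB


def simulate_discrete(
    matrices: StateSpaceMatrices,
    inputs: np.ndarray,
    x0: np.ndarray,
    h: float,
):
    """Forward-Euler simulation of the model over a sampled input record.

    The recursion is ``X[k+1] = X[k] + h*(A X[k] + B U[k])`` with output
    ``Y[k] = C X[k]``; the first output is evaluated at ``x0`` itself, so
    one output is produced per input sample.

    Parameters
    ----------
    inputs : (m, 3) array
        Rows are ``[Q_ao, dQ_ao/dt, p_sv]`` samples.
    x0 : (3,) array or StateVector
        Initial state ``[p_ao, p_sa, Q_Csa1]``.
    h : float
        Sample interval in seconds (> 0).

    Returns
    -------
    states : (m, 3) array, outputs : (m,) array

    Raises
    ------
    DivergenceError
        If the recursion produces a non-finite or numerically exploding
        state (Euler instability at too large ``h``).
    """
    if h <= 0:
        raise ValueError(f"h must be > 0, got {h}")
    if isinstance(x0, StateVector):
        x0 = x0.as_array()
    U = np.atleast_2d(np.asarray(inputs, dtype=float))
    if U.shape[0] == 0:
        raise ValueError("inputs must be non-empty")
    if U.shape[1] != 3:
        raise ValueError(f"inputs must have 3 columns, got shape {U.shape}")
    m = U.shape[0]
    A, B, C = matrices.A, matrices.B, matrices.C
    X = np.empty((m, 3))
    x = np.asarray(x0, dtype=float).copy()
    for k in range(m):
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > 1e12:
            raise DivergenceError(step=k)
        X[k] = x
        x = x + h * (A @ x + B @ U[k])
    Y = X @ C.ravel()
    return X, Y


def dc_gain(theta: WindkesselParams) -> np.ndarray:
    """Steady-state gain from each input channel to the output.

    Closed form: ``-C A^{-1} B = [Rsa, Lsa, 1]`` — at rest the model is a
    pure series resistance above the venous pressure.
    """
    m = build_state_space(theta)
    return -(m.C @ np.linalg.solve(m.A, m.B)).ravel()


def transfer_function(theta: WindkesselParams, omega) -> np.ndarray:
    """MISO transfer function G(jw) = C (jw I - A)^{-1} B.

    Parameters
    ----------
    omega : array of angular frequencies [rad/s], finite and >= 0.

    Returns
    -------
    (n, 3) complex array: row i is the 1x3 frequency response at omega[i].
    """
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    if not np.all(np.isfinite(omega)) or np.any(omega < 0):
        raise ValueError("omega must be finite and non-negative")
    m = build_state_space(theta)
    I = np.eye(3)
    G = np.empty((omega.size, 3), dtype=complex)
    for i, w in enumerate(omega):
        G[i] = (m.C @ np.linalg.solve(1j * w * I - m.A, m.B)).ravel()
    return G
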