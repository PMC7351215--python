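"""Analytic parameter sensitivity of the arterial transfer function.

The MISO transfer function of the five-element model is
``G(s) = C (sI - A)^{-1} B`` (1x3: one entry per input channel).  The
sensitivity of G to parameter Theta_i at an expansion point Theta_0 is
the partial derivative

    S_i(s) = d G(s, Theta) / d Theta_i |_{Theta_0}
           = C (sI-A)^{-1} (dA/dTheta_i) (sI-A)^{-1} B
             + C (sI-A)^{-1} (dB/dTheta_i)

with dC/dTheta = 0 and the dA, dB matrices obtained symbolically from
the model entries (see :func:`wkident.windkessel.partial_matrices`).  A
central-finite-difference evaluator is provided as an independent
numerical oracle, and Bode-style magnitude/phase tables render the
result for plotting or export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .windkessel import (
    PARAM_NAMES,
    WindkesselParams,
    build_state_space,
    partial_matrices,
    transfer_function,
)

__all__ = [
    "SensitivityResult",
    "default_omega_grid",
    "analytic_sensitivity",
    "fd_sensitivity",
    "bode",
    "plot_bode",
]

#: Input-channel names in U order.
CHANNEL_NAMES = ("Qao", "dQao_dt", "psv")


def default_omega_grid(fmin: float = 0.01, fmax: float = 100.0, n: int = 200) -> np.ndarray:
    """Log-spaced angular-frequency grid [rad/s] covering fmin..fmax Hz
    (default 0.01-100 Hz, bracketing the ~1 Hz physiological anchor)."""
    return 2 * np.pi * np.logspace(np.log10(fmin), np.log10(fmax), n)


@dataclass
class SensitivityResult:
    """S[i, j, w]: sensitivity of the output to parameter i via input
    channel j at angular frequency omega[w]."""

    omega: np.ndarray
    S: np.ndarray  # (5, 3, n) complex
    theta0: WindkesselParams

    def __post_init__(self):
        self.omega = np.asarray(self.omega, dtype=float)
        if np.any(np.diff(self.omega) <= 0):
            raise ValueError("omega grid must be strictly increasing")
        if self.S.shape != (5, 3, self.omega.size):
            raise ValueError(f"S must be (5, 3, {self.omega.size}), got {self.S.shape}")


def analytic_sensitivity(theta0: WindkesselParams, omega=None) -> SensitivityResult:
    """Closed-form S_i(jw) for all five parameters and three channels."""
    if omega is None:
        omega = default_omega_grid()
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    m = build_state_space(theta0)
    dA, dB = partial_matrices(theta0)
    I = np.eye(3)
    S = np.empty((5, 3, omega.size), dtype=complex)
    for w_idx, w in enumerate(omega):
        M = np.linalg.inv(1j * w * I - m.A)
        CM = m.C @ M
        MB = M @ m.B
        for i in range(5):
            S[i, :, w_idx] = (CM @ dA[i] @ MB + CM @ dB[i]).ravel()
    return SensitivityResult(omega=omega, S=S, theta0=theta0)


def fd_sensitivity(
    theta0: WindkesselParams,
    omega=None,
    rel_step: float = 1e-6,
) -> SensitivityResult:
    """Central-difference approximation of the same sensitivities, built
    only on :func:`transfer_function` (verification oracle)."""
    if rel_step <= 0:
        raise ValueError("rel_step must be > 0")
    if omega is None:
        omega = default_omega_grid()
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    t0 = theta0.as_array()
    S = np.empty((5, 3, omega.size), dtype=complex)
    for i in range(5):
        dt = rel_step * t0[i]
        tp, tm = t0.copy(), t0.copy()
        tp[i] += dt
        tm[i] -= dt
        Gp = transfer_function(WindkesselParams.from_array(tp), omega)
        Gm = transfer_function(WindkesselParams.from_array(tm), omega)
        S[i] = ((Gp - Gm) / (2 * dt)).T
    return SensitivityResult(omega=omega, S=S, theta0=theta0)


def bode(result: SensitivityResult) -> pd.DataFrame:
    """Magnitude [dB] and unwrapped phase [deg] per (parameter, channel).

    Long-format table with columns ``omega`` [rad/s], ``freq_hz``,
    ``parameter``, ``channel``, ``mag_db``, ``phase_deg``.  A zero
    magnitude is reported as -inf dB.
    """
    rows = []
    with np.errstate(divide="ignore"):
        for i, pname in enumerate(PARAM_NAMES):
            for j, cname in enumerate(CHANNEL_NAMES):
                s = result.S[i, j]
                mag = 20.0 * np.log10(np.abs(s))
                phase = np.degrees(np.unwrap(np.angle(s)))
                rows.append(
                    pd.DataFrame(
                        {
                            "omega": result.omega,
                            "freq_hz": result.omega / (2 * np.pi),
                            "parameter": pname,
                            "channel": cname,
                            "mag_db": mag,
                            "phase_deg": phase,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


def plot_bode(result: SensitivityResult, path=None):
    """5x2 Bode grid (magnitude, phase per parameter; one line per input
    channel).  Saves to ``path`` if given, else returns the figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = bode(result)
    fig, axes = plt.subplots(5, 2, figsize=(9, 12), sharex=True)
    for i, pname in enumerate(PARAM_NAMES):
        for cname in CHANNEL_NAMES:
            sub = table[(table.parameter == pname) & (table.channel == cname)]
            axes[i, 0].semilogx(sub.freq_hz, sub.mag_db, label=cname)
            axes[i, 1].semilogx(sub.freq_hz, sub.phase_deg, label=cname)
        axes[i, 0].set_ylabel(f"{pname}\n|S| [dB]")
        axes[i, 1].set_ylabel("phase [deg]")
        axes[i, 0].grid(True, which="both", alpha=0.3)
        axes[i, 1].grid(True, which="both", alpha=0.3)
    axes[0, 0].legend(fontsize=8)
    axes[-1, 0].set_xlabel("frequency [Hz]")
    axes[-1, 1].set_xlabel("frequency [Hz]")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
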