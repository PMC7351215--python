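"""Shared fixtures: simulated traces and synthetic open-loop cycles."""

import numpy as np
import pytest

import wkident as wk


@pytest.fixture(scope="session")
def normal_trace():
    """12 s of calibrated normal haemodynamics at 60 bpm (noiseless)."""
    return wk.simulate(wk.normal_config(), 12.0, warmup=12.0)


@pytest.fixture(scope="session")
def normal_cycles(normal_trace):
    return wk.segment_cycles(normal_trace)


def make_open_loop_cycle(theta=None, m=1000, h=1e-3, seed=123):
    """A self-generated cycle: smooth, persistently exciting inputs run
    open-loop through the Euler-discretised model itself, so the predictor
    reproduces the output exactly at the generating parameters.

    The input U is built from a pulse-like flow (half-wave rectified
    two-harmonic wave), its analytic derivative and a gently varying
    venous pressure; the cycle starts at rest (x0 = 0, "zero" policy).
    """
    theta = theta or wk.NORMAL_PARAMS
    rng = np.random.default_rng(seed)
    t = np.arange(m) * h
    f = 1.0
    amp = 300.0 + 50.0 * rng.random()
    q = amp * np.maximum(np.sin(2 * np.pi * f * t), 0.0) ** 2
    dq = np.where(
        np.sin(2 * np.pi * f * t) > 0,
        amp * 2 * np.sin(2 * np.pi * f * t) * np.cos(2 * np.pi * f * t) * 2 * np.pi * f,
        0.0,
    )
    psv = 5.0 + 0.5 * np.sin(2 * np.pi * 0.5 * t)
    U = np.column_stack([q, dq, psv])
    mats = wk.build_state_space(theta)
    _, Y = wk.simulate_discrete(mats, U, np.zeros(3), h)
    return wk.CycleBuffer(h=h, U=U, Y=Y, cycle_index=0)


@pytest.fixture()
def open_loop_cycle():
    return make_open_loop_cycle()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_theta(rng, bounds=wk.DEFAULT_BOUNDS):
    lb, ub = bounds.lb.as_array(), bounds.ub.as_array()
    # log-uniform: the box spans 4 decades on Lsa
    return wk.WindkesselParams.from_array(
        np.exp(rng.uniform(np.log(lb), np.log(ub)))
    )
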