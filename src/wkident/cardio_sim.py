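"""Closed-loop lumped cardiovascular simulator (synthetic-data generator).

The circulation is a fixed-topology lumped network: four heart chambers
driven by periodic time-varying elastances, four valves modelled as ideal
diodes in series with a resistance and an inertance, a five-element
Windkessel block for each of the systemic and pulmonary arterial trees,
and an RC bed for each venous return.  The systemic arterial block is
*exactly* the model of :mod:`wkident.windkessel`, so traces produced here
have a well-defined parameter ground truth for the identifier.

The default configuration is calibrated so that the normal run at
60 bpm reproduces textbook adult haemodynamics: cycle-mean aortic flow
of about 84 mL/s (cardiac output ~5 L/min), peak ejection flow of about
450 mL/s, and an aortic pressure wave peaking near 125 mmHg, with the
systemic arterial parameters at their normal values
(Rsa0=0.1, Rsa=1.0, Csa1=0.9, Csa2=0.25, Lsa=3e-4).

Time-varying experiment protocols (linear ramps on Rsa and Csa1) and
additive white Gaussian measurement noise emulate the validation
scenarios the identifier is meant to survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from . import _kernels
from .windkessel import WindkesselParams, NORMAL_PARAMS

__all__ = [
    "ElastanceParams",
    "ValveParams",
    "VenousParams",
    "CardioConfig",
    "RampSegment",
    "RampProtocol",
    "HemoTrace",
    "normal_config",
    "default_ramp_protocol",
    "normalized_elastance",
    "apply_ramp",
    "step",
    "simulate",
    "add_noise",
    "STATE_FIELDS",
]

#: Layout of the raw circulation state vector used by :func:`step`.
STATE_FIELDS = (
    "V_lv", "V_la", "V_rv", "V_ra",
    "Q_mi", "Q_ao", "Q_ti", "Q_po",
    "p_ao", "p_sa", "Q_Csa1",
    "p_pa", "p_ps", "Q_Cpa1",
    "V_sv", "V_pv",
)


@dataclass(frozen=True)
class ElastanceParams:
    """Double-Hill time-varying elastance of one heart chamber.

    The normalised activation is
    ``e(t) = [(t/tau1)^n1 / (1+(t/tau1)^n1)] * [1 / (1+(t/tau2)^n2)]``
    rescaled to peak at exactly 1, with ``tau1``/``tau2`` expressed as
    fractions of the beat period and the whole waveform shifted by
    ``onset`` (fraction of the beat; atria contract late in diastole).
    Chamber pressure is ``p = E(t) * (V - V0)`` with
    ``E = Emin + (Emax - Emin) * e``.
    """

    Emax: float  # peak elastance [mmHg/mL]
    Emin: float  # baseline elastance [mmHg/mL]
    V0: float  # unstressed volume [mL]
    tau1_frac: float = 0.269
    tau2_frac: float = 0.452
    n1: float = 1.9
    n2: float = 21.9
    onset: float = 0.0

    def __post_init__(self):
        if not (self.Emax > self.Emin > 0):
            raise ValueError("need Emax > Emin > 0")
        if not (0 <= self.onset < 1):
            raise ValueError("onset must be in [0, 1)")

    @property
    def norm(self) -> float:
        """Peak of the raw double-Hill shape (activation normaliser)."""
        tloc = np.linspace(1e-6, 1.0, 4001)
        a = (tloc / self.tau1_frac) ** self.n1
        raw = a / (1 + a) / (1 + (tloc / self.tau2_frac) ** self.n2)
        return float(raw.max())


@dataclass(frozen=True)
class ValveParams:
    """Ideal diode valve in series with resistance R and inertance L."""

    R: float  # [mmHg*s/mL]
    L: float  # [mmHg*s^2/mL]

    def __post_init__(self):
        if self.R <= 0 or self.L < 0:
            raise ValueError("valve needs R > 0 and L >= 0")


@dataclass(frozen=True)
class VenousParams:
    """Lumped RC venous bed: drain resistance and storage compliance."""

    R: float  # [mmHg*s/mL]
    C: float  # [mL/mmHg]

    def __post_init__(self):
        if self.R <= 0 or self.C <= 0:
            raise ValueError("venous bed needs R > 0 and C > 0")


@dataclass(frozen=True)
class RampSegment:
    t_start: float
    t_end: float
    v_start: float
    v_end: float


@dataclass(frozen=True)
class RampProtocol:
    """Piecewise-linear schedules per parameter name ("Rsa", "Csa1").

    Outside all segments a parameter sits at its baseline value, so a
    continuous experiment needs explicit hold segments.
    """

    schedules: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, segs in self.schedules.items():
            prev_end = -np.inf
            for s in segs:
                if s.t_end < s.t_start:
                    raise ValueError(f"{name}: segment ends before it starts")
                if s.t_start < prev_end:
                    raise ValueError(f"{name}: overlapping/unordered segments")
                prev_end = s.t_end

    def segment_array(self, name: str) -> np.ndarray:
        segs = self.schedules.get(name, [])
        if not segs:
            return np.zeros((0, 4))
        return np.array([[s.t_start, s.t_end, s.v_start, s.v_end] for s in segs])


def default_ramp_protocol(rsa: bool = True, csa1: bool = True) -> RampProtocol:
    """The standard 200 s experiment: baseline 0-50 s, linear rise 50-100 s,
    hold 100-150 s, linear return 150-200 s; Rsa 1.0->1.3 mmHg*s/mL and
    Csa1 0.9->0.8 mL/mmHg."""
    sched = {}
    if rsa:
        sched["Rsa"] = [
            RampSegment(50.0, 100.0, 1.0, 1.3),
            RampSegment(100.0, 150.0, 1.3, 1.3),
            RampSegment(150.0, 200.0, 1.3, 1.0),
        ]
    if csa1:
        sched["Csa1"] = [
            RampSegment(50.0, 100.0, 0.9, 0.8),
            RampSegment(100.0, 150.0, 0.8, 0.8),
            RampSegment(150.0, 200.0, 0.8, 0.9),
        ]
    return RampProtocol(schedules=sched)


@dataclass(frozen=True)
class CardioConfig:
    """Full parameterisation of the closed-loop circulation."""

    lv: ElastanceParams
    la: ElastanceParams
    rv: ElastanceParams
    ra: ElastanceParams
    mitral: ValveParams
    aortic: ValveParams
    tricuspid: ValveParams
    pulmonic: ValveParams
    systemic_arterial: WindkesselParams
    pulmonary_arterial: WindkesselParams
    systemic_venous: VenousParams
    pulmonary_venous: VenousParams
    heart_rate: float = 60.0  # [bpm]
    total_blood_volume: float = 900.0  # stressed volume [mL]
    dt: float = 1e-4  # internal RK4 step [s]

    def __post_init__(self):
        if self.heart_rate <= 0:
            raise ValueError("heart rate must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate

    # ---- packing for the compiled kernels -------------------------------

    def _chambers_array(self) -> np.ndarray:
        T = self.period
        rows = []
        for ch in (self.lv, self.la, self.rv, self.ra):
            rows.append([
                ch.Emax, ch.Emin, ch.V0,
                ch.tau1_frac * T, ch.tau2_frac * T,
                ch.n1, ch.n2, ch.onset, ch.norm,
            ])
        return np.array(rows)

    def _valves_array(self) -> np.ndarray:
        return np.array([
            [v.R, v.L]
            for v in (self.mitral, self.aortic, self.tricuspid, self.pulmonic)
        ])

    def _ven_array(self) -> np.ndarray:
        return np.array([
            self.systemic_venous.R, self.systemic_venous.C,
            self.pulmonary_venous.R, self.pulmonary_venous.C,
        ])

    def initial_state(self) -> np.ndarray:
        """A physiologically plausible starting state; the systemic venous
        volume absorbs the slack so the state sums to total_blood_volume."""
        sa, pa = self.systemic_arterial, self.pulmonary_arterial
        y = np.zeros(16)
        y[0:4] = [120.0, 50.0, 120.0, 50.0]  # chamber volumes
        y[8], y[9], y[10] = 90.0, 88.0, 0.0  # systemic arterial
        y[11], y[12], y[13] = 15.0, 14.0, 0.0  # pulmonary arterial
        y[15] = 8.0 * self.pulmonary_venous.C
        v_sa = sa.Csa1 * (y[8] - sa.Rsa0 * y[10]) + sa.Csa2 * y[9]
        v_pa = pa.Csa1 * (y[11] - pa.Rsa0 * y[13]) + pa.Csa2 * y[12]
        committed = y[0:4].sum() + v_sa + v_pa + y[15]
        y[14] = self.total_blood_volume - committed
        if y[14] <= 0:
            raise ValueError("total_blood_volume too small for initial state")
        return y


def normal_config() -> CardioConfig:
    """The calibrated normal (healthy adult, 60 bpm) configuration."""
    return CardioConfig(
        lv=ElastanceParams(Emax=2.1, Emin=0.06, V0=10.0,
                           tau1_frac=0.45, tau2_frac=0.42),
        la=ElastanceParams(Emax=0.25, Emin=0.15, V0=3.0,
                           tau1_frac=0.065, tau2_frac=0.11, onset=0.85),
        rv=ElastanceParams(Emax=0.55, Emin=0.045, V0=10.0,
                           tau1_frac=0.45, tau2_frac=0.42),
        ra=ElastanceParams(Emax=0.20, Emin=0.12, V0=3.0,
                           tau1_frac=0.065, tau2_frac=0.11, onset=0.85),
        mitral=ValveParams(R=0.005, L=2e-4),
        aortic=ValveParams(R=0.028, L=5e-4),
        tricuspid=ValveParams(R=0.005, L=2e-4),
        pulmonic=ValveParams(R=0.006, L=4e-4),
        systemic_arterial=NORMAL_PARAMS,
        pulmonary_arterial=WindkesselParams(0.02, 0.08, 3.5, 1.0, 2e-4),
        systemic_venous=VenousParams(R=0.03, C=40.0),
        pulmonary_venous=VenousParams(R=0.025, C=8.0),
        heart_rate=60.0,
        total_blood_volume=886.0,
    )


# ---------------------------------------------------------------------------
# Trace container
# ---------------------------------------------------------------------------


@dataclass
class HemoTrace:
    """Uniformly sampled multi-channel haemodynamic record.

    Channels: time [s], aortic pressure [mmHg], aortic flow [mL/s],
    systemic venous pressure [mmHg]; optional extras (e.g. left
    ventricular pressure ``plv``, total stressed volume ``vtot``).
    """

    t: np.ndarray
    pao: np.ndarray
    qao: np.ndarray
    psv: np.ndarray
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.t)
        for name in ("pao", "qao", "psv"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name} length mismatch")
        for name, ch in self.extra.items():
            if len(ch) != n:
                raise ValueError(f"extra channel {name} length mismatch")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0) or np.ptp(dt) > 1e-9:
                raise ValueError("time grid must be strictly increasing and uniform")

    @property
    def h(self) -> float:
        return float(self.t[1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def normalized_elastance(phase, params: ElastanceParams):
    """Elastance value(s) at beat fraction ``phase`` in [0, 1)."""
    phase = np.asarray(phase, dtype=float)
    if np.any(phase < 0) or np.any(phase >= 1):
        raise ValueError("phase must lie in [0, 1)")
    tloc = (phase - params.onset) % 1.0
    tloc = np.maximum(tloc, 1e-12)
    a = (tloc / params.tau1_frac) ** params.n1
    act = a / (1 + a) / (1 + (tloc / params.tau2_frac) ** params.n2) / params.norm
    out = params.Emin + (params.Emax - params.Emin) * act
    return float(out) if out.ndim == 0 else out


def apply_ramp(protocol: RampProtocol | None, name: str, t: float, baseline: float) -> float:
    """Scheduled value of parameter ``name`` at time ``t`` (baseline when no
    segment covers ``t``)."""
    if protocol is None:
        return baseline
    return float(_kernels._ramp_val(t, protocol.segment_array(name), baseline))


def step(state: np.ndarray, t: float, dt: float, config: CardioConfig,
         protocol: RampProtocol | None = None) -> np.ndarray:
    """Advance the full circulation state one RK4 step of size ``dt``.

    Raises on negative chamber volume (integration failure diagnostic).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    state = np.asarray(state, dtype=float)
    if state.shape != (16,):
        raise ValueError(f"state must have shape (16,), got {state.shape}")
    p = protocol or RampProtocol()
    sa = config.systemic_arterial.as_array()
    y = _kernels.rk4_step(
        t, state, dt, config._chambers_array(), config._valves_array(),
        sa, config.pulmonary_arterial.as_array(), config._ven_array(),
        config.period, p.segment_array("Rsa"), p.segment_array("Csa1"),
    )
    bad = np.where(y[:4] < 0)[0]
    if bad.size:
        raise RuntimeError(
            f"negative volume in chamber {STATE_FIELDS[bad[0]]} at t={t + dt:.4f} s"
        )
    return y


def simulate(
    config: CardioConfig,
    duration: float,
    protocol: RampProtocol | None = None,
    warmup: float = 10.0,
    output_rate: float = 1000.0,
) -> HemoTrace:
    """Run the closed loop and return the sampled haemodynamic trace.

    The model is integrated with RK4 at ``config.dt`` starting ``warmup``
    seconds before t = 0; the warm-up is discarded and the returned trace
    covers t in [0, duration) sampled at ``output_rate``.  Ramp protocol
    times refer to the post-warm-up clock.  Extra channels returned:
    ``plv`` (left ventricular pressure), ``vlv`` (LV volume) and ``vtot``
    (total stressed blood volume, for conservation checks).
    """
    T = config.period
    if duration < 3 * T:
        raise ValueError("duration must cover at least 3 beats")
    out_dt = 1.0 / output_rate
    n_sub = max(1, round(out_dt / config.dt))
    n_warm = round(warmup / out_dt)
    n_out = round(duration / out_dt)
    p = protocol or RampProtocol()
    sa = config.systemic_arterial.as_array()
    pa = config.pulmonary_arterial.as_array()
    chambers = config._chambers_array()
    valves = config._valves_array()
    ven = config._ven_array()
    rsa_segs = p.segment_array("Rsa")
    csa1_segs = p.segment_array("Csa1")

    out = np.empty((n_warm + n_out, 6))
    status, _ = _kernels.cardio_run(
        config.initial_state(), -warmup, n_warm + n_out, out_dt, n_sub,
        chambers, valves, sa, pa, ven, T, rsa_segs, csa1_segs, out,
    )
    if status >= 0:
        t_bad = -warmup + status * out_dt
        raise RuntimeError(f"circulation model diverged at t={t_bad:.4f} s")
    out = out[n_warm:]
    # total stressed volume needs the (possibly ramped) Csa1
    t = np.arange(n_out) * out_dt
    return HemoTrace(
        t=t,
        pao=out[:, 0].copy(),
        qao=out[:, 1].copy(),
        psv=out[:, 2].copy(),
        extra={"plv": out[:, 3].copy(), "vlv": out[:, 4].copy(),
               "vtot": out[:, 5].copy()},
    )


def add_noise(trace: HemoTrace, variance: float, seed=None) -> HemoTrace:
    """Add independent zero-mean white Gaussian noise of the given variance
    (native squared units) to the pao, qao and psv channels."""
    if variance < 0:
        raise ValueError("variance must be >= 0")
    rng = np.random.default_rng(seed)
    sd = np.sqrt(variance)
    n = len(trace)
    return HemoTrace(
        t=trace.t.copy(),
        pao=trace.pao + rng.normal(0.0, sd, n),
        qao=trace.qao + rng.normal(0.0, sd, n),
        psv=trace.psv + rng.normal(0.0, sd, n),
        extra={k: v.copy() for k, v in trace.extra.items()},
    )


# ---------------------------------------------------------------------------
# Scenario config files (YAML)
# ---------------------------------------------------------------------------


def load_scenario(path):
    """Read a scenario file: nested keys override the normal configuration.

    Recognised top-level sections: ``chambers`` (lv/la/rv/ra), ``valves``
    (mitral/aortic/tricuspid/pulmonic), ``systemic_arterial``,
    ``pulmonary_arterial``, ``systemic_venous``, ``pulmonary_venous``,
    scalars (``heart_rate``, ``total_blood_volume``, ``dt``), ``protocol``
    (parameter name -> list of [t_start, t_end, v_start, v_end]), ``noise``
    (``variance``, ``seed``).  Returns (CardioConfig, RampProtocol|None,
    noise dict).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    cfg = normal_config()
    for name in ("lv", "la", "rv", "ra"):
        if name in doc.get("chambers", {}):
            cfg = replace(cfg, **{name: replace(getattr(cfg, name), **doc["chambers"][name])})
    for name in ("mitral", "aortic", "tricuspid", "pulmonic"):
        if name in doc.get("valves", {}):
            cfg = replace(cfg, **{name: replace(getattr(cfg, name), **doc["valves"][name])})
    for name in ("systemic_arterial", "pulmonary_arterial"):
        if name in doc:
            cfg = replace(cfg, **{name: WindkesselParams(**doc[name])})
    for name in ("systemic_venous", "pulmonary_venous"):
        if name in doc:
            cfg = replace(cfg, **{name: VenousParams(**doc[name])})
    for name in ("heart_rate", "total_blood_volume", "dt"):
        if name in doc:
            cfg = replace(cfg, **{name: float(doc[name])})
    protocol = None
    if "protocol" in doc:
        protocol = RampProtocol(schedules={
            k: [RampSegment(*row) for row in rows]
            for k, rows in doc["protocol"].items()
        })
    return cfg, protocol, doc.get("noise", {})
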