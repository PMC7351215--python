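"""Closed-loop circulation generator: elastance, ramps, valves, noise."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

import wkident as wk
from wkident import cardio_sim as cs


class TestNormalizedElastance:
    def test_baseline_at_phase_zero(self):
        p = cs.ElastanceParams(Emax=2.0, Emin=0.06, V0=10.0)
        assert cs.normalized_elastance(0.0, p) == pytest.approx(0.06, abs=1e-9)

    def test_peak_reaches_emax(self):
        p = cs.ElastanceParams(Emax=2.0, Emin=0.06, V0=10.0)
        phases = np.linspace(0, 1, 5000, endpoint=False)
        assert cs.normalized_elastance(phases, p).max() == pytest.approx(2.0, abs=1e-6)

    def test_never_below_emin(self):
        p = cs.ElastanceParams(Emax=2.0, Emin=0.06, V0=10.0, onset=0.85)
        phases = np.linspace(0, 1, 2000, endpoint=False)
        assert np.all(cs.normalized_elastance(phases, p) >= 0.06 - 1e-12)

    @pytest.mark.parametrize("phase", [-0.1, 1.0, 1.5])
    def test_phase_domain_error(self, phase):
        p = cs.ElastanceParams(Emax=2.0, Emin=0.06, V0=10.0)
        with pytest.raises(ValueError):
            cs.normalized_elastance(phase, p)


class TestApplyRamp:
    def test_default_protocol_values(self):
        prot = cs.default_ramp_protocol()
        assert cs.apply_ramp(prot, "Rsa", 0.0, 1.0) == pytest.approx(1.0)
        assert cs.apply_ramp(prot, "Rsa", 125.0, 1.0) == pytest.approx(1.3)
        assert cs.apply_ramp(prot, "Rsa", 75.0, 1.0) == pytest.approx(1.15)
        assert cs.apply_ramp(prot, "Rsa", 300.0, 1.0) == pytest.approx(1.0)
        assert cs.apply_ramp(prot, "Csa1", 125.0, 0.9) == pytest.approx(0.8)

    def test_continuity_at_segment_joins(self):
        prot = cs.default_ramp_protocol()
        for t in (50.0, 100.0, 150.0, 200.0):
            lo = cs.apply_ramp(prot, "Rsa", t - 1e-7, 1.0)
            hi = cs.apply_ramp(prot, "Rsa", t + 1e-7, 1.0)
            assert lo == pytest.approx(hi, abs=1e-5)

    @settings(derandomize=True, max_examples=80)
    @given(st.floats(0.0, 250.0))
    def test_schedule_between_endpoint_values(self, t):
        """Anywhere in time the scheduled Rsa lies between its baseline
        and ramp-target values (linear interpolation never overshoots)."""
        v = cs.apply_ramp(cs.default_ramp_protocol(), "Rsa", t, 1.0)
        assert 1.0 - 1e-12 <= v <= 1.3 + 1e-12

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError):
            cs.RampProtocol(schedules={"Rsa": [
                cs.RampSegment(0, 10, 1, 2), cs.RampSegment(5, 15, 2, 1),
            ]})


class TestStep:
    def test_volume_conserved_over_one_step(self):
        cfg = cs.normal_config()
        y = cfg.initial_state()

        def total(y):
            sa, pa = cfg.systemic_arterial, cfg.pulmonary_arterial
            v_sa = sa.Csa1 * (y[8] - sa.Rsa0 * y[10]) + sa.Csa2 * y[9]
            v_pa = pa.Csa1 * (y[11] - pa.Rsa0 * y[13]) + pa.Csa2 * y[12]
            return y[:4].sum() + v_sa + v_pa + y[14] + y[15]

        y2 = cs.step(y, 0.0, 1e-4, cfg)
        assert total(y2) == pytest.approx(total(y), abs=1e-8)

    def test_closed_valve_carries_no_flow(self):
        """Aortic valve with adverse gradient and zero flow stays shut."""
        cfg = cs.normal_config()
        y = cfg.initial_state()
        # at phase 0 the LV is relaxed: p_lv << p_ao, Q_ao = 0
        y2 = cs.step(y, 0.0, 1e-4, cfg)
        assert y[5] == 0.0 and y2[5] == 0.0

    def test_passive_network_relaxes(self):
        """With (near-)frozen elastances the pressures decay toward a
        common equilibrium: the spread across compartments shrinks."""
        cfg = cs.normal_config()
        frozen = replace(
            cfg,
            lv=replace(cfg.lv, Emax=cfg.lv.Emin * 1.0001),
            la=replace(cfg.la, Emax=cfg.la.Emin * 1.0001),
            rv=replace(cfg.rv, Emax=cfg.rv.Emin * 1.0001),
            ra=replace(cfg.ra, Emax=cfg.ra.Emin * 1.0001),
        )
        tr = cs.simulate(frozen, 25.0, warmup=0.0)

        def spread(i):
            ps = [tr.pao[i], tr.psv[i], tr.extra["plv"][i]]
            return max(ps) - min(ps)

        assert spread(-1) < 0.05 * spread(0)
        # and the decay is monotone at the 5 s scale
        per = round(5.0 / tr.h)
        spreads = [spread(k * per) for k in range(5)]
        assert all(a >= b for a, b in zip(spreads, spreads[1:]))

    def test_bad_state_shape_rejected(self):
        with pytest.raises(ValueError):
            cs.step(np.zeros(4), 0.0, 1e-4, cs.normal_config())


class TestSimulate:
    def test_volume_conservation_long_run(self, normal_trace):
        """Total stressed volume drifts < 0.1 mL across the whole run."""
        vtot = normal_trace.extra["vtot"]
        assert np.abs(vtot - vtot[0]).max() < 0.1

    def test_aortic_valve_one_way(self, normal_trace):
        """No regurgitant aortic flow is ever recorded."""
        assert normal_trace.qao.min() >= 0.0

    def test_beat_to_beat_periodicity(self, normal_trace):
        """Consecutive post-warm-up pressure waves agree < 0.5 mmHg RMS."""
        per = round(1.0 / normal_trace.h)
        a = normal_trace.pao[: 5 * per].reshape(5, per)
        rms = np.sqrt(np.mean(np.diff(a, axis=0) ** 2, axis=1))
        assert rms.max() < 0.5

    def test_raising_rsa_raises_mean_pressure(self):
        """Afterload up -> mean aortic pressure up (load response sign)."""
        cfg = cs.normal_config()
        hi = replace(
            cfg,
            systemic_arterial=replace(cfg.systemic_arterial, Rsa=1.3),
        )
        lo_tr = cs.simulate(cfg, 4.0, warmup=10.0)
        hi_tr = cs.simulate(hi, 4.0, warmup=10.0)
        assert hi_tr.pao.mean() > lo_tr.pao.mean() + 5.0

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError):
            cs.simulate(cs.normal_config(), 2.0)

    def test_ramp_changes_pressure_course(self):
        """During the resistance/compliance rise the systolic pressure
        climbs well above its baseline and returns afterwards."""
        cfg = cs.normal_config()
        # compressed protocol: rise 10-20 s, hold 20-30 s, return 30-40 s
        prot = cs.RampProtocol(schedules={
            "Rsa": [cs.RampSegment(10, 20, 1.0, 1.3),
                    cs.RampSegment(20, 30, 1.3, 1.3),
                    cs.RampSegment(30, 40, 1.3, 1.0)],
            "Csa1": [cs.RampSegment(10, 20, 0.9, 0.8),
                     cs.RampSegment(20, 30, 0.8, 0.8),
                     cs.RampSegment(30, 40, 0.8, 0.9)],
        })
        tr = cs.simulate(cfg, 45.0, protocol=prot, warmup=10.0)
        per = round(1.0 / tr.h)

        def sbp(t0):
            s = slice(t0 * per, (t0 + 1) * per)
            return tr.pao[s].max()

        assert sbp(25) > sbp(5) + 10.0  # hold window clearly elevated
        assert abs(sbp(43) - sbp(5)) < 3.0  # back near baseline


class TestAddNoise:
    def test_zero_variance_identity(self, normal_trace):
        out = cs.add_noise(normal_trace, 0.0, seed=1)
        np.testing.assert_array_equal(out.pao, normal_trace.pao)

    def test_seed_reproducibility(self, normal_trace):
        a = cs.add_noise(normal_trace, 10.0, seed=7)
        b = cs.add_noise(normal_trace, 10.0, seed=7)
        np.testing.assert_array_equal(a.qao, b.qao)

    def test_sample_variance_matches(self, normal_trace):
        noisy = cs.add_noise(normal_trace, 10.0, seed=3)
        for clean, dirty in [(normal_trace.pao, noisy.pao),
                             (normal_trace.qao, noisy.qao),
                             (normal_trace.psv, noisy.psv)]:
            v = np.var(dirty - clean)
            assert v == pytest.approx(10.0, rel=0.05)

    def test_negative_variance_rejected(self, normal_trace):
        with pytest.raises(ValueError):
            cs.add_noise(normal_trace, -1.0)


class TestScenarioConfig:
    def test_roundtrip_overrides(self, tmp_path):
        doc = """
heart_rate: 75
systemic_arterial: {Rsa0: 0.12, Rsa: 1.1, Csa1: 0.8, Csa2: 0.3, Lsa: 0.0004}
chambers:
  lv: {Emax: 2.5}
protocol:
  Rsa:
  - [5.0, 10.0, 1.1, 1.4]
noise: {variance: 10.0, seed: 3}
"""
        path = tmp_path / "scenario.yaml"
        path.write_text(doc)
        cfg, prot, noise = cs.load_scenario(path)
        assert cfg.heart_rate == 75
        assert cfg.systemic_arterial.Rsa == 1.1
        assert cfg.lv.Emax == 2.5
        assert cfg.lv.Emin == cs.normal_config().lv.Emin  # untouched
        assert cs.apply_ramp(prot, "Rsa", 7.5, 1.1) == pytest.approx(1.25)
        assert noise["variance"] == 10.0


class TestHemoTrace:
    def test_nonuniform_grid_rejected(self):
        t = np.array([0.0, 1e-3, 2.5e-3])
        with pytest.raises(ValueError):
            cs.HemoTrace(t=t, pao=np.zeros(3), qao=np.zeros(3), psv=np.zeros(3))

    def test_channel_length_mismatch_rejected(self):
        t = np.arange(5) * 1e-3
        with pytest.raises(ValueError):
            cs.HemoTrace(t=t, pao=np.zeros(5), qao=np.zeros(4), psv=np.zeros(5))
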