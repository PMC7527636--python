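"""Cable integrator: analytic oracles, clamp modes, pharmacology, shares."""

import numpy as np
import pytest

from olmcell.channels import IhParams, ih_channel_spec, ih_rinf, ih_tau
from olmcell.model import CellModel
from olmcell.morphology import discretize, distribute_conductance, select_by_hdist
from olmcell.simulator import (
    PassiveParams,
    PharmacologyFlags,
    Protocol,
    Simulator,
    Sweep,
    apply_pharmacology,
    cc_step_protocol,
    current_shares,
    run_current_clamp,
    run_voltage_clamp,
    vc_activation_protocol,
)


def _rc_prediction(t, onset, I_A, R_ohm, tau_ms, E):
    """Membrane charging of an isopotential RC compartment."""
    out = np.full_like(t, E)
    m = t >= onset
    out[m] = E + I_A * R_ohm * 1e3 * (1.0 - np.exp(-(t[m] - onset) / tau_ms))
    return out


class TestCurrentClamp:
    def test_rc_step_matches_analytic(self, iso_cell):
        geom, passive = iso_cell
        proto = cc_step_protocol(
            amplitudes_pA=[-120], pre_ms=200, step_ms=1000, post_ms=100
        )
        tr = run_current_clamp(geom, passive, [], proto, dt=0.01)[0]
        area_cm2 = geom.area.sum() * 1e-8
        R = 1.0 / (passive.Gpas * area_cm2)
        pred = _rc_prediction(
            tr.t, 200.0, -120e-12, R, passive.tau_m, passive.Epas
        )
        m = (tr.t >= 200) & (tr.t <= 1200)
        assert np.abs(tr.y[m] - pred[m]).max() < 0.01

    def test_zero_amplitude_is_flat(self, iso_cell):
        geom, passive = iso_cell
        proto = cc_step_protocol(amplitudes_pA=[0], pre_ms=100, step_ms=300, post_ms=100)
        tr = run_current_clamp(geom, passive, [], proto, dt=0.05)[0]
        assert np.abs(tr.y - passive.Epas).max() < 1e-6

    def test_passive_linearity(self, ball_and_stick):
        geom = discretize(ball_and_stick, 0.1, 100.0, 150.0, 1.0)
        passive = PassiveParams(Ra=150.0, Cm=1.0, Gpas=3e-5, Epas=-65.0)
        proto = cc_step_protocol(
            amplitudes_pA=[-30, -120], pre_ms=100, step_ms=500, post_ms=100
        )
        tr30, tr120 = run_current_clamp(geom, passive, [], proto, dt=0.05)
        d30 = tr30.y - passive.Epas
        d120 = tr120.y - passive.Epas
        assert np.abs(4.0 * d30 - d120).max() < 1e-6

    def test_ball_and_stick_matches_refined_reference(self, ball_and_stick):
        passive = PassiveParams(Ra=150.0, Cm=1.0, Gpas=3e-5, Epas=-65.0)
        proto = cc_step_protocol(
            amplitudes_pA=[-60], pre_ms=100, step_ms=400, post_ms=100
        )
        coarse_geom = discretize(ball_and_stick, 0.1, 100.0, passive.Ra, passive.Cm)
        fine_geom = discretize(ball_and_stick, 0.01, 100.0, passive.Ra, passive.Cm)
        coarse = run_current_clamp(coarse_geom, passive, [], proto, dt=0.05)[0]
        fine = run_current_clamp(fine_geom, passive, [], proto, dt=0.005)[0]
        ref = np.interp(coarse.t, fine.t, fine.y)
        assert np.abs(coarse.y - ref).max() < 0.05

    def test_resting_balance_at_steady_state(self, iso_cell):
        geom, passive = iso_cell
        proto = cc_step_protocol(amplitudes_pA=[0], pre_ms=50, step_ms=100, post_ms=50)
        ih = IhParams()
        dens = distribute_conductance(geom, ih.gh_total_nS, select_by_hdist(geom, 0.0))
        sim = Simulator(geom, passive, [(ih_channel_spec(ih), dens)])
        tr = sim.run_protocol(proto, dt=0.1, settle_ms=5000)[0]
        v = tr.y[-1]
        # zero net current: g_leak (V-Epas) + g_h r_inf(V) (V-E_h) = 0
        area = geom.area.sum()
        g_leak = passive.Gpas * area * 1e-2  # uS
        g_h = dens * area * 1e-6
        balance = g_leak * (v - passive.Epas) + g_h * float(ih_rinf(v, ih)) * (v - ih.e_h)
        assert abs(balance) < 1e-4  # nA
        assert abs(tr.y[-1] - tr.y[-100]) < 1e-6  # dV/dt -> 0


class TestVoltageClamp:
    def test_ohmic_steady_state(self, iso_cell):
        geom, passive = iso_cell
        proto = vc_activation_protocol(
            commands_mV=[-60], holding_mV=-65, pre_ms=100, step_ms=400, post_ms=50
        )
        tr = run_voltage_clamp(geom, passive, [], proto, dt=0.05)[0]
        area_cm2 = geom.area.sum() * 1e-8
        pred_pA = passive.Gpas * area_cm2 * 5e-3 * 1e12
        assert tr.y[int(480 / 0.05)] == pytest.approx(pred_pA, rel=1e-3)

    def test_capacitive_spike_at_command_step(self, iso_cell):
        geom, passive = iso_cell
        proto = vc_activation_protocol(
            commands_mV=[-80], holding_mV=-65, pre_ms=100, step_ms=200, post_ms=50
        )
        tr = run_voltage_clamp(geom, passive, [], proto, dt=0.05)[0]
        onset_idx = int(100 / 0.05)
        # one-sample capacitive transient, then settled ohmic current
        assert tr.y[onset_idx] < -1e4  # large negative spike (charging -15 mV)
        assert abs(tr.y[onset_idx + 10]) < 100.0

    def test_ih_step_current_matches_gating_solution(self, iso_cell):
        geom, passive = iso_cell
        ih = IhParams()
        dens = distribute_conductance(geom, ih.gh_total_nS, select_by_hdist(geom, 0.0))
        sim = Simulator(geom, passive, [(ih_channel_spec(ih), dens)])
        proto = vc_activation_protocol(
            commands_mV=[-120], holding_mV=-40, pre_ms=100, step_ms=1200, post_ms=50
        )
        tr = sim.run_protocol(proto, dt=0.01)[0]
        r0 = float(ih_rinf(-40.0, ih))
        rinf = float(ih_rinf(-120.0, ih))
        tau = float(ih_tau(-120.0, ih))
        m = (tr.t > 101.0) & (tr.t <= 1300.0)  # skip the capacitive sample
        r_t = rinf + (r0 - rinf) * np.exp(-(tr.t[m] - 100.0) / tau)
        g_leak = passive.Gpas * geom.area.sum() * 1e-2
        i_pred = (
            ih.gh_total_nS * 1e-3 * r_t * (-120.0 - ih.e_h)
            + g_leak * (-120.0 - passive.Epas)
        ) * 1e3
        assert np.abs(tr.y[m] - i_pred).max() < 0.5


class TestPharmacology:
    def _channels(self):
        ih = ih_channel_spec(IhParams())
        from olmcell.channels import nat_channel_spec

        nat = nat_channel_spec("soma", 0.0, 90.0)
        return [(ih, 0.2), (nat, 50.0)]

    def test_ttx_removes_na_k_keeps_ih(self):
        out = apply_pharmacology(self._channels(), PharmacologyFlags(ttx_tea_4ap=True))
        assert [s.name for s, _ in out] == ["ih"]

    def test_zd_additionally_removes_ih(self):
        out = apply_pharmacology(
            self._channels(), PharmacologyFlags(ttx_tea_4ap=True, zd7288=True)
        )
        assert out == []

    def test_idempotent(self):
        flags = PharmacologyFlags(ttx_tea_4ap=True)
        once = apply_pharmacology(self._channels(), flags)
        twice = apply_pharmacology(once, flags)
        assert [s.name for s, _ in once] == [s.name for s, _ in twice]

    def test_ttx_minus30_matches_zd_when_ih_barely_activated(self, iso_cell):
        # with few h-channels open near holding, the TTX response is nearly
        # identical to the fully blocked one
        geom, passive = iso_cell
        ih = IhParams()
        dens = distribute_conductance(geom, ih.gh_total_nS, select_by_hdist(geom, 0.0))
        channels = [(ih_channel_spec(ih), dens)]
        proto_ttx = cc_step_protocol(
            amplitudes_pA=[-30], pre_ms=200, step_ms=1000, post_ms=200,
            pharmacology=PharmacologyFlags(ttx_tea_4ap=True),
        )
        proto_zd = cc_step_protocol(
            amplitudes_pA=[-30], pre_ms=200, step_ms=1000, post_ms=200,
            pharmacology=PharmacologyFlags(ttx_tea_4ap=True, zd7288=True),
        )
        proto_ttx_120 = cc_step_protocol(
            amplitudes_pA=[-120], pre_ms=200, step_ms=1000, post_ms=200,
            pharmacology=PharmacologyFlags(ttx_tea_4ap=True),
        )
        proto_zd_120 = cc_step_protocol(
            amplitudes_pA=[-120], pre_ms=200, step_ms=1000, post_ms=200,
            pharmacology=PharmacologyFlags(ttx_tea_4ap=True, zd7288=True),
        )
        sim = Simulator(geom, passive, channels)

        def baseline_subtracted_diff(pa, pb):
            # the experimental comparison normalized traces to their own
            # baselines; blocking I_h shifts the resting potential slightly
            ya = sim.run_protocol(pa, dt=0.05)[0]
            yb = sim.run_protocol(pb, dt=0.05)[0]
            base = ya.t < 200
            da = ya.y - ya.y[base].mean()
            db = yb.y - yb.y[base].mean()
            return np.abs(da - db).max()

        d30 = baseline_subtracted_diff(proto_ttx, proto_zd)
        d120 = baseline_subtracted_diff(proto_ttx_120, proto_zd_120)
        # the -30 pA step barely activates I_h, the -120 pA step strongly does
        assert d30 < 2.0
        assert d30 < 0.15 * d120


class TestConvergence:
    def test_error_shrinks_first_order_with_dt(self, iso_cell):
        geom, passive = iso_cell
        proto = cc_step_protocol(
            amplitudes_pA=[-120], pre_ms=100, step_ms=400, post_ms=50
        )
        area_cm2 = geom.area.sum() * 1e-8
        R = 1.0 / (passive.Gpas * area_cm2)
        errs = []
        for dt in (0.08, 0.04, 0.02, 0.01):
            tr = run_current_clamp(geom, passive, [], proto, dt=dt)[0]
            pred = _rc_prediction(tr.t, 100.0, -120e-12, R, passive.tau_m, passive.Epas)
            m = (tr.t >= 100) & (tr.t <= 500)
            errs.append(np.abs(tr.y[m] - pred[m]).max())
        rates = np.diff(np.log(errs)) / np.log(0.5)
        assert np.all(rates > 0.8)  # backward Euler: first order


class TestCurrentShares:
    def test_single_channel_has_unit_share(self, iso_cell):
        geom, passive = iso_cell
        ih = IhParams()
        dens = distribute_conductance(geom, ih.gh_total_nS, select_by_hdist(geom, 0.0))
        sim = Simulator(
            geom, passive, [(ih_channel_spec(ih), dens)], record_channels=True
        )
        proto = cc_step_protocol(amplitudes_pA=[-90], pre_ms=100, step_ms=500, post_ms=100)
        tr = sim.run_protocol(proto, dt=0.1)[0]
        shares = current_shares(tr)
        m = (tr.t > 300) & (tr.t < 600)
        inward_total = sum(v[m] for v in shares["inward"].values())
        assert np.allclose(inward_total, 1.0)
        # during hyperpolarization both I_h and leak flow inward; only they exist
        assert set(shares["inward"]) == {"ih", "leak"}

    def test_shares_invariant_to_uniform_current_scaling(self):
        # the ratio property at frozen gating: scaling every mechanism's
        # current by a common factor leaves the fractions unchanged
        from olmcell.simulator import Trace

        t = np.linspace(0, 10, 50)
        currents = {
            "a": -np.abs(np.sin(t)) - 0.1,
            "b": -0.5 * np.ones_like(t),
            "c": np.cos(t) ** 2 + 0.05,
        }
        tr1 = Trace(t=t, y=t * 0, dt=0.2, channel_currents=currents)
        tr2 = Trace(
            t=t, y=t * 0, dt=0.2,
            channel_currents={k: 3.7 * v for k, v in currents.items()},
        )
        s1, s2 = current_shares(tr1), current_shares(tr2)
        for sign in ("inward", "outward"):
            for k in s1[sign]:
                assert np.allclose(s1[sign][k], s2[sign][k])

    def test_requires_channel_record(self, iso_cell):
        geom, passive = iso_cell
        proto = cc_step_protocol(amplitudes_pA=[-30], pre_ms=50, step_ms=100, post_ms=50)
        tr = run_current_clamp(geom, passive, [], proto, dt=0.1)[0]
        with pytest.raises(ValueError, match="record"):
            current_shares(tr)


class TestProtocolValidation:
    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            Protocol(name="x", mode="vc2", holding=0.0, sweeps=[])

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            Protocol(
                name="x",
                mode="cc",
                holding=0.0,
                sweeps=[Sweep(label="s", levels=[(0.0, -5.0)])],
            )

    def test_mode_mismatch_in_wrappers(self, iso_cell):
        geom, passive = iso_cell
        cc = cc_step_protocol(amplitudes_pA=[0], pre_ms=10, step_ms=10, post_ms=10)
        with pytest.raises(ValueError):
            run_voltage_clamp(geom, passive, [], cc)
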