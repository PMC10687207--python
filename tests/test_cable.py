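import math

import numpy as np
import pytest

from stellatesim import channels as chan
from stellatesim.cable import (
    BLOCKERS,
    DiscretisedCell,
    Morphology,
    PassiveParams,
    Section,
    SimConfig,
    apply_pharmacology,
    build_cell,
    read_swc,
    run_current_clamp,
    run_voltage_clamp,
    write_swc,
)

SOMA_AREA_CM2 = math.pi * 20.0 * 20.0 * 1e-8
R_SOMA_OHM = 50e3 / SOMA_AREA_CM2  # Rm / area


def branched_morphology():
    secs = [Section(1, None, "soma", 20.0, 20.0)]
    secs += [Section(2 + k, 1, "dendrite", 150.0, 1.5, 5) for k in range(4)]
    secs.append(Section(6, 1, "axon", 100.0, 1.0, 3))
    return Morphology(tuple(secs))


class TestMorphology:
    def test_cylinder_area(self, soma_morphology):
        disc = DiscretisedCell(build_cell(soma_morphology))
        assert disc.total_area_um2 == pytest.approx(math.pi * 20.0 * 20.0)

    def test_single_root_enforced(self):
        with pytest.raises(ValueError):
            Morphology((Section(1, None, "soma", 10, 10),
                        Section(2, None, "soma", 10, 10)))

    def test_orphan_parent_rejected(self):
        with pytest.raises(ValueError):
            Morphology((Section(1, None, "soma", 10, 10),
                        Section(2, 99, "dendrite", 10, 1)))

    def test_nonpositive_geometry_rejected(self):
        with pytest.raises(ValueError):
            Section(1, None, "soma", 0.0, 10.0)

    def test_swc_round_trip(self, tmp_path):
        morph = branched_morphology()
        path = tmp_path / "cell.swc"
        write_swc(morph, path)
        back = read_swc(path)
        assert back.total_area() == pytest.approx(morph.total_area(), rel=1e-3)
        assert len(back.sections) == len(morph.sections)
        regions = sorted(s.region for s in back.sections)
        assert regions == sorted(s.region for s in morph.sections)

    def test_malformed_swc_names_line(self, tmp_path):
        path = tmp_path / "bad.swc"
        path.write_text("1 1 0 0 0 5 -1\nnot an swc line\n")
        with pytest.raises(ValueError, match="line 2"):
            read_swc(path)


class TestPassiveOracles:
    def test_input_resistance_closed_form(self, passive_cell):
        disc = DiscretisedCell(passive_cell)
        assert disc.passive_input_resistance() == pytest.approx(
            R_SOMA_OHM / 1e6, rel=1e-9)

    def test_membrane_time_constant_50_ms(self, passive_cell, fast_cfg):
        # step response reaches (1 - 1/e) of its plateau at t = tau = Rm*Cm
        wave = np.full(int(400.0 / fast_cfg.dt), 20.0)
        tr = run_current_clamp(passive_cell, wave, fast_cfg)
        dv = tr.samples - tr.samples[0] + (tr.samples[0] + 70.0)
        plateau = 20e-12 * R_SOMA_OHM * 1e3
        i_tau = int(round(50.0 / fast_cfg.dt))
        assert dv[i_tau - 1] == pytest.approx(plateau * (1 - 1 / math.e),
                                              rel=5e-3)

    def test_step_response_matches_closed_form(self, passive_cell, fast_cfg):
        amp = 50.0
        wave = np.full(int(300.0 / fast_cfg.dt), amp)
        tr = run_current_clamp(passive_cell, wave, fast_cfg)
        t = tr.time + fast_cfg.dt
        pred = -70.0 + amp * 1e-12 * R_SOMA_OHM * 1e3 * (1 - np.exp(-t / 50.0))
        # within 0.5% of the full deflection
        assert np.abs(tr.samples - pred).max() < 0.005 * (pred[-1] + 70.0)

    def test_branched_tree_matches_dense_solution(self, fast_cfg):
        cell = build_cell(branched_morphology())
        disc = DiscretisedCell(cell)
        rn_dense = disc.passive_input_resistance()
        wave = np.full(int(3000.0 / fast_cfg.dt), 50.0)
        tr = run_current_clamp(cell, wave, fast_cfg)
        rn_sim = (tr.samples[-1] + 70.0) / 50.0 * 1e3
        assert rn_sim == pytest.approx(rn_dense, rel=0.01)

    def test_zero_stimulus_rests_at_leak_reversal(self, passive_cell, fast_cfg):
        tr = run_current_clamp(passive_cell, np.zeros(2000), fast_cfg)
        assert np.allclose(tr.samples, -70.0, atol=1e-6)

    def test_superposition(self, passive_cell, fast_cfg):
        waves = {}
        for amp in (40.0, -40.0, 80.0):
            wave = np.full(4000, amp)
            waves[amp] = run_current_clamp(passive_cell, wave, fast_cfg).samples + 70.0
        assert np.allclose(waves[40.0], -waves[-40.0], atol=1e-9)
        assert np.allclose(2 * waves[40.0], waves[80.0], atol=1e-9)

    def test_dt_convergence(self, fast_cfg):
        cell = build_cell(branched_morphology())
        vals = []
        for dt in (0.05, 0.025):
            wave = np.full(int(500.0 / dt), 80.0)
            tr = run_current_clamp(cell, wave,
                                   SimConfig(dt=dt, settle_time=200.0))
            vals.append(tr.samples[-1])
        assert abs(vals[0] - vals[1]) < 0.1


class TestVoltageClamp:
    def test_passive_steady_current_is_ohmic(self, passive_cell):
        cmd = np.full(int(500.0 / 0.05), -60.0)
        tr = run_voltage_clamp(passive_cell, cmd,
                               SimConfig(dt=0.05, settle_time=100.0))
        expected = (-60.0 + 70.0) * 1e-3 / R_SOMA_OHM * 1e12  # pA
        assert tr.samples[-1] == pytest.approx(expected, rel=1e-6)

    def test_step_has_decaying_capacitive_transient(self, passive_cell):
        cmd = np.concatenate([np.full(2000, -70.0), np.full(2000, -60.0)])
        tr = run_voltage_clamp(passive_cell, cmd,
                               SimConfig(dt=0.05, settle_time=50.0))
        # the onset sample carries a large capacitive spike, gone within 1 ms
        assert tr.samples[2000] > 10 * abs(tr.samples[-1])
        assert abs(tr.samples[2020] - tr.samples[-1]) < abs(tr.samples[-1])

    def test_t_current_peak_matches_independent_ode(self, soma_morphology):
        """Clamp steps are piecewise constant, so the gate ODEs have exact
        exponential solutions; that independent reconstruction must match
        the simulated clamp current within 1%."""
        spec = chan.t_type(gbar=2e-4)
        cell = build_cell(soma_morphology, distributions={"soma": (spec,)})
        dt = 0.05
        cmd = np.concatenate([np.full(int(1000 / dt), -100.0),
                              np.full(int(1000 / dt), -45.0)])
        tr = run_voltage_clamp(cell, cmd, SimConfig(dt=dt, settle_time=500.0))
        test = tr.samples[int(1000 / dt) + 40:]  # skip capacitive sample
        sim_peak = test.min()

        m_gate, h_gate = spec.gates
        m = chan.boltzmann_eval(m_gate.steady_state, -100.0)
        h = chan.boltzmann_eval(h_gate.steady_state, -100.0)
        t = np.arange(2.0, 1000.0, 0.001)  # 10x finer, post-blank
        minf = chan.boltzmann_eval(m_gate.steady_state, -45.0)
        hinf = chan.boltzmann_eval(h_gate.steady_state, -45.0)
        tau_m = chan.tau_eval(m_gate.tau, -45.0)
        tau_h = chan.tau_eval(h_gate.tau, -45.0)
        mt = minf + (m - minf) * np.exp(-t / tau_m)
        ht = hinf + (h - hinf) * np.exp(-t / tau_h)
        i = 2e-4 * SOMA_AREA_CM2 * mt * ht * (-45.0 - 120.0) * 1e9  # mA -> pA
        leak = (-45.0 + 70.0) * 1e-3 / R_SOMA_OHM * 1e12
        ode_peak = i.min() + leak
        assert sim_peak == pytest.approx(ode_peak, rel=0.01)


class TestPharmacology:
    def test_blockers_zero_their_targets(self, ventral_cell):
        for drug, scales in BLOCKERS.items():
            blocked = apply_pharmacology(ventral_cell, {drug: 0.0})
            for chans in blocked.distributions.values():
                for c in chans:
                    if c.name in scales:
                        assert c.gbar == 0.0

    def test_original_unchanged(self, ventral_cell):
        before = {c.name: c.gbar
                  for chans in ventral_cell.distributions.values()
                  for c in chans}
        apply_pharmacology(ventral_cell, {"tta-p2": 0.0})
        after = {c.name: c.gbar
                 for chans in ventral_cell.distributions.values()
                 for c in chans}
        assert before == after

    def test_unknown_channel_is_error(self, ventral_cell):
        with pytest.raises(KeyError, match="unknown channel"):
            apply_pharmacology(ventral_cell, {"gabazine": 0.0})


def test_kernel_matches_reference_integrator(ventral_cell):
    """The compiled whole-sweep kernel and the per-step reference path are
    the same arithmetic; their trajectories must agree to rounding."""
    from stellatesim._kernel import HAVE_NUMBA

    if not HAVE_NUMBA:
        # without numba run_wave already IS the reference path
        return
    d1 = DiscretisedCell(ventral_cell)
    d2 = DiscretisedCell(ventral_cell)
    d1.init_state(-67.0)
    d2.init_state(-67.0)
    rng = np.random.default_rng(7)
    wave = np.repeat(rng.normal(20.0, 40.0, 40), 25)  # 50 ms of steps
    out1 = d1.run_wave(wave, 0.05)
    out2 = np.empty(wave.size)
    for k in range(wave.size):
        d2.step(0.05, wave[k] * 1e-9)
        out2[k] = d2.v[0]
    assert np.abs(out1 - out2).max() < 1e-9
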