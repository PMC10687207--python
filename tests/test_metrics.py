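import math

import numpy as np
import pytest

from stellatesim.cable import SimConfig, Trace, run_current_clamp
from stellatesim.metrics import (
    MetricsConfig,
    SpikesPresentError,
    ap_metrics,
    count_spikes,
    fit_alpha_decay,
    measure_step,
    summation_and_coupling,
)
from stellatesim.protocols import AlphaTrainProtocol, build_alpha_train

DT = 0.05


def passive_step_trace(r_mohm=100.0, i_pa=50.0, tau=20.0, baseline=-70.0,
                       pre=500.0, dur=5000.0, post=200.0):
    """Analytically constructed passive step response (no simulator)."""
    t = np.arange(0.0, pre + dur + post, DT)
    v = np.full(t.size, baseline)
    on = t >= pre
    v[on] += i_pa * r_mohm * 1e-3 * (1 - np.exp(-(t[on] - pre) / tau))
    off = t >= pre + dur
    v[off] = baseline + (v[int((pre + dur) / DT) - 1] - baseline) * \
        np.exp(-(t[off] - pre - dur) / tau)
    meta = {"amplitude_pA": i_pa, "step_onset_ms": pre,
            "step_offset_ms": pre + dur}
    return Trace(DT, v, "voltage", stimulus=meta)


class TestMeasureStep:
    def test_passive_input_resistance(self):
        m = measure_step(passive_step_trace())
        assert m.r_n == pytest.approx(100.0, rel=1e-3)
        assert m.sag_amplitude == pytest.approx(0.0, abs=0.01)
        assert m.baseline == pytest.approx(-70.0)
        assert m.spike_count == 0

    def test_rn_invariant_to_current_on_linear_cell(self):
        m1 = measure_step(passive_step_trace(i_pa=50.0))
        m2 = measure_step(passive_step_trace(i_pa=100.0))
        assert m1.r_n == pytest.approx(m2.r_n, rel=1e-9)

    def test_hyperpolarizing_sign_convention(self):
        m = measure_step(passive_step_trace(i_pa=-80.0))
        assert m.r_n == pytest.approx(100.0, rel=1e-3)
        assert m.initial_peak_dv < 0

    def test_sag_measured_from_early_peak(self):
        tr = passive_step_trace()
        # superpose a decaying hump: early peak then relaxation
        t = tr.time
        hump = 3.0 * np.exp(-(t - 700.0) ** 2 / (2 * 80.0 ** 2))
        tr2 = Trace(DT, tr.samples + hump, "voltage", stimulus=tr.stimulus)
        m = measure_step(tr2)
        assert m.sag_amplitude == pytest.approx(3.0, abs=0.1)

    def test_zero_current_rejected(self):
        tr = passive_step_trace()
        tr.stimulus["amplitude_pA"] = 0.0
        with pytest.raises(ValueError):
            measure_step(tr)

    def test_spiking_trace_refused_for_subthreshold_metrics(self):
        tr = passive_step_trace()
        v = tr.samples.copy()
        v[int(1000 / DT):int(1002 / DT)] = 20.0  # a spike
        spiky = Trace(DT, v, "voltage", stimulus=tr.stimulus)
        with pytest.raises(SpikesPresentError):
            measure_step(spiky)
        m = measure_step(spiky, allow_spikes=True)
        assert m.spike_count == 1 and math.isnan(m.r_n)

    def test_offset_shifts_baseline_not_rn(self):
        tr = passive_step_trace()
        shifted = Trace(DT, tr.samples + 7.0, "voltage", stimulus=tr.stimulus)
        m0, m1 = measure_step(tr), measure_step(shifted)
        assert m1.baseline - m0.baseline == pytest.approx(7.0)
        assert m1.r_n == pytest.approx(m0.r_n)
        assert m1.sag_amplitude == pytest.approx(m0.sag_amplitude, abs=1e-9)


class TestCountSpikes:
    def test_flat_trace(self):
        tr = Trace(DT, np.full(1000, -65.0), "voltage")
        assert count_spikes(tr)[0] == 0

    @pytest.mark.parametrize("n", [1, 7, 100])
    def test_template_train(self, n):
        v = np.full(int(n * 10 / DT) + 200, -70.0)
        for k in range(n):
            i0 = int((5.0 + 10.0 * k) / DT)
            v[i0:i0 + int(1.0 / DT)] = 10.0
        got, times = count_spikes(Trace(DT, v, "voltage"))
        assert got == n
        assert len(times) == n

    def test_refractory_guard_merges_fast_double_crossings(self):
        v = np.full(2000, -70.0)
        v[100:110] = 0.0
        v[115:125] = 0.0  # re-crossing 0.25 ms later: same spike
        assert count_spikes(Trace(DT, v, "voltage"))[0] == 1


class TestAPMetrics:
    def make_spike(self, shift=0.0, sigma=0.3):
        t = np.arange(0.0, 20.0, 0.01)
        v = -65.0 + 90.0 * np.exp(-(t - 10.0) ** 2 / (2 * sigma ** 2)) + shift
        return Trace(0.01, v, "voltage"), sigma

    def test_gaussian_bump_half_width(self):
        tr, sigma = self.make_spike()
        m = ap_metrics(tr)
        # FWHM of the gaussian above half of the threshold-to-peak amplitude
        peak = -65.0 + 90.0
        half = (m.threshold + peak) / 2.0
        frac = (half + 65.0) / 90.0
        expected = 2.0 * sigma * math.sqrt(2.0 * math.log(1.0 / frac))
        assert m.half_width == pytest.approx(expected, rel=0.02)
        assert m.amplitude > 0 and m.ahp_amplitude >= 0

    def test_translation_invariance(self):
        m0 = ap_metrics(self.make_spike()[0])
        m1 = ap_metrics(self.make_spike(shift=10.0)[0])
        assert m1.threshold - m0.threshold == pytest.approx(10.0, abs=0.05)
        assert m1.amplitude == pytest.approx(m0.amplitude, abs=0.05)
        assert m1.half_width == pytest.approx(m0.half_width, rel=1e-6)

    def test_criterion_sensitivity_below_2mv(self):
        tr, _ = self.make_spike()
        thresholds = [ap_metrics(tr, MetricsConfig(dvdt_criterion=c)).threshold
                      for c in (10.0, 15.0, 20.0)]
        assert max(thresholds) - min(thresholds) < 2.0

    def test_no_spike_is_error(self):
        with pytest.raises(ValueError):
            ap_metrics(Trace(0.01, np.full(1000, -70.0), "voltage"))


class TestAlphaDecay:
    def test_exact_exponential_self_fit(self):
        t = np.arange(0.0, 300.0, DT)
        v = 4.0 * np.exp(-t / 10.0)
        tr = Trace(DT, v, "voltage", stimulus={"onsets_ms": [0.0]})
        assert fit_alpha_decay(tr) == pytest.approx(10.0, rel=1e-6)

    def test_noisy_recovery_within_5_percent(self):
        rng = np.random.default_rng(42)
        t = np.arange(0.0, 400.0, DT)
        v = 5.0 * np.exp(-t / 30.0) + rng.normal(0.0, 0.05, t.size)
        tr = Trace(DT, v, "voltage", stimulus={"onsets_ms": [0.0]})
        assert fit_alpha_decay(tr) == pytest.approx(30.0, rel=0.05)

    def test_passive_epsp_decay_near_membrane_tau(self, passive_cell,
                                                  fast_cfg):
        wave, meta = build_alpha_train(AlphaTrainProtocol(count=1, tail=400.0),
                                       fast_cfg.dt, amplitude=300.0)
        tr = run_current_clamp(passive_cell, wave, fast_cfg,
                               hold_voltage=-70.0, stimulus_meta=meta)
        tau = fit_alpha_decay(tr)
        assert tau == pytest.approx(50.0, rel=0.05)


class TestSummation:
    def synth_train(self, freq, tau_m=50.0, amp=1.0, n=5):
        """Linear superposition of alpha-EPSP-shaped responses (analytic)."""
        dt = DT
        dur = 100.0 + 1000.0 / freq * (n - 1) + 600.0
        t = np.arange(0.0, dur, dt)
        v = np.full(t.size, -70.0)
        onsets = [100.0 + k * 1000.0 / freq for k in range(n)]
        for t0 in onsets:
            s = np.maximum(t - t0, 0.0)
            # alpha current filtered by one membrane time constant
            v += amp * (np.exp(-s / tau_m) - np.exp(-s / 1.0)) * (s > 0)
        return Trace(dt, v, "voltage",
                     stimulus={"onsets_ms": onsets, "frequency_hz": freq})

    def test_sparse_train_ratio_near_one(self):
        m = summation_and_coupling(self.synth_train(2.0))
        assert m.summation_ratio == pytest.approx(1.0, abs=0.02)

    def test_linear_50hz_matches_superposition(self, passive_cell, fast_cfg):
        proto = AlphaTrainProtocol(frequency=50.0)
        wave, meta = build_alpha_train(proto, fast_cfg.dt, amplitude=200.0)
        tr = run_current_clamp(passive_cell, wave, fast_cfg,
                               hold_voltage=-70.0, stimulus_meta=meta)
        m = summation_and_coupling(tr)
        # closed-form superposition of single-EPSP responses
        single_wave, smeta = build_alpha_train(
            AlphaTrainProtocol(count=1, tail=1000.0), fast_cfg.dt,
            amplitude=200.0)
        single = run_current_clamp(passive_cell, single_wave, fast_cfg,
                                   hold_voltage=-70.0, stimulus_meta=smeta)
        resp = single.samples - single.samples[:int(100 / fast_cfg.dt)].mean()
        acc = np.zeros(tr.samples.size + 40000)
        for k in range(5):
            i0 = int(k * 20.0 / fast_cfg.dt)
            acc[i0:i0 + resp.size] += resp
        base = np.mean(tr.samples[:int(100 / fast_cfg.dt)])
        i4 = int((meta["onsets_ms"][4] - 100.0 + 100.0) / fast_cfg.dt)
        seg5 = acc[i4:i4 + int(20.0 / fast_cfg.dt)]
        seg1 = acc[:int(20.0 / fast_cfg.dt) + int(100 / fast_cfg.dt)]
        expected = seg5.max() / seg1.max()
        assert m.summation_ratio == pytest.approx(expected, rel=0.02)

    def test_ratio_independent_of_amplitude_linear(self, passive_cell,
                                                   fast_cfg):
        ratios = []
        for amp in (50.0, 150.0, 450.0):
            wave, meta = build_alpha_train(AlphaTrainProtocol(frequency=50.0),
                                           fast_cfg.dt, amplitude=amp)
            tr = run_current_clamp(passive_cell, wave, fast_cfg,
                                   hold_voltage=-70.0, stimulus_meta=meta)
            ratios.append(summation_and_coupling(tr).summation_ratio)
        assert max(ratios) - min(ratios) < 1e-3

    def test_coupling_records_first_amplitude_only_with_spike(self):
        tr = self.synth_train(50.0)
        m = summation_and_coupling(tr)
        assert math.isnan(m.coupling_first_amp)
        v = tr.samples.copy()
        v[int(180.0 / DT):int(181.0 / DT)] = 10.0
        spiky = Trace(DT, v, "voltage", stimulus=tr.stimulus)
        m2 = summation_and_coupling(spiky)
        assert m2.coupling_first_amp == pytest.approx(m.peaks[0], rel=0.05)
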