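import numpy as np
import pytest

from menpsim.config import default_scenario
from menpsim.dynamics import (BondModelParams, build_waveform,
                              default_bond_params, peak_table, q_ionic,
                              time_dependent_run)


@pytest.fixture(scope="module")
def protocol(bv_config):
    return bv_config.stimulation


class TestWaveform:
    def test_two_phase_structure(self, protocol):
        wf = build_waveform(protocol, H_AC=6.5e-3)
        dc = wf.t < wf.t_dc_off
        assert np.allclose(wf.H[dc], protocol.dc_field)
        ac = wf.H[~dc]
        assert np.abs(ac).max() == pytest.approx(6.5e-3, rel=1e-6)

    def test_peak_at_quarter_period(self, protocol):
        wf = build_waveform(protocol, H_AC=6.5e-3)
        t_pk = wf.ac_peak_times()[0]
        assert t_pk == pytest.approx(wf.t_dc_off + 0.25 / protocol.ac_frequency)
        i = int(np.argmin(np.abs(wf.t - t_pk)))
        assert wf.H[i] == pytest.approx(6.5e-3, rel=1e-9)

    def test_zero_amplitude_is_silent_after_switch_off(self, protocol):
        wf = build_waveform(protocol, H_AC=0.0)
        assert np.all(wf.H[wf.t >= wf.t_dc_off] == 0.0)

    def test_grid_density_contract(self, protocol):
        wf = build_waveform(protocol, H_AC=1e-3)
        dt = np.diff(wf.t)
        assert np.allclose(dt, dt[0])
        assert (1.0 / protocol.ac_frequency) / dt[0] >= 200

    def test_nonpositive_duration_rejected(self, bv_config):
        import copy

        p = copy.deepcopy(bv_config.stimulation)
        p.ac_duration = -1.0
        with pytest.raises(ValueError):
            build_waveform(p, H_AC=1e-3)


class TestQIonic:
    def test_zero_and_strict_linearity(self, bv_config):
        bond = default_bond_params(bv_config)
        assert q_ionic(0.0, bond) == 0.0
        assert q_ionic(2 * 1.7, bond) == pytest.approx(2 * q_ionic(1.7, bond),
                                                       rel=1e-14)

    def test_default_gain_maps_published_potential_range(self, bv_config):
        # the published AC-phase dV range spans 2.86-2.92 mV
        bond = default_bond_params(bv_config)
        assert q_ionic(2.86, bond) == pytest.approx(1.29e-17, rel=0.05)
        assert q_ionic(2.92, bond) == pytest.approx(1.32e-17, rel=0.05)

    def test_negative_gain_rejected(self):
        bond = BondModelParams(k_q=-1.0)
        with pytest.raises(ValueError):
            q_ionic(1.0, bond)


@pytest.fixture(scope="module")
def release_runs(bv_config, bv_model):
    runs = []
    for a in bv_config.stimulation.ac_amplitudes:
        wf = build_waveform(bv_config.stimulation, H_AC=a)
        runs.append(time_dependent_run(bv_config, wf, model=bv_model))
    return runs


class TestTimeDependentRun:
    def test_magnetization_constant_during_dc_phase(self, release_runs):
        r = release_runs[-1]
        dc = (r.t > 0.2 * r.waveform.t_dc_off) & (r.t < r.waveform.t_dc_off)
        M_dc = r.M[dc]
        assert M_dc.std() / abs(M_dc.mean()) < 1e-6

    def test_remanence_positive_and_below_dc_value(self, release_runs):
        r = release_runs[-1]
        assert 0 < r.M_remanent < r.M_dc

    def test_dv_oscillates_at_input_frequency(self, release_runs):
        r = release_runs[-1]
        ac = r.t >= r.waveform.t_dc_off
        sig = r.dV_mV[ac] - r.dV_mV[ac].mean()
        freqs = np.fft.rfftfreq(sig.size, d=r.t[1] - r.t[0])
        spec = np.abs(np.fft.rfft(sig))
        f_dom = freqs[1:][np.argmax(spec[1:])]
        assert f_dom == pytest.approx(r.waveform.frequency, rel=0.02)

    def test_q_and_dv_extrema_coincide(self, release_runs):
        r = release_runs[-1]
        ac = r.t >= r.waveform.t_dc_off
        assert np.argmax(r.Q_ionic[ac]) == np.argmax(r.dV_mV[ac])
        assert np.argmin(r.Q_ionic[ac]) == np.argmin(r.dV_mV[ac])

    def test_cm_and_bv_time_series_overlap(self, bv_config, bv_model,
                                           cm_model):
        cm_cfg = default_scenario("CM")
        wf = build_waveform(bv_config.stimulation, H_AC=6.5e-3)
        r_bv = time_dependent_run(bv_config, wf, model=bv_model)
        r_cm = time_dependent_run(cm_cfg, wf, model=cm_model)
        scale = r_bv.dV_mV.max()
        assert np.abs(r_bv.dV_mV - r_cm.dV_mV).max() < 0.02 * scale

    def test_time_step_convergence_of_peak_dv(self, bv_config, bv_model):
        peaks = []
        for n in (200, 400):
            wf = build_waveform(bv_config.stimulation, H_AC=6.5e-3,
                                points_per_period=n)
            r = time_dependent_run(bv_config, wf, model=bv_model)
            t_pk = wf.ac_peak_times()[0]
            peaks.append(r.dV_mV[int(np.argmin(np.abs(r.t - t_pk)))])
        assert peaks[1] == pytest.approx(peaks[0], rel=0.005)


class TestPeakTable:
    def test_dv_monotone_in_amplitude(self, release_runs, bv_config):
        tab = peak_table(release_runs, bv_config)
        assert np.all(np.diff(tab.dV_mV.values) > 0)
        assert np.all(np.diff(tab.H_AC_mT.values) > 0)

    def test_both_alpha_conventions_reported(self, release_runs, bv_config):
        tab = peak_table(release_runs, bv_config)
        assert "alpha_ac_mV_per_Oe_cm" in tab
        assert "alpha_dc_referred_mV_per_Oe_cm" in tab
        # the AC-referred convention diverges as amplitude shrinks
        assert tab.alpha_ac_mV_per_Oe_cm.iloc[0] > \
            tab.alpha_ac_mV_per_Oe_cm.iloc[-1]

    def test_missing_amplitude_reported(self, release_runs, bv_config):
        with pytest.raises(ValueError, match="missing amplitudes"):
            peak_table(release_runs[:3], bv_config)
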