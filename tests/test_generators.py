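"""Waveform and cohort generators: determinism, calibration, device behaviour."""

import numpy as np
import pytest

import neovent as nv
from neovent import synth


class TestOperatorSampling:
    def test_same_seed_identical(self):
        a = nv.sample_operator(synth.TPIECE_OPERATOR_DEFAULTS, seed=42)
        b = nv.sample_operator(synth.TPIECE_OPERATOR_DEFAULTS, seed=42)
        assert a == b

    def test_zero_scale_degenerates_to_medians(self):
        cfg = {"pip": (19.9, 0.0), "peep": (5.1, 0.0), "ti": (1.0, 0.0),
               "rr": (40.0, 0.0), "sli_target": (20.0, 0.0)}
        op = nv.sample_operator(cfg, seed=0)
        assert op.pip_target == 19.9
        assert op.peep_target == 5.1
        assert op.ti_mean == 1.0
        # Ti 1.0 s forces the rate down to the duty-cycle cap 0.6 -> 36/min
        assert op.rr_mean == pytest.approx(36.0)
        cfg["ti"] = (0.5, 0.0)
        assert nv.sample_operator(cfg, seed=0).rr_mean == 40.0

    def test_negative_scale_rejected(self):
        with pytest.raises(ValueError):
            synth.lognormal_from_median_iqr(20.0, -1.0, np.random.default_rng(0))

    def test_lognormal_median_recovered(self):
        """10,000 draws with configured median 21.1: empirical median within 1%."""
        rng = np.random.default_rng(3)
        draws = synth.lognormal_from_median_iqr(21.1, 7.9, rng, size=10_000)
        assert np.median(draws) == pytest.approx(21.1, rel=0.01)


class TestTpieceGenerator:
    def test_breath_count_and_plateau(self, steady_tpiece_epoch):
        """Jitter-free RR 40 over 180 s: 120 breaths, every PIP on the plateau."""
        breaths = nv.analyze_recording(steady_tpiece_epoch)
        assert len(breaths) == 120
        pips = np.array([b.pip for b in breaths])
        assert np.abs(pips - 20.0).max() < 0.05

    def test_end_expiratory_pressure_equals_set_peep(self, steady_tpiece_epoch):
        breaths = nv.analyze_recording(steady_tpiece_epoch)
        peeps = np.array([b.peep for b in breaths])
        assert np.abs(peeps - 5.0).max() < 0.1

    def test_wrong_device_rejected(self, sib_dev, steady_op, lung):
        with pytest.raises(ValueError):
            nv.generate_tpiece_recording(steady_op, sib_dev, lung, 30.0, seed=0)

    def test_cohort_median_vt_and_ti_on_study_scale(self, default_cohort):
        """Default calibration: cohort median Vt in the low 20s mL, Ti near 1 s."""
        _, _, subjects, _, _ = default_cohort
        tp = subjects[subjects.device == "tpiece"]
        assert 20.0 <= tp.vt.median() <= 23.0
        assert 0.85 <= tp.ti.median() <= 1.15


class TestSibGenerator:
    def test_popoff_caps_every_sample(self, sib_dev, lung):
        op = nv.OperatorParams(pip_target=50.0, peep_target=0.0, ti_mean=0.5,
                               rr_mean=40.0, breath_jitter_cv=0.0)
        ts = nv.generate_sib_recording(op, sib_dev, lung, 30.0, seed=0)
        assert ts.pressure.max() <= 40.0 + 1e-12
        peaks = [b.pip for b in nv.analyze_recording(ts)]
        assert np.allclose(peaks, 40.0, atol=0.05)

    def test_no_peep_valve_baseline_zero(self, steady_sib_epoch):
        """Every SIB breath ends at zero pressure (no PEEP valve)."""
        breaths = nv.analyze_recording(steady_sib_epoch)
        assert np.abs([b.peep for b in breaths]).max() < 0.1

    def test_per_breath_pip_jitter_cv(self, sib_dev, lung):
        op = nv.OperatorParams(pip_target=21.0, peep_target=0.0, ti_mean=0.5,
                               rr_mean=40.0, breath_jitter_cv=0.15)
        ts = nv.generate_sib_recording(op, sib_dev, lung, 360.0, seed=5)
        pips = np.array([b.pip for b in nv.analyze_recording(ts)])
        assert len(pips) >= 200
        assert pips.std() / pips.mean() == pytest.approx(0.15, abs=0.03)


class TestSLITraces:
    def test_tpiece_near_ideal_square_pulse(self, lung):
        """circuit taus -> 0 approaches the ideal 20 cmH2O x 10 s pulse."""
        dev = nv.DeviceParams.tpiece(circuit_tau=1e-4, sli_rise_tau=1e-4)
        op = nv.OperatorParams(pip_target=20.0, peep_target=0.0, sli_target=20.0)
        ts = nv.generate_sli_trace(op, dev, lung, seed=0)
        m = nv.analyze_sli_trace(ts)
        assert m.auptc == pytest.approx(200.0, rel=0.005)
        assert m.p_max == pytest.approx(20.0, abs=0.01)

    def test_tpiece_first_order_hold_integral(self, lung):
        """Rise tau 1.0 s toward 20: window integral ~ 20*(10 - (1 - e^-10))."""
        dev = nv.DeviceParams.tpiece(sli_rise_tau=1.0)
        op = nv.OperatorParams(pip_target=20.0, peep_target=0.0, sli_target=20.0)
        # hold slightly past the window so release does not clip the integral
        ts = nv.generate_sli_trace(op, dev, lung, seed=0, hold=10.5)
        onset = nv.detect_sli_onset(ts)
        # closed form from the detected onset t0 (rise measured from command)
        t0 = onset.onset_time - 2.0
        expected = 20.0 * 10.0 - 20.0 * np.exp(-t0) * (1 - np.exp(-10.0))
        m = nv.compute_sli_metrics(ts, onset.onset_time)
        assert m.auptc == pytest.approx(expected, rel=0.002)

    def test_onset_near_commanded_start(self, lung):
        dev = nv.DeviceParams.tpiece(sli_rise_tau=1.0)
        op = nv.OperatorParams(pip_target=20.0, peep_target=5.0, sli_target=20.0)
        ts = nv.generate_sli_trace(op, dev, lung, seed=0)
        onset = nv.detect_sli_onset(ts)
        assert abs(onset.onset_time - 2.0) < 0.15

    def test_sib_decay_scale(self, sib_dev, lung):
        """SIB hold fails: pressure decays, AUPTC far below the T-piece's."""
        op = nv.OperatorParams(pip_target=21.0, peep_target=0.0, sli_target=23.6)
        m = nv.analyze_sli_trace(nv.generate_sli_trace(op, sib_dev, lung, seed=0))
        assert m.p_max == pytest.approx(23.6, abs=0.05)
        assert 40.0 < m.auptc < 80.0
        assert m.t_max == pytest.approx(1.0, abs=0.1)

    def test_unknown_sli_refused(self, tpiece_dev, lung):
        op = nv.OperatorParams(pip_target=20.0, knows_sli=False)
        with pytest.raises(synth.SLINotPerformedError):
            nv.generate_sli_trace(op, tpiece_dev, lung, seed=0)


class TestCohortGenerator:
    def test_empty_cohort(self):
        recordings, manifest = nv.generate_cohort(0, 0, seed=0)
        assert recordings == {}
        assert manifest.empty

    def test_same_seed_identical_outputs(self):
        cfg = synth.CohortConfig(epoch_duration=6.0, n_acq_failures=(0, 0),
                                 n_sli_unknown=(0, 0))
        r1, m1 = nv.generate_cohort(2, 1, config=cfg, seed=9)
        r2, m2 = nv.generate_cohort(2, 1, config=cfg, seed=9)
        assert m1.equals(m2)
        for sid in r1:
            for name in r1[sid]:
                assert np.array_equal(r1[sid][name].pressure, r2[sid][name].pressure)
                assert np.array_equal(r1[sid][name].flow, r2[sid][name].flow)

    def test_manifest_flags_match_config(self):
        cfg = synth.CohortConfig()
        rng = np.random.default_rng(0)
        man = synth.build_manifest(54, 60, cfg, rng)
        by_group = man.groupby("group")
        assert by_group.acq_failure.sum().to_dict() == {"instructor": 3,
                                                        "non_instructor": 1}
        ok = man[man.acq_failure == 0]
        unable = ok.groupby("group").knows_sli.apply(lambda s: (s == 0).sum())
        assert unable.to_dict() == {"instructor": 13, "non_instructor": 13}
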