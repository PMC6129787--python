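"""Synthetic-data generator: template constraints, schedules, determinism."""

import numpy as np
import pytest

from mstate import synth
from mstate.gfp import compute_gfp
from mstate.io_preprocess import Recording


class TestMakeTemplates:
    def test_single_class_is_zero_mean_unit_gfp(self):
        t = synth.make_templates(1, 9, 0.5, seed=7)
        assert t.maps.shape == (1, 9)
        assert abs(t.maps[0].mean()) < 1e-12
        assert abs(t.maps[0].std(ddof=0) - 1.0) < 1e-9

    def test_pairwise_correlation_ceiling_holds(self):
        t = synth.make_templates(3, 9, 0.5, seed=1)
        for i in range(3):
            assert abs(t.maps[i].mean()) < 1e-10
            assert abs(t.maps[i].std(ddof=0) - 1.0) < 1e-9
            for j in range(i + 1, 3):
                r = np.corrcoef(t.maps[i], t.maps[j])[0, 1]
                assert abs(r) <= 0.5 + 1e-12

    def test_infeasible_ceiling_raises(self):
        # two-channel zero-mean maps are all collinear: |corr| = 1 > 0.1
        with pytest.raises(RuntimeError):
            synth.make_templates(3, 2, 0.1, seed=0)

    def test_deterministic_given_seed(self):
        a = synth.make_templates(4, 9, 0.5, seed=42)
        b = synth.make_templates(4, 9, 0.5, seed=42)
        np.testing.assert_array_equal(a.maps, b.maps)


class TestScheduleSampling:
    def test_half_open_segments_tile_the_window(self):
        schedule = ((0, 0.0, 500.0), (1, 500.0, 2000.0), (2, 2000.0, 3500.0))
        labels = synth.schedule_to_labels(schedule, 125.0, 3500.0)
        runs = [(labels[s], int(np.sum(labels == labels[s])))
                for s in [0, 100, 300]]
        lengths = [int((labels == c).sum()) for c in (0, 1, 2)]
        assert labels.size == 438
        assert lengths == [62, 188, 188]
        # contiguity: labels are non-decreasing for this ordered schedule
        assert np.all(np.diff(labels) >= 0)

    def test_overlapping_schedule_rejected(self):
        with pytest.raises(ValueError):
            synth.SimPlan(schedule=((0, 0.0, 600.0), (1, 500.0, 3500.0)))

    def test_schedule_class_out_of_range(self, templates3):
        plan = synth.SimPlan(schedule=((0, 0.0, 1000.0), (5, 1000.0, 3500.0)))
        with pytest.raises(ValueError):
            synth.synthesize_recording(templates3, plan)


class TestSynthesizeRecording:
    def test_noiseless_maps_proportional_to_active_template(self, templates3,
                                                            noiseless_recording):
        rec = noiseless_recording
        data = rec.data - rec.data.mean(axis=0, keepdims=True)
        for t in range(0, rec.n_samples, 37):
            m = data[:, t]
            if np.linalg.norm(m) < 1e-9:     # envelope zero-crossing
                continue
            tmpl = templates3.maps[rec.truth_labels[t]]
            r = np.corrcoef(m, tmpl)[0, 1]
            # the signed carrier flips polarity; the topography is identical
            assert abs(r) > 1 - 1e-9

    def test_truth_labels_match_schedule(self, noiseless_recording):
        plan = synth.SimPlan(snr=np.inf, seed=2)
        np.testing.assert_array_equal(
            noiseless_recording.truth_labels,
            synth.schedule_to_labels(plan.schedule, 125.0, 3500.0))

    def test_amplitude_scale_doubles_gfp(self, templates3):
        gfps = []
        for scale in (1.0, 2.0):
            plan = synth.SimPlan(snr=np.inf, seed=4, amplitude_scale=scale)
            rec = synth.synthesize_recording(templates3, plan)
            g = compute_gfp(Recording(data=rec.data, sampling_rate=125.0))
            gfps.append(g.values.mean())
        assert gfps[1] == pytest.approx(2.0 * gfps[0], rel=1e-12)

    def test_mean_gfp_monotone_in_amplitude_scale(self, templates3):
        means = []
        for scale in (0.5, 1.0, 2.0, 3.5):
            plan = synth.SimPlan(snr=2.0, seed=9, amplitude_scale=scale)
            rec = synth.synthesize_recording(templates3, plan)
            g = compute_gfp(Recording(data=rec.data, sampling_rate=125.0))
            means.append(g.values.mean())
        assert np.all(np.diff(means) > 0)


class TestSimulateStudy:
    def test_bitwise_determinism(self):
        cfg = synth.StudyConfig(seed=42, n_trials=1)
        a = synth.simulate_study(cfg)
        b = synth.simulate_study(cfg)
        for ra, rb in zip(a.recordings, b.recordings):
            np.testing.assert_array_equal(ra.data, rb.data)
            np.testing.assert_array_equal(ra.truth_labels, rb.truth_labels)

    def test_noiseless_gfp_ratio_matches_amplitude_presets(self):
        """Mean-GFP presets: executed vs imagined 4 kg is exactly 2.16/1.82
        in the noiseless limit (shared envelope, different scale)."""
        cfg = synth.StudyConfig(seed=5, n_trials=1, snr=np.inf)
        study = synth.simulate_study(cfg)
        by = {r.condition: r for r in study.recordings}
        mg = {}
        for cond in ("executed_4kg", "imagined_4kg"):
            g = compute_gfp(Recording(data=by[cond].data, sampling_rate=125.0))
            mg[cond] = g.values.mean()
        assert mg["executed_4kg"] / mg["imagined_4kg"] == \
            pytest.approx(2.16 / 1.82, rel=1e-9)

    def test_trials_share_truth_but_not_noise(self):
        cfg = synth.StudyConfig(seed=6, n_trials=3)
        study = synth.simulate_study(cfg)
        assert len(study.recordings) == 18
        by = study.by_condition()
        for cond, recs in by.items():
            assert len(recs) == 3
            for r in recs[1:]:
                np.testing.assert_array_equal(r.truth_labels,
                                              recs[0].truth_labels)
                assert not np.array_equal(r.data, recs[0].data)

    def test_written_study_round_trips(self, tmp_path):
        from mstate.io_preprocess import read_recording, read_events
        study = synth.simulate_study(synth.StudyConfig(seed=3, n_trials=1))
        synth.write_study(study, tmp_path)
        ev = read_events(tmp_path / "events.tsv")
        assert len(ev) == 6
        rec = read_recording(tmp_path / "executed_4kg_trial00.csv",
                             sampling_rate=125.0)
        orig = study.by_condition()["executed_4kg"][0]
        assert rec.data.shape == orig.data.shape
        np.testing.assert_allclose(rec.data, orig.data, rtol=1e-4, atol=1e-4)
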