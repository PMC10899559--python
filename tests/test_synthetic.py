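"""Phantom-cohort generator: determinism, dropout structure, survival
distribution, lesion rendering and disk round-trip."""

import numpy as np
import pytest

from longict.synthetic import (PhantomConfig, render_lesion_patch,
                               simulate_cohort, simulate_survival,
                               write_cohort)
from oracles import cindex_bruteforce


def records_equal(a, b) -> bool:
    if a.patient_id != b.patient_id or len(a.lesions) != len(b.lesions):
        return False
    if not np.allclose(a.markers, b.markers, equal_nan=True):
        return False
    if (a.sex, a.her2_status, a.event) != (b.sex, b.her2_status, b.event):
        return False
    if not np.isclose(a.os_months, b.os_months):
        return False
    for ta, tb in zip(a.lesions, b.lesions):
        if (ta.lesion_id, ta.site, ta.box, ta.slice_index) != \
                (tb.lesion_id, tb.site, tb.box, tb.slice_index):
            return False
        if not np.allclose(ta.diameters_mm, tb.diameters_mm, equal_nan=True):
            return False
        for pa, pb in zip(ta.patches, tb.patches):
            if (pa is None) != (pb is None):
                return False
            if pa is not None and not np.array_equal(pa.array, pb.array):
                return False
    return True


class TestSimulateCohort:
    def test_seeded_runs_are_identical(self):
        cfg = PhantomConfig(n_patients=4, seed=21, patch_size=32)
        ra, _ = simulate_cohort(cfg)
        rb, _ = simulate_cohort(cfg)
        assert all(records_equal(a, b) for a, b in zip(ra, rb))

    def test_no_dropout_gives_full_followup(self):
        cfg = PhantomConfig(n_patients=6, seed=3, followup_missing_prob=0.0,
                            patch_size=32)
        records, _ = simulate_cohort(cfg)
        for rec in records:
            assert rec.available_timepoints.all()

    def test_missingness_is_monotone(self):
        cfg = PhantomConfig(n_patients=20, seed=9, followup_missing_prob=0.4,
                            patch_size=32)
        records, _ = simulate_cohort(cfg)
        saw_partial = False
        for rec in records:
            avail = rec.available_timepoints
            n = int(avail.sum())
            assert avail[:n].all() and not avail[n:].any()
            saw_partial |= n < cfg.n_timepoints_max
        assert saw_partial

    def test_every_patient_has_baseline_and_primary(self, tiny_cohort):
        _, records, _ = tiny_cohort
        for rec in records:
            assert rec.available_timepoints[0]
            assert rec.lesions[0].is_primary
            assert 1 <= len(rec.lesions) <= 6

    def test_observed_os_is_min_of_death_and_censoring(self, tiny_cohort):
        _, records, truths = tiny_cohort
        for rec, tr in zip(records, truths):
            assert rec.os_months == pytest.approx(
                min(tr.true_survival_time, tr.censoring_time))
            assert rec.event == int(tr.true_survival_time < tr.censoring_time)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(n_patients=0)
        with pytest.raises(ValueError):
            PhantomConfig(lesion_count_range=(1, 6))
        with pytest.raises(ValueError):
            PhantomConfig(baseline_diameter_range=(8.0, 30.0))
        with pytest.raises(ValueError):
            PhantomConfig(censoring_rate=1.5)


class TestSurvivalDistribution:
    def test_censoring_fraction_matches_target(self):
        cfg = PhantomConfig(censoring_rate=0.25)
        rng = np.random.default_rng(0)
        z = rng.normal(size=2000)
        t, c = simulate_survival(cfg, rng, z)
        frac = np.mean(c < t)
        assert abs(frac - 0.25) < 0.05

    def test_zero_hazard_coef_decouples_risk_and_survival(self):
        cfg = PhantomConfig(hazard_coef=0.0, censoring_rate=0.0)
        rng = np.random.default_rng(1)
        z = rng.normal(size=2000)
        t, c = simulate_survival(cfg, rng, z)
        from scipy.stats import kendalltau
        tau, p = kendalltau(z, np.minimum(t, c))
        assert abs(tau) < 0.04  # null: no association beyond sampling error
        assert p > 0.001

    def test_concordance_increases_with_hazard_coef(self):
        cs = []
        for beta in (0.5, 1.0, 2.0):
            cfg = PhantomConfig(hazard_coef=beta, censoring_rate=0.25)
            rng = np.random.default_rng(5)
            z = rng.normal(size=1000)
            t, c = simulate_survival(cfg, rng, z)
            os_m = np.minimum(t, c)
            ev = (t < c).astype(int)
            cs.append(cindex_bruteforce(z, os_m, ev))
        assert cs[0] > 0.5
        assert cs[0] < cs[1] < cs[2]


class TestRenderLesion:
    def test_rejects_nonpositive_diameter_and_unknown_site(self, rng):
        with pytest.raises(ValueError):
            render_lesion_patch(0.0, "liver", 5.0, rng)
        with pytest.raises(ValueError):
            render_lesion_patch(20.0, "brain", 5.0, rng)

    def test_same_rng_state_gives_identical_array(self):
        a = render_lesion_patch(20.0, "liver", 5.0, np.random.default_rng(4))
        b = render_lesion_patch(20.0, "liver", 5.0, np.random.default_rng(4))
        assert np.array_equal(a, b)

    def test_blob_area_scales_with_diameter_squared(self, rng):
        def blob_pixels(d):
            arr = render_lesion_patch(d, "lung", noise_sd=0.0,
                                      rng=np.random.default_rng(8),
                                      canvas_px=int(3 * d),
                                      background_hu=-800.0, orientation=0.3)
            mid = arr[..., 1]
            return np.sum(mid > (-800.0 + 40.0) / 2)
        ratio = blob_pixels(40.0) / blob_pixels(20.0)
        assert ratio == pytest.approx(4.0, rel=0.15)

    def test_background_hu_tracks_site(self, rng):
        lung = render_lesion_patch(15.0, "lung", 1.0, rng, canvas_px=64)
        abd = render_lesion_patch(15.0, "lymph_node", 1.0, rng, canvas_px=64)
        assert np.median(lung[0:5, :, 1]) < -700
        assert -10 < np.median(abd[0:5, :, 1]) < 50


class TestWriteCohort:
    def test_round_trip_reproduces_records(self, tiny_cohort, tmp_path):
        from longict.io import load_cohort
        cfg, records, truths = tiny_cohort
        paths = write_cohort(records, truths, tmp_path, spacing=cfg.spacing)
        loaded = load_cohort(paths["annotation_csv"], paths["image_dir"],
                             paths["marker_csv"], paths["clinical_csv"],
                             patch_size=cfg.patch_size, spacing=cfg.spacing,
                             n_timepoints=cfg.n_timepoints_max)
        assert len(loaded) == len(records)
        for a, b in zip(records, sorted(loaded, key=lambda r: r.patient_id)):
            assert records_equal(a, b)

    def test_annotation_rows_count_lesions_times_timepoints(self, tiny_cohort,
                                                            tmp_path):
        import pandas as pd
        cfg, records, truths = tiny_cohort
        paths = write_cohort(records, truths, tmp_path / "w2", spacing=cfg.spacing)
        df = pd.read_csv(paths["annotation_csv"])
        expected = sum(int(t.valid.sum()) for r in records for t in r.lesions)
        assert len(df) == expected

    def test_fully_missing_marker_series_round_trips(self, tmp_path):
        from longict.io import load_cohort
        cfg = PhantomConfig(n_patients=2, seed=13, marker_missing_prob=1.0,
                            patch_size=32)
        records, truths = simulate_cohort(cfg, keep_volumes=True)
        assert np.isnan(records[0].markers).all()
        paths = write_cohort(records, truths, tmp_path, spacing=cfg.spacing)
        loaded = load_cohort(paths["annotation_csv"], paths["image_dir"],
                             paths["marker_csv"], paths["clinical_csv"],
                             patch_size=cfg.patch_size,
                             n_timepoints=cfg.n_timepoints_max)
        assert np.isnan(loaded[0].markers).all()

    def test_writing_without_volumes_is_an_error(self, tmp_path):
        cfg = PhantomConfig(n_patients=1, seed=1, patch_size=32)
        records, truths = simulate_cohort(cfg, keep_volumes=False)
        with pytest.raises(ValueError, match="keep_volumes"):
            write_cohort(records, truths, tmp_path)
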