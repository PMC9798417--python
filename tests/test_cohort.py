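"""Synthetic cohort generator: layout arithmetic, determinism, ground truth."""

import numpy as np
import pytest

from metafinger import (CohortDesign, generate_cohort, generate_raster,
                        generate_scan_set, records_to_manifest, split_by_patient)
from metafinger.cohort import manifest_to_records


class TestCohortLayout:
    def test_study_scale_counts(self):
        # 40 patients x 2 tissues x 3 points and a 242 + 139 serum cohort
        records, _ = generate_cohort(CohortDesign(seed=0))
        tissue = [r for r in records if r.specimen == "tissue"]
        serum = [r for r in records if r.specimen == "serum"]
        assert len(tissue) == 240
        assert len(serum) == 381
        assert sum(r.group == "TNBC" for r in serum) == 242
        assert sum(r.group == "HD" for r in serum) == 139

    def test_patient_level_split_is_150_90(self):
        records, _ = generate_cohort(CohortDesign(seed=0))
        train, test = split_by_patient(records, n_train_patients=25)
        assert len(train) == 150 and len(test) == 90
        assert {r.patient_id for r in train}.isdisjoint({r.patient_id for r in test})

    def test_qc_inserted_at_every_spacing_position(self, tiny_design):
        records, _ = generate_cohort(tiny_design)
        for r in records:
            if (r.run_index + 1) % tiny_design.qc_every == 0:
                assert r.specimen == "qc" and r.group == "QC"
            else:
                assert r.specimen != "qc"

    def test_tissue_points_are_paired_by_patient(self, tiny_design):
        records, _ = generate_cohort(tiny_design)
        tissue = [r for r in records if r.specimen == "tissue"]
        by_patient = {}
        for r in tissue:
            by_patient.setdefault(r.patient_id, []).append(r.group)
        for groups in by_patient.values():
            assert groups.count("TNBC") == tiny_design.points_per_tissue
            assert groups.count("PNT") == tiny_design.points_per_tissue

    def test_run_index_unique_and_conserved(self, tiny_design):
        records, _ = generate_cohort(tiny_design)
        d = tiny_design
        n_real = (d.n_patients * 2 * d.points_per_tissue
                  + d.n_tnbc_serum + d.n_hd_serum)
        assert sum(r.specimen != "qc" for r in records) == n_real

    def test_deterministic_from_seed(self, tiny_design):
        a, truth_a = generate_cohort(tiny_design)
        b, truth_b = generate_cohort(tiny_design)
        assert a == b and truth_a == truth_b

    def test_ground_truth_lists_directions(self, tiny_design):
        _, truth = generate_cohort(tiny_design)
        assert truth[3] == {"fold_change": 4.0, "direction": "up"}
        assert truth[17] == {"fold_change": 0.25, "direction": "down"}

    def test_marker_index_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            CohortDesign(n_ions=10, marker_spec=((10, 2.0),))

    def test_nonpositive_fold_change_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            CohortDesign(marker_spec=((0, 0.0),))

    def test_inconsistent_direction_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            CohortDesign(marker_spec=((0, 4.0, "down"),))

    def test_manifest_round_trip(self, tiny_design):
        records, _ = generate_cohort(tiny_design)
        assert manifest_to_records(records_to_manifest(records)) == records


class TestScanSets:
    def test_scan_count_and_ion_count(self, tiny_design):
        records, _ = generate_cohort(tiny_design)
        scans = generate_scan_set(records[0], tiny_design, n_scans=10)
        assert len(scans) == 10
        assert all(len(s) == tiny_design.n_ions for s in scans)

    def test_scan_sets_deterministic(self, tiny_design):
        records, _ = generate_cohort(tiny_design)
        a = generate_scan_set(records[3], tiny_design, n_scans=3)
        b = generate_scan_set(records[3], tiny_design, n_scans=3)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.mz, sb.mz)
            np.testing.assert_array_equal(sa.intensity, sb.intensity)

    def test_zero_noise_non_marker_ions_identical(self, tiny_design):
        from dataclasses import replace
        quiet = replace(tiny_design, noise_sd=0.0, tic_cv=0.0,
                        patient_effect_sd=0.0, drift_slope=1.0)
        records, truth = generate_cohort(quiet)
        real = [r for r in records if r.specimen != "qc"]
        rows = np.array([generate_scan_set(r, quiet, 1)[0].intensity for r in real])
        non_marker = np.setdiff1d(np.arange(quiet.n_ions), list(truth))
        assert np.all(rows[:, non_marker] == rows[0, non_marker])

    def test_marker_ion_differs_between_groups_at_zero_noise(self, tiny_design):
        from dataclasses import replace
        quiet = replace(tiny_design, noise_sd=0.0, tic_cv=0.0,
                        patient_effect_sd=0.0, drift_slope=1.0)
        records, _ = generate_cohort(quiet)
        case = next(r for r in records if r.group == "TNBC")
        ctrl = next(r for r in records if r.group in ("PNT", "HD"))
        a = generate_scan_set(case, quiet, 1)[0].intensity
        b = generate_scan_set(ctrl, quiet, 1)[0].intensity
        assert a[3] / b[3] == pytest.approx(4.0)
        assert a[17] / b[17] == pytest.approx(0.25)

    def test_fold_change_recovered_across_many_samples(self):
        # Monte-Carlo: mean TNBC/control intensity ratio of a 4x marker
        design = CohortDesign(n_patients=1, points_per_tissue=1,
                              n_tnbc_serum=120, n_hd_serum=120, n_ions=50,
                              mz_range=(100.0, 300.0), marker_spec=((5, 4.0),),
                              tic_cv=0.0, drift_slope=1.0, seed=9)
        records, _ = generate_cohort(design)
        serum = [r for r in records if r.specimen == "serum"]
        rows = np.array([generate_scan_set(r, design, 1)[0].intensity for r in serum])
        case = np.array([r.group == "TNBC" for r in serum])
        ratio = rows[case, 5].mean() / rows[~case, 5].mean()
        assert ratio == pytest.approx(4.0, rel=0.15)

    def test_mz_jitter_bounded_within_bin(self, tiny_design):
        from metafinger.cohort import _ion_params
        centers, _ = _ion_params(tiny_design)
        records, _ = generate_cohort(tiny_design)
        for scan in generate_scan_set(records[0], tiny_design, 5):
            assert np.max(np.abs(scan.mz - centers)) <= tiny_design.mz_jitter + 1e-12

    def test_qc_profile_is_deterministic_mean_with_drift_only(self, tiny_design):
        records, _ = generate_cohort(tiny_design)
        qcs = [r for r in records if r.specimen == "qc"][:2]
        a = generate_scan_set(qcs[0], tiny_design, 1)[0].intensity
        b = generate_scan_set(qcs[1], tiny_design, 1)[0].intensity
        drift = tiny_design.drift_slope ** (qcs[1].run_index - qcs[0].run_index)
        np.testing.assert_allclose(b, a * drift)


class TestRaster:
    def test_grid_dimensions(self):
        raster = generate_raster(2.0, 2.0, raster_speed=0.2, line_spacing=0.2,
                                 scan_rate=1.0, pattern=lambda x, y: 1.0)
        lines = {r for r, _, _ in raster}
        assert len(lines) == 10
        assert len(raster) == 100

    def test_constant_pattern_gives_equal_scans(self):
        raster = generate_raster(1.0, 1.0, 0.2, 0.2, 1.0, lambda x, y: 7.0)
        assert all(spec.intensity[0] == 7.0 for _, _, spec in raster)

    def test_step_pattern_splits_at_midline(self):
        raster = generate_raster(2.0, 0.2, 0.2, 0.2, 1.0,
                                 lambda x, y: 10.0 if x < 1.0 else 1.0)
        values = [spec.intensity[0] for _, _, spec in raster]
        assert values == [10.0] * 5 + [1.0] * 5

    def test_nonpositive_geometry_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            generate_raster(0.0, 1.0, 0.2, 0.2, 1.0, lambda x, y: 1.0)
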