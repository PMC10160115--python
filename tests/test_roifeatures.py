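"""Sphere voxel selection, ROI time-series extraction, matrix assembly."""

import numpy as np
import pytest

from stimlabel.alignment import TRLabelSeries
from stimlabel.roifeatures import (
    REFERENCE_ROI_VOXEL_COUNTS,
    FeatureMatrix,
    ROISpec,
    VoxelTimeSeries,
    assemble_feature_matrix,
    extract_roi_timeseries,
    load_roi_specs,
    load_timeseries_dir,
    sphere_voxel_indices,
)

nib = pytest.importorskip("nibabel")


def brute_force_sphere(shape, affine, seed_mm, radius_mm):
    """Exhaustive oracle: scan every voxel in the grid."""
    out = []
    seed = np.asarray(seed_mm, dtype=float)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                mm = affine[:3, :3] @ np.array([i, j, k], float) + affine[:3, 3]
                if np.linalg.norm(mm - seed) <= radius_mm + 1e-9:
                    out.append((i, j, k))
    return out


class TestSphereSelection:
    def test_zero_radius_at_voxel_center_gives_one_voxel(self):
        affine = np.diag([3.2, 3.2, 3.2, 1.0])
        vox = sphere_voxel_indices((10, 10, 10), affine, (6.4, 9.6, 3.2), 0.0)
        assert vox == [(2, 3, 1)]

    def test_radius_below_half_spacing_gives_one_voxel(self):
        affine = np.diag([3.2, 3.2, 3.2, 1.0])
        vox = sphere_voxel_indices((10, 10, 10), affine, (6.4, 6.4, 6.4), 1.0)
        assert vox == [(2, 2, 2)]

    def test_matches_brute_force_on_study_grid(self):
        affine = np.diag([3.2, 3.2, 3.2, 1.0])
        got = sphere_voxel_indices((20, 20, 20), affine, (32.0, 32.0, 32.0),
                                   5.0)
        expect = brute_force_sphere((20, 20, 20), affine, (32.0, 32.0, 32.0),
                                    5.0)
        assert sorted(got) == sorted(expect)

    def test_matches_brute_force_on_random_affines(self, rng):
        """100 random (seed, radius) pairs on random oblique affines."""
        shape = (8, 9, 7)
        for _ in range(100):
            A = np.eye(4)
            A[:3, :3] = rng.uniform(2.0, 4.0) * np.eye(3) \
                + rng.normal(0, 0.3, (3, 3))
            A[:3, 3] = rng.uniform(-10, 10, 3)
            center_vox = rng.uniform(1, 6, 3)
            seed = A[:3, :3] @ center_vox + A[:3, 3]
            radius = float(rng.uniform(0.5, 8.0))
            expect = sorted(brute_force_sphere(shape, A, seed, radius))
            if not expect:
                with pytest.raises(ValueError):
                    sphere_voxel_indices(shape, A, seed, radius)
            else:
                got = sorted(sphere_voxel_indices(shape, A, seed, radius))
                assert got == expect

    def test_voxel_count_monotone_in_radius(self, rng):
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        seed = (15.0, 15.0, 15.0)
        counts = [
            len(sphere_voxel_indices((12, 12, 12), affine, seed, r))
            for r in (0.0, 2.0, 4.0, 6.0, 9.0)
        ]
        assert counts == sorted(counts)

    def test_seed_outside_grid_rejected(self):
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        with pytest.raises(ValueError, match="outside|no voxel"):
            sphere_voxel_indices((5, 5, 5), affine, (500.0, 500.0, 500.0), 5.0)

    def test_reference_voxel_counts_total_111(self):
        assert sum(REFERENCE_ROI_VOXEL_COUNTS.values()) == 111
        assert len(REFERENCE_ROI_VOXEL_COUNTS) == 6


class TestExtraction:
    def make_image(self, data):
        return nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                               np.diag([3.2, 3.2, 3.2, 1.0]))

    def test_constructed_ramp_signal_recovered(self):
        data = np.zeros((6, 6, 6, 5), dtype=np.float32)
        data[2, 3, 1, :] = np.arange(5)
        img = self.make_image(data)
        roi = ROISpec("toy", seed_mm=(6.4, 9.6, 3.2), radius_mm=0.5)
        ts = extract_roi_timeseries(img, roi)
        assert ts.data.shape == (5, 1)
        assert np.allclose(ts.data[:, 0], np.arange(5))

    def test_extraction_matches_direct_indexing_oracle(self, rng):
        data = rng.standard_normal((8, 8, 8, 12)).astype(np.float32)
        img = self.make_image(data)
        roi = ROISpec("rand", seed_mm=(12.8, 12.8, 12.8), radius_mm=5.0)
        ts = extract_roi_timeseries(img, roi)
        assert ts.n_volumes == 12
        for col, (i, j, k) in enumerate(ts.voxel_indices):
            assert np.allclose(ts.data[:, col], data[i, j, k, :])

    def test_non_4d_input_rejected(self):
        img = nib.Nifti1Image(np.zeros((4, 4, 4), dtype=np.float32), np.eye(4))
        with pytest.raises(ValueError, match="4-D"):
            extract_roi_timeseries(img, ROISpec("x", (0, 0, 0), 2.0))

    def test_roi_spec_yaml_loading(self, tmp_path):
        p = tmp_path / "rois.yaml"
        p.write_text(
            "- name: L_ACC\n  seed_mm: [-4.0, 36.0, 12.0]\n  radius_mm: 5\n"
            "- name: R_STG\n  seed_mm: [58.0, -20.0, 2.0]\n"
        )
        specs = load_roi_specs(p)
        assert specs[0] == ROISpec("L_ACC", (-4.0, 36.0, 12.0), 5.0)
        assert specs[1].radius_mm == 5.0  # default radius


def make_series(subject, roi, data):
    return VoxelTimeSeries(
        subject=subject, roi=roi, data=np.asarray(data, float),
        voxel_indices=tuple((0, 0, j) for j in range(data.shape[1])),
    )


class TestFeatureMatrix:
    def test_small_assembly_shape_and_label_column(self, rng):
        n_vol = 10
        per_subject = []
        for s in range(2):
            series = [make_series(f"sub-{s}", "roi1",
                                  rng.standard_normal((n_vol, 3)))]
            labels = TRLabelSeries(tr=1.0, t_start=0.0,
                                   labels=np.full(n_vol, s, dtype=int))
            per_subject.append((series, labels))
        fm = assemble_feature_matrix(per_subject)
        assert fm.shape == (20, 4)
        assert (fm.labels[:10] == 0).all() and (fm.labels[10:] == 1).all()

    def test_values_recoverable_from_row_column_index(self, rng):
        """Assembly is a bijection: (subject, volume, voxel) -> (row, col)."""
        n_vol, n_vox = 7, 4
        data = {s: rng.standard_normal((n_vol, n_vox)) for s in range(3)}
        per_subject = [
            ([make_series(f"sub-{s}", "r", data[s])],
             TRLabelSeries(1.0, 0.0, np.zeros(n_vol, int) + 1))
            for s in range(3)
        ]
        fm = assemble_feature_matrix(per_subject)
        for s in range(3):
            for t in range(n_vol):
                for v in range(n_vox):
                    assert fm.features[s * n_vol + t, v] == data[s][t, v]

    def test_shape_mismatch_names_subject_and_roi(self, rng):
        a = ([make_series("sub-a", "r", rng.standard_normal((5, 3)))],
             TRLabelSeries(1.0, 0.0, np.ones(5, int)))
        b = ([make_series("sub-b", "r", rng.standard_normal((5, 4)))],
             TRLabelSeries(1.0, 0.0, np.ones(5, int)))
        with pytest.raises(ValueError, match="sub-b"):
            assemble_feature_matrix([a, b])

    def test_tsv_round_trip(self, tmp_path, rng):
        series = [make_series("sub-a", "r", rng.standard_normal((6, 2)))]
        fm = assemble_feature_matrix(
            [(series, TRLabelSeries(1.0, 0.0, np.arange(6) % 2))]
        )
        p = tmp_path / "fm.tsv"
        fm.to_tsv(p)
        again = FeatureMatrix.from_tsv(p, subjects=["sub-a"])
        assert np.allclose(again.features, fm.features)
        assert (again.labels == fm.labels).all()

    def test_timeseries_dir_bypass(self, tmp_path, rng):
        import pandas as pd
        data = rng.standard_normal((6, 3))
        pd.DataFrame(data).to_csv(tmp_path / "sub-a_roi1.tsv", sep="\t",
                                  index=False)
        series = load_timeseries_dir(tmp_path, "sub-a", ["roi1"])
        assert np.allclose(series[0].data, data)
        with pytest.raises(FileNotFoundError):
            load_timeseries_dir(tmp_path, "sub-a", ["missing"])
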