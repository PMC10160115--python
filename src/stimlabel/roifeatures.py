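"""Spherical-ROI voxel extraction and feature-matrix assembly.

Regions of interest are spheres of fixed radius (default 5 mm) around MNI
seed coordinates.  A voxel belongs to the sphere when the Euclidean distance
from its *center* (mapped to mm through the image affine) to the seed is at
most the radius, boundary inclusive.  The time series of every voxel in
every ROI, across all subjects, are stacked into the decoding feature
matrix: one row per (subject, volume), one column per voxel plus a trailing
label column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .alignment import TRLabelSeries

#: reference ROI configuration: the six sentiment-network regions with their
#: published per-ROI voxel counts (sums to 111 on the study grid); MNI seed
#: coordinates are study-specific and must be supplied by the user
REFERENCE_ROI_VOXEL_COUNTS = {
    "L_ACC": 19,
    "R_STG": 20,
    "L_cere": 20,
    "L_medFG": 20,
    "R_IFG": 16,
    "L_ch": 16,
}
DEFAULT_RADIUS_MM = 5.0


@dataclass(frozen=True)
class ROISpec:
    """A named sphere: MNI seed in mm and radius in mm."""

    name: str
    seed_mm: tuple[float, float, float]
    radius_mm: float = DEFAULT_RADIUS_MM

    def __post_init__(self) -> None:
        if self.radius_mm < 0:
            raise ValueError(f"ROI {self.name}: radius must be non-negative")


@dataclass(frozen=True)
class VoxelTimeSeries:
    """Per-voxel signal over time for one subject and one ROI."""

    subject: str
    roi: str
    data: np.ndarray  # (n_volumes, n_voxels)
    voxel_indices: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[1] < 1:
            raise ValueError("time-series matrix must be (n_volumes, n_voxels>=1)")
        if np.isnan(self.data).any():
            raise ValueError(
                f"subject {self.subject} ROI {self.roi}: missing values after "
                "extraction"
            )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class FeatureMatrix:
    """Labeled decoding matrix: (subjects × volumes) rows, voxel columns + label."""

    features: np.ndarray  # (n_rows, n_voxels_total)
    labels: np.ndarray    # (n_rows,)
    subjects: tuple[str, ...]
    n_volumes: int
    column_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.features.shape[0] != self.labels.size:
            raise ValueError("feature rows and labels disagree")
        if self.features.shape[0] != len(self.subjects) * self.n_volumes:
            raise ValueError("row count must equal n_subjects * n_volumes")

    @property
    def shape(self) -> tuple[int, int]:
        """Rows × columns including the label column."""
        return (self.features.shape[0], self.features.shape[1] + 1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=list(self.column_names))
        df["label"] = self.labels
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, n_volumes: int | None = None,
                 subjects: Sequence[str] | None = None) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        labels = df.pop("label").to_numpy(dtype=int)
        n_rows = len(df)
        if subjects is None:
            subjects = ("sub-unknown",)
            n_volumes = n_rows
        if n_volumes is None:
            n_volumes = n_rows // len(subjects)
        return cls(
            features=df.to_numpy(dtype=float),
            labels=labels,
            subjects=tuple(subjects),
            n_volumes=n_volumes,
            column_names=tuple(df.columns),
        )


def load_roi_specs(path: str | Path) -> list[ROISpec]:
    """Read ROI specs from YAML: list of {name, seed_mm: [x,y,z], radius_mm}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    specs = []
    for entry in raw:
        specs.append(
            ROISpec(
                name=str(entry["name"]),
                seed_mm=tuple(float(v) for v in entry["seed_mm"]),
                radius_mm=float(entry.get("radius_mm", DEFAULT_RADIUS_MM)),
            )
        )
    return specs


def sphere_voxel_indices(
    shape: Sequence[int],
    affine: np.ndarray,
    seed_mm: Sequence[float],
    radius_mm: float,
) -> list[tuple[int, int, int]]:
    """All grid voxels whose center lies within ``radius_mm`` of the seed.

    The voxel→mm mapping goes through ``affine`` (4×4, invertible); the
    boundary is inclusive.  Raises if the sphere captures no voxel (seed far
    outside the grid or radius smaller than the grid can resolve).
    """
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    seed = np.asarray(seed_mm, dtype=float)
    nx, ny, nz = (int(s) for s in shape[:3])

    # restrict the scan to the bounding box of the sphere in voxel space
    inv = np.linalg.inv(affine)
    seed_vox = inv[:3, :3] @ seed + inv[:3, 3]
    # conservative per-axis half-width: radius over the smallest singular value
    min_scale = np.linalg.svd(affine[:3, :3], compute_uv=False)[-1]
    halfwidth = radius_mm / max(min_scale, 1e-12) + 1.0
    lo = np.maximum(np.floor(seed_vox - halfwidth).astype(int), 0)
    hi = np.minimum(np.ceil(seed_vox + halfwidth).astype(int) + 1, [nx, ny, nz])
    if np.any(lo >= hi):
        raise ValueError(
            f"sphere at {tuple(seed)} mm (r={radius_mm}) lies outside the grid"
        )

    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0]),
        np.arange(lo[1], hi[1]),
        np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    ijk = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1).astype(float)
    mm = ijk @ affine[:3, :3].T + affine[:3, 3]
    dist = np.linalg.norm(mm - seed, axis=1)
    inside = dist <= radius_mm + 1e-9
    if not inside.any():
        raise ValueError(
            f"sphere at {tuple(seed)} mm (r={radius_mm}) contains no voxel "
            "center"
        )
    picked = ijk[inside].astype(int)
    return [tuple(int(v) for v in row) for row in picked]


def extract_roi_timeseries(
    image_4d,
    roi: ROISpec,
    subject: str = "sub-01",
) -> VoxelTimeSeries:
    """Extract every ROI voxel's time series from a 4-D NIfTI image.

    ``image_4d`` may be a nibabel image object or a path to a .nii/.nii.gz
    file.  Column j of the result is the scan-order signal of voxel j.
    """
    import nibabel as nib

    if isinstance(image_4d, (str, Path)):
        image_4d = nib.load(str(image_4d))
    data = np.asanyarray(image_4d.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D image, got {data.ndim}-D")
    voxels = sphere_voxel_indices(
        data.shape[:3], image_4d.affine, roi.seed_mm, roi.radius_mm
    )
    cols = np.stack([data[i, j, k, :] for (i, j, k) in voxels], axis=1)
    return VoxelTimeSeries(
        subject=subject,
        roi=roi.name,
        data=cols.astype(float),
        voxel_indices=tuple(voxels),
    )


def assemble_feature_matrix(
    per_subject: Sequence[tuple[Sequence[VoxelTimeSeries], TRLabelSeries]],
) -> FeatureMatrix:
    """Stack per-subject ROI time series into the labeled decoding matrix.

    Every subject must contribute the same ROIs with identical voxel counts
    and the same number of volumes; subjects are stacked vertically in input
    order, ROI columns concatenated in the declared ROI order, and the final
    column holds the per-volume class labels.
    """
    if not per_subject:
        raise ValueError("no subjects supplied")
    ref_rois, ref_series = per_subject[0]
    ref_counts = [(ts.roi, ts.n_voxels) for ts in ref_rois]
    n_volumes = ref_series.n_volumes

    blocks, label_blocks, subjects = [], [], []
    for s_idx, (roi_series, tr_labels) in enumerate(per_subject):
        subject = roi_series[0].subject if roi_series else f"sub-{s_idx:02d}"
        counts = [(ts.roi, ts.n_voxels) for ts in roi_series]
        if counts != ref_counts:
            raise ValueError(
                f"subject {subject}: ROI layout {counts} differs from "
                f"reference {ref_counts}"
            )
        for ts in roi_series:
            if ts.n_volumes != n_volumes:
                raise ValueError(
                    f"subject {subject} ROI {ts.roi}: {ts.n_volumes} volumes, "
                    f"expected {n_volumes}"
                )
        if tr_labels.n_volumes != n_volumes:
            raise ValueError(
                f"subject {subject}: {tr_labels.n_volumes} labels for "
                f"{n_volumes} volumes"
            )
        blocks.append(np.concatenate([ts.data for ts in roi_series], axis=1))
        label_blocks.append(tr_labels.labels)
        subjects.append(subject)

    column_names = tuple(
        f"{ts.roi}_v{j}" for ts in ref_rois for j in range(ts.n_voxels)
    )
    return FeatureMatrix(
        features=np.vstack(blocks),
        labels=np.concatenate(label_blocks),
        subjects=tuple(subjects),
        n_volumes=n_volumes,
        column_names=column_names,
    )


def load_timeseries_dir(
    directory: str | Path,
    subject: str,
    roi_names: Sequence[str],
) -> list[VoxelTimeSeries]:
    """TSV bypass: read pre-extracted per-ROI matrices ``<subject>_<roi>.tsv``.

    Each file holds one column per voxel, one row per volume, with a header.
    Lets the decoding half of the pipeline run without any NIfTI input.
    """
    directory = Path(directory)
    series = []
    for roi in roi_names:
        path = directory / f"{subject}_{roi}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"missing time-series table {path}")
        df = pd.read_csv(path, sep="\t")
        series.append(
            VoxelTimeSeries(
                subject=subject,
                roi=roi,
                data=df.to_numpy(dtype=float),
                voxel_indices=tuple((0, 0, j) for j in range(df.shape[1])),
            )
        )
    return series
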