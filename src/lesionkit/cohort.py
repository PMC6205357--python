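"""Lesion-cohort containers and voxel-level preprocessing.

A cohort is a set of binary 3D lesion masks, one per participant, all living
in a single common volume geometry, together with a behavioral score table.
This module provides the operations every lesion-symptom mapping (LSM) stage
builds on:

* geometry-checked NIfTI I/O (:func:`load_cohort`),
* the analysis mask restricting statistics to voxels lesioned in at least a
  minimum fraction of participants (:func:`build_analysis_mask`),
* direct total lesion volume control (dTLVC), which rescales each lesioned
  voxel of participant *i* to ``1/sqrt(V_i)`` where ``V_i`` is that
  participant's whole-lesion voxel count (:func:`dtlvc_normalize`),
* lesion frequency (overlap) maps and parcellation overlap summaries.

Voxels are addressed by flat C-order indices into the volume; the NIfTI
affine carries the voxel-to-world mapping.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "VolumeGeometry",
    "LesionMask",
    "LesionCohort",
    "AnalysisMask",
    "NormalizedLesionMatrix",
    "Template",
    "load_cohort",
    "build_analysis_mask",
    "dtlvc_normalize",
    "lesion_frequency_map",
    "region_overlap_summary",
]


@dataclass(frozen=True)
class VolumeGeometry:
    """Common 3D sampling grid shared by every volume in an analysis.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis, all >= 1.
    affine : ndarray, shape (4, 4)
        Voxel-index to world (mm) affine map.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(d) for d in self.shape)
        object.__setattr__(self, "shape", shape)
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "affine", aff)
        if len(shape) != 3 or any(d < 1 for d in shape):
            raise ValueError(f"invalid volume shape {shape}")
        if self.voxel_volume_mm3 <= 0:
            raise ValueError("voxel volume must be strictly positive")

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (per axis)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def matches(self, other: "VolumeGeometry", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass(frozen=True)
class LesionMask:
    """One participant's binary lesion map on a :class:`VolumeGeometry`."""

    participant_id: str
    data: np.ndarray  # boolean, 3D

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.dtype != bool:
            uniq = np.unique(data)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError(
                    f"mask for {self.participant_id!r} is not binary "
                    f"(values {uniq[:5]}...)"
                )
            data = data.astype(bool)
        if data.ndim != 3:
            raise ValueError("lesion mask must be 3D")
        if not data.any():
            raise ValueError(
                f"mask for {self.participant_id!r} has no lesioned voxels"
            )
        object.__setattr__(self, "data", data)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def flat_indices(self) -> np.ndarray:
        """Sorted flat (C-order) indices of lesioned voxels."""
        return np.flatnonzero(self.data.ravel())


@dataclass
class LesionCohort:
    """Aligned lesion masks + lesion sizes + behavioral table.

    ``masks``, ``sizes_cc`` and the rows of ``behavior`` share one ordering.
    """

    geometry: VolumeGeometry
    masks: list[LesionMask]
    behavior: pd.DataFrame
    sizes_cc: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.masks) == 0:
            raise ValueError("cohort must contain at least one participant")
        if len(self.behavior) != len(self.masks):
            raise ValueError(
                f"behavior table has {len(self.behavior)} rows for "
                f"{len(self.masks)} masks"
            )
        for m in self.masks:
            if m.data.shape != self.geometry.shape:
                raise ValueError(
                    f"mask {m.participant_id!r} shape {m.data.shape} does not "
                    f"match cohort geometry {self.geometry.shape}"
                )
        if self.sizes_cc is None:
            vol = self.geometry.voxel_volume_mm3 / 1000.0
            self.sizes_cc = np.array([m.n_voxels * vol for m in self.masks])
        self.sizes_cc = np.asarray(self.sizes_cc, dtype=float)
        if (self.sizes_cc <= 0).any():
            raise ValueError("all lesion sizes must be positive")

    def __len__(self) -> int:
        return len(self.masks)

    @property
    def participant_ids(self) -> list[str]:
        return [m.participant_id for m in self.masks]

    def sizes_voxels(self) -> np.ndarray:
        """Whole-lesion voxel counts per participant."""
        return np.array([m.n_voxels for m in self.masks], dtype=float)

    def stacked(self) -> np.ndarray:
        """Participants x n_voxels boolean matrix (flattened masks)."""
        return np.stack([m.data.ravel() for m in self.masks])

    def subset(self, idx: np.ndarray) -> "LesionCohort":
        """Sub-cohort by positional index (e.g. a training fold)."""
        idx = np.asarray(idx)
        return LesionCohort(
            geometry=self.geometry,
            masks=[self.masks[i] for i in idx],
            behavior=self.behavior.iloc[idx].reset_index(drop=True),
            sizes_cc=self.sizes_cc[idx],
        )


@dataclass(frozen=True)
class AnalysisMask:
    """Voxels eligible for statistics: lesioned in >= min_frequency of cohort.

    ``voxel_index`` holds sorted, unique flat indices into the geometry.
    """

    geometry: VolumeGeometry
    voxel_index: np.ndarray
    min_frequency: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.voxel_index, dtype=np.int64)
        if idx.size and not (np.diff(idx) > 0).all():
            idx = np.unique(idx)
        object.__setattr__(self, "voxel_index", idx)

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_index.size)

    def to_volume(self) -> np.ndarray:
        vol = np.zeros(self.geometry.n_voxels, dtype=bool)
        vol[self.voxel_index] = True
        return vol.reshape(self.geometry.shape)


@dataclass(frozen=True)
class NormalizedLesionMatrix:
    """dTLVC-scaled participants x in-mask-voxels design matrix.

    Entry ``(i, j)`` is 0 for an intact voxel and ``1/sqrt(V_i)`` for a
    lesioned one, where ``V_i`` is participant *i*'s whole-lesion voxel
    count.  Larger lesions therefore carry smaller per-voxel values.
    """

    values: np.ndarray
    source_mask: AnalysisMask

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class Template:
    """Thresholded binary critical-region volume (flat in-mask voxel indices)."""

    geometry: VolumeGeometry
    voxels: np.ndarray  # sorted flat indices
    provenance: str = ""

    def __post_init__(self) -> None:
        vox = np.unique(np.asarray(self.voxels, dtype=np.int64))
        object.__setattr__(self, "voxels", vox)

    @property
    def size(self) -> int:
        return int(self.voxels.size)

    def to_volume(self) -> np.ndarray:
        vol = np.zeros(self.geometry.n_voxels, dtype=bool)
        vol[self.voxels] = True
        return vol.reshape(self.geometry.shape)

    def save(self, path) -> None:
        img = nib.Nifti1Image(
            self.to_volume().astype(np.uint8), self.geometry.affine
        )
        nib.save(img, str(path))


# ---------------------------------------------------------------------------
# operations


def load_cohort(mask_paths, behavior_path) -> LesionCohort:
    """Read binary NIfTI lesion masks + a CSV behavior table into a cohort.

    The behavior CSV must have a header row with the participant identifier
    in the first column and one row per mask, in mask order.  All masks must
    share a single geometry bit-for-bit; non-binary masks are rejected rather
    than silently thresholded.
    """
    behavior = pd.read_csv(behavior_path)
    if len(mask_paths) != len(behavior):
        raise ValueError(
            f"{len(mask_paths)} masks but {len(behavior)} behavior rows"
        )
    ids = behavior.iloc[:, 0].astype(str).tolist()
    geometry = None
    masks = []
    for pid, path in zip(ids, mask_paths):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        geo = VolumeGeometry(shape=data.shape, affine=img.affine)
        if geometry is None:
            geometry = geo
        elif not geometry.matches(geo):
            raise ValueError(
                f"geometry mismatch in {path}: shape {geo.shape} vs "
                f"{geometry.shape} (or differing affine)"
            )
        try:
            masks.append(LesionMask(participant_id=pid, data=data))
        except ValueError as err:
            raise ValueError(f"{path}: {err}") from err
    return LesionCohort(
        geometry=geometry, masks=masks, behavior=behavior.iloc[:, 1:]
    )


def build_analysis_mask(
    cohort: LesionCohort, min_frequency: float = 0.10
) -> AnalysisMask:
    """Voxels lesioned in at least ``min_frequency`` of participants.

    A voxel enters the mask iff ``count / n >= min_frequency``; a 10%
    threshold on 128 participants therefore requires 13 lesions (12/128 =
    9.4% is excluded).
    """
    if not 0 < min_frequency <= 1:
        raise ValueError("min_frequency must be in (0, 1]")
    counts = np.zeros(cohort.geometry.n_voxels, dtype=np.int64)
    for m in cohort.masks:
        counts[m.flat_indices()] += 1
    n = len(cohort)
    # compare counts to the integer ceiling to dodge float-division edge cases
    idx = np.flatnonzero(counts >= min_frequency * n - 1e-9)
    idx = idx[counts[idx] / n >= min_frequency - 1e-12]
    if idx.size == 0:
        raise ValueError(
            f"no voxels meet frequency threshold {min_frequency:g} "
            f"in a cohort of {n}"
        )
    return AnalysisMask(
        geometry=cohort.geometry, voxel_index=idx, min_frequency=min_frequency
    )


def dtlvc_normalize(
    cohort: LesionCohort, mask: AnalysisMask
) -> NormalizedLesionMatrix:
    """Direct total lesion volume control of the lesion matrix.

    Each lesioned in-mask voxel of participant *i* takes the value
    ``1/sqrt(V_i)`` with ``V_i`` the participant's total lesioned-voxel
    count over the whole brain (not restricted to the analysis mask), so
    voxels from smaller lesions are weighted more.
    """
    if mask.geometry.shape != cohort.geometry.shape:
        raise ValueError("mask geometry does not match cohort")
    volumes = cohort.sizes_voxels()
    stacked = cohort.stacked()[:, mask.voxel_index]
    values = stacked.astype(float) * (1.0 / np.sqrt(volumes))[:, None]
    return NormalizedLesionMatrix(values=values, source_mask=mask)


def lesion_frequency_map(cohort: LesionCohort) -> np.ndarray:
    """Per-voxel fraction of participants lesioned there (the overlap map)."""
    acc = np.zeros(cohort.geometry.shape, dtype=float)
    for m in cohort.masks:
        acc += m.data
    return acc / len(cohort)


def region_overlap_summary(
    template: Template,
    parcellation: np.ndarray,
    denominator: str = "region",
) -> pd.DataFrame:
    """Percent overlap between a template and each parcellation region.

    Parameters
    ----------
    template : Template
    parcellation : ndarray of int
        Integer-labelled region volume on the template's geometry; 0 is
        background.
    denominator : {"region", "template"}
        Whether percentages are of each region's volume (default) or of the
        template's volume.

    Returns
    -------
    DataFrame with columns ``region_id``, ``percent`` sorted by region id;
    regions with zero overlap are omitted.
    """
    parc = np.asarray(parcellation)
    if parc.shape != template.geometry.shape:
        raise ValueError("parcellation geometry does not match template")
    if not (parc != 0).any():
        raise ValueError("parcellation contains no labelled regions")
    if denominator not in ("region", "template"):
        raise ValueError("denominator must be 'region' or 'template'")
    flat = parc.ravel()
    rows = []
    for rid in np.unique(flat[flat != 0]):
        region_idx = np.flatnonzero(flat == rid)
        inter = np.intersect1d(
            template.voxels, region_idx, assume_unique=True
        ).size
        if inter == 0:
            continue
        denom = region_idx.size if denominator == "region" else template.size
        rows.append({"region_id": int(rid), "percent": 100.0 * inter / denom})
    return pd.DataFrame(rows, columns=["region_id", "percent"])


def save_volume(data: np.ndarray, geometry: VolumeGeometry, path) -> None:
    """Write a volume (float or binary) as NIfTI in the cohort geometry."""
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, geometry.affine), str(path))
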