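"""Region-of-interest quantification for paired-scan differential PET.

Volumes are normalized to the mean uptake inside the brain mask of each
scan ("SUV" in this pipeline means mean-normalized uptake, not
dose/body-weight-scaled uptake).  Region masks are organized as one
object per (region, coronal slice, hemisphere); prefrontal-style regions
are kept as a single object per slice spanning both hemispheres.  The
two sessions are differenced object-wise into delta-SUV = SUV_post -
SUV_pre.

Axis convention: x = left-right, y = anterior-posterior (coronal slice
axis), z = dorsal-ventral.  Hemispheres are split at a midline plane at
the grid's x-center by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from deltapet.errors import InputError, MaskError, NormalizationError, PairingError

__all__ = [
    "VolumeImage",
    "MaskObject",
    "RegionMaskSet",
    "SUV_COLUMNS",
    "DELTA_COLUMNS",
    "normalize_to_brain_mean",
    "extract_suvs",
    "compute_delta_suv",
    "region_group_mean",
    "subject_region_mean",
]

#: Column schema of the SUV record table returned by :func:`extract_suvs`.
SUV_COLUMNS = ["subject_id", "group", "session", "region", "slice_index",
               "bregma_mm", "hemisphere", "suv"]

#: Column schema of the delta-SUV table returned by :func:`compute_delta_suv`.
DELTA_COLUMNS = ["subject_id", "group", "region", "slice_index", "hemisphere",
                 "suv_f1", "suv_f3", "delta_suv"]

_OBJECT_KEY = ["subject_id", "region", "slice_index", "hemisphere"]


@dataclass(frozen=True)
class VolumeImage:
    """A 3D scalar grid with voxel spacing and slice metadata.

    ``bregma_origin_mm`` is the distance from bregma (mm, positive =
    anterior) of coronal slice index 0; slice ``j`` maps to
    ``bregma_origin_mm - j * voxel_size_mm[1]``.
    """

    voxels: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (0.78, 0.78, 0.8)
    subject_id: str | None = None
    session: str | None = None
    bregma_origin_mm: float = 0.0

    def __post_init__(self) -> None:
        voxels = np.asarray(self.voxels, dtype=float)
        object.__setattr__(self, "voxels", voxels)
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))
        if voxels.ndim != 3:
            raise InputError(f"expected a 3D volume, got shape {voxels.shape}")
        if not np.all(np.isfinite(voxels)):
            raise InputError("voxel values must be finite")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise InputError("voxel_size_mm components must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def bregma_mm(self, slice_index: int) -> float:
        return self.bregma_origin_mm - slice_index * self.voxel_size_mm[1]

    def affine(self) -> np.ndarray:
        return np.diag([*self.voxel_size_mm, 1.0])

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.voxels.astype(np.float32), self.affine())

    @classmethod
    def from_nifti(cls, path, subject_id=None, session=None,
                   bregma_origin_mm: float = 0.0) -> "VolumeImage":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        return cls(voxels=np.asanyarray(img.dataobj, dtype=float),
                   voxel_size_mm=tuple(float(z) for z in zooms),
                   subject_id=subject_id, session=session,
                   bregma_origin_mm=bregma_origin_mm)


@dataclass(frozen=True)
class MaskObject:
    """One quantification unit: a 2D mask on a single coronal slice."""

    region: str
    slice_index: int
    hemisphere: str  # "L", "R" or "BOTH"
    mask: np.ndarray  # boolean, shape (nx, nz)

    def __post_init__(self) -> None:
        if self.hemisphere not in ("L", "R", "BOTH"):
            raise MaskError(f"bad hemisphere {self.hemisphere!r}")
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.region, self.slice_index, self.hemisphere)


@dataclass
class RegionMaskSet:
    """Brain mask plus named per-slice/per-hemisphere region objects."""

    brain_mask: np.ndarray
    objects: list[MaskObject] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        seen = set()
        for obj in self.objects:
            if obj.key in seen:
                raise MaskError(f"duplicate mask object {obj.key}")
            seen.add(obj.key)
            inside = self.brain_mask[:, obj.slice_index, :]
            if np.any(obj.mask & ~inside):
                raise MaskError(
                    f"region {obj.region} slice {obj.slice_index} extends outside the brain mask")

    @property
    def regions(self) -> list[str]:
        return sorted({o.region for o in self.objects})

    def objects_for(self, region: str) -> list[MaskObject]:
        return [o for o in self.objects if o.region == region]

    @classmethod
    def from_label_volume(cls, labels: np.ndarray, names: dict[int, str],
                          brain_mask: np.ndarray | None = None,
                          midline_x: int | None = None,
                          single_object_regions: tuple[str, ...] = ()) -> "RegionMaskSet":
        """Build objects from a label volume (one integer region id per voxel).

        Hemispheres are inferred by splitting each slice at ``midline_x``
        (default: grid x-center); regions listed in
        ``single_object_regions`` become one BOTH object per slice.
        """
        labels = np.asarray(labels)
        if brain_mask is None:
            brain_mask = labels > 0
        nx = labels.shape[0]
        if midline_x is None:
            midline_x = nx // 2
        objects: list[MaskObject] = []
        for label_id, region in sorted(names.items()):
            region_vox = labels == label_id
            for j in np.flatnonzero(region_vox.any(axis=(0, 2))):
                plane = region_vox[:, j, :]
                if region in single_object_regions:
                    objects.append(MaskObject(region, int(j), "BOTH", plane))
                    continue
                left = plane.copy()
                left[midline_x:, :] = False
                right = plane.copy()
                right[:midline_x, :] = False
                if left.any():
                    objects.append(MaskObject(region, int(j), "L", left))
                if right.any():
                    objects.append(MaskObject(region, int(j), "R", right))
        return cls(brain_mask=brain_mask, objects=objects)

    def to_label_volume(self) -> tuple[np.ndarray, dict[int, str]]:
        labels = np.zeros(self.brain_mask.shape, dtype=np.int16)
        names: dict[int, str] = {}
        for i, region in enumerate(self.regions, start=1):
            names[i] = region
            for obj in self.objects_for(region):
                labels[:, obj.slice_index, :][obj.mask] = i
        return labels, names


def normalize_to_brain_mean(vol: VolumeImage, brain_mask: np.ndarray) -> VolumeImage:
    """Divide in-mask voxels by the in-mask mean; zero elsewhere.

    The resulting in-mask mean is 1 to within 1e-10.  Raises
    :class:`NormalizationError` if the in-mask mean is not positive.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != vol.shape:
        raise InputError("brain mask grid does not match volume grid")
    if not brain_mask.any():
        raise NormalizationError("brain mask is empty")
    mean = float(vol.voxels[brain_mask].mean())
    if mean <= 0:
        raise NormalizationError(f"in-mask mean must be > 0, got {mean}")
    out = np.zeros_like(vol.voxels)
    out[brain_mask] = vol.voxels[brain_mask] / mean
    return VolumeImage(voxels=out, voxel_size_mm=vol.voxel_size_mm,
                       subject_id=vol.subject_id, session=vol.session,
                       bregma_origin_mm=vol.bregma_origin_mm)


def extract_suvs(vol: VolumeImage, masks: RegionMaskSet,
                 group: str | None = None) -> pd.DataFrame:
    """Mean normalized uptake per (region, slice, hemisphere) object.

    Returns one row per mask object with columns :data:`SUV_COLUMNS`.
    The volume is expected to be normalized already (see
    :func:`normalize_to_brain_mean`).
    """
    if masks.brain_mask.shape != vol.shape:
        raise InputError("mask set grid does not match volume grid")
    rows = []
    for obj in masks.objects:
        if not obj.mask.any():
            raise MaskError(f"empty mask: region {obj.region}, slice {obj.slice_index}, "
                            f"hemisphere {obj.hemisphere}")
        plane = vol.voxels[:, obj.slice_index, :]
        rows.append({
            "subject_id": vol.subject_id,
            "group": group,
            "session": vol.session,
            "region": obj.region,
            "slice_index": obj.slice_index,
            "bregma_mm": vol.bregma_mm(obj.slice_index),
            "hemisphere": obj.hemisphere,
            "suv": float(plane[obj.mask].mean()),
        })
    return pd.DataFrame(rows, columns=SUV_COLUMNS)


def compute_delta_suv(f1: pd.DataFrame, f3: pd.DataFrame) -> pd.DataFrame:
    """Object-wise difference table: delta_suv = suv_f3 - suv_f1.

    Rows are matched on (subject, region, slice, hemisphere); any record
    lacking a counterpart in the other session raises
    :class:`PairingError` listing the offending keys.
    """
    merged = pd.merge(
        f1.rename(columns={"suv": "suv_f1"}),
        f3.rename(columns={"suv": "suv_f3"})[_OBJECT_KEY + ["suv_f3"]],
        on=_OBJECT_KEY, how="outer", indicator=True, validate="one_to_one")
    unmatched = merged[merged["_merge"] != "both"]
    if len(unmatched):
        keys = unmatched[_OBJECT_KEY + ["_merge"]].to_dict("records")
        raise PairingError(f"unmatched session records: {keys}")
    out = merged[["subject_id", "group", "region", "slice_index", "hemisphere",
                  "suv_f1", "suv_f3"]].copy()
    out["delta_suv"] = out["suv_f3"] - out["suv_f1"]
    return out.sort_values(_OBJECT_KEY, ignore_index=True)


def region_group_mean(table: pd.DataFrame, region: str, group: str,
                      voxel_weighted: bool = False,
                      voxel_counts: pd.Series | None = None) -> float:
    """Mean delta-SUV over all rows of one region and group.

    Slices and hemispheres are pooled unweighted by default (each mask
    object contributes one row); pass ``voxel_weighted=True`` together
    with per-row ``voxel_counts`` for a voxel-count-weighted mean.
    """
    sub = table[(table["region"] == region) & (table["group"] == group)]
    if sub.empty:
        raise InputError(f"no rows for region {region!r}, group {group!r}")
    if voxel_weighted:
        if voxel_counts is None:
            raise InputError("voxel_weighted=True requires voxel_counts")
        w = voxel_counts.loc[sub.index].to_numpy(dtype=float)
        return float(np.average(sub["delta_suv"], weights=w))
    return float(sub["delta_suv"].mean())


def subject_region_mean(table: pd.DataFrame, region: str) -> pd.Series:
    """Per-subject mean delta-SUV in one region (classifier feature source)."""
    sub = table[table["region"] == region]
    if sub.empty:
        raise InputError(f"no rows for region {region!r}")
    return sub.groupby("subject_id")["delta_suv"].mean()
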