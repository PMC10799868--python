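"""Core data containers for masked voxel-level activation maps.

Every downstream stage (harmonization, classification, bootstrap signature
mapping) operates on vectors of in-mask voxel values.  This module defines the
brain-mask geometry, the per-map record, the map collection, and the NIfTI
plumbing that converts between 3D volumes and mask-aligned vectors.

Voxel scan order is C-order over the mask grid (last axis fastest): the vector
returned by :func:`apply_mask` is ``volume[mask.inside]`` with ``inside`` a
boolean array, which numpy flattens in C-order.  The order is deterministic
and identical across reads of the same mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

#: Fixed encoding of the three task conditions used everywhere in the package.
CLASS_LABELS: tuple[str, str, str] = ("neutral", "negative", "decrease")
CLASS_TO_INDEX: dict[str, int] = {c: i for i, c in enumerate(CLASS_LABELS)}

#: Tolerance on per-entry affine agreement between a map and the mask.
AFFINE_ATOL = 1e-4


class DimensionError(ValueError):
    """Shape, affine, or vector-length mismatch against the mask."""


class DuplicateRecordError(ValueError):
    """Two maps share the same (subject_id, class_label)."""


class LabelError(ValueError):
    """A class label outside the three-condition set."""


@dataclass(frozen=True)
class BrainMask:
    """Binary analysis mask with voxel geometry.

    Parameters
    ----------
    inside : ndarray of bool, 3D
        True at in-mask voxels.
    affine : (4, 4) ndarray
        Voxel-to-world (mm) transform.
    """

    inside: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        inside = np.asarray(self.inside, dtype=bool)
        affine = np.asarray(self.affine, dtype=float)
        if inside.ndim != 3:
            raise DimensionError(f"mask grid must be 3D, got shape {inside.shape}")
        if affine.shape != (4, 4):
            raise DimensionError("affine must be 4x4")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("mask affine is singular")
        object.__setattr__(self, "inside", inside)
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.inside.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.inside.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        """Product of voxel edge lengths in mm (3-mm isotropic -> 27)."""
        edges = np.linalg.norm(self.affine[:3, :3], axis=0)
        return float(np.prod(edges))

    def voxel_coords(self) -> np.ndarray:
        """(n_voxels, 3) integer grid coordinates of in-mask voxels, scan order."""
        return np.argwhere(self.inside)

    def world_coords(self) -> np.ndarray:
        """(n_voxels, 3) world-space (mm) coordinates via the affine."""
        ijk = self.voxel_coords()
        ijk1 = np.c_[ijk, np.ones(len(ijk))]
        return (ijk1 @ self.affine.T)[:, :3]

    @classmethod
    def from_nifti(cls, path: str | Path) -> "BrainMask":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        return cls(inside=data > 0, affine=np.asarray(img.affine))


def apply_mask(volume: np.ndarray, mask: BrainMask) -> np.ndarray:
    """Extract in-mask values from a 3D volume in mask scan order."""
    volume = np.asarray(volume)
    if volume.shape != mask.shape:
        raise DimensionError(
            f"volume shape {volume.shape} does not match mask shape {mask.shape}"
        )
    return volume[mask.inside].astype(float, copy=False)


def unmask(
    values: np.ndarray, mask: BrainMask, background: float = 0.0
) -> np.ndarray:
    """Scatter a mask-aligned vector back onto the 3D grid.

    Out-of-mask voxels are set to ``background`` (0 by default; pass
    ``np.nan`` for visualization output).  Round-trip identity:
    ``apply_mask(unmask(v, m), m) == v`` exactly.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (mask.n_voxels,):
        raise DimensionError(
            f"vector length {values.shape} does not match mask n_voxels "
            f"{mask.n_voxels}"
        )
    grid = np.full(mask.shape, background, dtype=float)
    grid[mask.inside] = values
    return grid


def write_signature_nifti(
    values: np.ndarray,
    mask: BrainMask,
    path: str | Path,
    background: float = 0.0,
) -> Path:
    """Write a mask-aligned vector as a NIfTI volume carrying the mask affine."""
    grid = unmask(values, mask, background=background)
    img = nib.Nifti1Image(grid.astype(np.float64), mask.affine)
    path = Path(path)
    nib.save(img, str(path))
    return path


@dataclass(frozen=True)
class BetaMap:
    """One subject x condition activation map, vectorized against a mask."""

    subject_id: str
    class_label: str
    site_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_TO_INDEX:
            raise LabelError(
                f"unknown class label {self.class_label!r}; "
                f"expected one of {CLASS_LABELS}"
            )
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float).ravel()
        )


@dataclass
class BetaMapSet:
    """An ordered collection of beta maps sharing one brain mask.

    Invariants enforced at construction: all value vectors match the mask
    voxel count; at most one map per (subject_id, class_label).
    """

    mask: BrainMask
    maps: list[BetaMap] = field(default_factory=list)
    class_encoding: tuple[str, ...] = CLASS_LABELS

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for m in self.maps:
            if m.values.shape != (self.mask.n_voxels,):
                raise DimensionError(
                    f"map ({m.subject_id}, {m.class_label}) has "
                    f"{m.values.shape[0]} values, mask has {self.mask.n_voxels}"
                )
            key = (m.subject_id, m.class_label)
            if key in seen:
                raise DuplicateRecordError(
                    f"duplicate map for subject {m.subject_id!r}, "
                    f"class {m.class_label!r}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.maps)

    def __iter__(self):
        return iter(self.maps)

    @property
    def subjects(self) -> list[str]:
        """Unique subject ids in first-appearance order."""
        out: list[str] = []
        seen: set[str] = set()
        for m in self.maps:
            if m.subject_id not in seen:
                seen.add(m.subject_id)
                out.append(m.subject_id)
        return out

    @property
    def sites(self) -> list[str]:
        out: list[str] = []
        seen: set[str] = set()
        for m in self.maps:
            if m.site_id not in seen:
                seen.add(m.site_id)
                out.append(m.site_id)
        return out

    def values_matrix(self) -> np.ndarray:
        """(n_maps, n_voxels) stacked value matrix in map order."""
        if not self.maps:
            return np.empty((0, self.mask.n_voxels))
        return np.vstack([m.values for m in self.maps])

    def labels(self) -> np.ndarray:
        """Integer class labels per map using the fixed encoding."""
        return np.array([CLASS_TO_INDEX[m.class_label] for m in self.maps])

    def label_names(self) -> list[str]:
        return [m.class_label for m in self.maps]

    def subject_ids(self) -> np.ndarray:
        return np.array([m.subject_id for m in self.maps])

    def site_ids(self) -> np.ndarray:
        return np.array([m.site_id for m in self.maps])

    def with_values(self, matrix: np.ndarray) -> "BetaMapSet":
        """Copy of the set with replaced value matrix, annotations preserved."""
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (len(self.maps), self.mask.n_voxels):
            raise DimensionError(
                f"matrix shape {matrix.shape} does not match "
                f"({len(self.maps)}, {self.mask.n_voxels})"
            )
        new_maps = [
            BetaMap(m.subject_id, m.class_label, m.site_id, matrix[i])
            for i, m in enumerate(self.maps)
        ]
        return BetaMapSet(self.mask, new_maps, self.class_encoding)

    def subset(self, indices: Sequence[int] | np.ndarray) -> "BetaMapSet":
        return BetaMapSet(
            self.mask, [self.maps[int(i)] for i in indices], self.class_encoding
        )

    def select_class(self, class_label: str) -> "BetaMapSet":
        if class_label not in CLASS_TO_INDEX:
            raise LabelError(f"unknown class label {class_label!r}")
        return BetaMapSet(
            self.mask,
            [m for m in self.maps if m.class_label == class_label],
            self.class_encoding,
        )

    def select_subjects(self, subject_ids: Iterable[str]) -> "BetaMapSet":
        wanted = set(subject_ids)
        return BetaMapSet(
            self.mask,
            [m for m in self.maps if m.subject_id in wanted],
            self.class_encoding,
        )


def read_beta_maps(
    paths: Sequence[str | Path],
    annotations: pd.DataFrame | Sequence[dict],
    mask: BrainMask | str | Path,
) -> BetaMapSet:
    """Load NIfTI beta maps into a :class:`BetaMapSet`.

    Parameters
    ----------
    paths
        NIfTI files, one volume each, on the mask grid.
    annotations
        Per-file records with columns/keys ``subject_id``, ``class_label``,
        ``site_id``, aligned with ``paths``.
    mask
        A :class:`BrainMask` or path to a binary mask NIfTI.
    """
    if not isinstance(mask, BrainMask):
        mask = BrainMask.from_nifti(mask)
    ann = pd.DataFrame(annotations).reset_index(drop=True)
    if len(ann) != len(paths):
        raise ValueError(
            f"{len(paths)} paths but {len(ann)} annotation records"
        )
    maps: list[BetaMap] = []
    for i, p in enumerate(paths):
        img = nib.load(str(p))
        data = np.asanyarray(img.dataobj)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        if data.shape != mask.shape:
            raise DimensionError(
                f"{p}: volume shape {data.shape} != mask shape {mask.shape}"
            )
        if not np.allclose(img.affine, mask.affine, atol=AFFINE_ATOL, rtol=0):
            raise DimensionError(f"{p}: affine disagrees with mask affine")
        row = ann.iloc[i]
        maps.append(
            BetaMap(
                subject_id=str(row["subject_id"]),
                class_label=str(row["class_label"]),
                site_id=str(row["site_id"]),
                values=apply_mask(data, mask),
            )
        )
    return BetaMapSet(mask=mask, maps=maps)


def read_manifest(
    manifest_csv: str | Path, mask: BrainMask | str | Path
) -> BetaMapSet:
    """Load maps listed in a CSV manifest (columns: path, subject_id,
    class_label, site_id).  Relative paths resolve against the manifest dir."""
    manifest_csv = Path(manifest_csv)
    df = pd.read_csv(manifest_csv)
    required = {"path", "subject_id", "class_label", "site_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    paths = [
        p if Path(p).is_absolute() else manifest_csv.parent / p
        for p in df["path"]
    ]
    return read_beta_maps(paths, df[["subject_id", "class_label", "site_id"]], mask)


def write_beta_maps(
    data: BetaMapSet, out_dir: str | Path, prefix: str = "beta"
) -> Path:
    """Write a BetaMapSet as NIfTI volumes plus a CSV manifest; returns the
    manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for m in data:
        fname = f"{prefix}_{m.subject_id}_{m.class_label}.nii.gz"
        write_signature_nifti(m.values, data.mask, out_dir / fname)
        rows.append(
            {
                "path": fname,
                "subject_id": m.subject_id,
                "class_label": m.class_label,
                "site_id": m.site_id,
            }
        )
    mask_img = nib.Nifti1Image(
        data.mask.inside.astype(np.uint8), data.mask.affine
    )
    nib.save(mask_img, str(out_dir / "mask.nii.gz"))
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
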