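"""Core data containers and ingestion for the scoring pipeline.

The pipeline operates on co-registered 3D intensity volumes (one per
candidate sequence per subject) and binary structure masks drawn by one or
more observers on the same voxel lattice.  Everything downstream — SNR/CNR,
conspicuity, pairwise agreement, the statistics gate and the rubric — works
on the types defined here.

Conventions: voxel indices are 0-based; the third array axis holds axial
slices (the plane structures are segmented in); all physical distances are
computed with the per-axis voxel spacing in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

#: Recognised structure labels.  ``fat`` and ``noise`` are reference
#: segmentations (subcutaneous fat, air-filled cavity), not scored anatomy.
STRUCTURE_LABELS = frozenset(
    {
        "GTV",
        "lymph_nodes",
        "parotid_L",
        "parotid_R",
        "pterygoid_L",
        "pterygoid_R",
        "fat",
        "noise",
    }
)


class LoadError(RuntimeError):
    """Raised when a volume or mask file cannot be ingested."""


class GridMismatchError(ValueError):
    """Raised when a mask does not share its volume's voxel lattice."""


@dataclass
class VolumeImage:
    """A 3D scalar intensity grid for one (subject, sequence).

    Parameters
    ----------
    intensities
        3D array of signal intensities (arbitrary units).
    spacing_mm
        Per-axis voxel size in millimetres, all components positive.
    sequence_id, subject_id
        Identity tags used throughout pooling and reporting.
    """

    intensities: np.ndarray
    spacing_mm: tuple[float, float, float]
    sequence_id: str
    subject_id: str

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"intensities must be 3D, got {self.intensities.ndim}D"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain non-finite values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"invalid voxel spacing {self.spacing_mm!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class StructureMask:
    """A binary mask on the lattice of a :class:`VolumeImage`."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    structure_label: str
    observer_id: str
    subject_id: str
    sequence_id: str

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels) != 0
        if self.voxels.ndim != 3:
            raise ValueError(f"mask must be 3D, got {self.voxels.ndim}D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if self.structure_label not in STRUCTURE_LABELS:
            raise ValueError(f"unknown structure label {self.structure_label!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def is_empty(self) -> bool:
        return not self.voxels.any()

    def require_nonempty(self, context: str = "metric input") -> None:
        if self.is_empty:
            raise ValueError(
                f"empty mask ({self.structure_label}, observer "
                f"{self.observer_id}) used as {context}"
            )

    def matches_grid(self, volume: VolumeImage) -> bool:
        return (
            self.voxels.shape == volume.shape
            and np.allclose(self.spacing_mm, volume.spacing_mm)
        )


@dataclass
class SequenceStructurePair:
    """One structure as segmented on one sequence, all observers' masks."""

    sequence_id: str
    structure_label: str
    subject_id: str
    masks: list[StructureMask]

    def __post_init__(self) -> None:
        if not self.masks:
            raise ValueError("a sequence-structure pair needs >=1 observer mask")
        for m in self.masks:
            if (
                m.sequence_id != self.sequence_id
                or m.structure_label != self.structure_label
                or m.subject_id != self.subject_id
            ):
                raise ValueError("mask tags do not match the pair's tags")

    @property
    def observer_ids(self) -> list[str]:
        return [m.observer_id for m in self.masks]


@dataclass
class MetricSample:
    """Pooled per-(sequence, structure) metric values with provenance.

    ``provenance`` holds one ``(subject_id, observer_tag, slice_index)``
    tuple per value; ``observer_tag`` is an observer id, an observer-pair
    string like ``"obs1|obs2"``, or ``None``; ``slice_index`` is ``None``
    for non-slicewise metrics.  ``filtered`` records whether the inner
    percentile band has already been applied — filtering a filtered sample
    is a no-op.
    """

    metric_name: str
    sequence_id: str
    structure_label: str | None
    values: np.ndarray
    provenance: list[tuple] = field(default_factory=list)
    filtered: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("metric values must be finite")
        if self.provenance and len(self.provenance) != self.values.size:
            raise ValueError("provenance length must equal value count")

    @property
    def n(self) -> int:
        return self.values.size

    def filter(self, inner_fraction: float = 0.90) -> "MetricSample":
        """Return the sample trimmed to its inner percentile band.

        Idempotent: if ``filtered`` is already set the sample is returned
        unchanged.
        """
        if self.filtered:
            return self
        keep = inner_band_mask(self.values, inner_fraction)
        prov = (
            [p for p, k in zip(self.provenance, keep) if k]
            if self.provenance
            else []
        )
        return replace(
            self, values=self.values[keep], provenance=prov, filtered=True
        )


def inner_band_mask(values: np.ndarray, inner_fraction: float = 0.90) -> np.ndarray:
    """Boolean mask of values inside the symmetric inner percentile band.

    A value survives when its mean percentile rank (average of the strict
    and weak empirical CDF ranks, in percent) lies inside the inclusive
    band ``[(1-f)/2, 1-(1-f)/2] * 100``.  For the integers 1..100 at the
    default 90% band this keeps exactly 6..95.  Order of survivors is the
    input order.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("cannot filter an empty sample")
    if not 0 < inner_fraction <= 1:
        raise ValueError(f"inner_fraction must be in (0, 1], got {inner_fraction}")
    order = np.sort(v)
    strict = np.searchsorted(order, v, side="left")
    weak = np.searchsorted(order, v, side="right")
    rank_pct = (strict + weak) / 2.0 / v.size * 100.0
    lo = (1.0 - inner_fraction) / 2.0 * 100.0
    return (rank_pct >= lo) & (rank_pct <= 100.0 - lo)


def pool_and_filter(values, inner_fraction: float = 0.90) -> np.ndarray:
    """Trim pooled metric values to the inner percentile band (two-sided).

    This is the outlier filter applied to slice-wise and pairwise metric
    stacks before statistical testing: symmetric tails of
    ``(1 - inner_fraction)/2`` are dropped on each side, keeping roughly
    ``inner_fraction * n`` values (within ±1 from ties/rounding).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size and not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    return v[inner_band_mask(v, inner_fraction)]


def _spacing_affine(spacing_mm) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    return aff


def load_volume(path, sequence_id: str, subject_id: str) -> VolumeImage:
    """Load a 3D NIfTI volume; spacing is read from the header.

    Trailing singleton dimensions (e.g. a length-1 time axis) are squeezed.
    Non-3D data or non-finite voxels raise :class:`LoadError` naming the
    file.
    """
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=float)
    except Exception as exc:  # noqa: BLE001 - rewrap with file name
        raise LoadError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = np.squeeze(data)
    if data.ndim != 3:
        raise LoadError(f"{path}: expected 3D data, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise LoadError(f"{path}: volume contains NaN/Inf voxels")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeImage(data, spacing, sequence_id=sequence_id, subject_id=subject_id)


def load_mask(
    path,
    structure_label: str,
    observer_id: str,
    subject_id: str,
    sequence_id: str,
    reference: VolumeImage | None = None,
) -> StructureMask:
    """Load a binary NIfTI mask; nonzero voxels become True.

    Empty masks are tolerated at load (metric operations reject them).  If
    ``reference`` is given, a lattice mismatch raises
    :class:`GridMismatchError`.
    """
    try:
        img = nib.load(str(path))
        data = np.squeeze(np.asarray(img.get_fdata()))
    except Exception as exc:  # noqa: BLE001
        raise LoadError(f"cannot read NIfTI mask {path}: {exc}") from exc
    if data.ndim != 3:
        raise LoadError(f"{path}: expected 3D mask, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    mask = StructureMask(
        data != 0,
        spacing,
        structure_label=structure_label,
        observer_id=observer_id,
        subject_id=subject_id,
        sequence_id=sequence_id,
    )
    if reference is not None and not mask.matches_grid(reference):
        raise GridMismatchError(
            f"{path}: mask grid {mask.voxels.shape} @ {spacing} does not "
            f"match volume {reference.shape} @ {reference.spacing_mm}"
        )
    return mask


def save_volume(volume: VolumeImage, path) -> None:
    img = nib.Nifti1Image(
        volume.intensities.astype(np.float32), _spacing_affine(volume.spacing_mm)
    )
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))


def save_mask(mask: StructureMask, path) -> None:
    img = nib.Nifti1Image(
        mask.voxels.astype(np.uint8), _spacing_affine(mask.spacing_mm)
    )
    img.header.set_zooms(mask.spacing_mm)
    nib.save(img, str(path))
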