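"""Slice-wise conspicuity: ROI contrast over surround signal complexity.

Conspicuity quantifies how visible a structure is against its local
background — a more perceptual descriptor than SNR or CNR.  The
implementation here derives, from each observer mask, a family of
isotropically contracted/expanded masks (±1 mm, ±2 mm, spacing-aware 3D
Euclidean morphology) and evaluates, per axial slice occupied by the
structure:

    contrast   = |mean(core on slice) - mean(surround ring on slice)|
    complexity = sample SD of the surround ring on slice
    conspicuity = contrast / complexity

where the core is the 1 mm contraction (a guard band against
partial-volume boundary voxels) and the surround ring is the 1–2 mm
expansion shell.  This concrete formulation is one admissible reading of
the classic contrast/complexity definition; it is isolated in
:func:`slice_conspicuity` so it can be swapped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt

from .data_model import MetricSample, StructureMask, VolumeImage

#: Relative floor for ring complexity, as a fraction of the volume's
#: intensity range; noiseless synthetic inputs must not divide by zero.
COMPLEXITY_FLOOR_REL = 1e-6


def _bbox_slices(voxels: np.ndarray, pad_vox) -> tuple[slice, ...]:
    """Mask bounding box padded per axis, clipped to the array."""
    idx = np.nonzero(voxels)
    return tuple(
        slice(max(int(ax.min()) - p, 0), min(int(ax.max()) + p + 1, n))
        for ax, p, n in zip(idx, pad_vox, voxels.shape)
    )


def _morph_pad(spacing_mm, distance_mm) -> tuple[int, ...]:
    return tuple(
        int(np.ceil(abs(distance_mm) / s)) + 1 for s in spacing_mm
    )


def morph_binary(
    voxels: np.ndarray, spacing_mm, distance_mm: float
) -> np.ndarray:
    """Expand (+) or contract (−) a binary array by a physical distance.

    Expansion keeps voxels whose Euclidean distance (mm, 3D,
    spacing-aware) to the mask is ≤ ``distance_mm``; contraction keeps
    voxels whose distance to the mask complement exceeds
    ``|distance_mm|``.  A contraction may empty the array; callers decide
    whether that is an error.

    The distance transform runs on the mask's padded bounding box — the
    result cannot change farther than ``distance_mm`` from the mask.
    """
    voxels = np.asarray(voxels, dtype=bool)
    if distance_mm == 0 or not voxels.any():
        return voxels.copy()
    box = _bbox_slices(voxels, _morph_pad(spacing_mm, distance_mm))
    sub = voxels[box]
    if distance_mm > 0:
        out = np.zeros_like(voxels)
        dt = distance_transform_edt(~sub, sampling=spacing_mm)
        out[box] = dt <= distance_mm
        return out
    out = np.zeros_like(voxels)
    dt = distance_transform_edt(sub, sampling=spacing_mm)
    out[box] = dt > -distance_mm
    return out


def morph_mask(mask: StructureMask, distance_mm: float) -> StructureMask:
    """Morph a :class:`StructureMask`; see :func:`morph_binary`."""
    mask.require_nonempty("morphology input")
    out = morph_binary(mask.voxels, mask.spacing_mm, distance_mm)
    return StructureMask(
        out,
        mask.spacing_mm,
        structure_label=mask.structure_label,
        observer_id=mask.observer_id,
        subject_id=mask.subject_id,
        sequence_id=mask.sequence_id,
    )


@dataclass
class MaskFamily:
    """Original mask plus its ±1/±2 mm morphs, all on the image grid.

    Invariant: contracted(2) ⊆ contracted(1) ⊆ original ⊆ expanded(1) ⊆
    expanded(2).
    """

    original: np.ndarray
    contracted_1: np.ndarray
    contracted_2: np.ndarray
    expanded_1: np.ndarray
    expanded_2: np.ndarray
    spacing_mm: tuple[float, float, float]

    @property
    def surround_ring(self) -> np.ndarray:
        """The 1–2 mm expansion shell used as the surround region."""
        return self.expanded_2 & ~self.expanded_1

    def nested(self) -> bool:
        chain = (
            self.contracted_2,
            self.contracted_1,
            self.original,
            self.expanded_1,
            self.expanded_2,
        )
        return all(
            not np.any(inner & ~outer) for inner, outer in zip(chain, chain[1:])
        )


def mask_family(mask: StructureMask, distances_mm=(1.0, 2.0)) -> MaskFamily:
    """Build the contraction/expansion family for one observer mask."""
    mask.require_nonempty("conspicuity input")
    d1, d2 = sorted(float(d) for d in distances_mm)
    vox, sp = mask.voxels, mask.spacing_mm
    box = _bbox_slices(vox, _morph_pad(sp, d2))
    sub = vox[box]
    # one distance transform per side serves both radii
    dt_in = distance_transform_edt(sub, sampling=sp)
    dt_out = distance_transform_edt(~sub, sampling=sp)
    full = {
        name: np.zeros_like(vox)
        for name in ("c1", "c2", "e1", "e2")
    }
    full["c1"][box] = dt_in > d1
    full["c2"][box] = dt_in > d2
    full["e1"][box] = sub | (dt_out <= d1)
    full["e2"][box] = sub | (dt_out <= d2)
    return MaskFamily(
        original=vox.copy(),
        contracted_1=full["c1"],
        contracted_2=full["c2"],
        expanded_1=full["e1"],
        expanded_2=full["e2"],
        spacing_mm=sp,
    )


def slice_conspicuity(
    volume: VolumeImage,
    family: MaskFamily,
    slice_index: int,
    complexity_floor: float | None = None,
) -> float | None:
    """Conspicuity on one axial slice, or ``None`` when the slice is
    unusable (core empty, or ring with fewer than two voxels there).

    Complexity below the floor is clamped to the floor, capping the ratio
    rather than raising.
    """
    core = family.contracted_1[:, :, slice_index]
    ring = family.surround_ring[:, :, slice_index]
    if not core.any() or ring.sum() < 2:
        return None
    plane = volume.intensities[:, :, slice_index]
    contrast = abs(float(plane[core].mean()) - float(plane[ring].mean()))
    complexity = float(plane[ring].std(ddof=1))
    if complexity_floor is None:
        rng = float(np.ptp(volume.intensities))
        complexity_floor = COMPLEXITY_FLOOR_REL * rng if rng > 0 else COMPLEXITY_FLOOR_REL
    return contrast / max(complexity, complexity_floor)


def conspicuity_values(
    volume: VolumeImage, mask: StructureMask, distances_mm=(1.0, 2.0)
) -> tuple[list[float], list[int], list[int]]:
    """Per-slice conspicuity over all slices occupied by the mask.

    Returns ``(values, slice_indices, skipped_slices)``; occupied slices
    whose core or ring vanish on that plane are skipped, not errors.
    """
    mask.require_nonempty("conspicuity input")
    fam = mask_family(mask, distances_mm)
    occupied = np.flatnonzero(mask.voxels.any(axis=(0, 1)))
    rng = float(np.ptp(volume.intensities))
    floor = COMPLEXITY_FLOOR_REL * rng if rng > 0 else COMPLEXITY_FLOOR_REL
    # per-slice counts / sums in one pass over each region's voxels
    nz = volume.shape[2]
    core_n, core_mean, _ = _slice_stats(volume.intensities, fam.contracted_1, nz)
    ring_n, ring_mean, ring_sd = _slice_stats(volume.intensities, fam.surround_ring, nz)
    values: list[float] = []
    slices: list[int] = []
    skipped: list[int] = []
    for z in occupied:
        z = int(z)
        if core_n[z] < 1 or ring_n[z] < 2:
            skipped.append(z)
            continue
        contrast = abs(core_mean[z] - ring_mean[z])
        values.append(contrast / max(ring_sd[z], floor))
        slices.append(z)
    return values, slices, skipped


def _slice_stats(intensities: np.ndarray, region: np.ndarray, nz: int):
    """Per-axial-slice voxel count, mean and sample SD of a region."""
    ii, jj, zz = np.nonzero(region)
    vals = intensities[ii, jj, zz]
    shift = vals.mean() if vals.size else 0.0  # numerical stability
    v = vals - shift
    n = np.bincount(zz, minlength=nz).astype(float)
    s1 = np.bincount(zz, weights=v, minlength=nz)
    s2 = np.bincount(zz, weights=v * v, minlength=nz)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / n + shift
        var = (s2 - s1**2 / n) / (n - 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    return n, mean, sd


def conspicuity_series(
    volume: VolumeImage,
    mask: StructureMask,
    distances_mm=(1.0, 2.0),
) -> MetricSample:
    """Unfiltered slice-wise conspicuity sample for one observer mask.

    Values are tagged ``(subject, observer, slice)``; pooling across
    observers/subjects and the inner-percentile filter are applied at the
    (sequence, structure) level by the pipeline.
    """
    values, slices, _ = conspicuity_values(volume, mask, distances_mm)
    if not values:
        raise ValueError(
            f"no valid conspicuity slice for {mask.structure_label} "
            f"(observer {mask.observer_id}, subject {mask.subject_id})"
        )
    prov = [(mask.subject_id, mask.observer_id, z) for z in slices]
    return MetricSample(
        metric_name="conspicuity",
        sequence_id=mask.sequence_id,
        structure_label=mask.structure_label,
        values=np.asarray(values),
        provenance=prov,
        filtered=False,
    )
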