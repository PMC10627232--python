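"""SNR, fat-suppression SNR and CNR.

SNR of a sequence-structure pair is the mean signal under the structure
segmentation divided by the standard deviation of a dedicated noise
segmentation (an air-filled cavity).  These metrics are observer-agnostic:
voxels from every observer's ROI are averaged together (each observer's
voxels contribute, so duplicated masks change nothing), yielding one value
per subject.  CNR is the signed difference of two SNRs — structure minus a
fat or muscle reference.  Fat SNR, computed on the fat reference mask,
measures residual fat signal: lower means better suppression.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

from .data_model import StructureMask, VolumeImage


def _mask_values(volume: VolumeImage, mask: StructureMask) -> np.ndarray:
    if not mask.matches_grid(volume):
        raise ValueError(
            f"mask {mask.structure_label} is not on the grid of volume "
            f"{volume.sequence_id}/{volume.subject_id}"
        )
    return volume.intensities[mask.voxels]


def noise_sd(volume: VolumeImage, noise_mask: StructureMask) -> float:
    """Sample SD (ddof=1) of intensities under the noise segmentation."""
    noise_mask.require_nonempty("noise ROI")
    vals = _mask_values(volume, noise_mask)
    if vals.size < 2:
        raise ValueError("noise ROI must contain >=2 voxels")
    sd = float(vals.std(ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate noise ROI: zero standard deviation")
    return sd


def mean_signal(
    volume: VolumeImage, masks: Sequence[StructureMask]
) -> float:
    """Mean intensity over the union-with-multiplicity of observer ROIs.

    Equivalent to the mean over all (observer, voxel) samples; an observer
    covering a voxel twice as often weights it accordingly, and identical
    masks leave the mean unchanged.
    """
    nonempty = [m for m in masks if not m.is_empty]
    if not nonempty:
        raise ValueError("all observer masks are empty")
    vals = np.concatenate([_mask_values(volume, m) for m in nonempty])
    return float(vals.mean())


def snr(
    volume: VolumeImage,
    structure_masks: Sequence[StructureMask] | StructureMask,
    noise_mask: StructureMask,
) -> float:
    """Mean structure signal over the noise SD; one value per subject."""
    if isinstance(structure_masks, StructureMask):
        structure_masks = [structure_masks]
    return mean_signal(volume, structure_masks) / noise_sd(volume, noise_mask)


def cnr(
    volume: VolumeImage,
    masks_a: Sequence[StructureMask] | StructureMask,
    masks_b: Sequence[StructureMask] | StructureMask,
    noise_mask: StructureMask,
) -> float:
    """Signed contrast-to-noise ratio: snr(a) − snr(b).

    Antisymmetric in its mask arguments.
    """
    return snr(volume, masks_a, noise_mask) - snr(volume, masks_b, noise_mask)
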