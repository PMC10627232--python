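"""Pairwise inter-observer agreement: Dice overlap and 95% Hausdorff.

With no ground-truth contour available, segmentation quality is measured
as precision between observers: every unordered observer pair contributes
one Dice similarity coefficient (volumetric overlap) and one 95th
percentile Hausdorff distance (surface disagreement, mm) per subject.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.ndimage import binary_erosion, generate_binary_structure
from scipy.spatial import cKDTree

from .data_model import MetricSample, SequenceStructurePair, StructureMask

#: Percentile of the pooled bidirectional surface distances (linear
#: interpolation between order statistics, fixed for bit-stability).
HD_PERCENTILE = 95.0


def _check_pair(a: StructureMask, b: StructureMask) -> None:
    if a.voxels.shape != b.voxels.shape or not np.allclose(
        a.spacing_mm, b.spacing_mm
    ):
        raise ValueError("masks are not on the same voxel lattice")


def dice(a: StructureMask, b: StructureMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|), in [0, 1]."""
    _check_pair(a, b)
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        raise ValueError("Dice undefined for two empty masks")
    inter = int(np.count_nonzero(a.voxels & b.voxels))
    return 2.0 * inter / (na + nb)


def surface_voxels(voxels: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one face neighbor outside the mask.

    Voxels on the array border count as surface.
    """
    voxels = np.asarray(voxels, dtype=bool)
    footprint = generate_binary_structure(3, 1)  # 6-connectivity
    interior = binary_erosion(voxels, structure=footprint, border_value=0)
    return voxels & ~interior


def _surface_points_mm(mask: StructureMask) -> np.ndarray:
    idx = np.argwhere(surface_voxels(mask.voxels))
    return idx * np.asarray(mask.spacing_mm)


def hausdorff95(
    a: StructureMask, b: StructureMask, percentile: float = HD_PERCENTILE
) -> float:
    """Percentile Hausdorff distance between two mask surfaces, in mm.

    For every surface voxel of A the minimum Euclidean distance (voxel
    centers, spacing-aware) to B's surface is collected, and vice versa;
    the requested percentile of the concatenated vector is returned.
    Identical masks give 0.
    """
    _check_pair(a, b)
    a.require_nonempty("Hausdorff input")
    b.require_nonempty("Hausdorff input")
    pa, pb = _surface_points_mm(a), _surface_points_mm(b)
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    return float(np.percentile(np.concatenate([d_ab, d_ba]), percentile))


def pairwise_agreement(
    pair: SequenceStructurePair,
) -> tuple[MetricSample, MetricSample]:
    """Dice and HD95 over all C(n_observers, 2) unordered mask pairs.

    Returns unfiltered per-pair samples tagged with the observer pair;
    pooling across subjects and the inner-percentile filter happen at the
    (sequence, structure) level.
    """
    if len(pair.masks) < 2:
        raise ValueError("pairwise agreement needs >=2 observer masks")
    dscs, hds, prov = [], [], []
    for ma, mb in combinations(pair.masks, 2):
        dscs.append(dice(ma, mb))
        hds.append(hausdorff95(ma, mb))
        prov.append(
            (pair.subject_id, f"{ma.observer_id}|{mb.observer_id}", None)
        )
    mk = dict(sequence_id=pair.sequence_id, structure_label=pair.structure_label)
    return (
        MetricSample(metric_name="dsc", values=np.asarray(dscs), provenance=prov, **mk),
        MetricSample(metric_name="hd95", values=np.asarray(hds), provenance=list(prov), **mk),
    )
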