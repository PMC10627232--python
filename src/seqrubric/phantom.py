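"""Synthetic multi-sequence, multi-observer digital phantom.

Generates a complete study with known ground truth so the whole pipeline
can be exercised end to end: per subject, one intensity volume per
candidate sequence (axis-aligned ellipsoidal structures on a uniform
background, a fat slab whose mean is scaled by each sequence's
fat-suppression factor, a tubular air cavity, additive zero-mean Gaussian
noise per sequence), observer contours derived from the ground-truth
masks by random isotropic dilation/erosion plus a random translation, and
a simulated qualitative-feedback table.

Everything is driven by a single seed: the same configuration and seed
reproduce the study bit for bit.  The noise model is additive Gaussian —
the noise estimate downstream is the SD of an air ROI, so Gaussian noise
keeps the SNR oracle exact; the pipeline itself never assumes a noise
family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .conspicuity import morph_binary
from .data_model import StructureMask, VolumeImage

log = logging.getLogger(__name__)

#: Anatomical structure components carried by the phantom (left/right
#: organs are separate masks; the analysis pools them per organ).
COMPONENT_LABELS = (
    "GTV",
    "lymph_nodes",
    "parotid_L",
    "parotid_R",
    "pterygoid_L",
    "pterygoid_R",
)

#: Number of axial slices of the air cavity used as the noise ROI.
NOISE_ROI_SLICES = 10


@dataclass
class SequenceParams:
    """Acquisition parameters of one simulated sequence.

    ``structure_means`` are mean signal intensities (arbitrary units) per
    organ (``GTV``, ``lymph_nodes``, ``parotid``, ``pterygoid``; sides
    share a mean).  ``fat_factor`` scales the unsuppressed fat mean (1.0
    = no suppression, 0.05 = strong suppression).  ``noise_sd`` is the
    SD of the additive Gaussian noise.
    """

    sequence_id: str
    structure_means: dict[str, float]
    fat_factor: float
    noise_sd: float
    background_mean: float = 35.0
    fat_mean: float = 90.0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.fat_factor < 0 or any(v < 0 for v in self.structure_means.values()):
            raise ValueError("means and fat factor must be >= 0")


def default_sequences() -> list[SequenceParams]:
    """Four analyzed sequences: one nonsuppressed T2w-like plus three
    SPAIR-like variants with strong fat suppression and slightly
    different structure signal and noise levels."""
    return [
        SequenceParams(
            "nonfs",
            {"GTV": 60.0, "lymph_nodes": 55.0, "parotid": 45.0, "pterygoid": 70.0},
            fat_factor=1.0,
            noise_sd=6.0,
        ),
        SequenceParams(
            "spair1",
            {"GTV": 65.0, "lymph_nodes": 60.0, "parotid": 55.0, "pterygoid": 50.0},
            fat_factor=0.04,
            noise_sd=7.0,
        ),
        SequenceParams(
            "spair3",
            {"GTV": 55.0, "lymph_nodes": 50.0, "parotid": 45.0, "pterygoid": 45.0},
            fat_factor=0.06,
            noise_sd=9.0,
        ),
        SequenceParams(
            "spair4",
            {"GTV": 70.0, "lymph_nodes": 65.0, "parotid": 60.0, "pterygoid": 50.0},
            fat_factor=0.05,
            noise_sd=6.0,
        ),
    ]


@dataclass
class PhantomConfig:
    """Geometry, signal and observer model of the synthetic study.

    Structure geometry is placed as fractions of the in-plane field of
    view so the same layout scales to any grid.  Observer jitter draws a
    signed boundary radius from N(0, ``jitter_radius_sd_mm``) (dilate or
    erode) and an independent translation from N(0,
    ``jitter_translation_sd_mm``) per axis.
    """

    shape: tuple[int, int, int] = (64, 64, 40)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    sequences: list[SequenceParams] = field(default_factory=default_sequences)
    n_subjects: int = 5
    n_observers: int = 5
    jitter_radius_sd_mm: float = 1.0
    jitter_translation_sd_mm: float = 0.5
    #: per-sequence (p_positive, p_neutral, p_negative); default mildly
    #: favors the suppressed sequences the way segmentors favored them
    favorability: dict[str, tuple[float, float, float]] | None = None
    seed: int = 0

    def sequence_ids(self) -> list[str]:
        return [s.sequence_id for s in self.sequences]


@dataclass
class PhantomStudy:
    """Generated study: volumes, truth masks, observer masks, feedback."""

    config: PhantomConfig
    volumes: dict[tuple[str, str], VolumeImage]
    truth_masks: dict[tuple[str, str], StructureMask]
    observer_masks: dict[tuple[str, str, str, str], StructureMask]
    qualitative: pd.DataFrame

    @property
    def subject_ids(self) -> list[str]:
        return sorted({s for s, _ in self.volumes})

    @property
    def sequence_ids(self) -> list[str]:
        return self.config.sequence_ids()

    @property
    def observer_ids(self) -> list[str]:
        return [f"obs{i + 1}" for i in range(self.config.n_observers)]


def _ellipsoid(shape, spacing, center_frac, radii_mm) -> np.ndarray:
    coords = [
        (np.arange(n) + 0.5) * sp for n, sp in zip(shape, spacing)
    ]
    fov = [n * sp for n, sp in zip(shape, spacing)]
    cx, cy, cz = (f * e for f, e in zip(center_frac, fov))
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    rx, ry, rz = radii_mm
    return ((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 + ((Z - cz) / rz) ** 2 <= 1.0


def build_geometry(
    shape, spacing_mm
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Ground-truth region masks: (structures, fat slab, air cavity).

    Layout (fractions of the field of view): a central GTV, paired lymph
    nodes, parotids and pterygoids, a tubular air cavity mimicking the
    trachea, and a fat slab along the first in-plane edge.
    """
    fov = [n * s for n, s in zip(shape, spacing_mm)]
    L = min(fov[0], fov[1])

    def radii(r_frac):
        r = r_frac * L
        return (r, r, min(r, 0.30 * fov[2]))

    spec = {
        "GTV": ((0.50, 0.38, 0.50), radii(0.14)),
        "lymph_nodes": None,  # two blobs, built below
        "parotid_L": ((0.18, 0.72, 0.55), radii(0.105)),
        "parotid_R": ((0.82, 0.72, 0.55), radii(0.105)),
        "pterygoid_L": ((0.32, 0.16, 0.50), radii(0.105)),
        "pterygoid_R": ((0.68, 0.16, 0.50), radii(0.105)),
    }
    structures: dict[str, np.ndarray] = {}
    for label, geom in spec.items():
        if geom is None:
            continue
        structures[label] = _ellipsoid(shape, spacing_mm, *geom)
    structures["lymph_nodes"] = _ellipsoid(
        shape, spacing_mm, (0.27, 0.50, 0.45), radii(0.085)
    ) | _ellipsoid(shape, spacing_mm, (0.73, 0.50, 0.45), radii(0.085))

    # tubular air cavity (trachea-like) along the slice axis
    ij = np.meshgrid(
        (np.arange(shape[0]) + 0.5) * spacing_mm[0],
        (np.arange(shape[1]) + 0.5) * spacing_mm[1],
        indexing="ij",
    )
    air2d = (ij[0] - 0.50 * fov[0]) ** 2 + (ij[1] - 0.62 * fov[1]) ** 2 <= (
        0.07 * L
    ) ** 2
    air = np.repeat(air2d[:, :, None], shape[2], axis=2)

    fat_thickness = max(2, int(round(0.05 * fov[0] / spacing_mm[0])))
    fat = np.zeros(shape, dtype=bool)
    fat[:fat_thickness, :, :] = True

    for label, m in structures.items():
        if np.any(m & air):
            raise ValueError(f"phantom config error: {label} overlaps the air cavity")
        if np.any(m & fat):
            raise ValueError(f"phantom config error: {label} overlaps the fat slab")
        if m.sum() == 0:
            raise ValueError(f"phantom config error: {label} is empty on this grid")
    return structures, fat, air


def _organ_of(label: str) -> str:
    return label.split("_")[0] if label.split("_")[-1] in ("L", "R") else label


def render_volume(
    params: SequenceParams,
    structures: dict[str, np.ndarray],
    fat: np.ndarray,
    air: np.ndarray,
    rng: np.random.Generator,
    shape,
) -> np.ndarray:
    """Piecewise-constant tissue means plus Gaussian noise."""
    img = np.full(shape, params.background_mean, dtype=float)
    img[fat] = params.fat_mean * params.fat_factor
    for label, m in structures.items():
        img[m] = params.structure_means[_organ_of(label)]
    img[air] = 0.0
    img += rng.normal(0.0, params.noise_sd, size=shape)
    return img


def simulate_observer_masks(
    truth: StructureMask,
    jitter_radius_sd_mm: float,
    jitter_translation_sd_mm: float,
    n_observers: int,
    rng: np.random.Generator | int,
) -> list[StructureMask]:
    """Observer contours: truth randomly dilated/eroded and translated.

    A jitter so large that the mask empties is retried with the radius
    halved (logged); at radius 0 the truth itself is returned.
    """
    truth.require_nonempty("observer simulation input")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    out = []
    for i in range(n_observers):
        radius = float(rng.normal(0.0, jitter_radius_sd_mm)) if jitter_radius_sd_mm > 0 else 0.0
        shift_mm = (
            rng.normal(0.0, jitter_translation_sd_mm, size=3)
            if jitter_translation_sd_mm > 0
            else np.zeros(3)
        )
        vox = _jittered(truth, radius, shift_mm)
        while not vox.any():
            radius *= 0.5
            if abs(radius) < 0.25:
                radius = 0.0
            log.warning(
                "observer jitter emptied %s; retrying with radius %.2f mm",
                truth.structure_label, radius,
            )
            vox = _jittered(truth, radius, shift_mm)
        out.append(
            replace(truth, voxels=vox, observer_id=f"obs{i + 1}")
        )
    return out


def _jittered(truth: StructureMask, radius_mm: float, shift_mm) -> np.ndarray:
    vox = morph_binary(truth.voxels, truth.spacing_mm, radius_mm)
    shift_vox = np.round(np.asarray(shift_mm) / np.asarray(truth.spacing_mm)).astype(int)
    if np.any(shift_vox):
        vox = np.roll(vox, shift_vox, axis=(0, 1, 2))
    return vox


def simulate_qualitative_feedback(
    sequence_ids: list[str],
    structures: list[str],
    subject_ids: list[str],
    observer_ids: list[str],
    favorability: dict[str, tuple[float, float, float]],
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Simulated grades and comments.

    Per (observer, subject, structure) each sequence gets a latent
    preference ``p_positive − p_negative`` plus Gaussian taste noise; the
    descending latent order yields grades 1..S (1 = most preferred).  One
    comment category per record is drawn from the sequence's
    (positive, neutral, negative) probabilities.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    for seq, probs in favorability.items():
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"favorability for {seq!r} must sum to 1")
    rows = []
    cats = np.array(["positive", "neutral", "negative"])
    for obs in observer_ids:
        for subj in subject_ids:
            for struct in structures:
                latent = np.array(
                    [
                        favorability[s][0] - favorability[s][2]
                        for s in sequence_ids
                    ]
                ) + rng.normal(0.0, 0.35, size=len(sequence_ids))
                order = np.argsort(-latent, kind="stable")
                grade = np.empty(len(sequence_ids), dtype=int)
                grade[order] = np.arange(1, len(sequence_ids) + 1)
                for k, seq in enumerate(sequence_ids):
                    comment = str(rng.choice(cats, p=favorability[seq]))
                    rows.append(
                        (subj, seq, struct, obs, int(grade[k]), comment)
                    )
    return pd.DataFrame(
        rows,
        columns=["subject", "sequence", "structure", "observer", "grade", "comment"],
    )


def generate_phantom(config: PhantomConfig) -> PhantomStudy:
    """Generate the full synthetic study; seed-deterministic."""
    structures, fat, air = build_geometry(config.shape, config.spacing_mm)
    rng = np.random.default_rng(config.seed)
    sp = tuple(config.spacing_mm)

    mid = config.shape[2] // 2
    half = NOISE_ROI_SLICES // 2
    lo = max(0, mid - half)
    hi = min(config.shape[2], lo + NOISE_ROI_SLICES)
    noise_vox = np.zeros(config.shape, dtype=bool)
    noise_vox[:, :, lo:hi] = air[:, :, lo:hi]

    volumes: dict[tuple[str, str], VolumeImage] = {}
    truth_masks: dict[tuple[str, str], StructureMask] = {}
    observer_masks: dict[tuple[str, str, str, str], StructureMask] = {}
    subject_ids = [f"subj{i + 1}" for i in range(config.n_subjects)]

    for subj in subject_ids:
        for label, m in structures.items():
            truth_masks[(subj, label)] = StructureMask(
                m, sp, label, observer_id="truth", subject_id=subj, sequence_id="all"
            )
        truth_masks[(subj, "fat")] = StructureMask(
            fat, sp, "fat", observer_id="truth", subject_id=subj, sequence_id="all"
        )
        truth_masks[(subj, "noise")] = StructureMask(
            noise_vox, sp, "noise", observer_id="truth", subject_id=subj, sequence_id="all"
        )
        for params in config.sequences:
            seq = params.sequence_id
            volumes[(subj, seq)] = VolumeImage(
                render_volume(params, structures, fat, air, rng, config.shape),
                sp,
                sequence_id=seq,
                subject_id=subj,
            )
            for label in COMPONENT_LABELS:
                truth = replace(truth_masks[(subj, label)], sequence_id=seq)
                for obs_mask in simulate_observer_masks(
                    truth,
                    config.jitter_radius_sd_mm,
                    config.jitter_translation_sd_mm,
                    config.n_observers,
                    rng,
                ):
                    observer_masks[(subj, seq, label, obs_mask.observer_id)] = obs_mask

    seq_ids = config.sequence_ids()
    favor = config.favorability or {
        s.sequence_id: (0.25, 0.50, 0.25) for s in config.sequences
    }
    organs = sorted({_organ_of(c) for c in COMPONENT_LABELS})
    qualitative = simulate_qualitative_feedback(
        seq_ids,
        organs,
        subject_ids,
        [f"obs{i + 1}" for i in range(config.n_observers)],
        favor,
        rng,
    )
    return PhantomStudy(
        config=config,
        volumes=volumes,
        truth_masks=truth_masks,
        observer_masks=observer_masks,
        qualitative=qualitative,
    )
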