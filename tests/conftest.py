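import numpy as np
import pytest

from seqrubric.data_model import StructureMask, VolumeImage
from seqrubric.phantom import PhantomConfig, generate_phantom


def make_mask(voxels, spacing=(1.0, 1.0, 1.0), label="GTV", observer="obs1",
              subject="subj1", sequence="seq1"):
    return StructureMask(np.asarray(voxels, dtype=bool), spacing, label,
                         observer, subject, sequence)


def make_volume(intensities, spacing=(1.0, 1.0, 1.0), sequence="seq1",
                subject="subj1"):
    return VolumeImage(np.asarray(intensities, dtype=float), spacing,
                       sequence, subject)


def sphere_mask(shape, center, radius_vox, spacing=(1.0, 1.0, 1.0), **kw):
    idx = np.indices(shape)
    d2 = sum((idx[i] - center[i]) ** 2 for i in range(3))
    return make_mask(d2 <= radius_vox**2, spacing=spacing, **kw)


def random_blob_pair(rng, shape=(12, 12, 10), spacing=(1.0, 1.0, 1.0)):
    """Two random small masks (<=500 voxels) sharing a lattice."""
    masks = []
    for tag in ("obs1", "obs2"):
        center = rng.uniform(3, np.array(shape) - 3)
        radius = rng.uniform(1.5, 3.5)
        idx = np.indices(shape)
        d2 = sum(((idx[i] - center[i]) * spacing[i]) ** 2 for i in range(3))
        vox = d2 <= (radius * min(spacing)) ** 2
        if not vox.any():
            vox[tuple(np.round(center).astype(int))] = True
        masks.append(make_mask(vox, spacing=spacing, observer=tag))
    return masks


@pytest.fixture(scope="session")
def small_study():
    """A compact deterministic phantom study shared across tests."""
    cfg = PhantomConfig(
        shape=(36, 36, 24),
        spacing_mm=(1.5, 1.5, 1.5),
        n_subjects=3,
        n_observers=3,
        seed=7,
    )
    return generate_phantom(cfg)
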