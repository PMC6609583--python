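from __future__ import annotations

import numpy as np
import pytest

from wstlg import BinaryMask, ImageGrid, VolumeImage
from wstlg.phantom import LesionSpec, MarrowSite, PhantomSpec


@pytest.fixture
def unit_grid():
    """A small isotropic 2 mm grid (voxel volume 0.008 mL)."""
    return ImageGrid(shape=(12, 12, 12), spacing=(2.0, 2.0, 2.0))


def make_suv(grid: ImageGrid, values: np.ndarray) -> VolumeImage:
    return VolumeImage(grid=grid, values=values, value_kind="SUV")


def make_mask(grid: ImageGrid, membership) -> BinaryMask:
    return BinaryMask(grid=grid, membership=np.asarray(membership, dtype=bool))


def full_mask(grid: ImageGrid) -> BinaryMask:
    return make_mask(grid, np.ones(grid.shape, dtype=bool))


def random_phantom_spec(seed: int) -> PhantomSpec:
    """A seeded random phantom: one bone sphere holding 1-3 non-overlapping
    lesions of random type/SUV, with mild noise."""
    rng = np.random.default_rng(seed)
    grid = ImageGrid(shape=(40, 40, 40), spacing=(2.6, 2.6, 2.6))
    center = np.array([52.0, 52.0, 52.0])
    site = MarrowSite(label="Th7", center_mm=tuple(center), radius_mm=34.0, suv=1.6)
    n_lesions = int(rng.integers(1, 4))
    lesions = []
    # Anchors inside the bone sphere, far enough apart that radius <= 8 mm
    # plus +/-2 mm jitter can never overlap.
    anchors = np.array(
        [[38.0, 52.0, 52.0], [66.0, 52.0, 52.0], [52.0, 52.0, 34.0]]
    )
    for anchor in anchors[:n_lesions]:
        # Lesion SUV either clearly below or clearly above the 4.0 cutoff so
        # that mild noise cannot flip supra-cutoff membership wholesale.
        suv = (
            float(rng.uniform(1.5, 3.0))
            if rng.random() < 0.4
            else float(rng.uniform(5.5, 10.0))
        )
        lesions.append(
            LesionSpec(
                center_mm=tuple(anchor + rng.uniform(-2, 2, size=3)),
                radius_mm=float(rng.uniform(6.0, 8.0)),
                suv=suv,
                ct_type=str(
                    rng.choice(["blastic", "intertrabecular", "lytic", "mixed"])
                ),
            )
        )
    return PhantomSpec(
        grid=grid,
        marrow_sites=(site,),
        lesions=tuple(lesions),
        noise_sd_suv=float(rng.uniform(0.0, 0.15)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
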