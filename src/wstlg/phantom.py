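"""Synthetic PET/CT phantom generator with analytic ground truth.

The phantom emulates the features of a whole-body FDG-PET/CT acquisition
that the WS-TLG pipeline depends on, at desk scale:

* a CT volume with a soft-tissue compartment (default 40 HU) and spherical
  bone sites (default 700 HU) standing in for marrow-bearing skeleton;
* a PET/SUV volume with soft-tissue background uptake (default SUV 1.0),
  physiologic marrow uptake at published normal-bone mean levels
  (sternum 1.43, rib 1.27, Th7 2.29, L3 2.33, ilium 1.66), and focal
  spherical lesions of specified SUV;
* the four CT morphologies of skeletal metastasis: *lytic* lesions carve
  the CT down to soft-tissue attenuation, *blastic* lesions raise it above
  the bone level, *intertrabecular* lesions leave the CT unchanged (the
  "invisible type"), and *mixed* lesions do both in halves;
* optional isotropic Gaussian PSF blur of the PET (CT stays sharp) and
  additive Gaussian noise, applied in that order.

Lesions are spheres and may not overlap each other, so every lesion's
volume and TLG have closed forms and the whole-phantom truth WS-TLG at any
cutoff is exactly computable — the oracle every other module is tested
against.  Geometry is deterministic; the seed drives only the noise term.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .image_model import ImageGrid, VolumeImage

__all__ = [
    "MARROW_SUV_MEANS",
    "MarrowSite",
    "LesionSpec",
    "PhantomSpec",
    "PhantomTruth",
    "LesionTruth",
    "generate",
    "truth_wstlg",
    "truth_wstlg_band",
    "default_marrow_sites",
    "spec_from_yaml",
    "spec_to_yaml",
]

#: Published physiologic marrow SUVmax means in patients without skeletal
#: metastasis, used as the default site uptake levels.
MARROW_SUV_MEANS = {
    "sternum": 1.43,
    "rib": 1.27,
    "Th7": 2.29,
    "L3": 2.33,
    "ilium": 1.66,
}

CTLesionType = Literal["lytic", "blastic", "mixed", "intertrabecular"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Default grid approximating clinical PET sampling (2.6 mm in-plane) at a
#: desk-scale extent.
DEFAULT_GRID = ImageGrid(shape=(128, 128, 160), spacing=(2.6, 2.6, 3.0))


@dataclass(frozen=True)
class MarrowSite:
    """A spherical bone region with physiologic marrow uptake."""

    label: str
    center_mm: tuple[float, float, float]
    radius_mm: float
    suv: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError(f"site {self.label}: radius must be > 0")
        if self.suv < 0:
            raise ValueError(f"site {self.label}: SUV must be >= 0")


@dataclass(frozen=True)
class LesionSpec:
    """A spherical focal lesion of given uptake and CT morphology."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    suv: float
    ct_type: CTLesionType = "intertrabecular"

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be > 0")
        if self.suv < 0:
            raise ValueError("lesion SUV must be >= 0")
        if self.ct_type not in ("lytic", "blastic", "mixed", "intertrabecular"):
            raise ValueError(f"unknown ct_type {self.ct_type!r}")

    @property
    def volume_ml(self) -> float:
        """Analytic sphere volume in mL."""
        return 4.0 / 3.0 * np.pi * self.radius_mm**3 / 1000.0


def default_marrow_sites(grid: ImageGrid = DEFAULT_GRID) -> list[MarrowSite]:
    """Five marrow sites spaced along the central axis of ``grid``."""
    lo, hi = grid.world_bounds()
    cx, cy = (lo[0] + hi[0]) / 2.0, (lo[1] + hi[1]) / 2.0
    extent_z = hi[2] - lo[2]
    sites = []
    labels = ["sternum", "rib", "Th7", "L3", "ilium"]
    for i, label in enumerate(labels):
        z = lo[2] + extent_z * (i + 1) / (len(labels) + 1)
        sites.append(
            MarrowSite(
                label=label,
                center_mm=(cx, cy, float(z)),
                radius_mm=18.0,
                suv=MARROW_SUV_MEANS[label],
            )
        )
    return sites


@dataclass(frozen=True)
class PhantomSpec:
    """Full generative description of one synthetic PET/CT pair."""

    grid: ImageGrid = DEFAULT_GRID
    soft_tissue_hu: float = 40.0
    bone_hu: float = 700.0
    background_suv: float = 1.0
    marrow_sites: tuple[MarrowSite, ...] = field(default=None)  # type: ignore[assignment]
    lesions: tuple[LesionSpec, ...] = ()
    psf_fwhm_mm: float = 0.0
    noise_sd_suv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        sites = (
            tuple(default_marrow_sites(self.grid))
            if self.marrow_sites is None
            else tuple(self.marrow_sites)
        )
        object.__setattr__(self, "marrow_sites", sites)
        object.__setattr__(self, "lesions", tuple(self.lesions))
        if self.psf_fwhm_mm < 0 or self.noise_sd_suv < 0:
            raise ValueError("psf_fwhm_mm and noise_sd_suv must be >= 0")
        lo, hi = self.grid.world_bounds()
        for obj in (*sites, *self.lesions):
            c = np.asarray(obj.center_mm, dtype=float)
            r = obj.radius_mm
            if np.any(c - r < lo) or np.any(c + r > hi):
                raise ValueError(f"{obj} extends outside the grid")
        # Overlapping lesions would break the closed-form per-lesion truth.
        for i, a in enumerate(self.lesions):
            for b in self.lesions[i + 1 :]:
                dist = float(
                    np.linalg.norm(
                        np.asarray(a.center_mm) - np.asarray(b.center_mm)
                    )
                )
                if dist < a.radius_mm + b.radius_mm:
                    raise ValueError(
                        f"lesions at {a.center_mm} and {b.center_mm} overlap; "
                        "ground truth would no longer be analytic"
                    )


@dataclass(frozen=True)
class LesionTruth:
    """Analytic per-lesion ground truth (pre-blur, pre-noise)."""

    index: int
    ct_type: CTLesionType
    suv: float
    volume_ml: float
    radius_mm: float

    def tlg_at(self, cutoff: float) -> float:
        """Truth TLG at a cutoff: volume x SUV if supra-cutoff, else 0."""
        return self.volume_ml * self.suv if self.suv > cutoff else 0.0


@dataclass(frozen=True)
class PhantomTruth:
    lesions: tuple[LesionTruth, ...]
    blurred: bool
    noisy: bool


def _sphere_mask(grid: ImageGrid, center: Sequence[float], radius: float) -> np.ndarray:
    xs, ys, zs = grid.axis_coordinates()
    d2 = (
        (xs[:, None, None] - center[0]) ** 2
        + (ys[None, :, None] - center[1]) ** 2
        + (zs[None, None, :] - center[2]) ** 2
    )
    return d2 <= radius**2


def generate(spec: PhantomSpec) -> tuple[VolumeImage, VolumeImage, PhantomTruth]:
    """Render (CT, PET, truth) from a phantom description.

    Deterministic given the seed: identical specs produce bit-identical
    volumes.  Truth is computed from the analytic geometry before blur and
    noise are applied.
    """
    grid = spec.grid
    ct = np.full(grid.shape, spec.soft_tissue_hu, dtype=np.float64)
    pet = np.full(grid.shape, spec.background_suv, dtype=np.float64)

    for site in spec.marrow_sites:
        mask = _sphere_mask(grid, site.center_mm, site.radius_mm)
        ct[mask] = spec.bone_hu
        pet[mask] = site.suv

    blastic_hu = spec.bone_hu + 300.0
    truths = []
    for i, lesion in enumerate(spec.lesions):
        mask = _sphere_mask(grid, lesion.center_mm, lesion.radius_mm)
        pet[mask] = lesion.suv
        if lesion.ct_type == "lytic":
            ct[mask] = spec.soft_tissue_hu
        elif lesion.ct_type == "blastic":
            ct[mask] = blastic_hu
        elif lesion.ct_type == "mixed":
            zs = grid.axis_coordinates()[2]
            upper = np.zeros(grid.shape, dtype=bool)
            upper |= zs[None, None, :] >= lesion.center_mm[2]
            ct[mask & upper] = blastic_hu
            ct[mask & ~upper] = spec.soft_tissue_hu
        # intertrabecular: CT unchanged ("invisible type")
        truths.append(
            LesionTruth(
                index=i,
                ct_type=lesion.ct_type,
                suv=lesion.suv,
                volume_ml=lesion.volume_ml,
                radius_mm=lesion.radius_mm,
            )
        )

    if spec.psf_fwhm_mm > 0:
        sigma_vox = [
            spec.psf_fwhm_mm * _FWHM_TO_SIGMA / s for s in grid.spacing
        ]
        pet = ndimage.gaussian_filter(pet, sigma=sigma_vox)
    if spec.noise_sd_suv > 0:
        rng = np.random.default_rng(spec.seed)
        pet = pet + rng.normal(0.0, spec.noise_sd_suv, size=grid.shape)
    np.clip(pet, 0.0, None, out=pet)

    truth = PhantomTruth(
        lesions=tuple(truths),
        blurred=spec.psf_fwhm_mm > 0,
        noisy=spec.noise_sd_suv > 0,
    )
    return (
        VolumeImage(grid=grid, values=ct, value_kind="HU"),
        VolumeImage(grid=grid, values=pet, value_kind="SUV"),
        truth,
    )


def truth_wstlg(truth: PhantomTruth, cutoff: float) -> float:
    """Exact WS-TLG of an unblurred, noiseless phantom at a cutoff.

    Sum over lesions with SUV strictly above the cutoff of volume x SUV.
    Refuses blurred/noisy phantoms, whose truth is no longer exact — use
    :func:`truth_wstlg_band` for those.
    """
    if truth.blurred or truth.noisy:
        raise ValueError(
            "exact truth is only available for unblurred, noiseless phantoms; "
            "use truth_wstlg_band(truth, cutoff) for a tolerance band"
        )
    return float(sum(t.tlg_at(cutoff) for t in truth.lesions))


def truth_wstlg_band(
    truth: PhantomTruth, cutoff: float, rel_tol: float = 0.2
) -> tuple[float, float]:
    """A (lo, hi) band around the analytic WS-TLG for blurred/noisy phantoms.

    Blur moves counts across the lesion boundary and noise perturbs voxel
    values, so the pipeline result is expected within a relative band of
    the analytic value rather than at it exactly.
    """
    nominal = float(sum(t.tlg_at(cutoff) for t in truth.lesions))
    return nominal * (1.0 - rel_tol), nominal * (1.0 + rel_tol)


# ---------------------------------------------------------------------------
# YAML round-trip for the CLI
# ---------------------------------------------------------------------------

def spec_to_yaml(spec: PhantomSpec, path: str | Path) -> None:
    import yaml

    data = {
        "grid": {
            "shape": list(spec.grid.shape),
            "spacing": list(spec.grid.spacing),
            "origin": list(spec.grid.origin),
        },
        "soft_tissue_hu": spec.soft_tissue_hu,
        "bone_hu": spec.bone_hu,
        "background_suv": spec.background_suv,
        "marrow_sites": [
            {
                "label": s.label,
                "center_mm": list(s.center_mm),
                "radius_mm": s.radius_mm,
                "suv": s.suv,
            }
            for s in spec.marrow_sites
        ],
        "lesions": [
            {
                "center_mm": list(l.center_mm),
                "radius_mm": l.radius_mm,
                "suv": l.suv,
                "ct_type": l.ct_type,
            }
            for l in spec.lesions
        ],
        "psf_fwhm_mm": spec.psf_fwhm_mm,
        "noise_sd_suv": spec.noise_sd_suv,
        "seed": spec.seed,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def spec_from_yaml(path: str | Path) -> PhantomSpec:
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    grid = (
        ImageGrid(
            shape=tuple(data["grid"]["shape"]),
            spacing=tuple(data["grid"]["spacing"]),
            origin=tuple(data["grid"].get("origin", (0.0, 0.0, 0.0))),
        )
        if "grid" in data
        else DEFAULT_GRID
    )
    sites = data.get("marrow_sites")
    marrow = (
        tuple(
            MarrowSite(
                label=s["label"],
                center_mm=tuple(s["center_mm"]),
                radius_mm=float(s["radius_mm"]),
                suv=float(s["suv"]),
            )
            for s in sites
        )
        if sites is not None
        else None
    )
    lesions = tuple(
        LesionSpec(
            center_mm=tuple(l["center_mm"]),
            radius_mm=float(l["radius_mm"]),
            suv=float(l["suv"]),
            ct_type=l.get("ct_type", "intertrabecular"),
        )
        for l in data.get("lesions", ())
    )
    return PhantomSpec(
        grid=grid,
        soft_tissue_hu=float(data.get("soft_tissue_hu", 40.0)),
        bone_hu=float(data.get("bone_hu", 700.0)),
        background_suv=float(data.get("background_suv", 1.0)),
        marrow_sites=marrow,
        lesions=lesions,
        psf_fwhm_mm=float(data.get("psf_fwhm_mm", 0.0)),
        noise_sd_suv=float(data.get("noise_sd_suv", 0.0)),
        seed=int(data.get("seed", 0)),
    )
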