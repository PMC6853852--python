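"""Synthetic OCT B-scan phantoms with known ground-truth boundaries.

No public ground-truth dataset accompanies this package, so every pipeline
stage is exercised on simulated scans: a piecewise-constant axial
reflectivity profile rendered per column from 8 smooth interface curves
(bright nerve-fibre, photoreceptor IS-OS and RPE bands separated by darker
plexiform/nuclear layers), degraded by the two noise sources that dominate
real B-scans — multiplicative, non-Gaussian, spatially correlated speckle,
and vertical shadows cast by retinal blood vessels.

The reflectivity defaults are chosen so each interface exhibits the
transition polarity and relative strength the segmentation order relies on
in real scans: the ILM is the strongest dark-to-bright transition, the
IS-OS the second strongest, and the RPE-Choroid the strongest
bright-to-dark drop — orderings that survive the monotone FHH remap across
the admissible fuzzifier window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ParameterError
from .image import BScanImage
from .segment import BOUNDARY_LABELS, Boundary

__all__ = [
    "VesselSpec",
    "PhantomSpec",
    "default_profiles",
    "generate_bscan",
    "add_speckle",
    "add_vessel_shadows",
    "simulate_bscan",
]

#: Mean reflectivity (8-bit grey levels) of the background and the 7 layers,
#: vitreous to choroid. Bright bands: NFL, OS (photoreceptor outer segments /
#: IS-OS junction vicinity) and RPE; dark bands: nuclear/plexiform layers.
DEFAULT_REFLECTIVITY = {
    "vitreous": 20.0,
    "NFL": 200.0,
    "GCL+IPL": 100.0,
    "INL": 60.0,
    "OPL": 120.0,
    "ONL+IS": 55.0,
    "OS": 185.0,
    "RPE": 240.0,
    "choroid": 70.0,
}

#: Interface depths for a 256-row scan, scaled linearly for other heights.
DEFAULT_BASE_ROWS = (60.0, 78.0, 108.0, 124.0, 140.0, 170.0, 182.0, 196.0)


@dataclass
class VesselSpec:
    """One retinal vessel casting a vertical shadow.

    center/width are lateral pixels; attenuation is the multiplicative
    factor applied beneath the vessel (1 = no shadow).
    """

    center: float
    width: float
    attenuation: float

    def __post_init__(self) -> None:
        if not (0 < self.attenuation <= 1):
            raise ParameterError(
                f"attenuation must be in (0, 1], got {self.attenuation}"
            )
        if self.width <= 0:
            raise ParameterError(f"vessel width must be positive, got {self.width}")


def _default_vessels(width: int) -> list[VesselSpec]:
    return [
        VesselSpec(center=0.3 * width, width=12.0, attenuation=0.55),
        VesselSpec(center=0.7 * width, width=16.0, attenuation=0.65),
    ]


@dataclass
class PhantomSpec:
    """Geometry, optics and noise of one synthetic B-scan.

    boundary_profiles, when given, is an (8, width) array of per-column
    interface rows; otherwise gently sloped low-order polynomial curves
    (plus an optional foveal dip) are generated from the seed.
    speckle_looks is the gamma-speckle shape parameter (smaller = noisier;
    None disables speckle).
    """

    height: int = 256
    width: int = 512
    boundary_profiles: np.ndarray | None = None
    layer_reflectivities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REFLECTIVITY)
    )
    speckle_looks: float | None = 4.0
    speckle_corr_sigma: float = 0.75
    vessels: list[VesselSpec] | None = None
    slope_px: float = 3.0
    curve_px: float = 2.0
    foveal_dip_px: float = 0.0
    max_grey: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ParameterError(f"phantom too small: {self.height}x{self.width}")
        if self.speckle_looks is not None and self.speckle_looks < 1:
            raise ParameterError(f"speckle_looks must be >= 1, got {self.speckle_looks}")
        for v in self.layer_reflectivities.values():
            if not (0 <= v <= self.max_grey - 1):
                raise ParameterError(f"reflectivity {v} outside [0, {self.max_grey - 1}]")
        if self.vessels is None:
            self.vessels = _default_vessels(self.width)

    def profiles(self) -> np.ndarray:
        """(8, width) integer interface rows, strictly ordered top to bottom."""
        if self.boundary_profiles is not None:
            prof = np.asarray(self.boundary_profiles)
            prof = np.round(prof).astype(np.int64)
        else:
            prof = default_profiles(self)
        if prof.shape != (8, self.width):
            raise ParameterError(
                f"boundary_profiles must be (8, {self.width}), got {prof.shape}"
            )
        if np.any(np.diff(prof, axis=0) < 2):
            raise ParameterError("interfaces must keep >= 2 px separation")
        if prof.min() < 1 or prof.max() > self.height - 2:
            raise ParameterError("interfaces outside the image interior")
        return prof


def default_profiles(spec: PhantomSpec) -> np.ndarray:
    """Gently sloped quadratic interfaces with an optional foveal dip.

    Per-interface tilt and curvature are drawn once from the seed, small
    enough that consecutive columns never differ by more than one row.
    """
    rng = np.random.default_rng(spec.seed)
    x = np.linspace(-0.5, 0.5, spec.width)
    base = np.asarray(DEFAULT_BASE_ROWS) * (spec.height / 256.0)
    tilt = rng.uniform(-spec.slope_px, spec.slope_px, size=8)
    curve = rng.uniform(-spec.curve_px, spec.curve_px, size=8)
    prof = base[:, None] + tilt[:, None] * x[None, :] + curve[:, None] * (
        4 * x[None, :] ** 2 - 0.5
    )
    if spec.foveal_dip_px > 0:
        # inner interfaces dip towards the outer retina at the fovea
        dip = spec.foveal_dip_px * np.exp(-0.5 * (x / 0.08) ** 2)
        weight = np.linspace(1.0, 0.0, 8)[:5]
        prof[:5] += weight[:, None] * dip[None, :]
    return np.round(prof).astype(np.int64)


def generate_bscan(spec: PhantomSpec) -> tuple[BScanImage, dict[str, Boundary]]:
    """Render the noise-free layered phantom and its exact ground truth.

    Layer k occupies rows ``profile[k] <= r < profile[k+1]`` in each
    column, i.e. a boundary row is the first row of the deeper layer —
    the same row at which the axial first difference peaks, so a perfect
    segmentation reproduces the ground truth exactly. Deterministic for a
    given spec (profiles depend only on the seed).
    """
    prof = spec.profiles()
    refl = spec.layer_reflectivities
    values = [refl["vitreous"]] + [
        refl[name] for name in ("NFL", "GCL+IPL", "INL", "OPL", "ONL+IS", "OS", "RPE")
    ] + [refl["choroid"]]
    rows = np.arange(spec.height)[:, None]
    img = np.full((spec.height, spec.width), values[0])
    for k in range(8):  # deeper layers overwrite, top to bottom
        img = np.where(rows >= prof[k][None, :], values[k + 1], img)
    truth = {
        lb: Boundary(lb, prof[i]) for i, lb in enumerate(BOUNDARY_LABELS)
    }
    return BScanImage(img, max_grey=spec.max_grey), truth


def add_speckle(
    image: BScanImage,
    looks: float,
    seed: int,
    corr_sigma: float = 0.75,
) -> BScanImage:
    """Multiplicative gamma speckle with short-range spatial correlation.

    Each pixel is multiplied by a unit-mean gamma factor (shape ``looks``:
    fewer looks = heavier speckle), smoothed with a small Gaussian kernel
    before multiplication to mimic the neighbourhood correlation of real
    speckle. Smoothing preserves the unit mean, so the expected intensity
    is unchanged; the product is clipped to the valid grey range.
    """
    if looks < 1:
        raise ParameterError(f"looks must be >= 1, got {looks}")
    rng = np.random.default_rng(seed)
    noise = rng.gamma(shape=looks, scale=1.0 / looks, size=image.shape)
    if corr_sigma > 0:
        noise = gaussian_filter(noise, sigma=corr_sigma, mode="reflect")
    out = np.clip(image.pixels * noise, 0, image.max_grey - 1)
    return BScanImage(out, image.max_grey, image.crop_offset)


def add_vessel_shadows(
    image: BScanImage,
    vessels: list[VesselSpec],
    start_rows: np.ndarray | int,
) -> BScanImage:
    """Attenuate columns beneath retinal vessels.

    Light blocked by a vessel darkens everything below it: intensities in
    each vessel's column band are multiplied by its attenuation from
    ``start_rows`` (scalar or per-column) downward, at full strength inside
    the band and with a smooth cosine falloff over a quarter-width on each
    flank. Ground-truth boundary rows are unaffected by construction.
    """
    h, w = image.shape
    cols = np.arange(w)
    profile = np.ones(w)
    for v in vessels:
        if not (0 <= v.center < w):
            raise ParameterError(f"vessel center {v.center} outside image width {w}")
        half = v.width / 2.0
        taper = max(v.width / 4.0, 1.0)
        d = np.abs(cols - v.center)
        vp = np.ones(w)
        vp[d <= half] = v.attenuation
        flank = (d > half) & (d <= half + taper)
        t = (d[flank] - half) / taper  # 0 at band edge, 1 at end of taper
        vp[flank] = v.attenuation + (1 - v.attenuation) * 0.5 * (1 - np.cos(np.pi * t))
        profile = np.minimum(profile, vp)
    start = np.broadcast_to(np.asarray(start_rows), (w,))
    rows = np.arange(h)[:, None]
    factor = np.where(rows >= start[None, :], profile[None, :], 1.0)
    return BScanImage(image.pixels * factor, image.max_grey, image.crop_offset)


def simulate_bscan(spec: PhantomSpec) -> tuple[BScanImage, dict[str, Boundary]]:
    """Render the phantom and apply vessel shadows and speckle.

    Shadows start at the NFL-GCL interface (vessels run inside the nerve
    fibre layer) and are applied before speckle, matching the physical
    order of signal attenuation and coherent noise.
    """
    image, truth = generate_bscan(spec)
    if spec.vessels:
        image = add_vessel_shadows(
            image, spec.vessels, truth["NFL-GCL"].rows
        )
    if spec.speckle_looks is not None:
        image = add_speckle(
            image, spec.speckle_looks, spec.seed, spec.speckle_corr_sigma
        )
    return image, truth
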