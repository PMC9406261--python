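"""Synthetic fluorescence phantoms of eosin-stained lung with known truth.

The generator emulates the spectral and morphological behaviour of eosin Y
in H&E-stained FFPE lung sections: bulk tissue fluoresces with an emission
maximum near 550 nm, while erythrocytes are brighter, punctate and
red-shifted to a maximum near 570 nm, appearing as ~5-um donut-shaped
objects.  A phantom consists of a lambda stack (one plane per 10-nm
emission band, by default 480-690 nm), FITC/TRITC channel images derived
from it by band integration, and the ground-truth tissue and blood masks
that make parameter-recovery tests possible.

Emission curves are modelled as single Gaussians — the simplest shape that
reproduces a unimodal peak and a 20-nm shift.  Erythrocytes replace the
tissue fluorophore within their footprint (eosin bound to the erythrocyte
is the red-shifted species), so blood pixels carry a pure blood spectrum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from .quantify import ChannelPair
from .spectral import LambdaStack

__all__ = [
    "SpectralModel",
    "EllipseRegion",
    "NoiseModel",
    "PhantomSpec",
    "Phantom",
    "emission_spectrum",
    "integrate_band",
    "render_phantom",
    "FITC_BAND",
    "TRITC_BAND",
    "DEFAULT_WAVELENGTH_GRID",
]

#: Emission pass bands of the widefield filter sets, nm.
FITC_BAND = (520.0, 540.0)
TRITC_BAND = (570.0, 610.0)

#: Default spectral sampling: 10-nm bands stepped from 480 to 690 nm.
DEFAULT_WAVELENGTH_GRID = tuple(float(w) for w in range(480, 691, 10))

# Erythrocyte donut geometry: dark core diameter and relative intensity.
RBC_CORE_DIAMETER_FRACTION = 0.4
RBC_CORE_INTENSITY = 0.3

# Per-cell brightness variability (uniform range).  Real erythrocytes take
# up eosin unevenly, so the bright blood mode smears into a continuum
# instead of a single isolated grey level.
_RBC_BRIGHTNESS_RANGE = (0.75, 1.0)

# Tissue rendering: correlation lengths (px) of the coverage field and the
# staining-intensity texture, and the texture's intensity range.  The range
# straddles unity so the brightest tissue outshines the erythrocyte tail
# that leaks into the green (FITC) band, as in real sections where tissue
# dominates the green channel.
_MASK_FIELD_SIGMA_PX = 20.0
_TEXTURE_SIGMA_PX = 10.0
_TEXTURE_RANGE = (0.7, 1.2)

_PLACEMENT_ATTEMPTS = 2000


@dataclass(frozen=True)
class SpectralModel:
    """Gaussian emission model: amplitude * exp(-(l - peak)^2 / (2 sigma^2))."""

    peak_wavelength: float
    bandwidth_sigma: float
    amplitude: float

    def __post_init__(self) -> None:
        if not 400.0 <= self.peak_wavelength <= 750.0:
            raise ValueError("peak_wavelength must lie in [400, 750] nm")
        if self.bandwidth_sigma <= 0:
            raise ValueError("bandwidth_sigma must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


def emission_spectrum(model: SpectralModel, grid) -> np.ndarray:
    """Evaluate a Gaussian emission model on a wavelength grid (nm).

    Intensities are non-negative everywhere and maximal at the grid point
    nearest the model's peak.
    """
    grid = np.asarray(grid, dtype=np.float64)
    if grid.size == 0:
        raise ValueError("empty wavelength grid")
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("wavelength grid must be 1-D and strictly increasing")
    z = (grid - model.peak_wavelength) / model.bandwidth_sigma
    return model.amplitude * np.exp(-0.5 * z**2)


@dataclass(frozen=True)
class EllipseRegion:
    """Ellipse in pixel coordinates: centre (row, col), semi-axes, rotation."""

    center: tuple[float, float]
    axes: tuple[float, float]
    angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if min(self.axes) <= 0:
            raise ValueError("ellipse semi-axes must be positive")

    @property
    def area(self) -> float:
        return math.pi * self.axes[0] * self.axes[1]

    def shrunk(self, margin: float) -> "EllipseRegion | None":
        """The ellipse with both semi-axes reduced by ``margin`` px, or None."""
        a, b = self.axes[0] - margin, self.axes[1] - margin
        if a <= 0 or b <= 0:
            return None
        return EllipseRegion(center=self.center, axes=(a, b), angle_deg=self.angle_deg)

    def _local(self, dr: np.ndarray, dc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        th = math.radians(self.angle_deg)
        p = dr * math.cos(th) + dc * math.sin(th)
        q = -dr * math.sin(th) + dc * math.cos(th)
        return p, q

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        p, q = self._local(rows - self.center[0], cols - self.center[1])
        return (p / self.axes[0]) ** 2 + (q / self.axes[1]) ** 2 <= 1.0

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
        return self.contains(rows.astype(np.float64), cols.astype(np.float64))

    def sample_point(self, rng: np.random.Generator) -> tuple[float, float]:
        """Uniform random point inside the ellipse."""
        r = math.sqrt(rng.uniform())
        th = rng.uniform(0.0, 2.0 * math.pi)
        p, q = self.axes[0] * r * math.cos(th), self.axes[1] * r * math.sin(th)
        rot = math.radians(self.angle_deg)
        dr = p * math.cos(rot) - q * math.sin(rot)
        dc = p * math.sin(rot) + q * math.cos(rot)
        return self.center[0] + dr, self.center[1] + dc


@dataclass(frozen=True)
class NoiseModel:
    """Shot + read noise: scaled Poisson resampling, then additive Gaussian.

    ``poisson_scale`` is the expected photon count per unit intensity
    (0 disables shot noise); ``gaussian_sigma`` is the read-noise standard
    deviation in intensity units (0 disables).
    """

    poisson_scale: float = 100.0
    gaussian_sigma: float = 0.005

    def __post_init__(self) -> None:
        if self.poisson_scale < 0 or self.gaussian_sigma < 0:
            raise ValueError("noise parameters must be non-negative")

    @property
    def enabled(self) -> bool:
        return self.poisson_scale > 0 or self.gaussian_sigma > 0


def _default_vessels() -> list[EllipseRegion]:
    return [
        EllipseRegion(center=(170.0, 160.0), axes=(110.0, 75.0), angle_deg=25.0),
        EllipseRegion(center=(360.0, 340.0), axes=(85.0, 60.0), angle_deg=-40.0),
    ]


@dataclass(frozen=True)
class PhantomSpec:
    """Complete, seeded description of a synthetic field.

    Defaults reproduce the reference scene: a 512 x 512 px field at
    0.32 um/px, tissue emission peaking at 550 nm, erythrocyte emission
    red-shifted to 570 nm at twice the amplitude, 5-um donut-shaped
    erythrocytes inside two elliptical vessels, and mild shot + read
    noise.  Rendering is deterministic in (spec, seed); the seed is
    mandatory — there is no unseeded mode.
    """

    seed: int
    width_px: int = 512
    height_px: int = 512
    pixel_size_um: float = 0.32
    wavelength_grid: tuple[float, ...] = DEFAULT_WAVELENGTH_GRID
    tissue_model: SpectralModel = SpectralModel(550.0, 30.0, 1.0)
    blood_model: SpectralModel = SpectralModel(570.0, 30.0, 2.0)
    rbc_diameter_um: float = 5.0
    rbc_count: int = 100
    rbc_min_separation_um: float = 0.0
    vessel_regions: tuple[EllipseRegion, ...] = field(default_factory=lambda: tuple(_default_vessels()))
    tissue_fill_fraction: float = 0.45
    noise: NoiseModel = NoiseModel()
    allow_dim_blood: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("a seed is mandatory; unseeded phantom generation is an error")
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        grid = tuple(float(w) for w in self.wavelength_grid)
        if len(grid) < 2 or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("wavelength_grid must be strictly increasing with >= 2 entries")
        if self.rbc_count < 0:
            raise ValueError("rbc_count must be >= 0")
        if self.rbc_min_separation_um < 0:
            raise ValueError("rbc_min_separation_um must be >= 0")
        if self.rbc_diameter_um / self.pixel_size_um < 3:
            raise ValueError(
                "erythrocytes unresolvable: rbc_diameter_um / pixel_size_um must be >= 3"
            )
        if not 0.0 <= self.tissue_fill_fraction <= 1.0:
            raise ValueError("tissue_fill_fraction must lie in [0, 1]")
        if not self.allow_dim_blood and self.blood_model.amplitude <= self.tissue_model.amplitude:
            raise ValueError(
                "blood must be brighter than tissue "
                "(set allow_dim_blood=True to override explicitly)"
            )
        object.__setattr__(self, "wavelength_grid", grid)
        object.__setattr__(self, "vessel_regions", tuple(self.vessel_regions))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PhantomSpec":
        data = dict(data)
        for key in ("tissue_model", "blood_model"):
            if key in data and isinstance(data[key], dict):
                data[key] = SpectralModel(**data[key])
        if "noise" in data and isinstance(data["noise"], dict):
            data["noise"] = NoiseModel(**data["noise"])
        vessels = []
        for v in data.get("vessel_regions", ()):
            if isinstance(v, dict):
                v = EllipseRegion(
                    center=tuple(v["center"]), axes=tuple(v["axes"]),
                    angle_deg=v.get("angle_deg", 0.0),
                )
            vessels.append(v)
        data["vessel_regions"] = tuple(vessels)
        if "wavelength_grid" in data:
            data["wavelength_grid"] = tuple(data["wavelength_grid"])
        return cls(**data)


@dataclass(frozen=True)
class Phantom:
    """Rendered synthetic scene with its ground truth."""

    stack: LambdaStack
    channels: ChannelPair
    tissue_mask: np.ndarray
    blood_mask: np.ndarray
    true_blood_percent: float
    spec: PhantomSpec

    def __post_init__(self) -> None:
        tissue = np.asarray(self.tissue_mask, dtype=bool)
        blood = np.asarray(self.blood_mask, dtype=bool)
        if tissue.shape != self.stack.shape or blood.shape != self.stack.shape:
            raise ValueError("masks and stack planes must share dimensions")
        if np.any(blood & ~tissue):
            raise ValueError("blood mask must lie inside the tissue mask")
        object.__setattr__(self, "tissue_mask", tissue)
        object.__setattr__(self, "blood_mask", blood)


def integrate_band(stack: LambdaStack, band: tuple[float, float]) -> np.ndarray:
    """Sum the stack planes whose band centres fall in [low, high] nm.

    Emulates a band-pass emission filter in front of a monochrome camera;
    the defaults :data:`FITC_BAND` (520-540 nm) and :data:`TRITC_BAND`
    (570-610 nm) match the widefield filter sets.
    """
    low, high = float(band[0]), float(band[1])
    if high < low:
        raise ValueError("band must be (low, high) with low <= high")
    sel = (stack.wavelengths >= low) & (stack.wavelengths <= high)
    if not np.any(sel):
        raise ValueError("band outside stack range")
    return stack.planes[sel].sum(axis=0)


def _rescale(field_img: np.ndarray, lo: float, hi: float) -> np.ndarray:
    fmin, fmax = float(field_img.min()), float(field_img.max())
    if fmax == fmin:
        return np.full_like(field_img, 0.5 * (lo + hi))
    return lo + (field_img - fmin) / (fmax - fmin) * (hi - lo)


def _tissue_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    shape = spec.shape
    if spec.tissue_fill_fraction >= 1.0:
        mask = np.ones(shape, dtype=bool)
    elif spec.tissue_fill_fraction <= 0.0:
        mask = np.zeros(shape, dtype=bool)
    else:
        fld = gaussian_filter(rng.standard_normal(shape), _MASK_FIELD_SIGMA_PX)
        mask = fld >= np.quantile(fld, 1.0 - spec.tissue_fill_fraction)
    for vessel in spec.vessel_regions:
        mask |= vessel.mask(shape)
    return mask


def _place_rbcs(spec: PhantomSpec, rng: np.random.Generator) -> list[tuple[float, float]]:
    radius_px = 0.5 * spec.rbc_diameter_um / spec.pixel_size_um
    pools = [v.shrunk(radius_px) for v in spec.vessel_regions]
    pools = [p for p in pools if p is not None]
    if not pools:
        raise ValueError("no vessel region to place erythrocytes")
    weights = np.array([p.area for p in pools])
    weights = weights / weights.sum()
    min_sep_px = spec.rbc_min_separation_um / spec.pixel_size_um

    centers: list[tuple[float, float]] = []
    for _ in range(spec.rbc_count):
        for _attempt in range(_PLACEMENT_ATTEMPTS):
            pool = pools[rng.choice(len(pools), p=weights)]
            cand = pool.sample_point(rng)
            if min_sep_px > 0 and any(
                math.hypot(cand[0] - r, cand[1] - c) < min_sep_px for r, c in centers
            ):
                continue
            centers.append(cand)
            break
        else:
            raise RuntimeError(
                "could not place erythrocytes at the requested separation; "
                "reduce rbc_count or rbc_min_separation_um"
            )
    return centers


def _rasterize_rbcs(
    spec: PhantomSpec,
    centers: list[tuple[float, float]],
    brightness: np.ndarray,
    shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Donut intensity profile (ring ~1.0, core dimmer) and the footprint mask."""
    radius_px = 0.5 * spec.rbc_diameter_um / spec.pixel_size_um
    core_px = RBC_CORE_DIAMETER_FRACTION * radius_px
    profile = np.zeros(shape, dtype=np.float64)
    footprint = np.zeros(shape, dtype=bool)
    reach = int(math.ceil(radius_px)) + 1
    for (r0, c0), bright in zip(centers, brightness):
        r_lo, r_hi = max(0, int(r0) - reach), min(shape[0], int(r0) + reach + 1)
        c_lo, c_hi = max(0, int(c0) - reach), min(shape[1], int(c0) + reach + 1)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        rows, cols = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        dist = np.hypot(rows - r0, cols - c0)
        inside = dist <= radius_px
        local = bright * np.where(dist <= core_px, RBC_CORE_INTENSITY, 1.0) * inside
        view = profile[r_lo:r_hi, c_lo:c_hi]
        np.maximum(view, local, out=view)
        footprint[r_lo:r_hi, c_lo:c_hi] |= inside
    return profile, footprint


def render_phantom(spec: PhantomSpec) -> Phantom:
    """Render a phantom: lambda stack, channel pair and ground-truth masks.

    Deterministic in the spec (including its seed): identical specs yield
    bit-identical phantoms.  Noise perturbs only the rendered intensities;
    the ground-truth masks and the true blood percentage are drawn before
    noise and are invariant to the noise settings.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape

    tissue_mask = _tissue_mask(spec, rng)

    if spec.rbc_count > 0:
        if not spec.vessel_regions:
            raise ValueError("no vessel region to place erythrocytes")
        centers = _place_rbcs(spec, rng)
        brightness = rng.uniform(*_RBC_BRIGHTNESS_RANGE, size=len(centers))
        blood_profile, blood_mask = _rasterize_rbcs(spec, centers, brightness, shape)
        # erythrocytes sit inside vessels, which are part of the tissue mask
        blood_mask &= tissue_mask
        blood_profile = np.where(blood_mask, blood_profile, 0.0)
    else:
        blood_profile = np.zeros(shape, dtype=np.float64)
        blood_mask = np.zeros(shape, dtype=bool)

    texture = _rescale(
        gaussian_filter(rng.standard_normal(shape), _TEXTURE_SIGMA_PX), *_TEXTURE_RANGE
    )
    # erythrocytes displace the tissue fluorophore within their footprint
    tissue_field = np.where(tissue_mask & ~blood_mask, texture, 0.0)

    grid = np.asarray(spec.wavelength_grid)
    tissue_spec = emission_spectrum(spec.tissue_model, grid)
    blood_spec = emission_spectrum(spec.blood_model, grid)
    planes = (
        tissue_field[None, :, :] * tissue_spec[:, None, None]
        + blood_profile[None, :, :] * blood_spec[:, None, None]
    )

    if spec.noise.poisson_scale > 0:
        planes = rng.poisson(planes * spec.noise.poisson_scale) / spec.noise.poisson_scale
    if spec.noise.gaussian_sigma > 0:
        planes = planes + rng.normal(0.0, spec.noise.gaussian_sigma, planes.shape)
    planes = np.maximum(planes, 0.0)

    stack = LambdaStack(wavelengths=grid, planes=planes, pixel_size_um=spec.pixel_size_um)
    channels = ChannelPair(
        fitc=integrate_band(stack, FITC_BAND),
        tritc=integrate_band(stack, TRITC_BAND),
        pixel_size_um=spec.pixel_size_um,
    )

    n_tissue = int(tissue_mask.sum())
    n_blood = int(blood_mask.sum())
    true_percent = 100.0 * n_blood / n_tissue if n_tissue else 0.0
    return Phantom(
        stack=stack,
        channels=channels,
        tissue_mask=tissue_mask,
        blood_mask=blood_mask,
        true_blood_percent=true_percent,
        spec=spec,
    )
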