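"""Synthetic cellular phantoms: clean hyperspectral Raman cubes with known truth.

Each phantom is a linear mixture

    cube = background + Σ_c  abundance_c ⊗ spectrum_c

where ``abundance_c`` is an H×W map, ``spectrum_c`` a length-B component
spectrum (sum of Lorentzian or Gaussian lines), and ``⊗`` the outer product
over space × spectrum.  Cells are ellipses with a nucleus sub-ellipse that
carries elevated nucleic-acid abundance; cytoplasm carries protein and lipid.
This reproduces the qualitative structure of cellular Raman maps (DNA band
near 790 cm⁻¹, CH₂ deformation near 1450 cm⁻¹, amide I / C=C near
1660 cm⁻¹) with exactly known ground truth — it makes no claim of
biological realism.

The generator is fully seeded: one ``PhantomSpec`` + one seed is one cube,
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from raman3d.cube import HyperspectralCube
from raman3d.errors import PlacementError, ValidationError

Lineshape = Literal["gaussian", "lorentzian"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SpectralComponent:
    """A named biochemical component: a list of Raman lines.

    ``peaks`` is a sequence of ``(center_cm1, fwhm_cm1, amplitude)`` tuples;
    ``abundance_range`` the (low, high) of the uniform draw per cell;
    ``in_nucleus``/``in_cytoplasm`` restrict where the component lives.
    Raman lines are near-Lorentzian, so that is the default lineshape.
    """

    name: str
    peaks: Sequence[tuple[float, float, float]]
    lineshape: Lineshape = "lorentzian"
    abundance_range: tuple[float, float] = (0.5, 1.0)
    in_nucleus: bool = True
    in_cytoplasm: bool = True

    def __post_init__(self) -> None:
        for center, fwhm, amp in self.peaks:
            if fwhm <= 0:
                raise ValidationError(f"{self.name}: FWHM must be > 0, got {fwhm}")
            if amp < 0:
                raise ValidationError(f"{self.name}: amplitude must be >= 0, got {amp}")
        lo, hi = self.abundance_range
        if lo < 0 or hi < lo:
            raise ValidationError(f"{self.name}: bad abundance range {self.abundance_range}")


def default_components() -> list[SpectralComponent]:
    """Protein / lipid / DNA recipe echoing common cellular marker bands."""
    return [
        SpectralComponent(
            "protein",
            peaks=[(1003.0, 12.0, 60.0), (1450.0, 20.0, 45.0), (1660.0, 25.0, 55.0)],
            in_nucleus=True,
            in_cytoplasm=True,
        ),
        SpectralComponent(
            "lipid",
            peaks=[(1085.0, 18.0, 30.0), (1302.0, 16.0, 40.0), (1440.0, 18.0, 50.0)],
            in_nucleus=False,
            in_cytoplasm=True,
        ),
        SpectralComponent(
            "DNA",
            peaks=[(795.0, 14.0, 50.0), (1095.0, 16.0, 35.0), (1578.0, 14.0, 30.0)],
            in_nucleus=True,
            in_cytoplasm=False,
        ),
    ]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and spectral recipe for one clean phantom cube.

    Defaults emulate desk-scale versions of typical cellular HRI cubes
    (64×64 px, 500 bands over 500–1800 cm⁻¹).  ``blur_px`` smooths the
    abundance maps inside each cell so line profiles across a cell are
    non-trivial; the blur is re-masked to the cell support so abundances
    stay exactly zero outside cells.
    """

    height: int = 64
    width: int = 64
    n_bands: int = 500
    wn_start: float = 500.0
    wn_end: float = 1800.0
    n_cells: int = 3
    cell_radius_range: tuple[float, float] = (8.0, 14.0)
    components: Sequence[SpectralComponent] = field(default_factory=default_components)
    background_level: float = 5.0
    blur_px: float = 1.0
    nucleus_scale: float = 0.45
    allow_overlap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wn_end <= self.wn_start:
            raise ValidationError("wn_end must exceed wn_start")
        if self.n_bands < 2:
            raise ValidationError("n_bands must be >= 2")
        if self.n_cells < 0:
            raise ValidationError("n_cells must be >= 0")
        if self.background_level < 0:
            raise ValidationError("background_level must be >= 0")
        r_lo, r_hi = self.cell_radius_range
        if r_lo <= 0 or r_hi < r_lo:
            raise ValidationError(f"bad cell_radius_range {self.cell_radius_range}")
        if 2 * r_hi > min(self.height, self.width):
            raise ValidationError("cell radii do not fit within the image")

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.linspace(self.wn_start, self.wn_end, self.n_bands)


def make_component_spectrum(component: SpectralComponent, axis: np.ndarray) -> np.ndarray:
    """Evaluate a component's line spectrum on a wavenumber axis.

    The spectrum is the sum of one kernel per peak — Gaussian or Lorentzian
    with the stated center, FWHM and amplitude — and is nonnegative
    everywhere.  Raises if a peak center falls outside the axis range.
    """
    axis = np.asarray(axis, dtype=np.float64)
    if axis.ndim != 1 or (len(axis) > 1 and not np.all(np.diff(axis) > 0)):
        raise ValidationError("wavenumber axis must be 1-D and strictly increasing")
    spectrum = np.zeros_like(axis)
    for center, fwhm, amp in component.peaks:
        if not (axis[0] <= center <= axis[-1]):
            raise ValidationError(
                f"{component.name}: peak center {center} cm-1 outside axis "
                f"range [{axis[0]}, {axis[-1]}]"
            )
        if component.lineshape == "gaussian":
            sigma = fwhm * _FWHM_TO_SIGMA
            spectrum += amp * np.exp(-0.5 * ((axis - center) / sigma) ** 2)
        else:  # lorentzian
            hwhm = fwhm / 2.0
            spectrum += amp * hwhm**2 / ((axis - center) ** 2 + hwhm**2)
    return spectrum


def _ellipse_mask(h: int, w: int, cy: float, cx: float, ry: float, rx: float, theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - cy
    dx = xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * dx + st * dy
    v = -st * dx + ct * dy
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _place_cells(spec: PhantomSpec, rng: np.random.Generator) -> list[dict]:
    """Sample cell geometries; rejection-sample centers in non-overlap mode."""
    r_lo, r_hi = spec.cell_radius_range
    cells: list[dict] = []
    for _ in range(spec.n_cells):
        placed = False
        for _attempt in range(100):
            ry = rng.uniform(r_lo, r_hi)
            rx = rng.uniform(r_lo, r_hi)
            r_max = max(ry, rx)
            cy = rng.uniform(r_max, spec.height - r_max)
            cx = rng.uniform(r_max, spec.width - r_max)
            theta = rng.uniform(0, np.pi)
            if spec.allow_overlap or all(
                np.hypot(cy - c["cy"], cx - c["cx"]) > r_max + max(c["ry"], c["rx"])
                for c in cells
            ):
                cells.append(dict(cy=cy, cx=cx, ry=ry, rx=rx, theta=theta))
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place {spec.n_cells} non-overlapping cells in "
                f"{spec.height}x{spec.width} after 100 attempts"
            )
    return cells


def render_phantom(spec: PhantomSpec) -> tuple[HyperspectralCube, dict[str, np.ndarray]]:
    """Render one clean phantom cube and its per-component abundance maps.

    Returns the cube and a dict ``{component name: H×W abundance map}``.  The
    cube equals ``background + Σ_c abundance_c ⊗ spectrum_c`` exactly (up to
    float64 rounding), so callers can reconstruct it from the returned maps.
    """
    rng = np.random.default_rng(spec.seed)
    axis = spec.wavenumbers
    spectra = {c.name: make_component_spectrum(c, axis) for c in spec.components}
    cells = _place_cells(spec, rng)

    maps = {c.name: np.zeros((spec.height, spec.width)) for c in spec.components}
    for cell in cells:
        body = _ellipse_mask(spec.height, spec.width, cell["cy"], cell["cx"],
                             cell["ry"], cell["rx"], cell["theta"])
        nucleus = _ellipse_mask(
            spec.height, spec.width, cell["cy"], cell["cx"],
            cell["ry"] * spec.nucleus_scale, cell["rx"] * spec.nucleus_scale, cell["theta"],
        )
        cytoplasm = body & ~nucleus
        for comp in spec.components:
            lo, hi = comp.abundance_range
            level = rng.uniform(lo, hi)
            # per-pixel texture, smoothed then re-masked so support is exact
            texture = level * rng.uniform(0.6, 1.4, size=body.shape)
            if spec.blur_px > 0:
                texture = ndimage.gaussian_filter(texture, spec.blur_px)
            region = np.zeros(body.shape, dtype=bool)
            if comp.in_nucleus:
                region |= nucleus
                if comp.name.upper() == "DNA":
                    texture = texture * 1.6  # elevated nucleic acid in the nucleus
            if comp.in_cytoplasm:
                region |= cytoplasm
            maps[comp.name] = np.maximum(maps[comp.name], np.where(region, texture, 0.0))

    data = np.full((spec.height, spec.width, spec.n_bands), float(spec.background_level))
    for comp in spec.components:
        data += maps[comp.name][:, :, None] * spectra[comp.name][None, None, :]

    cube = HyperspectralCube(
        data=data, wavenumbers=axis, pixel_size=0.5, provenance="phantom",
    )
    return cube, maps


def component_spectra(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """The component spectra a phantom spec would mix, keyed by name."""
    axis = spec.wavenumbers
    return {c.name: make_component_spectrum(c, axis) for c in spec.components}


def generate_dataset(spec: PhantomSpec, n: int, base_seed: int) -> list[HyperspectralCube]:
    """Generate ``n`` clean phantoms with per-item seeds ``base_seed + i``."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    return [render_phantom(replace(spec, seed=base_seed + i))[0] for i in range(n)]
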