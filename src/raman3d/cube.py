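"""Hyperspectral cube data model, HDF5 container round-trip, normalization.

A cube is an ``H×W×B`` intensity volume: ``H`` and ``W`` are spatial pixels,
``B`` is the number of spectral bands, and the spectral axis is always last.
The wavenumber axis (Raman shift, cm⁻¹) is strictly increasing and has
length ``B``.

Container layout (HDF5, ``format_version`` "1.0")::

    /cube              float32, H×W×B
    /wavenumber_cm1    float64, B
    attrs: pixel_size_um (optional), integration_time_s (optional),
           provenance, format_version

Intensities are stored as 32-bit floats (deep-learning numerics), the axis
as 64-bit floats so band positions stay exact.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional

import h5py
import numpy as np

from raman3d.errors import FormatError, ShapeError, ValidationError

FORMAT_VERSION = "1.0"


@dataclass
class HyperspectralCube:
    """An H×W×B Raman intensity volume plus its wavenumber axis.

    Parameters
    ----------
    data:
        3-axis array of intensities (arbitrary units, finite).  Axis order is
        fixed as (height, width, band) with the spectral axis last.
    wavenumbers:
        Strictly increasing Raman-shift axis in cm⁻¹, length ``B``.
    pixel_size:
        Spatial resolution in µm (optional, > 0 when given).
    integration_time:
        Acquisition time per pixel in seconds (optional).
    provenance:
        Free-text origin tag, e.g. ``"phantom"`` or an instrument/dataset name.
    """

    data: np.ndarray
    wavenumbers: np.ndarray
    pixel_size: Optional[float] = None
    integration_time: Optional[float] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=np.float64)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ShapeError(f"cube data must have 3 axes (H, W, B), got {self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ShapeError(f"cube axes must all be >= 1, got shape {self.data.shape}")
        if self.wavenumbers.ndim != 1 or len(self.wavenumbers) != self.data.shape[2]:
            raise ShapeError(
                f"wavenumber axis length {self.wavenumbers.shape} does not match "
                f"B={self.data.shape[2]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("cube data contains NaN or Inf")
        if len(self.wavenumbers) > 1 and not np.all(np.diff(self.wavenumbers) > 0):
            raise ValidationError("wavenumber axis must be strictly increasing")
        if self.pixel_size is not None and not self.pixel_size > 0:
            raise ValidationError(f"pixel_size must be > 0, got {self.pixel_size}")

    # -- conveniences -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def spectrum_at(self, row: int, col: int) -> np.ndarray:
        """Return the single-pixel spectrum at (row, col)."""
        return self.data[row, col, :]

    def with_data(self, data: np.ndarray) -> "HyperspectralCube":
        """A copy of this cube with the intensity volume replaced."""
        return replace(self, data=data)


@dataclass(frozen=True)
class ScaleRecord:
    """Global extrema used by min-max scaling, kept to invert it.

    ``degenerate`` marks a constant cube (``x_max == x_min``), which
    normalizes to all zeros rather than raising — background tiles in a batch
    pipeline should not abort a run.
    """

    x_min: float
    x_max: float
    degenerate: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.x_max < self.x_min:
            raise ValidationError(f"x_max {self.x_max} < x_min {self.x_min}")


def min_max_normalize(cube: HyperspectralCube) -> tuple[HyperspectralCube, ScaleRecord]:
    """Scale a cube to [0, 1] with ONE global (min, max) pair.

    The extrema are taken over all ``H·W·B`` voxels of the cube — not per
    band — so relative band intensities are preserved.  Returns the scaled
    cube (float64) and the :class:`ScaleRecord` needed by
    :func:`min_max_denormalize`.
    """
    x = np.asarray(cube.data, dtype=np.float64)
    x_min = float(x.min())
    x_max = float(x.max())
    if x_max == x_min:
        return cube.with_data(np.zeros_like(x)), ScaleRecord(x_min, x_max, degenerate=True)
    scaled = (x - x_min) / (x_max - x_min)
    return cube.with_data(scaled), ScaleRecord(x_min, x_max, degenerate=False)


def min_max_denormalize(cube: HyperspectralCube, record: ScaleRecord) -> HyperspectralCube:
    """Invert :func:`min_max_normalize` using its ScaleRecord."""
    x = np.asarray(cube.data, dtype=np.float64)
    if record.degenerate:
        return cube.with_data(np.full_like(x, record.x_min))
    return cube.with_data(x * (record.x_max - record.x_min) + record.x_min)


def write_cube(cube: HyperspectralCube, path: str | os.PathLike, overwrite: bool = False) -> None:
    """Write a cube to the HDF5 container layout.

    Refuses to clobber an existing file unless ``overwrite=True``.
    """
    cube.validate()
    path = os.fspath(path)
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    with h5py.File(path, "w") as f:
        f.create_dataset("cube", data=cube.data.astype(np.float32))
        f.create_dataset("wavenumber_cm1", data=cube.wavenumbers.astype(np.float64))
        if cube.pixel_size is not None:
            f.attrs["pixel_size_um"] = float(cube.pixel_size)
        if cube.integration_time is not None:
            f.attrs["integration_time_s"] = float(cube.integration_time)
        f.attrs["provenance"] = cube.provenance
        f.attrs["format_version"] = FORMAT_VERSION


def read_cube(path: str | os.PathLike) -> HyperspectralCube:
    """Read a cube from the HDF5 container layout, validating invariants."""
    path = os.fspath(path)
    with h5py.File(path, "r") as f:
        for name in ("cube", "wavenumber_cm1"):
            if name not in f:
                raise FormatError(f"{path!s} is missing required dataset '/{name}'")
        data = f["cube"][()]
        wn = f["wavenumber_cm1"][()]
        pixel_size = f.attrs.get("pixel_size_um")
        integration_time = f.attrs.get("integration_time_s")
        provenance = f.attrs.get("provenance", "")
    if data.ndim != 3:
        raise ShapeError(f"/cube in {path!s} has {data.ndim} axes, expected 3")
    if wn.ndim != 1 or len(wn) != data.shape[2]:
        raise ShapeError(
            f"/wavenumber_cm1 length {wn.shape} does not match /cube bands {data.shape[2]}"
        )
    return HyperspectralCube(
        data=data,
        wavenumbers=wn,
        pixel_size=float(pixel_size) if pixel_size is not None else None,
        integration_time=float(integration_time) if integration_time is not None else None,
        provenance=str(provenance),
    )


def export_spectrum_csv(cube: HyperspectralCube, row: int, col: int, path: str | os.PathLike) -> None:
    """Dump one pixel's spectrum as a two-column CSV for inspection."""
    spec = cube.spectrum_at(row, col)
    arr = np.column_stack([cube.wavenumbers, spec])
    np.savetxt(path, arr, delimiter=",", header="wavenumber_cm1,intensity", comments="")
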