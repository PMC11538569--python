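"""Conversion of a conjugated hologram phase into a printable pixel relief.

Each lens pixel is a square resin pillar of height h on a Delta_w lattice.
The complex transmission of a pillar between the lens bottom (z = 0) and the
holographic surface at z = l is the Fabry–Perot slab coefficient

    T(h) = 2 Z exp(-i k0 [l - h]) / (2 Z cos(kL h) + i (Z^2 + 1) sin(kL h)),

with Z = Z_lens / Z_outer the normalized impedance, k0 and kL the water and
resin wavenumbers.  The lens is designed phase-only: for each pixel the
height whose arg T(h) best matches the conjugated hologram phase is chosen
by exhaustive scan (arg T is non-monotone across slab resonances, so scanning
is more robust than root finding and costs little for ~10^3 pixels).  The
|T(h)| amplitude variation is recorded per pixel for diagnostics but not
inverted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Medium, wavenumber, wrap_phase
from .errors import GeometryError, InvalidArgumentError, InvalidStateError
from .holography import Hologram

__all__ = [
    "LensSpec",
    "HeightMap",
    "slab_T",
    "slab_phase",
    "solve_height",
    "design_height_map",
    "quantize_heights",
]

#: Total build height of the printed part, m (base slab + tallest pixel).
TOTAL_BUILD_HEIGHT = 2e-3


@dataclass(frozen=True)
class LensSpec:
    """Geometry and materials of the pixelated holographic lens.

    aperture : (width, height) m
    pixel_width : square pixel pitch Delta_w, m
    base_thickness : the distance l from the lens bottom to the holographic
        surface used as the phase reference in T(h), m
    h_max : tallest admissible pixel, m
    print_resolution : stereolithography voxel pitch used for quantization, m
    """

    aperture: tuple[float, float] = (10e-3, 10e-3)
    pixel_width: float = 0.25e-3
    base_thickness: float = 0.8e-3
    h_max: float = 1.2e-3
    lens_medium: Medium = Medium("lens", 1180.0, 2700.0, 1160.0)
    outer_medium: Medium = Medium("water", 1000.0, 1500.0)
    print_resolution: float = 100e-6

    def __post_init__(self):
        if self.pixel_width <= 0:
            raise InvalidArgumentError("pixel_width must be > 0")
        if not 0 < self.h_max:
            raise InvalidArgumentError("h_max must be > 0")
        if self.base_thickness + self.h_max > TOTAL_BUILD_HEIGHT + 1e-12:
            raise InvalidArgumentError(
                f"base_thickness + h_max exceeds the {TOTAL_BUILD_HEIGHT*1e3:g} mm build height"
            )
        for extent in self.aperture:
            n = extent / self.pixel_width
            if abs(n - round(n)) > 1e-9:
                raise InvalidArgumentError(
                    "aperture must divide into whole pixels"
                )

    @property
    def n_pixels(self) -> tuple[int, int]:
        return (
            int(round(self.aperture[0] / self.pixel_width)),
            int(round(self.aperture[1] / self.pixel_width)),
        )

    @property
    def normalized_impedance(self) -> float:
        """Z = Z_lens / Z_outer."""
        return self.lens_medium.impedance / self.outer_medium.impedance

    def pixel_centers(self, z: float = 0.0) -> np.ndarray:
        """(nx*ny, 3) pixel-center coordinates, aperture centered on (0,0,z)."""
        nx, ny = self.n_pixels
        x = (np.arange(nx) - (nx - 1) / 2) * self.pixel_width
        y = (np.arange(ny) - (ny - 1) / 2) * self.pixel_width
        xx, yy = np.meshgrid(x, y, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), np.full(xx.size, z)])


@dataclass
class HeightMap:
    """Per-pixel lens relief h(x, y) plus design diagnostics.

    heights and phase_residuals are (nx, ny) matrices in m and rad;
    target_phase keeps the per-pixel design phase so residuals can be
    recomputed after quantization.
    """

    lens: LensSpec
    frequency: float
    heights: np.ndarray
    phase_residuals: np.ndarray
    target_phase: np.ndarray
    quantized: bool = False

    def __post_init__(self):
        nx, ny = self.lens.n_pixels
        self.heights = np.asarray(self.heights, dtype=float).reshape(nx, ny)
        self.phase_residuals = np.asarray(self.phase_residuals, dtype=float).reshape(nx, ny)
        self.target_phase = np.asarray(self.target_phase, dtype=float).reshape(nx, ny)
        if np.any(self.heights < -1e-15) or np.any(self.heights > self.lens.h_max + 1e-15):
            raise InvalidArgumentError("pixel heights must lie in [0, h_max]")
        if np.any(np.abs(self.phase_residuals) > np.pi + 1e-12):
            raise InvalidArgumentError("phase residuals must lie in [-pi, pi]")

    def transmissions(self) -> np.ndarray:
        """Per-pixel complex T(h)."""
        return slab_T(self.heights, self.lens, self.frequency)

    def to_text(self, path) -> None:
        """Write the relief as a whitespace-delimited matrix in mm."""
        np.savetxt(
            path,
            self.heights * 1e3,
            header=(
                f"pixel heights (mm); pixel_width_mm={self.lens.pixel_width*1e3:g} "
                f"base_thickness_mm={self.lens.base_thickness*1e3:g} "
                f"quantized={self.quantized}"
            ),
        )


def slab_T(h, spec: LensSpec, frequency: float):
    """Complex transmission of a resin pillar of height ``h``.

    Vectorized over ``h``; raises for heights outside [0, h_max].  |T| <= 1
    always, with equality at h = 0 and at resin half-wave thicknesses
    (kL h = n pi).
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0) or np.any(h > spec.h_max + 1e-15):
        raise InvalidArgumentError("pixel height outside [0, h_max]")
    k0 = wavenumber(spec.outer_medium, frequency)
    kl = wavenumber(spec.lens_medium, frequency)
    z = spec.normalized_impedance
    num = 2.0 * z * np.exp(-1j * k0 * (spec.base_thickness - h))
    den = 2.0 * z * np.cos(kl * h) + 1j * (z**2 + 1.0) * np.sin(kl * h)
    return num / den


def slab_phase(h, spec: LensSpec, frequency: float):
    """Wrapped argument of :func:`slab_T` — the phase a pixel imposes."""
    return wrap_phase(np.angle(slab_T(h, spec, frequency)))


def solve_height(
    target_phase: float,
    spec: LensSpec,
    frequency: float,
    scan_step: float = 5e-6,
) -> tuple[float, float]:
    """Height in [0, h_max] whose slab phase best matches ``target_phase``.

    Exhaustive scan at ``scan_step`` pitch; ties broken toward the smaller
    height.  Returns (height, signed wrapped residual in rad).
    """
    if not -np.pi < target_phase <= np.pi + 1e-12:
        raise InvalidArgumentError("target_phase must lie in (-pi, pi]")
    grid = _height_scan_grid(spec, scan_step)
    phases = slab_phase(grid, spec, frequency)
    err = np.asarray(wrap_phase(phases - target_phase))
    idx = _first_minimum(np.abs(err))
    return float(grid[idx]), float(err[idx])


#: residuals within this of the minimum count as ties (float noise floor)
_TIE_TOL = 1e-9


def _first_minimum(abs_err: np.ndarray, axis: int = 0):
    """Index of the smallest-h residual minimum, treating near-equal
    residuals as ties broken toward smaller heights."""
    best = abs_err.min(axis=axis, keepdims=True)
    return np.asarray(abs_err <= best + _TIE_TOL).argmax(axis=axis)


def _height_scan_grid(spec: LensSpec, scan_step: float) -> np.ndarray:
    if scan_step <= 0 or spec.h_max < scan_step:
        raise InvalidArgumentError("scan step must satisfy 0 < scan_step <= h_max")
    n = int(np.floor(spec.h_max / scan_step))
    grid = np.arange(n + 1) * scan_step
    if grid[-1] < spec.h_max - 1e-15:
        grid = np.append(grid, spec.h_max)
    return grid


def design_height_map(
    hologram: Hologram,
    spec: LensSpec,
    frequency: float,
    scan_step: float = 5e-6,
) -> HeightMap:
    """One height solve per lens pixel from the conjugated hologram.

    The hologram plane must be congruent with the pixel lattice: same extent
    as the aperture and a spacing that divides the pixel width.  The design
    phase of a pixel is the argument of the mean complex pressure over its
    footprint, which is robust to sub-pixel phase gradients (center sampling
    is biased when the phase varies across the pixel).
    """
    if not hologram.conjugated:
        raise InvalidStateError("design requires a conjugated hologram")
    nx, ny = spec.n_pixels
    plane = hologram.plane
    sub = spec.pixel_width / plane.spacing
    if abs(sub - round(sub)) > 1e-9:
        raise GeometryError("plane spacing must divide the pixel width")
    sub = int(round(sub))
    if plane.shape != (nx * sub, ny * sub):
        raise GeometryError(
            f"plane shape {plane.shape} does not tile the {nx}x{ny} pixel aperture"
        )
    p = hologram.pressure.values.reshape(nx, sub, ny, sub)
    pixel_mean = p.mean(axis=(1, 3))
    target = np.asarray(wrap_phase(np.angle(pixel_mean)))

    grid = _height_scan_grid(spec, scan_step)
    table = slab_phase(grid, spec, frequency)  # (n_h,)
    err = np.asarray(wrap_phase(table[:, None] - target.ravel()[None, :]))  # (n_h, n_pix)
    idx = _first_minimum(np.abs(err), axis=0)
    heights = grid[idx].reshape(nx, ny)
    residuals = err[idx, np.arange(err.shape[1])].reshape(nx, ny)
    return HeightMap(
        lens=spec,
        frequency=frequency,
        heights=heights,
        phase_residuals=residuals,
        target_phase=target,
        quantized=False,
    )


def quantize_heights(height_map: HeightMap) -> HeightMap:
    """Round every pixel to the printer's height quantum and re-score.

    Heights are snapped to the nearest multiple of ``print_resolution`` and
    clamped to [0, h_max]; phase residuals are recomputed against the stored
    design phases.  Idempotent: re-quantizing changes nothing.
    """
    spec = height_map.lens
    q = np.round(height_map.heights / spec.print_resolution) * spec.print_resolution
    q = np.clip(q, 0.0, spec.h_max)
    residuals = np.asarray(
        wrap_phase(
            slab_phase(q, spec, height_map.frequency) - height_map.target_phase
        )
    )
    return HeightMap(
        lens=spec,
        frequency=height_map.frequency,
        heights=q,
        phase_residuals=residuals,
        target_phase=height_map.target_phase.copy(),
        quantized=True,
    )
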