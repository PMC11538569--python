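"""Media, sampling grids, complex pressure fields, and the monochromatic
Rayleigh–Sommerfeld point-source propagator.

The propagator evaluates the discrete form of the Rayleigh–Sommerfeld
diffraction integral for a cloud of monopole sources,

    p(d) = (i omega rho0 / 2 pi) * sum_j  s_j * exp(-i k0 |d - d_j|) / |d - d_j|,

where each source strength ``s_j`` carries the particle velocity times its
surface element (u0 dS).  The time convention is exp(+i omega t), so an
outgoing wave is exp(-i k r); every module in the package shares it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import yaml

from .errors import InvalidArgumentError, SingularEvaluationError

__all__ = [
    "Medium",
    "BUILTIN_MEDIA",
    "load_media_registry",
    "PlanarGrid",
    "VolumeGrid",
    "ComplexPressureField",
    "PhaseMap",
    "wavenumber",
    "wrap_phase",
    "phase_of",
    "rs_propagate",
    "piston_on_axis",
]


@dataclass(frozen=True)
class Medium:
    """A homogeneous fluid-like acoustic medium.

    Parameters
    ----------
    name : str
        Label used in config files and reports.
    density : float
        Mass density, kg/m^3.
    c_long : float
        Longitudinal (compressional) sound speed, m/s.
    c_shear : float or None
        Transversal (shear) speed, m/s, for solid media; ``None`` for fluids.
        Recorded for completeness; propagation in this package is purely
        longitudinal.
    """

    name: str
    density: float
    c_long: float
    c_shear: float | None = None

    def __post_init__(self):
        if self.density <= 0:
            raise InvalidArgumentError(f"density must be > 0, got {self.density}")
        if self.c_long <= 0:
            raise InvalidArgumentError(f"c_long must be > 0, got {self.c_long}")
        if self.c_shear is not None and self.c_shear < 0:
            raise InvalidArgumentError(f"c_shear must be >= 0, got {self.c_shear}")

    @property
    def impedance(self) -> float:
        """Characteristic longitudinal impedance rho * c, Pa s/m (rayl)."""
        return self.density * self.c_long


#: Water, photosensitive printing resin, and mouse skull at 3 MHz.
BUILTIN_MEDIA: dict[str, Medium] = {
    "water": Medium("water", 1000.0, 1500.0),
    "lens": Medium("lens", 1180.0, 2700.0, 1160.0),
    "skull": Medium("skull", 1912.0, 2300.0, 1626.0),
}


def load_media_registry(path) -> dict[str, Medium]:
    """Read a media registry from a YAML or JSON mapping.

    Each entry maps a name to ``{density, c_long, c_shear?}`` in SI units.
    """
    text = open(path).read()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    registry = {}
    for name, props in data.items():
        registry[name] = Medium(
            name=name,
            density=float(props["density"]),
            c_long=float(props["c_long"]),
            c_shear=None if props.get("c_shear") in (None, "null") else float(props["c_shear"]),
        )
    return registry


@dataclass(frozen=True)
class PlanarGrid:
    """A regular square-sample lattice on a plane.

    ``origin`` is the center of the first (index [0, 0]) sample; ``axes`` are
    two orthonormal in-plane direction vectors; ``spacing`` is the sample
    pitch along both axes.
    """

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int]
    axes: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (1.0, 0.0, 0.0),
        (0.0, 1.0, 0.0),
    )

    def __post_init__(self):
        if self.spacing <= 0:
            raise InvalidArgumentError("grid spacing must be > 0")
        a = np.asarray(self.axes, dtype=float)
        if not (
            np.allclose(np.linalg.norm(a, axis=1), 1.0, atol=1e-12)
            and abs(a[0] @ a[1]) < 1e-12
        ):
            raise InvalidArgumentError("plane axes must be orthonormal")

    @property
    def n_points(self) -> int:
        return self.shape[0] * self.shape[1]

    def points(self) -> np.ndarray:
        """Sample positions as an (n0*n1, 3) array, row-major in (i, j)."""
        i, j = np.meshgrid(
            np.arange(self.shape[0]), np.arange(self.shape[1]), indexing="ij"
        )
        a0 = np.asarray(self.axes[0])
        a1 = np.asarray(self.axes[1])
        pts = (
            np.asarray(self.origin)
            + i.reshape(-1, 1) * self.spacing * a0
            + j.reshape(-1, 1) * self.spacing * a1
        )
        return pts

    @classmethod
    def centered(cls, center, extent, spacing) -> "PlanarGrid":
        """Build an xy-plane grid of the given (wx, wy) extent centered on
        ``center``, with samples at cell centers."""
        nx = int(round(extent[0] / spacing))
        ny = int(round(extent[1] / spacing))
        origin = (
            center[0] - extent[0] / 2 + spacing / 2,
            center[1] - extent[1] / 2 + spacing / 2,
            center[2],
        )
        return cls(origin=origin, spacing=spacing, shape=(nx, ny))


@dataclass(frozen=True)
class VolumeGrid:
    """A regular axis-aligned 3D sampling lattice."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise InvalidArgumentError("all grid spacings must be > 0")

    @property
    def n_points(self) -> int:
        return int(np.prod(self.shape))

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def points(self) -> np.ndarray:
        xs = [self.axis_coords(k) for k in range(3)]
        g = np.meshgrid(*xs, indexing="ij")
        return np.stack([c.ravel() for c in g], axis=1)

    @classmethod
    def from_bounds(cls, bounds, spacing) -> "VolumeGrid":
        """Grid spanning ``bounds = ((x0,x1),(y0,y1),(z0,z1))`` inclusive of
        both ends, with pitch ``spacing`` (scalar or per-axis)."""
        sp = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
        shape = tuple(int(round((b[1] - b[0]) / s)) + 1 for b, s in zip(bounds, sp))
        return cls(
            origin=tuple(float(b[0]) for b in bounds),
            spacing=tuple(float(s) for s in sp),
            shape=shape,
        )


@dataclass
class ComplexPressureField:
    """Monochromatic complex pressure sampled on a planar or volume grid.

    ``values`` has the grid's shape; Pa; time convention exp(+i omega t).
    """

    grid: PlanarGrid | VolumeGrid
    values: np.ndarray
    frequency: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=complex).reshape(self.grid.shape)
        if self.frequency <= 0:
            raise InvalidArgumentError("frequency must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("field values must be finite")

    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    def to_text(self, path) -> None:
        """Write samples as delimited text columns x, y, z, Re(p), Im(p)."""
        pts = self.grid.points()
        v = self.values.ravel()
        data = np.column_stack([pts, v.real, v.imag])
        np.savetxt(path, data, header="x_m y_m z_m re_pa im_pa")

    def save(self, path) -> None:
        """Write the documented binary grid container (NumPy .npz).

        Keys: kind, origin, shape, frequency, values, and spacing (volume) or
        spacing+axes (plane).
        """
        g = self.grid
        if isinstance(g, VolumeGrid):
            np.savez(
                path, kind="volume", origin=g.origin, spacing=g.spacing,
                shape=g.shape, frequency=self.frequency, values=self.values,
            )
        else:
            np.savez(
                path, kind="plane", origin=g.origin, spacing=g.spacing,
                shape=g.shape, axes=np.asarray(g.axes), frequency=self.frequency,
                values=self.values,
            )

    @classmethod
    def load(cls, path) -> "ComplexPressureField":
        with np.load(path, allow_pickle=False) as z:
            kind = str(z["kind"])
            if kind == "volume":
                grid = VolumeGrid(
                    origin=tuple(z["origin"]),
                    spacing=tuple(z["spacing"]),
                    shape=tuple(int(n) for n in z["shape"]),
                )
            else:
                grid = PlanarGrid(
                    origin=tuple(z["origin"]),
                    spacing=float(z["spacing"]),
                    shape=tuple(int(n) for n in z["shape"]),
                    axes=tuple(map(tuple, z["axes"])),
                )
            return cls(grid=grid, values=z["values"], frequency=float(z["frequency"]))


@dataclass
class PhaseMap:
    """Phase samples on a planar grid, wrapped to (-pi, pi]."""

    grid: PlanarGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).reshape(self.grid.shape)
        if np.any(self.values <= -np.pi) or np.any(self.values > np.pi):
            raise InvalidArgumentError("phase values must lie in (-pi, pi]")


def wavenumber(medium: Medium, frequency: float) -> float:
    """Longitudinal wavenumber k = 2 pi f / c, rad/m."""
    if frequency <= 0:
        raise InvalidArgumentError(f"frequency must be > 0, got {frequency}")
    return 2.0 * np.pi * frequency / medium.c_long


def wrap_phase(phi):
    """Wrap angles to the half-open interval (-pi, pi]."""
    w = np.remainder(np.asarray(phi, dtype=float), 2.0 * np.pi)
    return np.where(w > np.pi, w - 2.0 * np.pi, w)


def phase_of(field: ComplexPressureField) -> PhaseMap:
    """Full-circle argument of the pressure, wrapped to (-pi, pi].

    Zero-magnitude samples map to phase 0 by convention (the argument is
    undefined there and a fixed value keeps the map total).
    """
    v = field.values
    phi = np.angle(v)
    phi = np.asarray(wrap_phase(phi))
    phi[v == 0] = 0.0
    return PhaseMap(grid=field.grid, values=phi)


def rs_propagate(
    source_positions,
    source_strengths,
    eval_points,
    medium: Medium,
    frequency: float,
    min_distance: float = 1e-9,
    chunk_size: int = 2_000_000,
) -> np.ndarray:
    """Discrete Rayleigh–Sommerfeld sum from monopole sources to field points.

    Parameters
    ----------
    source_positions : (M, 3) array
        Source locations, m.
    source_strengths : (M,) complex array
        u0 dS per source (particle velocity times surface element), m^3/s.
    eval_points : (N, 3) array
        Evaluation positions, m.
    medium, frequency
        Propagation medium and frequency, Hz.
    min_distance : float
        Singularity guard: any source–point distance at or below this raises
        :class:`SingularEvaluationError`.  Callers use one tenth of the local
        grid spacing.
    chunk_size : int
        Maximum number of (source, point) pairs evaluated per block; bounds
        memory, does not change the result.

    Returns
    -------
    (N,) complex array of pressures, Pa.
    """
    src = np.atleast_2d(np.asarray(source_positions, dtype=float))
    s = np.asarray(source_strengths, dtype=complex).ravel()
    pts = np.atleast_2d(np.asarray(eval_points, dtype=float))
    if src.shape[0] != s.shape[0]:
        raise InvalidArgumentError("one strength per source position required")
    k = wavenumber(medium, frequency)
    omega = 2.0 * np.pi * frequency
    prefac = 1j * omega * medium.density / (2.0 * np.pi)

    n_pts = pts.shape[0]
    out = np.empty(n_pts, dtype=complex)
    rows = max(1, chunk_size // max(1, src.shape[0]))
    for start in range(0, n_pts, rows):
        block = pts[start : start + rows]
        # (n_block, M) pairwise distances
        r = np.linalg.norm(block[:, None, :] - src[None, :, :], axis=2)
        if np.any(r <= min_distance):
            raise SingularEvaluationError(
                f"evaluation point within {min_distance:g} m of a source"
            )
        out[start : start + rows] = (np.exp(-1j * k * r) / r) @ s
    return prefac * out


def piston_on_axis(
    radius: float, z: float, u0: float, medium: Medium, frequency: float
) -> complex:
    """Closed-form on-axis pressure of a baffled circular piston.

    p(z) = rho c u0 [exp(-i k z) - exp(-i k sqrt(z^2 + a^2))], the exact
    integral of the Rayleigh–Sommerfeld kernel over the piston face; its
    magnitude is 2 rho c u0 |sin((k/2)(sqrt(z^2+a^2) - z))|.  Serves as the
    independent oracle for the discrete propagator.
    """
    if z <= 0:
        raise InvalidArgumentError("axial distance z must be > 0")
    k = wavenumber(medium, frequency)
    rc = medium.impedance * u0
    return rc * (np.exp(-1j * k * z) - np.exp(-1j * k * np.hypot(z, radius)))


def disc_source_lattice(radius: float, spacing: float, center=(0.0, 0.0, 0.0),
                        rim_subsample: int = 8):
    """Midpoint-rule discretization of a circular piston face.

    Returns (positions, areas): lattice cell centers covering the disc and a
    per-cell area weight.  Interior cells carry spacing^2; cells cut by the
    rim carry their overlap area (estimated by ``rim_subsample``^2 sub-cell
    midpoints), which removes the O(spacing) staircase bias of a hard
    center-in-disc mask.  Used to feed :func:`rs_propagate` when validating
    against :func:`piston_on_axis`.
    """
    if spacing <= 0:
        raise InvalidArgumentError("spacing must be > 0")
    n = int(np.ceil(radius / spacing))
    c = (np.arange(-n, n + 1)) * spacing
    xx, yy = np.meshgrid(c, c, indexing="ij")
    half = spacing / 2.0
    r_near = np.hypot(np.maximum(np.abs(xx) - half, 0), np.maximum(np.abs(yy) - half, 0))
    r_far = np.hypot(np.abs(xx) + half, np.abs(yy) + half)
    weights = np.where(r_far <= radius, 1.0, 0.0)
    off = ((np.arange(rim_subsample) + 0.5) / rim_subsample - 0.5) * spacing
    ox, oy = np.meshgrid(off, off, indexing="ij")
    for i, j in zip(*np.where((r_far > radius) & (r_near < radius))):
        sx, sy = xx[i, j] + ox, yy[i, j] + oy
        weights[i, j] = np.mean(sx**2 + sy**2 <= radius**2)
    keep = weights > 0
    pos = np.column_stack(
        [xx[keep] + center[0], yy[keep] + center[1], np.full(keep.sum(), center[2])]
    )
    return pos, weights[keep] * spacing**2
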