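"""Time-reversal recording of multi-focal targets through a skull layer.

The design step places clouds of virtual point sources at the desired foci,
propagates them back to a holographic plane (the lens exit face) through a
flat skull slab, and phase-conjugates the recorded field.  Re-emitting the
conjugated phase from the plane refocuses the wave at the targets — the core
time-reversal property the lens exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    ComplexPressureField,
    Medium,
    PhaseMap,
    PlanarGrid,
    phase_of,
    rs_propagate,
    wavenumber,
    wrap_phase,
)
from .errors import GeometryError, InvalidArgumentError, InvalidStateError

__all__ = [
    "FocusTarget",
    "VirtualSourceSet",
    "SkullLayer",
    "Hologram",
    "make_virtual_sources",
    "slab_transmission",
    "skull_layer_transmission",
    "record_hologram",
    "conjugate",
]


@dataclass(frozen=True)
class FocusTarget:
    """One desired focal spot: center (m), relative amplitude, and the number
    of virtual sources spread over it."""

    center: tuple[float, float, float]
    amplitude: float = 1.0
    n_sources: int = 100

    def __post_init__(self):
        if self.n_sources < 1:
            raise InvalidArgumentError("n_sources must be >= 1")
        if self.amplitude <= 0:
            raise InvalidArgumentError("amplitude must be > 0")


@dataclass(frozen=True)
class SkullLayer:
    """A flat homogeneous skull slab at normal incidence.

    ``z_entry`` is the standoff of the slab face nearest the holographic
    plane; the slab occupies z in [z_entry, z_entry + thickness].  Only the
    longitudinal speed enters the transmission model; shear conversion in the
    thin (~lambda/3) layer is neglected.
    """

    medium: Medium
    thickness: float = 250e-6
    z_entry: float = 0.5e-3
    flat_slab: bool = True

    def __post_init__(self):
        if self.thickness <= 0:
            raise InvalidArgumentError("skull thickness must be > 0")
        if self.z_entry < 0:
            raise InvalidArgumentError("skull standoff must be >= 0")


@dataclass
class VirtualSourceSet:
    """Point sources with complex strengths used in the recording step."""

    positions: np.ndarray  # (M, 3) m
    strengths: np.ndarray  # (M,) complex
    carrier_wavenumber: float  # rad/m, the k_z of the arrival-phase carrier

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.strengths = np.asarray(self.strengths, dtype=complex).ravel()
        if self.positions.shape[0] == 0:
            raise InvalidArgumentError("source set must be nonempty")
        if not np.all(np.isfinite(self.strengths)):
            raise InvalidArgumentError("source strengths must be finite")


@dataclass
class Hologram:
    """Complex pressure and phase recorded (or conjugated) on a plane."""

    plane: PlanarGrid
    pressure: ComplexPressureField
    phase: PhaseMap
    conjugated: bool = False


def make_virtual_sources(
    targets: list[FocusTarget],
    jitter_radius: float,
    seed: int,
    carrier_wavenumber: float,
    mirror_x: bool = False,
) -> VirtualSourceSet:
    """Draw the per-focus virtual-source clouds.

    For each target, ``n_sources`` points are sampled uniformly (seeded)
    inside a ball of ``jitter_radius`` about its center; each strength is
    amplitude / n_sources times the carrier phase exp(i k_z z_center), which
    removes the nominal plane-wave arrival phase of the wavefront.
    Deterministic for a fixed seed.

    With ``mirror_x``, a target whose center is the x-mirror of an earlier
    target reuses that target's jitter cloud reflected through the x = 0
    plane, so bilaterally mirror-placed foci (paired anatomical nuclei) get
    exactly mirror-symmetric source sets and hence a symmetric lens.
    """
    if not targets:
        raise InvalidArgumentError("at least one focus target is required")
    if jitter_radius < 0:
        raise InvalidArgumentError("jitter_radius must be >= 0")
    rng = np.random.default_rng(seed)
    positions, strengths = [], []
    drawn: dict[tuple, np.ndarray] = {}
    for t in targets:
        n = t.n_sources
        mirror_key = (round(-t.center[0], 12), round(t.center[1], 12),
                      round(t.center[2], 12), n)
        if mirror_x and mirror_key in drawn:
            offsets = drawn[mirror_key] * np.array([-1.0, 1.0, 1.0])
        elif jitter_radius == 0:
            offsets = np.zeros((n, 3))
        else:
            direction = rng.normal(size=(n, 3))
            direction /= np.linalg.norm(direction, axis=1, keepdims=True)
            radii = jitter_radius * rng.random(n) ** (1.0 / 3.0)
            offsets = direction * radii[:, None]
        drawn[(round(t.center[0], 12), round(t.center[1], 12),
               round(t.center[2], 12), n)] = offsets
        positions.append(np.asarray(t.center) + offsets)
        carrier = np.exp(1j * carrier_wavenumber * t.center[2])
        strengths.append(np.full(n, t.amplitude / n) * carrier)
    return VirtualSourceSet(
        positions=np.vstack(positions),
        strengths=np.concatenate(strengths),
        carrier_wavenumber=carrier_wavenumber,
    )


def slab_transmission(
    inner: Medium, outer: Medium, thickness: float, frequency: float
) -> complex:
    """Normal-incidence pressure transmission through a fluid slab.

    Three-medium stack outer | inner | outer; the coefficient relates the
    transmitted pressure at the exit face to the incident pressure at the
    entry face:

        t = 2 / (2 cos(k d) + i (Z + 1/Z) sin(k d)),   Z = Z_inner / Z_outer.

    |t| <= 1 always; t -> 1 as d -> 0, and an impedance-matched slab is a
    pure delay exp(-i k d).
    """
    k = wavenumber(inner, frequency)
    z = inner.impedance / outer.impedance
    kd = k * thickness
    return 2.0 / (2.0 * np.cos(kd) + 1j * (z + 1.0 / z) * np.sin(kd))


def skull_layer_transmission(
    layer: SkullLayer, frequency: float, outer: Medium
) -> complex:
    """Transmission factor of the skull slab immersed in ``outer``."""
    if frequency <= 0:
        raise InvalidArgumentError("frequency must be > 0")
    return slab_transmission(layer.medium, outer, layer.thickness, frequency)


def record_hologram(
    sources: VirtualSourceSet,
    layer: SkullLayer | None,
    plane: PlanarGrid,
    medium: Medium,
    frequency: float,
) -> Hologram:
    """Propagate the virtual sources to the holographic plane.

    Pressure at each plane sample is the Rayleigh–Sommerfeld sum over all
    sources, multiplied by the (spatially uniform, normal-incidence) skull
    transmission factor when a layer is present.  The plane must lie outside
    the slab.
    """
    pts = plane.points()
    if layer is not None:
        z0, z1 = layer.z_entry, layer.z_entry + layer.thickness
        pz = pts[:, 2]
        if np.any((pz >= z0) & (pz <= z1)):
            raise GeometryError(
                "holographic plane intersects the skull slab "
                f"[{z0:g}, {z1:g}] m"
            )
    p = rs_propagate(
        sources.positions,
        sources.strengths,
        pts,
        medium,
        frequency,
        min_distance=plane.spacing / 10.0,
    )
    if layer is not None:
        p = p * skull_layer_transmission(layer, frequency, medium)
    field = ComplexPressureField(grid=plane, values=p, frequency=frequency)
    return Hologram(plane=plane, pressure=field, phase=phase_of(field), conjugated=False)


def conjugate(hologram: Hologram, force: bool = False) -> Hologram:
    """Phase-conjugate a recorded hologram (the time-reversal emission step).

    Negates and rewraps the phase and conjugates the pressure; magnitudes are
    preserved.  Conjugating twice is rejected unless ``force`` is set.
    """
    if hologram.conjugated and not force:
        raise InvalidStateError("hologram is already conjugated")
    pressure = ComplexPressureField(
        grid=hologram.plane,
        values=np.conj(hologram.pressure.values),
        frequency=hologram.pressure.frequency,
    )
    phase = PhaseMap(grid=hologram.plane, values=np.asarray(wrap_phase(-hologram.phase.values)))
    return Hologram(
        plane=hologram.plane,
        pressure=pressure,
        phase=phase,
        conjugated=not hologram.conjugated,
    )
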