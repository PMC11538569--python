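"""Run configuration: parsing, validation, the built-in bilateral-DS fixture,
and the end-to-end pipeline helpers the CLI and scripts share.

Config files carry explicit units in their key names (mm, MHz, ...) and are
converted to SI at parse time; internally everything is meters, Hz, seconds.
The coordinate convention is: origin at the center of the lens-exit /
holographic plane, +z pointing into the brain.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from .core import BUILTIN_MEDIA, Medium, PlanarGrid, VolumeGrid, wavenumber
from .errors import GeometryError, InvalidArgumentError
from .exposure import PulseScheme
from .holography import (
    FocusTarget,
    SkullLayer,
    conjugate,
    make_virtual_sources,
    record_hologram,
)
from .lens import HeightMap, LensSpec, design_height_map, quantize_heights

__all__ = ["RunConfig", "bilateral_ds_config", "load_config", "save_config",
           "design_lens", "config_hash"]


@dataclass
class RunConfig:
    """Everything needed to design and validate one lens."""

    frequency: float
    media: dict[str, Medium]
    lens: LensSpec
    skull: SkullLayer | None
    targets: list[FocusTarget]
    jitter_radius: float = 0.25e-3
    seed: int = 7
    mirror_x: bool = True
    plane_subsample: int = 2
    volume_bounds: tuple = ((-2.5e-3, 2.5e-3), (-0.5e-3, 0.5e-3), (2.5e-3, 5.5e-3))
    volume_spacing: float = 0.125e-3
    pulse: PulseScheme = field(default_factory=PulseScheme)
    isppa: float = 0.9  # W/cm^2, pulse-average focal intensity
    pnp_mpa: float = 0.8660254037844386  # peak negative pressure 0.5*sqrt(3), MPa
    scan_step: float = 5e-6
    field_subsample: int = 2

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.frequency <= 0:
            raise InvalidArgumentError("frequency must be > 0")
        if self.jitter_radius < 0:
            raise InvalidArgumentError("jitter_radius must be >= 0")
        if self.plane_subsample < 1 or self.field_subsample < 1:
            raise InvalidArgumentError("subsampling factors must be >= 1")
        if not self.targets:
            raise InvalidArgumentError("at least one focus target is required")
        zmin_vol = self.volume_bounds[2][0]
        if zmin_vol <= 0:
            raise GeometryError("evaluation volume must lie downstream of the lens")
        if self.skull is not None:
            z_exit = self.skull.z_entry + self.skull.thickness
            if zmin_vol <= z_exit:
                raise GeometryError("evaluation volume overlaps the skull slab")
            for t in self.targets:
                if t.center[2] <= z_exit:
                    raise GeometryError("focus targets must lie beyond the skull")

    @property
    def outer_medium(self) -> Medium:
        return self.lens.outer_medium

    def recording_plane(self) -> PlanarGrid:
        """Holographic plane at z = 0, tiling the aperture at sub-pixel pitch."""
        spacing = self.lens.pixel_width / self.plane_subsample
        return PlanarGrid.centered((0.0, 0.0, 0.0), self.lens.aperture, spacing)

    def volume_grid(self) -> VolumeGrid:
        return VolumeGrid.from_bounds(self.volume_bounds, self.volume_spacing)


def bilateral_ds_config(seed: int = 7) -> RunConfig:
    """The built-in bilateral dorsal-striatum fixture.

    3 MHz; water / printing-resin / mouse-skull media; 10 mm x 10 mm lens at
    0.25 mm pixel pitch; a 250 um skull slab 0.5 mm downstream of the lens
    face; two foci of 100 virtual sources each at (+-1.5, 0, 3.5) mm.
    """
    media = dict(BUILTIN_MEDIA)
    lens = LensSpec(
        aperture=(10e-3, 10e-3),
        pixel_width=0.25e-3,
        base_thickness=0.8e-3,
        h_max=1.2e-3,
        lens_medium=media["lens"],
        outer_medium=media["water"],
        print_resolution=100e-6,
    )
    skull = SkullLayer(medium=media["skull"], thickness=250e-6, z_entry=0.5e-3)
    targets = [
        FocusTarget(center=(-1.5e-3, 0.0, 3.5e-3), amplitude=1.0, n_sources=100),
        FocusTarget(center=(+1.5e-3, 0.0, 3.5e-3), amplitude=1.0, n_sources=100),
    ]
    return RunConfig(
        frequency=3e6,
        media=media,
        lens=lens,
        skull=skull,
        targets=targets,
        jitter_radius=0.25e-3,
        seed=seed,
    )


def design_lens(config: RunConfig, quantize: bool = True) -> HeightMap:
    """Full design chain: virtual sources → recorded hologram through the
    skull → phase conjugation → per-pixel height solve (→ quantization)."""
    k0 = wavenumber(config.outer_medium, config.frequency)
    sources = make_virtual_sources(
        config.targets, config.jitter_radius, config.seed,
        carrier_wavenumber=k0, mirror_x=config.mirror_x,
    )
    hologram = record_hologram(
        sources, config.skull, config.recording_plane(),
        config.outer_medium, config.frequency,
    )
    height_map = design_height_map(
        conjugate(hologram), config.lens, config.frequency, config.scan_step
    )
    return quantize_heights(height_map) if quantize else height_map


# ---------------------------------------------------------------------------
# Serialization (units explicit in key names; SI internally)

def _medium_to_dict(m: Medium) -> dict:
    d = {"density": m.density, "c_long": m.c_long}
    if m.c_shear is not None:
        d["c_shear"] = m.c_shear
    return d


def save_config(config: RunConfig, path) -> None:
    doc = {
        "frequency_mhz": config.frequency / 1e6,
        "media": {name: _medium_to_dict(m) for name, m in config.media.items()},
        "lens": {
            "aperture_mm": [a * 1e3 for a in config.lens.aperture],
            "pixel_width_mm": config.lens.pixel_width * 1e3,
            "base_thickness_mm": config.lens.base_thickness * 1e3,
            "h_max_mm": config.lens.h_max * 1e3,
            "print_resolution_mm": config.lens.print_resolution * 1e3,
            "medium": config.lens.lens_medium.name,
            "outer": config.lens.outer_medium.name,
        },
        "skull": None
        if config.skull is None
        else {
            "medium": config.skull.medium.name,
            "thickness_mm": config.skull.thickness * 1e3,
            "standoff_mm": config.skull.z_entry * 1e3,
        },
        "targets": [
            {
                "center_mm": [c * 1e3 for c in t.center],
                "amplitude": t.amplitude,
                "n_sources": t.n_sources,
            }
            for t in config.targets
        ],
        "holography": {
            "jitter_radius_mm": config.jitter_radius * 1e3,
            "seed": config.seed,
            "mirror_x": config.mirror_x,
            "plane_subsample": config.plane_subsample,
        },
        "volume": {
            "x_mm": [b * 1e3 for b in config.volume_bounds[0]],
            "y_mm": [b * 1e3 for b in config.volume_bounds[1]],
            "z_mm": [b * 1e3 for b in config.volume_bounds[2]],
            "spacing_mm": config.volume_spacing * 1e3,
            "subsample": config.field_subsample,
        },
        "solver": {"scan_step_um": config.scan_step * 1e6},
        "pulse": {
            "ff_mhz": config.pulse.ff / 1e6,
            "prf_hz": config.pulse.prf,
            "tbd_ms": config.pulse.tbd * 1e3,
            "sd_s": config.pulse.sd,
            "isi_s": config.pulse.isi,
            "session_min": config.pulse.session / 60.0,
            "isppa_w_cm2": float(config.isppa),
            "pnp_mpa": float(config.pnp_mpa),
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _require(doc: dict, key: str, context: str):
    if key not in doc:
        raise InvalidArgumentError(f"config section '{context}' is missing key '{key}'")
    return doc[key]


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration (mm/MHz at the surface)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise InvalidArgumentError("config must be a YAML mapping")
    media = {
        name: Medium(
            name=name,
            density=float(_require(props, "density", f"media.{name}")),
            c_long=float(_require(props, "c_long", f"media.{name}")),
            c_shear=float(props["c_shear"]) if props.get("c_shear") is not None else None,
        )
        for name, props in _require(doc, "media", "root").items()
    }

    def medium_ref(name: str, context: str) -> Medium:
        if name not in media:
            raise InvalidArgumentError(
                f"config section '{context}' references unknown medium '{name}'"
            )
        return media[name]

    ld = _require(doc, "lens", "root")
    lens = LensSpec(
        aperture=tuple(a * 1e-3 for a in _require(ld, "aperture_mm", "lens")),
        pixel_width=float(_require(ld, "pixel_width_mm", "lens")) * 1e-3,
        base_thickness=float(_require(ld, "base_thickness_mm", "lens")) * 1e-3,
        h_max=float(_require(ld, "h_max_mm", "lens")) * 1e-3,
        print_resolution=float(_require(ld, "print_resolution_mm", "lens")) * 1e-3,
        lens_medium=medium_ref(_require(ld, "medium", "lens"), "lens"),
        outer_medium=medium_ref(_require(ld, "outer", "lens"), "lens"),
    )
    sd = doc.get("skull")
    skull = (
        None
        if sd is None
        else SkullLayer(
            medium=medium_ref(_require(sd, "medium", "skull"), "skull"),
            thickness=float(_require(sd, "thickness_mm", "skull")) * 1e-3,
            z_entry=float(_require(sd, "standoff_mm", "skull")) * 1e-3,
        )
    )
    targets = [
        FocusTarget(
            center=tuple(c * 1e-3 for c in _require(t, "center_mm", "targets")),
            amplitude=float(t.get("amplitude", 1.0)),
            n_sources=int(t.get("n_sources", 100)),
        )
        for t in _require(doc, "targets", "root")
    ]
    holo = doc.get("holography", {})
    vol = _require(doc, "volume", "root")
    bounds = tuple(
        tuple(b * 1e-3 for b in _require(vol, key, "volume"))
        for key in ("x_mm", "y_mm", "z_mm")
    )
    pulse_doc = doc.get("pulse", {})
    pulse = PulseScheme(
        ff=float(pulse_doc.get("ff_mhz", 3.0)) * 1e6,
        prf=float(pulse_doc.get("prf_hz", 500.0)),
        tbd=float(pulse_doc.get("tbd_ms", 0.4)) * 1e-3,
        sd=float(pulse_doc.get("sd_s", 1.0)),
        isi=float(pulse_doc.get("isi_s", 4.0)),
        session=float(pulse_doc.get("session_min", 20.0)) * 60.0,
    )
    return RunConfig(
        frequency=float(_require(doc, "frequency_mhz", "root")) * 1e6,
        media=media,
        lens=lens,
        skull=skull,
        targets=targets,
        jitter_radius=float(holo.get("jitter_radius_mm", 0.25)) * 1e-3,
        seed=int(holo.get("seed", 7)),
        mirror_x=bool(holo.get("mirror_x", True)),
        plane_subsample=int(holo.get("plane_subsample", 2)),
        volume_bounds=bounds,
        volume_spacing=float(_require(vol, "spacing_mm", "volume")) * 1e-3,
        pulse=pulse,
        isppa=float(pulse_doc.get("isppa_w_cm2", 0.9)),
        pnp_mpa=float(pulse_doc.get("pnp_mpa", 0.5 * np.sqrt(3.0))),
        scan_step=float(doc.get("solver", {}).get("scan_step_um", 5.0)) * 1e-6,
        field_subsample=int(vol.get("subsample", 2)),
    )


def config_hash(path) -> str:
    """SHA-256 of the raw config file, for run logging."""
    return hashlib.sha256(open(path, "rb").read()).hexdigest()[:16]
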