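"""Pulse-scheme arithmetic and regulatory safety indices.

The stimulation waveform is a hierarchy of timescales: a sinusoidal carrier
at the fundamental frequency (FF) is gated into tone bursts of duration TBD
repeating at the pulse repetition frequency (PRF); bursts run for a
sonication duration (SD), followed by an interstimulus interval (ISI); the
SD/ISI cycle repeats for a session.  Two duty factors follow:

    duty_cycle      = TBD * PRF            (within a sonication)
    effective_duty  = duty_cycle * SD / (SD + ISI)

Spatial-peak temporal-average intensity is the pulse-average intensity times
a duty factor, Ispta = Isppa * duty; the mechanical index is
MI = PNP[MPa] / sqrt(FF[MHz]).  Default regulatory ceilings are the FDA
diagnostic-ultrasound track values (MI 1.9, Ispta 720 mW/cm^2), overridable
in config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "PulseScheme",
    "ExposureReport",
    "duty_cycle",
    "effective_duty",
    "ispta_from_isppa",
    "mechanical_index",
    "limit_check",
    "build_report",
    "DEFAULT_LIMITS",
]

#: FDA diagnostic-track ceilings: MI (unitless) and Ispta (W/cm^2).
DEFAULT_LIMITS = {"mi_max": 1.9, "ispta_max": 0.72}


@dataclass(frozen=True)
class PulseScheme:
    """Timing parameters of the stimulation waveform (SI units)."""

    ff: float = 3e6  # fundamental frequency, Hz
    prf: float = 500.0  # pulse repetition frequency, Hz
    tbd: float = 0.4e-3  # tone-burst duration, s
    sd: float = 1.0  # sonication duration, s
    isi: float = 4.0  # interstimulus interval, s
    session: float = 20 * 60.0  # session length, s

    def __post_init__(self):
        if self.ff <= 0 or self.prf <= 0:
            raise InvalidArgumentError("ff and prf must be > 0")
        if self.tbd < 0 or self.tbd > 1.0 / self.prf + 1e-15:
            raise InvalidArgumentError("tbd must lie in [0, 1/prf]")
        if self.sd < 0 or self.isi < 0:
            raise InvalidArgumentError("sd and isi must be >= 0")


@dataclass
class ExposureReport:
    """Derived duty factors, intensities, index values, and limit flags.

    ``ispta`` uses the intra-burst duty cycle alone; ``ispta_effective``
    additionally folds in the SD/(SD+ISI) factor — the two are reported side
    by side because temporal averaging windows differ between conventions.
    """

    duty_cycle: float
    effective_duty: float
    isppa: float  # W/cm^2
    ispta: float  # W/cm^2
    ispta_effective: float  # W/cm^2
    mi: float
    limit_flags: dict = field(default_factory=dict)


def duty_cycle(tbd: float, prf: float) -> float:
    """Intra-sonication duty cycle TBD * PRF."""
    if prf <= 0:
        raise InvalidArgumentError("prf must be > 0")
    if tbd < 0 or tbd > 1.0 / prf + 1e-15:
        raise InvalidArgumentError("tbd must lie in [0, 1/prf]")
    return min(tbd * prf, 1.0)


def effective_duty(dc: float, sd: float, isi: float) -> float:
    """Duty cycle including the sonication/interstimulus gating."""
    if sd + isi <= 0:
        raise InvalidArgumentError("sd + isi must be > 0")
    if not 0 <= dc <= 1:
        raise InvalidArgumentError("duty cycle must lie in [0, 1]")
    return dc * sd / (sd + isi)


def ispta_from_isppa(isppa: float, duty: float) -> float:
    """Temporal-average from pulse-average intensity: Ispta = Isppa * duty."""
    if not 0 <= duty <= 1:
        raise InvalidArgumentError("duty must lie in [0, 1]")
    if isppa < 0:
        raise InvalidArgumentError("isppa must be >= 0")
    return isppa * duty


def mechanical_index(pnp_mpa: float, ff_mhz: float) -> float:
    """MI = peak negative pressure (MPa) / sqrt(frequency (MHz))."""
    if ff_mhz <= 0:
        raise InvalidArgumentError("frequency must be > 0")
    if pnp_mpa < 0:
        raise InvalidArgumentError("peak negative pressure must be >= 0")
    return float(pnp_mpa / np.sqrt(ff_mhz))


def limit_check(mi: float, ispta: float, limits: dict | None = None) -> dict:
    """Per-index pass/fail against regulatory ceilings (pass iff value <= limit)."""
    lim = dict(DEFAULT_LIMITS)
    if limits:
        lim.update(limits)
    if lim["mi_max"] <= 0 or lim["ispta_max"] <= 0:
        raise InvalidArgumentError("limits must be positive")
    return {
        "mi": bool(mi <= lim["mi_max"]),
        "ispta": bool(ispta <= lim["ispta_max"]),
    }


def build_report(
    scheme: PulseScheme,
    isppa: float,
    pnp_mpa: float,
    limits: dict | None = None,
) -> ExposureReport:
    """Full exposure report for a pulse scheme at given focal intensities."""
    dc = duty_cycle(scheme.tbd, scheme.prf)
    eff = effective_duty(dc, scheme.sd, scheme.isi)
    ispta = ispta_from_isppa(isppa, dc)
    ispta_eff = ispta_from_isppa(isppa, eff)
    mi = mechanical_index(pnp_mpa, scheme.ff / 1e6)
    return ExposureReport(
        duty_cycle=dc,
        effective_duty=eff,
        isppa=isppa,
        ispta=ispta,
        ispta_effective=ispta_eff,
        mi=mi,
        limit_flags=limit_check(mi, ispta, limits),
    )
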