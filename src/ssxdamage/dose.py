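"""Beam and dose bookkeeping.

Photon counts follow linear ring-current scaling from a reference flux;
absorbed dose here is a deliberately simple top-surface, uniform-beam
estimate (diffraction-weighted doses are inputs from external tools, never
recomputed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

EV_PER_JOULE = 1.602176634e-19  # J per eV


@dataclass(frozen=True)
class BeamSpec:
    """Beam parameters at the sample position."""

    flux_at_ref: float               # photons/s at the reference ring current
    ref_current: float               # mA
    current: float                   # mA
    exposure: float                  # s
    photon_energy: float             # keV
    beam_area: float                 # µm²
    attenuation_transmission: float = 1.0

    def __post_init__(self) -> None:
        for name in ("flux_at_ref", "ref_current", "current",
                     "photon_energy", "beam_area"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.exposure < 0:
            raise ValueError("exposure must be >= 0")
        if not 0.0 < self.attenuation_transmission <= 1.0:
            raise ValueError("transmission must be in (0, 1]")


@dataclass(frozen=True)
class AbsorberSpec:
    """Sample slab absorbing the beam."""

    thickness: float                 # µm
    density: float                   # kg/m³
    absorption_coefficient: float    # 1/m at the beam energy

    def __post_init__(self) -> None:
        if self.thickness < 0:
            raise ValueError("thickness must be >= 0")
        if self.density <= 0 or self.absorption_coefficient <= 0:
            raise ValueError("density and absorption coefficient must be positive")


#: Beamline presets mirroring the three experiments (reference flux at
#: 200 mA; XFEL entries carry an effective per-pulse bookkeeping).
BEAMLINE_PRESETS = {
    "id29-feb2024": BeamSpec(
        flux_at_ref=1.6e15, ref_current=200.0, current=68.0,
        exposure=90e-6, photon_energy=11.56, beam_area=8.0,
    ),
}


def photons_per_pulse(beam: BeamSpec) -> float:
    """Photons in one exposure under linear ring-current scaling."""
    return (beam.flux_at_ref * beam.current / beam.ref_current
            * beam.exposure * beam.attenuation_transmission)


def dose_rate(dose_gy: float, exposure: float) -> float:
    """Dose rate in Gy/s."""
    if exposure <= 0:
        raise ValueError("exposure must be positive")
    if dose_gy < 0:
        raise ValueError("dose must be >= 0")
    return dose_gy / exposure


def format_dose_rate(rate_gy_per_s: float) -> str:
    """Human-readable dose rate with MGy/GGy scaling."""
    for factor, unit in ((1e9, "GGy/s"), (1e6, "MGy/s"), (1e3, "kGy/s")):
        if abs(rate_gy_per_s) >= factor:
            return f"{rate_gy_per_s / factor:.3g} {unit}"
    return f"{rate_gy_per_s:.3g} Gy/s"


def simple_absorbed_dose(beam: BeamSpec, absorber: AbsorberSpec) -> float:
    """Mean absorbed dose (Gy) in a uniform slab under a uniform beam.

    Dose = absorbed energy / absorbing mass with
    ``E_abs = n_photons · E_photon · (1 − exp(−µ t))`` and mass
    ``ρ · beam_area · t``.  A top-surface estimate: no beam profile, no dose
    weighting by diffraction, no photoelectron escape.  The zero-thickness
    limit is the finite surface dose ``Φ E µ / ρ`` per unit area.
    """
    n_ph = photons_per_pulse(beam)
    e_photon = beam.photon_energy * 1e3 * EV_PER_JOULE  # keV -> J
    t = absorber.thickness * 1e-6
    area = beam.beam_area * 1e-12
    mu = absorber.absorption_coefficient
    if t == 0.0:
        # series limit of (1 - exp(-µt)) / t
        return n_ph * e_photon * mu / (area * absorber.density)
    absorbed = n_ph * e_photon * (1.0 - math.exp(-mu * t))
    return absorbed / (area * t * absorber.density)
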