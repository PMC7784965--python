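"""Aqueous sulfide speciation, diffusion coefficients, and diffusive scales.

H₂S microsensors sense only the protonated species; the total dissolved
sulfide pool S_tot = [H₂S] + [HS⁻] + [S²⁻] is reconstructed from the measured
[H₂S] and pH through the first dissociation equilibrium

    H₂S ⇌ H⁺ + HS⁻,   α₀ = [H₂S]/S_tot = 1 / (1 + 10^(pH − pK1)).

The second dissociation (HS⁻ ⇌ H⁺ + S²⁻) has pK2 ≳ 12 and is neglected:
at pH ≤ 9 the S²⁻ contribution is below 1e-4 of the pool.

Diffusion coefficients default to the values used for the flow-chamber
incubations (sulfide 1.35e-5, O₂ 1.78e-5 cm² s⁻¹, already corrected to the
incubation temperature and salinity); an optional Stokes–Einstein temperature
scaling is provided for other conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .errors import InvalidInputError
from .units import mm_to_cm

__all__ = [
    "SpeciationParams",
    "DiffusionConstants",
    "DEFAULT_DIFFUSION",
    "pk1_h2s",
    "h2s_fraction",
    "stot_from_h2s",
    "diffusion_coefficient",
    "diffusion_time",
    "DiffusionTime",
]

# Temperature/salinity validity windows for the speciation parameterization.
_T_MIN, _T_MAX = -2.0, 40.0


def pk1_h2s(temperature: float = 20.0, salinity: float = 0.0) -> float:
    """First dissociation exponent of H₂S (Millero 1988 formulation).

        ln K1 = 225.838 − 13275.3/T − 34.6435 ln T + 0.3449 √S − 0.0274 S

    with T in kelvin and S the practical salinity.  For fresh water at 25 °C
    this gives pK1 ≈ 6.98; salinity lowers the apparent pK.

    Parameters
    ----------
    temperature : °C, in [−2, 40]
    salinity : practical salinity, ≥ 0
    """
    if not (_T_MIN <= temperature <= _T_MAX):
        raise InvalidInputError(
            f"temperature {temperature} °C outside [{_T_MIN}, {_T_MAX}]"
        )
    if salinity < 0:
        raise InvalidInputError(f"salinity must be >= 0, got {salinity}")
    t_k = temperature + 273.15
    ln_k1 = (
        225.838
        - 13275.3 / t_k
        - 34.6435 * math.log(t_k)
        + 0.3449 * math.sqrt(salinity)
        - 0.0274 * salinity
    )
    return -ln_k1 / math.log(10.0)


@dataclass(frozen=True)
class SpeciationParams:
    """Equilibrium parameters for the H₂S/HS⁻ system.

    ``pk1`` may be supplied directly (overriding the temperature/salinity
    parameterization); otherwise it is computed from ``temperature`` and
    ``salinity`` at construction.  ``pk2_neglected`` records that S²⁻ is
    ignored throughout (valid at circumneutral pH).
    """

    temperature: float = 20.0
    salinity: float = 0.0
    pk1: float | None = None
    pk2_neglected: bool = True

    def __post_init__(self):
        if self.pk1 is None:
            object.__setattr__(self, "pk1", pk1_h2s(self.temperature, self.salinity))
        if not (0.0 < self.pk1 < 14.0):
            raise InvalidInputError(f"pK1 {self.pk1} outside (0, 14)")


def _check_ph(ph) -> np.ndarray:
    ph = np.asarray(ph, dtype=float)
    if np.any((ph <= 0.0) | (ph >= 14.0)):
        raise InvalidInputError("pH must lie strictly within (0, 14)")
    return ph


def h2s_fraction(ph, params: SpeciationParams | None = None):
    """Fraction α₀ of total sulfide present as H₂S at the given pH.

    α₀ = 1 / (1 + 10^(pH − pK1)); monotonically decreasing in pH, 0.5 at
    pH = pK1.  Accepts scalars or arrays.
    """
    params = params or SpeciationParams()
    ph = _check_ph(ph)
    alpha = 1.0 / (1.0 + 10.0 ** (ph - params.pk1))
    return float(alpha) if alpha.ndim == 0 else alpha


def stot_from_h2s(h2s, ph, params: SpeciationParams | None = None):
    """Total sulfide S_tot (µmol L⁻¹) from measured [H₂S] and pH.

    S_tot = [H₂S] / α₀(pH) ≥ [H₂S], with equality approached as pH → 0.
    """
    params = params or SpeciationParams()
    h2s = np.asarray(h2s, dtype=float)
    if np.any(h2s < 0):
        raise InvalidInputError("H2S concentrations must be >= 0")
    stot = h2s / h2s_fraction(ph, params)
    return float(stot) if stot.ndim == 0 else stot


@dataclass(frozen=True)
class DiffusionConstants:
    """Molecular diffusion coefficients (cm² s⁻¹) at a reference condition.

    Defaults are the incubation values (sulfide 1.35e-5, O₂ 1.78e-5 cm² s⁻¹,
    corrected for temperature and salinity); ``d_generic`` is a user-supplied
    coefficient for any other small solute (e.g. acetate ~1e-5).
    """

    d_sulfide: float = 1.35e-5
    d_o2: float = 1.78e-5
    d_generic: float = 1.0e-5
    reference_temperature: float = 20.0
    reference_salinity: float = 0.0

    def __post_init__(self):
        for name in ("d_sulfide", "d_o2", "d_generic"):
            d = getattr(self, name)
            if not (0.0 < d < 1e-4):
                raise InvalidInputError(
                    f"{name}={d} outside the sanity bound (0, 1e-4) cm2/s"
                )


DEFAULT_DIFFUSION = DiffusionConstants()

_ANALYTE_ATTR = {
    "sulfide": "d_sulfide",
    "h2s": "d_sulfide",
    "s_tot": "d_sulfide",
    "o2": "d_o2",
    "generic": "d_generic",
}


def _water_viscosity(t_celsius: float) -> float:
    """Dynamic viscosity of water (Pa s), Vogel-type correlation."""
    t_k = t_celsius + 273.15
    return 2.414e-5 * 10.0 ** (247.8 / (t_k - 140.0))


def diffusion_coefficient(
    analyte: str,
    temperature: float | None = None,
    salinity: float | None = None,
    constants: DiffusionConstants = DEFAULT_DIFFUSION,
) -> float:
    """Diffusion coefficient (cm² s⁻¹) for a supported analyte.

    With ``temperature=None`` (or equal to the reference) the tabulated
    incubation value is returned unchanged.  Otherwise a Stokes–Einstein
    scaling D ∝ T/µ(T) with a standard water-viscosity correlation is
    applied; D increases with temperature.  Salinity is accepted for
    interface symmetry but not used in the scaling (its effect on D is a few
    percent and the tabulated values are already salinity-corrected).
    """
    key = analyte.lower()
    if key not in _ANALYTE_ATTR:
        raise InvalidInputError(
            f"unknown analyte {analyte!r}; supported: sulfide, O2, generic "
            "(supply a DiffusionConstants with d_generic for other solutes)"
        )
    d_ref = getattr(constants, _ANALYTE_ATTR[key])
    if temperature is None or temperature == constants.reference_temperature:
        return d_ref
    if not (_T_MIN <= temperature <= _T_MAX):
        raise InvalidInputError(
            f"temperature {temperature} °C outside [{_T_MIN}, {_T_MAX}]"
        )
    t_ref_k = constants.reference_temperature + 273.15
    t_k = temperature + 273.15
    scale = (t_k / t_ref_k) * (
        _water_viscosity(constants.reference_temperature) / _water_viscosity(temperature)
    )
    return d_ref * scale


class DiffusionTime(NamedTuple):
    """Characteristic 1D diffusion time, in seconds and minutes."""

    seconds: float
    minutes: float


def diffusion_time(length_mm: float, d: float) -> DiffusionTime:
    """Characteristic time t = L²/(2D) to diffuse a distance L.

    The 1/(2D) convention reproduces the ~8 min transit of small organics
    (D ≈ 1e-5 cm² s⁻¹) across the ~1 mm separating the photosynthetic layer
    from the sulfide-production zone; the alternative L²/D convention is
    simply twice this value.

    Parameters
    ----------
    length_mm : diffusion distance in mm, ≥ 0
    d : diffusion coefficient in cm² s⁻¹, > 0
    """
    if d <= 0:
        raise InvalidInputError(f"diffusion coefficient must be > 0, got {d}")
    if length_mm < 0:
        raise InvalidInputError(f"length must be >= 0, got {length_mm}")
    l_cm = mm_to_cm(length_mm)
    t = l_cm * l_cm / (2.0 * d)
    return DiffusionTime(seconds=t, minutes=t / 60.0)
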