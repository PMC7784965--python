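"""Unit conventions and conversions used throughout the package.

Conventions (external API):

* depths in **mm**, zero at the mat surface, positive downward (overlying
  water negative);
* concentrations in **µmol L⁻¹** (numerically identical to nmol cm⁻³, which
  is what makes the flux arithmetic below clean);
* diffusion coefficients in **cm² s⁻¹**;
* diffusive fluxes in **nmol cm⁻² s⁻¹**, positive downward;
* volumetric rates in **nmol cm⁻³ s⁻¹**, positive = production.

Internally all Fick's-law arithmetic is done in cm.
"""

MM_PER_CM = 10.0
CM_PER_MM = 0.1

#: 1 µmol L⁻¹ == 1 nmol cm⁻³ (1 L = 1000 cm³, 1 µmol = 1000 nmol).
UMOL_L_AS_NMOL_CM3 = 1.0

#: nmol cm⁻² s⁻¹ -> mmol m⁻² d⁻¹ (1e-6 mmol/nmol * 1e4 cm²/m² * 86400 s/d)
NMOL_CM2_S_TO_MMOL_M2_D = 864.0


def mm_to_cm(x):
    return x * CM_PER_MM


def cm_to_mm(x):
    return x * MM_PER_CM


def slope_umol_l_mm_to_nmol_cm4(slope):
    """Concentration gradient µmol L⁻¹ mm⁻¹ -> nmol cm⁻⁴.

    1 µmol L⁻¹ mm⁻¹ = 1 nmol cm⁻³ per 0.1 cm = 10 nmol cm⁻⁴.
    """
    return slope * MM_PER_CM


def flux_to_mmol_m2_d(j_nmol_cm2_s):
    """Convenience conversion of a flux to mmol m⁻² d⁻¹."""
    return j_nmol_cm2_s * NMOL_CM2_S_TO_MMOL_M2_D
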