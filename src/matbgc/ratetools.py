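"""Flux and volumetric-rate inversion from steady-state microsensor profiles.

Steady-state diffusive transport in the mat obeys Fick's laws:

* first law — the flux across a depth z is J(z) = −D dC/dz (positive
  downward); in the diffusive boundary layer the profile is linear and its
  slope gives the interfacial flux;
* second law — at steady state D C″(z) + R(z) = 0, so the local net
  volumetric rate R (production positive) is read from the profile's
  curvature: a local concentration minimum (convex-up) means consumption,
  a local maximum means production.

Rather than double-differencing noisy data, :func:`volumetric_rates` fits
the piecewise-constant-rate steady-state model (constant R per zone,
continuity of concentration and flux at the zone boundaries, measured end
concentrations as Dirichlet conditions) by linear least squares — the
classical inverse approach for porewater profiles.  :func:`select_zonation`
chooses the number (and optionally positions) of zones by BIC.

Gross photosynthesis rates come from light–dark shifts: immediately after
darkening, diffusion has not yet re-equilibrated, so the initial rate of
O₂ decline equals gross oxygenic photosynthesis (OP) and the initial rate of
S_tot rise equals gross anoxygenic photosynthesis (AP) at that depth.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    FitQualityWarning,
    InvalidInputError,
    NumericalFailureError,
)
from .profiles import DepthProfile, LayerModel
from .units import CM_PER_MM, slope_umol_l_mm_to_nmol_cm4

__all__ = [
    "FluxEstimate",
    "RateProfile",
    "GrossRateProfile",
    "local_flux",
    "find_dbl_window",
    "volumetric_rates",
    "select_zonation",
    "layer_balance",
    "gross_rate_lightdark",
    "depth_integrate",
]

#: R² below which a "linear" fit window is flagged as curved.
LINEARITY_R2 = 0.98


@dataclass(frozen=True)
class FluxEstimate:
    """Diffusive flux from a linear fit of C(z) over a depth window.

    j is in nmol cm⁻² s⁻¹, positive downward; ``depth_mm`` is the depth the
    estimate refers to (mean of the fitted points); ``slope_se`` is the
    standard error of the concentration gradient in µmol L⁻¹ mm⁻¹.
    """

    j: float
    depth_mm: float
    window_mm: tuple[float, float]
    n_points: int
    slope_se: float
    r_squared: float


def local_flux(
    profile: DepthProfile,
    d: float,
    window: tuple[float, float],
    center: float | None = None,
) -> FluxEstimate:
    """Fick's-first-law flux from a least-squares slope over ``window`` (mm).

    J = −D dC/dz with the downward-positive sign convention.  At least three
    points are required; a detectably curved window (R² < 0.98) attaches a
    :class:`FitQualityWarning` rather than failing.

    If ``center`` is given, the points kept in the window are additionally
    trimmed to be (count-)symmetric about that depth; for a locally
    quadratic profile the fitted slope then equals the true derivative at
    the centre, which makes boundary fluxes of curved zones unbiased.
    """
    z1, z2 = window
    m = (profile.depths >= z1) & (profile.depths <= z2)
    z = profile.depths[m]
    c = profile.values[m]
    if center is not None and len(z) >= 3:
        below = int(np.sum(z < center))
        above = int(np.sum(z > center))
        k = min(below, above)
        if k >= 1:
            lo_i = below - k
            hi_i = (len(z) - above) + k  # keep any point exactly at center
            z, c = z[lo_i:hi_i], c[lo_i:hi_i]
    if len(z) < 3:
        raise InvalidInputError(
            f"flux window [{z1}, {z2}] mm contains {len(z)} points; need >= 3"
        )
    res = stats.linregress(z, c)
    r2 = float(res.rvalue**2) if np.std(c) > 0 else 1.0
    if np.std(c) > 0 and r2 < LINEARITY_R2:
        warnings.warn(
            f"flux window [{z1}, {z2}] mm is curved (R²={r2:.3f} < {LINEARITY_R2}); "
            "flux refers to the window mean depth",
            FitQualityWarning,
            stacklevel=2,
        )
    slope_nmol_cm4 = slope_umol_l_mm_to_nmol_cm4(res.slope)
    return FluxEstimate(
        j=float(-d * slope_nmol_cm4),
        depth_mm=float(np.mean(z)),
        window_mm=(z1, z2),
        n_points=len(z),
        slope_se=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
        r_squared=r2,
    )


def find_dbl_window(
    profile: DepthProfile,
    interface: float = 0.0,
    min_points: int = 3,
    r2_min: float = LINEARITY_R2,
) -> tuple[float, float]:
    """Auto-detect the diffusive-boundary-layer flux window.

    Returns the longest near-linear (R² ≥ ``r2_min``) run of consecutive
    points ending at the mat surface and extending upward into the water
    column (depths ≤ ``interface``).
    """
    m = profile.depths <= interface
    z = profile.depths[m]
    c = profile.values[m]
    if len(z) < min_points:
        raise InvalidInputError("fewer than 3 points above the interface")
    best = None
    for start in range(0, len(z) - min_points + 1):
        zz, cc = z[start:], c[start:]
        if np.std(cc) == 0:
            best = (zz[0], zz[-1])
            break
        r = stats.linregress(zz, cc)
        if r.rvalue**2 >= r2_min:
            best = (zz[0], zz[-1])
            break
    if best is None:
        best = (z[-min_points], z[-1])
    return best


# ---------------------------------------------------------------------------
# Piecewise-constant-rate steady-state model


def _unit_rate_response(z_cm: np.ndarray, p: float, q: float, d: float) -> np.ndarray:
    """Analytic response G(z) of D G″ = −1 on [p, q] (cm), G=0 at domain ends.

    Built from the double integral W of the indicator of [p, q]:
    G(z) = (W(L)·z/L − W(z)) / D with the domain mapped to [0, L].
    """
    z0, zl = z_cm[0], z_cm[-1]
    s = z_cm - z0
    sl = zl - z0
    a, b = p - z0, q - z0

    def w(x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        mid = (x > a) & (x <= b)
        hi = x > b
        out[mid] = 0.5 * (x[mid] - a) ** 2
        out[hi] = (b - a) * (x[hi] - 0.5 * (a + b))
        return out

    wl = float(w(np.array([sl]))[0])
    return (wl * s / sl - w(s)) / d


@dataclass
class RateProfile:
    """Result of the piecewise-constant-rate steady-state fit.

    ``boundaries_mm`` (len n+1) partition the fitted interval; ``rates``
    (len n) are the per-zone volumetric net rates in nmol cm⁻³ s⁻¹,
    positive = production.  The fitted concentration profile is continuous
    and flux-continuous at the zone boundaries by construction.
    """

    analyte: str
    d: float
    boundaries_mm: np.ndarray
    rates: np.ndarray
    depths_mm: np.ndarray
    fitted: np.ndarray
    residual_rms: float
    bic: float
    c_top: float
    c_bottom: float

    def flux_at(self, depth_mm: float) -> float:
        """Model flux −D C′ (nmol cm⁻² s⁻¹, positive downward) at a depth."""
        zb = self.boundaries_mm * CM_PER_MM
        z = depth_mm * CM_PER_MM
        if not (zb[0] <= z <= zb[-1]):
            raise InvalidInputError("depth outside the fitted interval")
        # C′(z) from the closed form: C = linear + Σ R_i G_i; use the exact
        # derivative of the analytic basis.
        l = zb[-1] - zb[0]
        dcdz = (self.c_bottom - self.c_top) / l
        for r_i, (p, q) in zip(self.rates, zip(zb[:-1], zb[1:])):
            # d/dz of G_i: (W(L)/L − W′(z))/D, with W′(z)=∫ indicator
            a, b = p - zb[0], q - zb[0]
            s = z - zb[0]
            wl = (b - a) * (l - 0.5 * (a + b))
            wp = 0.0 if s <= a else (s - a if s <= b else b - a)
            dcdz += r_i * (wl / l - wp) / self.d
        return float(-self.d * dcdz)

    def integrate(self, interval: tuple[float, float] | None = None) -> float:
        """Exact piecewise integral ∫R dz (nmol cm⁻² s⁻¹) over ``interval`` mm."""
        if interval is None:
            interval = (self.boundaries_mm[0], self.boundaries_mm[-1])
        lo, hi = interval
        if hi <= lo:
            raise InvalidInputError("empty integration interval")
        total = 0.0
        for r_i, (p, q) in zip(self.rates, zip(self.boundaries_mm[:-1], self.boundaries_mm[1:])):
            overlap = max(0.0, min(hi, q) - max(lo, p))
            total += r_i * overlap * CM_PER_MM
        return float(total)


def _resolve_boundaries(profile: DepthProfile, zones) -> np.ndarray:
    z = profile.depths
    if isinstance(zones, LayerModel):
        edges = zones.boundaries()
        edges = edges[(edges >= z[0]) & (edges <= z[-1])]
        b = np.unique(np.concatenate([[z[0]], edges, [z[-1]]]))
    elif isinstance(zones, int):
        if zones < 1:
            raise InvalidInputError("zone count must be >= 1")
        b = np.linspace(z[0], z[-1], zones + 1)
    else:
        b = np.unique(np.asarray(zones, dtype=float))
        if b[0] > z[0] or b[-1] < z[-1]:
            b = np.unique(np.concatenate([[z[0]], b, [z[-1]]]))
    return b


def volumetric_rates(
    profile: DepthProfile,
    d: float,
    zones: LayerModel | int | Sequence[float] = 1,
) -> RateProfile:
    """Invert a steady-state profile for per-zone volumetric net rates.

    Fits the model D C″ + R = 0 with R constant within each zone,
    concentration and flux continuous at zone boundaries, and the measured
    end concentrations as boundary conditions.  The fit is linear in the
    zone rates: the model profile is the Laplace (straight-line) solution
    plus a superposition of analytic unit-rate responses, and the rates are
    obtained by ordinary least squares against the interior points.

    ``zones`` may be a :class:`LayerModel` (its boundaries clipped to the
    profile), an integer count of equal-width zones, or an explicit boundary
    sequence in mm.  Sign convention: positive = production (concave-down
    curvature); a local minimum in C means R < 0 (consumption).
    """
    z_mm = profile.depths
    c = profile.values
    b_mm = _resolve_boundaries(profile, zones)
    nz = len(b_mm) - 1
    for p, q in zip(b_mm[:-1], b_mm[1:]):
        if np.sum((z_mm >= p) & (z_mm <= q)) < 2:
            raise InvalidInputError(
                f"zone [{p}, {q}] mm contains fewer than 2 points"
            )
    z = z_mm * CM_PER_MM
    zb = b_mm * CM_PER_MM
    c_top, c_bot = c[0], c[-1]
    base = c_top + (c_bot - c_top) * (z - z[0]) / (z[-1] - z[0])
    basis = np.column_stack([
        _unit_rate_response(z, p, q, d) for p, q in zip(zb[:-1], zb[1:])
    ])
    interior = slice(1, -1) if len(z) > 2 else slice(None)
    a_mat = basis[interior]
    rhs = (c - base)[interior]
    if a_mat.shape[0] < nz:
        raise InvalidInputError(
            f"{a_mat.shape[0]} interior points cannot constrain {nz} zone rates"
        )
    try:
        rates, _, rank, _ = np.linalg.lstsq(a_mat, rhs, rcond=None)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise NumericalFailureError(f"rate fit failed: {exc}") from exc
    if rank < nz:
        raise NumericalFailureError(
            "singular rate fit: zones are not identifiable from these depths"
        )
    fitted = base + basis @ rates
    resid = c - fitted
    n = len(c)
    rss = float(np.sum(resid**2))
    # Gaussian BIC with nz free rate parameters.
    bic = n * np.log(max(rss, 1e-300) / n) + nz * np.log(n)
    return RateProfile(
        analyte=profile.analyte,
        d=d,
        boundaries_mm=b_mm,
        rates=rates,
        depths_mm=z_mm,
        fitted=fitted,
        residual_rms=float(np.sqrt(rss / n)),
        bic=float(bic),
        c_top=float(c_top),
        c_bottom=float(c_bot),
    )


def select_zonation(
    profile: DepthProfile,
    d: float,
    max_zones: int = 4,
    free_knots: bool = True,
    max_candidates: int = 12,
) -> RateProfile:
    """Choose the zonation by BIC over 1…``max_zones`` zone models.

    For each zone count both equal-width knots and (optionally) free knots
    placed on a subsample of the measured depths are tried; free-knot
    models pay for their knot positions as extra parameters.  Deterministic
    tie-break: fewer zones win.
    """
    if max_zones < 1:
        raise InvalidInputError("max_zones must be >= 1")
    z = profile.depths
    best: RateProfile | None = None
    best_key: tuple[float, int] | None = None

    scale = float(np.max(np.abs(profile.values))) or 1.0
    # Fits whose residuals are at numerical precision are indistinguishable:
    # floor the RSS so the parameter penalty (not log-of-rounding-noise)
    # decides between them.
    rss_floor = len(profile) * (1e-9 * scale) ** 2

    def consider(fit: RateProfile, extra_params: int):
        nonlocal best, best_key
        n = len(profile)
        rss = fit.residual_rms**2 * n
        k = len(fit.rates) + extra_params
        bic = n * np.log(max(rss, rss_floor) / n) + k * np.log(n)
        key = (round(bic, 9), len(fit.rates))
        if best_key is None or key < best_key:
            best, best_key = fit, key
            best.bic = float(bic)

    interior = z[1:-1]
    if len(interior) > max_candidates:
        idx = np.unique(np.linspace(0, len(interior) - 1, max_candidates).astype(int))
        candidates = interior[idx]
    else:
        candidates = interior
    for m in range(1, max_zones + 1):
        try:
            consider(volumetric_rates(profile, d, m), extra_params=0)
        except (InvalidInputError, NumericalFailureError):
            pass
        if free_knots and m >= 2:
            for knots in itertools.combinations(candidates, m - 1):
                b = np.concatenate([[z[0]], knots, [z[-1]]])
                try:
                    consider(volumetric_rates(profile, d, b), extra_params=m - 1)
                except (InvalidInputError, NumericalFailureError):
                    continue
    if best is None:
        raise NumericalFailureError("no zonation could be fitted")
    return best


def layer_balance(
    profile: DepthProfile,
    d: float,
    layer: tuple[float, float],
    window_mm: float = 0.9,
) -> float:
    """Net consumption rate within a layer from the flux difference.

    Fluxes are estimated by :func:`local_flux` in windows of width
    ``window_mm`` just *outside* the layer — above its top boundary and
    below its bottom boundary — where the profile is not curved by the
    layer's own reaction; a curved outside window attaches a
    :class:`FitQualityWarning` (the flux then refers to the window mean,
    not the boundary).  With downward-positive fluxes,

        net consumption = J(z_top) − J(z_bottom),

    positive when the layer consumes the analyte; net production is the
    negative.  For a production zone whose fluxes diverge upward and
    downward this equals −(|J_up| + |J_down|).
    """
    z_top, z_bot = layer
    if z_bot <= z_top:
        raise InvalidInputError("layer bottom must exceed top")
    j_top = local_flux(profile, d, (z_top - window_mm, z_top))
    j_bot = local_flux(profile, d, (z_bot, z_bot + window_mm))
    return float(j_top.j - j_bot.j)


# ---------------------------------------------------------------------------
# Light–dark shift gross rates


def gross_rate_lightdark(
    times_s: np.ndarray,
    values: np.ndarray,
    window_s: float = 3.0,
    mode: str = "OP",
) -> float:
    """Gross photosynthesis rate from a light–dark shift time series.

    ``times_s``/``values`` sample one depth's concentration starting at the
    dark transition (t = 0 is the moment the light goes off).  The gross
    rate is the magnitude of the initial slope of a linear fit over the
    first ``window_s`` seconds: O₂ declines at gross OP, S_tot rises at
    gross AP, before diffusion re-equilibrates.  Longer windows
    systematically underestimate the rate (diffusive relaxation).

    ``mode`` is "OP" (expects decline) or "AP" (expects rise); a slope of
    the unexpected sign attaches a warning but the magnitude is returned
    either way.
    """
    times_s = np.asarray(times_s, dtype=float)
    values = np.asarray(values, dtype=float)
    if mode not in ("OP", "AP"):
        raise InvalidInputError("mode must be 'OP' or 'AP'")
    if times_s[0] < 0:
        raise InvalidInputError("series must start at the dark transition (t >= 0)")
    if window_s > times_s[-1] - times_s[0]:
        raise InvalidInputError(
            f"window {window_s}s exceeds the series span {times_s[-1] - times_s[0]}s"
        )
    m = times_s <= times_s[0] + window_s
    t, v = times_s[m], values[m]
    if len(t) < 3:
        raise InvalidInputError(f"{len(t)} samples in the fit window; need >= 3")
    if np.std(v) == 0:
        return 0.0
    res = stats.linregress(t, v)
    if res.rvalue**2 < LINEARITY_R2:
        warnings.warn(
            f"light-dark window is detectably nonlinear (R²={res.rvalue**2:.3f}); "
            "consider a shorter window",
            FitQualityWarning,
            stacklevel=2,
        )
    expected_sign = -1.0 if mode == "OP" else 1.0
    if res.slope * expected_sign < 0:
        warnings.warn(
            f"{mode} series slope has unexpected sign ({res.slope:+.3g})",
            FitQualityWarning,
            stacklevel=2,
        )
    return float(abs(res.slope))


@dataclass
class GrossRateProfile:
    """Depth-resolved gross rates from light–dark shifts.

    ``rates`` are nmol cm⁻³ s⁻¹, non-negative by construction (initial-slope
    magnitudes); ``mode`` is "OP" (from O₂) or "AP" (from S_tot).
    """

    depths_mm: np.ndarray
    rates: np.ndarray
    mode: str
    window_s: float = 3.0
    light_intensity: float = 0.0

    def __post_init__(self):
        self.depths_mm = np.asarray(self.depths_mm, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.rates < 0):
            raise InvalidInputError("gross rates must be >= 0")
        if np.any(np.diff(self.depths_mm) <= 0):
            raise InvalidInputError("depths must be strictly increasing")


def depth_integrate(rates, interval: tuple[float, float] | None = None) -> float:
    """Depth-integrated areal rate (nmol cm⁻² s⁻¹).

    For a :class:`GrossRateProfile` the integral is trapezoidal over the
    measured depths; for a :class:`RateProfile` it is the exact piecewise
    integral (identical to the boundary-flux difference of the fitted
    model).
    """
    if isinstance(rates, RateProfile):
        return rates.integrate(interval)
    if not isinstance(rates, GrossRateProfile):
        raise InvalidInputError("expected a GrossRateProfile or RateProfile")
    z, r = rates.depths_mm, rates.rates
    if interval is not None:
        lo, hi = interval
        if hi <= lo:
            raise InvalidInputError("empty integration interval")
        if lo < z[0] or hi > z[-1]:
            raise InvalidInputError("interval outside rate coverage")
        zz = np.unique(np.concatenate([z[(z > lo) & (z < hi)], [lo, hi]]))
        rr = np.interp(zz, z, r)
    else:
        zz, rr = z, r
    return float(np.trapezoid(rr, zz * CM_PER_MM))
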