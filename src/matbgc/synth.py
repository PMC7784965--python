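"""Forward models that generate every input the analysis chain consumes.

Two generators stand in for the (undeposited) raw measurements:

* a 1D layered reaction–diffusion simulator for O₂ and total sulfide —
  steady state (tridiagonal solve of D C″ + R(z) = 0 with Dirichlet
  boundaries) and light–dark transients (Crank–Nicolson integration of
  ∂C/∂t = D C″ + R(z,t) with the photosynthetic source terms switched off
  at the dark transition);
* a diel ¹³C-SIP trajectory generator that integrates an imposed
  carbon-fixation flux into bulk-mat labeling (linearized label balance),
  lets DOC enrichment rise only during oxygenic phases and decay in the
  dark, and integrates guild-specific uptake into per-FA δ¹³C.

Every stochastic output takes a mandatory seed, and each solve returns an
imposed-truth record (zone rates, boundary fluxes, phase fluxes, uptake
matrix) so that inverse methods can be tested against known ground truth.

The geometry mirrors the flow-chamber incubation: a thin (~6 mm) mat under
a water column, above an N₂-purged bottom chamber, with a
sulfur-oxidizing-bacteria (SOB) layer that sits on the surface in the dark
and relocates below the cyanobacterial layer once oxygenic photosynthesis
sets in.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import solve_banded

from .chem import DEFAULT_DIFFUSION
from .errors import InvalidInputError, NumericalFailureError
from .profiles import DepthProfile, LayerModel, ProfileSet
from .sip import R_VPDB, SIPSeries, atom_fraction_to_delta, delta_to_atom_fraction
from .units import CM_PER_MM

__all__ = [
    "Layer",
    "MatScenario",
    "SteadyStateResult",
    "LightDarkResult",
    "solve_steady_state",
    "simulate_lightdark",
    "Phase",
    "DielSIPScenario",
    "DielSIPResult",
    "simulate_diel_sip",
    "add_noise",
    "downsample_profile",
    "scenario_library",
    "apply_sob_migration_rule",
]

SOLUTES = ("O2", "S_tot")


@dataclass(frozen=True)
class Layer:
    """One horizontal slab of the scenario domain.

    ``rates`` are always-on volumetric net rates (nmol cm⁻³ s⁻¹, production
    positive) per solute; ``photo_rates`` are the light-driven terms (gross
    OP as O₂ production, gross AP as S_tot consumption) that are zeroed at a
    dark shift.  ``is_water`` marks slabs above the mat surface (water
    column / diffusive boundary layer), which sit at negative depths.
    """

    name: str
    thickness_mm: float
    rates: Mapping[str, float] = field(default_factory=dict)
    photo_rates: Mapping[str, float] = field(default_factory=dict)
    is_water: bool = False

    def __post_init__(self):
        if self.thickness_mm <= 0:
            raise InvalidInputError(f"layer {self.name!r}: thickness must be > 0")
        for d in (self.rates, self.photo_rates):
            for k, v in d.items():
                if k not in SOLUTES:
                    raise InvalidInputError(f"layer {self.name!r}: unknown solute {k!r}")
                if not np.isfinite(v):
                    raise InvalidInputError(f"layer {self.name!r}: non-finite rate")


@dataclass
class MatScenario:
    """Full forward-model specification for the reaction–diffusion solver.

    Boundary concentrations are Dirichlet values at the top of the water
    column and at the bottom chamber (µmol L⁻¹); layer thicknesses must sum
    to the domain depth and the grid must resolve the thinnest layer with
    at least three cells.
    """

    name: str
    layers: Sequence[Layer]
    top_bc: Mapping[str, float]
    bottom_bc: Mapping[str, float]
    grid_mm: float = 0.02
    light_intensity: float = 0.0
    diffusion: Mapping[str, float] = field(
        default_factory=lambda: {
            "O2": DEFAULT_DIFFUSION.d_o2,
            "S_tot": DEFAULT_DIFFUSION.d_sulfide,
        }
    )
    noise_sigma: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if not self.layers:
            raise InvalidInputError("scenario needs at least one layer")
        thinnest = min(l.thickness_mm for l in self.layers)
        if self.grid_mm > thinnest / 3.0 + 1e-12:
            raise InvalidInputError(
                f"grid spacing {self.grid_mm} mm must be <= 1/3 of the thinnest "
                f"layer ({thinnest} mm)"
            )
        for bc in (self.top_bc, self.bottom_bc):
            for k in bc:
                if k not in SOLUTES:
                    raise InvalidInputError(f"unknown solute {k!r} in boundary condition")

    @property
    def domain_mm(self) -> float:
        return float(sum(l.thickness_mm for l in self.layers))

    @property
    def surface_offset_mm(self) -> float:
        """Thickness of the water slabs above the mat surface."""
        off = 0.0
        for layer in self.layers:
            if layer.is_water:
                off += layer.thickness_mm
            else:
                break
        return off

    def grid(self) -> np.ndarray:
        """Node depths in mat coordinates (mm; water column negative)."""
        n = int(round(self.domain_mm / self.grid_mm))
        return np.linspace(0.0, self.domain_mm, n + 1) - self.surface_offset_mm

    def layer_edges_mm(self) -> np.ndarray:
        """Layer interfaces in mat coordinates (mm)."""
        edges = np.concatenate([[0.0], np.cumsum([l.thickness_mm for l in self.layers])])
        return edges - self.surface_offset_mm

    def layer_model(self) -> LayerModel:
        edges = self.layer_edges_mm()
        return LayerModel(
            {l.name: (edges[i], edges[i + 1]) for i, l in enumerate(self.layers)}
        )

    def rate_field(self, solute: str, include_photo: bool = True) -> np.ndarray:
        """Volumetric rate at each grid node (nmol cm⁻³ s⁻¹)."""
        z = self.grid()
        edges = self.layer_edges_mm()
        vals = []
        for layer in self.layers:
            v = layer.rates.get(solute, 0.0)
            if include_photo:
                v += layer.photo_rates.get(solute, 0.0)
            vals.append(v)
        r = np.zeros_like(z)
        for i, v in enumerate(vals):
            m = (z >= edges[i] - 1e-9) & (z < edges[i + 1] - 1e-9)
            if i == len(vals) - 1:
                m |= np.isclose(z, edges[-1])
            r[m] = v
        # Nodes sitting exactly on an interior interface get the mean of the
        # adjacent layers' rates: the trapezoid-consistent value that keeps
        # the finite-difference scheme second-order across rate jumps.
        for i in range(1, len(self.layers)):
            on_edge = np.isclose(z, edges[i], atol=1e-9)
            if np.any(on_edge):
                r[on_edge] = 0.5 * (vals[i - 1] + vals[i])
        return r


@dataclass
class SteadyTruth:
    """Exact imposed quantities for oracle tests."""

    zone_rates: dict[str, dict[str, float]]  # solute -> layer name -> rate
    zone_areal: dict[str, dict[str, float]]  # solute -> layer -> nmol cm^-2 s^-1
    boundary_flux_top: dict[str, float]  # discrete -D dC/dz at top (downward +)
    boundary_flux_bottom: dict[str, float]
    areal_total: dict[str, float]  # depth-integrated imposed rate per solute


@dataclass
class SteadyStateResult:
    profiles: ProfileSet
    truth: SteadyTruth
    scenario: MatScenario
    concentrations: dict[str, np.ndarray]  # raw grid solutions (noiseless)


def _steady_solve(c_top, c_bot, r, d, h_cm) -> np.ndarray:
    """Tridiagonal solve of D C″ + R = 0 with Dirichlet ends."""
    n = len(r)
    c = np.empty(n)
    c[0], c[-1] = c_top, c_bot
    m = n - 2
    if m <= 0:
        return np.linspace(c_top, c_bot, n)
    ab = np.zeros((3, m))
    ab[0, 1:] = 1.0  # superdiagonal
    ab[1, :] = -2.0
    ab[2, :-1] = 1.0  # subdiagonal
    rhs = -r[1:-1] * h_cm * h_cm / d
    rhs[0] -= c_top
    rhs[-1] -= c_bot
    try:
        c[1:-1] = solve_banded((1, 1), ab, rhs)
    except Exception as exc:
        raise NumericalFailureError(f"steady-state solve failed: {exc}") from exc
    if not np.all(np.isfinite(c)):
        raise NumericalFailureError("steady-state solution is not finite")
    return c


def solve_steady_state(
    scenario: MatScenario, include_photo: bool = True
) -> SteadyStateResult:
    """Solve D C″ + R(z) = 0 for every solute of a scenario.

    Returns noiseless profiles (mat coordinates, surface at 0) plus the
    imposed-truth record.  The discrete boundary fluxes in the truth record
    satisfy ∫R dz = J(bottom) − J(top) to machine precision (a consequence
    of summing the interior difference equations), which is the conservation
    identity the inverse methods are tested against.
    """
    z = scenario.grid()
    h_cm = scenario.grid_mm * CM_PER_MM
    concentrations: dict[str, np.ndarray] = {}
    flux_top: dict[str, float] = {}
    flux_bot: dict[str, float] = {}
    areal: dict[str, float] = {}
    zone_rates: dict[str, dict[str, float]] = {}
    zone_areal: dict[str, dict[str, float]] = {}
    members: dict[str, DepthProfile] = {}
    for solute in SOLUTES:
        if solute not in scenario.top_bc:
            continue
        d = scenario.diffusion[solute]
        r = scenario.rate_field(solute, include_photo)
        c = _steady_solve(
            scenario.top_bc[solute], scenario.bottom_bc[solute], r, d, h_cm
        )
        concentrations[solute] = c
        # Discrete fluxes at the half-cells adjacent to the boundaries; with
        # these definitions sum(r[1:-1])*h == J_bot - J_top exactly.
        flux_top[solute] = float(-d * (c[1] - c[0]) / h_cm)
        flux_bot[solute] = float(-d * (c[-1] - c[-2]) / h_cm)
        areal[solute] = float(np.sum(r[1:-1]) * h_cm)
        zone_rates[solute] = {
            l.name: l.rates.get(solute, 0.0)
            + (l.photo_rates.get(solute, 0.0) if include_photo else 0.0)
            for l in scenario.layers
        }
        zone_areal[solute] = {
            l.name: zone_rates[solute][l.name] * l.thickness_mm * CM_PER_MM
            for l in scenario.layers
        }
        if np.min(c) < -0.5:
            raise InvalidInputError(
                f"scenario {scenario.name!r} drives {solute} to "
                f"{np.min(c):.2f} µmol/L: consumption rates exceed the "
                "diffusive supply; reduce them or shrink the zone"
            )
        members[solute] = DepthProfile(
            analyte=solute,
            depths=z,
            values=np.maximum(c, 0.0),
            light_intensity=scenario.light_intensity,
        )
    truth = SteadyTruth(
        zone_rates=zone_rates,
        zone_areal=zone_areal,
        boundary_flux_top=flux_top,
        boundary_flux_bottom=flux_bot,
        areal_total=areal,
    )
    pset = ProfileSet(
        o2=members.get("O2"),
        s_tot=members.get("S_tot"),
        metadata={"scenario": scenario.name, "light_intensity": scenario.light_intensity},
    )
    return SteadyStateResult(
        profiles=pset, truth=truth, scenario=scenario, concentrations=concentrations
    )


@dataclass
class LightDarkResult:
    """Per-depth time series of O₂ and S_tot around a dark shift."""

    times_s: np.ndarray
    depths_mm: np.ndarray
    fields: dict[str, np.ndarray]  # solute -> (n_times, n_depths)
    scenario: MatScenario
    switch_time_s: float

    def series(self, solute: str, depth_mm: float) -> tuple[np.ndarray, np.ndarray]:
        """Concentration time series at the grid node nearest ``depth_mm``."""
        i = int(np.argmin(np.abs(self.depths_mm - depth_mm)))
        return self.times_s, self.fields[solute][:, i]


def simulate_lightdark(
    scenario: MatScenario,
    switch_time_s: float = 0.0,
    duration_s: float = 20.0,
    dt_s: float = 0.05,
) -> LightDarkResult:
    """Integrate the transient PDE through a light→dark shift.

    The initial condition is the pre-switch steady state (photosynthetic
    terms on); at ``switch_time_s`` the photosynthetic terms are zeroed and
    the diffusion–reaction system relaxes.  Crank–Nicolson stepping
    (unconditionally stable, second order) with default dt = 0.05 s.

    Immediately after the switch, ∂C/∂t at any depth equals minus the local
    photosynthetic term — the physical basis of the light–dark shift method.
    """
    if dt_s <= 0 or duration_s <= 0:
        raise InvalidInputError("dt and duration must be > 0")
    z = scenario.grid()
    h_cm = scenario.grid_mm * CM_PER_MM
    n = len(z)
    times = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    fields: dict[str, np.ndarray] = {}
    for solute in SOLUTES:
        if solute not in scenario.top_bc:
            continue
        d = scenario.diffusion[solute]
        r_on = scenario.rate_field(solute, include_photo=True)
        r_off = scenario.rate_field(solute, include_photo=False)
        c = _steady_solve(
            scenario.top_bc[solute], scenario.bottom_bc[solute], r_on, d, h_cm
        )
        lam = d * dt_s / (h_cm * h_cm)
        m = n - 2
        # Crank-Nicolson matrices on interior nodes.
        ab = np.zeros((3, m))
        ab[0, 1:] = -lam / 2
        ab[1, :] = 1 + lam
        ab[2, :-1] = -lam / 2
        out = np.empty((len(times), n))
        out[0] = c
        prev_norm = np.linalg.norm(c)
        for k in range(1, len(times)):
            t_mid = 0.5 * (times[k - 1] + times[k])
            r = r_off if t_mid >= switch_time_s else r_on
            interior = c[1:-1]
            lap = c[:-2] - 2 * interior + c[2:]
            rhs = interior + 0.5 * lam * lap + dt_s * r[1:-1]
            # lap already carries the explicit-side boundary values; only the
            # implicit-side Dirichlet terms are moved to the RHS here.
            rhs[0] += 0.5 * lam * scenario.top_bc[solute]
            rhs[-1] += 0.5 * lam * scenario.bottom_bc[solute]
            new = c.copy()
            new[1:-1] = solve_banded((1, 1), ab, rhs)
            c = new
            norm = np.linalg.norm(c)
            if not np.isfinite(norm) or norm > 1e6 * max(prev_norm, 1.0):
                raise NumericalFailureError("transient solve diverged")
            out[k] = c
        fields[solute] = out
    return LightDarkResult(
        times_s=times, depths_mm=z, fields=fields, scenario=scenario,
        switch_time_s=switch_time_s,
    )


# ---------------------------------------------------------------------------
# Diel SIP generator


@dataclass(frozen=True)
class Phase:
    """One contiguous stretch of the diel schedule.

    ``mode`` ∈ {"dark", "AP", "OP"}; ``cfix_flux`` is the imposed bulk
    carbon-fixation flux (mmol C m⁻² h⁻¹); ``doc_excretion`` scales DOC
    release (active only when mode == "OP"); ``uptake`` maps guild/subgroup
    labels to FA labeling rates (‰ h⁻¹).
    """

    name: str
    t_start_h: float
    t_end_h: float
    light: float
    mode: str
    cfix_flux: float
    doc_excretion: float = 0.0
    uptake: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("dark", "AP", "OP"):
            raise InvalidInputError("phase mode must be dark, AP or OP")
        if self.t_end_h <= self.t_start_h:
            raise InvalidInputError(f"phase {self.name!r}: end must exceed start")


@dataclass
class DielSIPScenario:
    """Specification of a simulated diel ¹³C-labeling experiment."""

    name: str
    phases: Sequence[Phase]
    areal_carbon: float = 500.0  # mmol C m⁻²
    dic_atom_fraction: float = 0.06
    fa_names: Sequence[str] = ()
    fa_baseline_delta: Mapping[str, float] = field(default_factory=dict)
    doc_dark_decay: float = 0.5  # h⁻¹, first-order loss of DOC label in the dark
    noise_sigma_delta: float = 0.0  # ‰, replicate noise on FA series
    sample_dt_h: float = 0.5
    seed: int = 0

    def __post_init__(self):
        prev_end = None
        for ph in self.phases:
            if prev_end is not None and not np.isclose(ph.t_start_h, prev_end):
                raise InvalidInputError("phases must be contiguous")
            prev_end = ph.t_end_h
        if not (0.0 < self.dic_atom_fraction < 1.0):
            raise InvalidInputError("DIC atom fraction must lie in (0, 1)")
        if self.areal_carbon <= 0:
            raise InvalidInputError("areal_carbon must be > 0")


@dataclass
class DielSIPTruth:
    cfix_flux_per_phase: dict[str, float]
    phase_intervals: dict[str, tuple[float, float]]
    uptake_per_phase: dict[str, dict[str, float]]
    dic_excess: float


@dataclass
class DielSIPResult:
    series: dict[str, SIPSeries]  # keys: mat_bulk, DIC, DOC, FA:<name>
    truth: DielSIPTruth
    scenario: DielSIPScenario


def simulate_diel_sip(scenario: DielSIPScenario) -> DielSIPResult:
    """Generate mat, DIC, DOC and per-FA label trajectories for a schedule.

    Bulk-mat atom fraction integrates the linearized label balance
    dx/dt = F × (x_DIC − x_nat) / A with x_nat the natural-abundance start
    point; DIC is held at the post-addition atom fraction; DOC enrichment
    (excess over 1) rises ∝ excretion × fixation during OP phases and decays
    first-order in the dark; each FA's δ¹³C integrates the uptake rate of
    its guild/subgroup in the current phase.  Replicate noise (if any) is
    Gaussian on the δ scale with the scenario seed.
    """
    from .sip import assign_guilds  # local import to avoid cycle at module load

    rng = np.random.default_rng(scenario.seed)
    t0 = scenario.phases[0].t_start_h
    t1 = scenario.phases[-1].t_end_h
    times = np.arange(t0, t1 + scenario.sample_dt_h / 2, scenario.sample_dt_h)
    x_nat = R_VPDB / (1.0 + R_VPDB)
    dic_excess = scenario.dic_atom_fraction - x_nat

    def phase_at(t: float) -> Phase:
        for ph in scenario.phases:
            if ph.t_start_h <= t < ph.t_end_h:
                return ph
        return scenario.phases[-1]

    # integrate on the sample grid (piecewise-constant forcing per phase)
    x_mat = np.empty_like(times)
    x_mat[0] = x_nat
    doc_excess = np.zeros_like(times)
    guilds = {g.fa: g for g in assign_guilds(scenario.fa_names)}
    fa_delta = {
        name: np.full_like(times, scenario.fa_baseline_delta.get(name, -30.0))
        for name in scenario.fa_names
    }
    for k in range(1, len(times)):
        dt = times[k] - times[k - 1]
        ph = phase_at(0.5 * (times[k - 1] + times[k]))
        x_mat[k] = x_mat[k - 1] + ph.cfix_flux * dic_excess / scenario.areal_carbon * dt
        growth = ph.doc_excretion * ph.cfix_flux * dt if ph.mode == "OP" else 0.0
        decay = scenario.doc_dark_decay * doc_excess[k - 1] * dt if ph.mode == "dark" else 0.0
        doc_excess[k] = max(0.0, doc_excess[k - 1] + growth - decay)
        for name in scenario.fa_names:
            g = guilds[name]
            key = g.subgroup if g.subgroup else g.guild
            rate = ph.uptake.get(key, ph.uptake.get(g.guild, 0.0))
            fa_delta[name][k] = fa_delta[name][k - 1] + rate * dt

    series: dict[str, SIPSeries] = {
        "mat_bulk": SIPSeries("mat_bulk", times, x_mat, scale="atom_fraction"),
        "DIC": SIPSeries(
            "DIC", times, np.full_like(times, scenario.dic_atom_fraction),
            scale="atom_fraction",
        ),
        "DOC": SIPSeries("DOC", times, 1.0 + doc_excess, scale="ratio"),
    }
    for name in scenario.fa_names:
        vals = fa_delta[name]
        if scenario.noise_sigma_delta > 0:
            vals = vals + rng.normal(0.0, scenario.noise_sigma_delta, size=vals.shape)
        series[f"FA:{name}"] = SIPSeries(f"FA:{name}", times, vals, scale="delta")
    truth = DielSIPTruth(
        cfix_flux_per_phase={ph.name: ph.cfix_flux for ph in scenario.phases},
        phase_intervals={ph.name: (ph.t_start_h, ph.t_end_h) for ph in scenario.phases},
        uptake_per_phase={ph.name: dict(ph.uptake) for ph in scenario.phases},
        dic_excess=dic_excess,
    )
    return DielSIPResult(series=series, truth=truth, scenario=scenario)


# ---------------------------------------------------------------------------
# Noise, downsampling, presets


def add_noise(obj, sigma, seed: int):
    """Return a copy of a DepthProfile / ProfileSet / SIPSeries with i.i.d.
    Gaussian noise of standard deviation ``sigma`` added to the values.

    ``sigma = 0`` returns an identical copy; the same seed reproduces the
    same draw.  For a ProfileSet, ``sigma`` may be a mapping per analyte.
    """
    if isinstance(obj, ProfileSet):
        rng = np.random.default_rng(seed)
        new = {}
        for attr in ("o2", "h2s", "ph", "s_tot"):
            p = getattr(obj, attr)
            if p is None:
                new[attr] = None
                continue
            s = sigma.get(p.analyte, 0.0) if isinstance(sigma, Mapping) else sigma
            if s < 0:
                raise InvalidInputError("sigma must be >= 0")
            vals = p.values + rng.normal(0.0, s, size=p.values.shape) if s > 0 else p.values.copy()
            if p.analyte != "pH":
                vals = np.maximum(vals, 0.0)
            new[attr] = replace(p, values=vals)
        return ProfileSet(metadata=dict(obj.metadata), **new)
    if sigma < 0:
        raise InvalidInputError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    if isinstance(obj, DepthProfile):
        vals = obj.values + rng.normal(0.0, sigma, size=obj.values.shape) if sigma > 0 else obj.values.copy()
        if obj.analyte != "pH":
            vals = np.maximum(vals, 0.0)
        return replace(obj, values=vals)
    if isinstance(obj, SIPSeries):
        vals = obj.values + rng.normal(0.0, sigma, size=obj.values.shape) if sigma > 0 else obj.values.copy()
        return replace(obj, values=vals)
    raise InvalidInputError(f"cannot add noise to {type(obj).__name__}")


def downsample_profile(profile: DepthProfile, spacing_mm: float = 0.18,
                       spacing_water_mm: float = 0.45) -> DepthProfile:
    """Resample a fine simulated profile at microsensor step sizes.

    Points are taken at ``spacing_water_mm`` in the water column (depth < 0)
    and ``spacing_mm`` inside the mat, by nearest-node selection on the
    simulated grid — the explicit counterpart of the profiling resolution
    (~180 µm in the mat, ~450 µm above).
    """
    z = profile.depths
    targets = np.concatenate([
        -np.arange(0.0, -z[0] + 1e-9, spacing_water_mm)[::-1],
        np.arange(spacing_mm, z[-1] + 1e-9, spacing_mm),
    ])
    idx = np.unique([int(np.argmin(np.abs(z - t))) for t in targets])
    return replace(profile, depths=z[idx], values=profile.values[idx])


#: Shared slab geometry of the presets: 1 mm water (0.7 mm free water +
#: 0.3 mm diffusive boundary layer) over a 6 mm mat.  Mat coordinates:
#: surface SOB blanket 0–0.3, cyanobacterial layer 0.3–1.1 (split so the
#: upper 0.2 mm can host near-surface O₂ consumption), a slab 1.1–1.6 the
#: SOB occupy after migrating, an inert gap, the sulfide-production zone at
#: 3–5 mm, and a bottom slab above the N₂-purged bottom chamber.
_PRESET_GEOMETRY = (
    ("water_column", 0.7, True),
    ("dbl", 0.3, True),
    ("sob_layer", 0.3, False),
    ("cyano_upper", 0.2, False),
    ("cyano_lower", 0.6, False),
    ("sob_below", 0.5, False),
    ("gap", 1.4, False),
    ("production_zone", 2.0, False),
    ("bottom", 1.0, False),
)


def _preset_layers(rates=None, photo_rates=None):
    """Assemble the shared preset geometry with per-slab rate dictionaries."""
    rates = rates or {}
    photo_rates = photo_rates or {}
    return [
        Layer(name, thick, rates=rates.get(name, {}),
              photo_rates=photo_rates.get(name, {}), is_water=water)
        for name, thick, water in _PRESET_GEOMETRY
    ]


def scenario_library() -> dict[str, object]:
    """Named presets mirroring the four light regimes of the incubation.

    * ``dark`` — SOB on the surface consume the upward sulfide flux with the
      little O₂ available; sulfide production at 3–5 mm mat depth; no
      photosynthesis.  Concave O₂/S_tot near the surface, convex S_tot at
      depth.
    * ``low_light_ap`` — at 7–19 µmol photons m⁻² s⁻¹ the cyanobacterial
      layer (0.3–1.1 mm) runs anoxygenic photosynthesis: the sulfide
      consumption zone expands into it; no net O₂ production.
    * ``op_sob_below`` — at ≥89 µmol photons m⁻² s⁻¹ the cyanobacteria run
      oxygenic photosynthesis (O₂ peak above the water-column value) and the
      SOB have migrated below them, oxidizing the upward sulfide flux with
      photosynthetic O₂.
    * ``dcmu`` — OP inhibited; only AP remains and O₂ penetrates ≤ ~0.5 mm.
    * ``ap_recovery`` — the three-zone oracle scenario (sulfide consumption
      in the cyano layer, inert zone, production at depth) with inert
      surroundings so boundary fluxes fall in linear segments.
    * ``diel_sip`` — a DielSIPScenario following the dark → AP → OP light
      staircase with guild-specific uptake (SRB subgroup 1 active only
      during OP, subgroup 3 dominant during AP).
    """
    presets: dict[str, object] = {}
    # Aerobic sulfide oxidation at the surface consumes S_tot and O2 at the
    # incomplete-oxidation ratio ~2.3; the O2 consumption is held just below
    # the diffusion-limited critical rate so O2 vanishes within ~0.5 mm
    # without the (unphysical) negative dip of a constant-rate zone.
    presets["dark"] = MatScenario(
        name="dark",
        layers=_preset_layers(rates={
            "sob_layer": {"S_tot": -0.095, "O2": -0.041},
            "cyano_upper": {"O2": -0.041},
            "production_zone": {"S_tot": 0.05},
        }),
        top_bc={"O2": 15.0, "S_tot": 250.0},
        bottom_bc={"O2": 0.0, "S_tot": 120.0},
        light_intensity=0.0,
    )
    presets["low_light_ap"] = MatScenario(
        name="low_light_ap",
        layers=_preset_layers(
            rates={
                "sob_layer": {"S_tot": -0.09, "O2": -0.039},
                "cyano_upper": {"O2": -0.039},
                "production_zone": {"S_tot": 0.04},
            },
            photo_rates={
                "cyano_upper": {"S_tot": -0.2},
                "cyano_lower": {"S_tot": -0.2},
            },
        ),
        top_bc={"O2": 15.0, "S_tot": 250.0},
        bottom_bc={"O2": 0.0, "S_tot": 120.0},
        light_intensity=7.0,
    )
    presets["op_sob_below"] = MatScenario(
        name="op_sob_below",
        layers=_preset_layers(
            rates={
                "cyano_upper": {"O2": -0.01},
                "cyano_lower": {"O2": -0.01},
                "sob_below": {"S_tot": -0.15, "O2": -0.065},
                "gap": {"O2": -0.002},
                "production_zone": {"S_tot": 0.05},
            },
            photo_rates={
                "cyano_upper": {"O2": 0.5, "S_tot": -0.05},
                "cyano_lower": {"O2": 0.5, "S_tot": -0.05},
            },
        ),
        top_bc={"O2": 15.0, "S_tot": 60.0},
        bottom_bc={"O2": 0.0, "S_tot": 120.0},
        light_intensity=89.0,
    )
    presets["dcmu"] = MatScenario(
        name="dcmu",
        layers=_preset_layers(
            rates={
                "sob_layer": {"S_tot": -0.1, "O2": -0.041},
                "cyano_upper": {"O2": -0.041},
                "production_zone": {"S_tot": 0.03},
            },
            photo_rates={
                "cyano_upper": {"S_tot": -0.25},
                "cyano_lower": {"S_tot": -0.25},
            },
        ),
        top_bc={"O2": 15.0, "S_tot": 250.0},
        bottom_bc={"O2": 0.0, "S_tot": 80.0},
        light_intensity=315.0,
    )
    presets["ap_recovery"] = MatScenario(
        name="ap_recovery",
        layers=_preset_layers(
            rates={"production_zone": {"S_tot": 0.05}},
            photo_rates={
                "cyano_upper": {"S_tot": -0.2},
                "cyano_lower": {"S_tot": -0.2},
            },
        ),
        top_bc={"O2": 15.0, "S_tot": 250.0},
        bottom_bc={"O2": 0.0, "S_tot": 120.0},
        light_intensity=7.0,
    )
    # Diel SIP schedule: dark (0-8 h), AP at 7/19 (8-14 h), OP at 89/315
    # (14-20 h).  Uptake in permil/h per guild or SRB subgroup.
    presets["diel_sip"] = DielSIPScenario(
        name="diel_sip",
        phases=[
            Phase("dark", 0.0, 8.0, light=0.0, mode="dark", cfix_flux=0.3,
                  uptake={"cyanobacteria": 0.5, "SRB-FA3": 1.0, "SRB-FA2": 0.4,
                          "SOB": 0.8, "ungrouped": 0.3}),
            Phase("ap_low", 8.0, 14.0, light=19.0, mode="AP", cfix_flux=2.0,
                  uptake={"cyanobacteria": 4.0, "SRB-FA3": 2.5, "SRB-FA2": 0.8,
                          "SOB": 0.5, "ungrouped": 0.4}),
            Phase("op_high", 14.0, 20.0, light=315.0, mode="OP", cfix_flux=6.0,
                  doc_excretion=0.05,
                  uptake={"cyanobacteria": 9.0, "SRB-FA1": 3.0, "SRB-FA2": 2.0,
                          "SRB-FA3": 1.0, "SOB": 2.5, "ungrouped": 0.5}),
        ],
        fa_names=(
            "C16:1ω9", "C18:1ω9", "C16:2", "C18:2",
            "aiC15:0", "iC15:0", "10Me-C16:0", "aiC17:0", "iC17:0", "iC17:1",
            "C15:1", "C17:0", "C17:1",
            "C16:1ω7", "C18:1ω7",
        ),
    )
    return presets


def load_scenario(source) -> MatScenario | DielSIPScenario:
    """Build a scenario from a YAML/dict configuration.

    A mapping with a ``layers`` key becomes a :class:`MatScenario` (each
    layer: name, thickness_mm, optional rates / photo_rates / is_water);
    one with a ``phases`` key becomes a :class:`DielSIPScenario`.  ``source``
    may be a path, an open file, a YAML string, or an already-parsed dict.
    """
    import yaml

    if isinstance(source, Mapping):
        cfg = dict(source)
    else:
        if hasattr(source, "read"):
            text = source.read()
        else:
            text = str(source)
            try:
                from pathlib import Path

                if "\n" not in text and Path(text).exists():
                    text = Path(text).read_text()
            except OSError:  # pragma: no cover - exotic path objects
                pass
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, Mapping):
        raise InvalidInputError("scenario config must be a mapping")
    if "layers" in cfg:
        layers = [Layer(**spec) for spec in cfg["layers"]]
        kwargs = {k: v for k, v in cfg.items() if k != "layers"}
        return MatScenario(layers=layers, **kwargs)
    if "phases" in cfg:
        phases = [Phase(**spec) for spec in cfg["phases"]]
        kwargs = {k: v for k, v in cfg.items() if k != "phases"}
        return DielSIPScenario(phases=phases, **kwargs)
    raise InvalidInputError("scenario config needs a 'layers' or 'phases' key")


def get_scenario(name: str):
    """Fetch one preset by name (unknown names are an invalid input)."""
    lib = scenario_library()
    if name not in lib:
        raise InvalidInputError(
            f"unknown preset {name!r}; available: {sorted(lib)}"
        )
    return lib[name]


def apply_sob_migration_rule(
    scenario: MatScenario,
    feasible: tuple[float, float] = (2.0 / 3.0, 2.5),
) -> tuple[MatScenario, bool]:
    """Relocate the SOB consumption terms below the cyanobacterial layer when
    the surface layer's S_tot:O₂ consumption-flux ratio leaves the feasible
    stoichiometric window.

    The simple structural rule: take the ratio of S_tot to O₂ consumption in
    the surface ``sob_layer``, and if it falls outside ``feasible`` (or O₂
    consumption is zero while sulfide consumption is not), move that slab's
    rates into the ``sob_below`` slab.  Returns (possibly modified scenario,
    migrated?).
    """
    names = [l.name for l in scenario.layers]
    if "sob_layer" not in names or "sob_below" not in names:
        raise InvalidInputError("scenario lacks sob_layer/sob_below slabs")
    surf = scenario.layers[names.index("sob_layer")]
    s_cons = -surf.rates.get("S_tot", 0.0)
    o_cons = -surf.rates.get("O2", 0.0)
    if s_cons <= 0 and o_cons <= 0:
        return scenario, False
    ratio = s_cons / o_cons if o_cons > 0 else np.inf
    if feasible[0] <= ratio <= feasible[1]:
        return scenario, False
    new_layers = list(scenario.layers)
    new_layers[names.index("sob_layer")] = replace(surf, rates={})
    below = scenario.layers[names.index("sob_below")]
    new_layers[names.index("sob_below")] = replace(below, rates=dict(surf.rates))
    return replace(scenario, layers=new_layers), True
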