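"""Stoichiometric conversion of photosynthesis and sulfide-oxidation rates
into predicted CO₂-fixation rates.

Four reactions span the mat's autotrophic carbon budget:

* oxygenic photosynthesis (OP):         H₂O + CO₂ → O₂ + CH₂O
* anoxygenic photosynthesis (AP):       2 H₂S + CO₂ → 2 S⁰ + CH₂O + H₂O
* incomplete aerobic sulfide oxidation: H₂S + 0.4 O₂ + 0.1 CO₂ → S⁰ + 0.1 CH₂O + 0.9 H₂O
* complete aerobic sulfide oxidation:   H₂S + 1.5 O₂ + 0.5 CO₂ + 0.5 H₂O → SO₄²⁻ + 0.5 CH₂O + 2 H⁺

The two sulfide-oxidation reactions are end members at a fixed energy
conservation efficiency (16.9 % for autotrophic aerobic sulfide oxidation in
these mats): oxidizing to elemental sulfur consumes little O₂ and fixes
little carbon, oxidizing through to sulfate consumes much O₂ and fixes five
times as much.  Sulfur-oxidizing bacteria (SOB) mix the two products, and
the mixture is pinned by the observed S_tot:O₂ consumption-flux ratio r:

    O₂ per S_tot = 1/r = 0.4 f + 1.5 (1 − f),
    C yield       = 0.1 f + 0.5 (1 − f),

where f is the fraction of sulfide oxidized only to S⁰.  Feasible ratios lie
in [2/3, 2.5]; outside that window the SOB cannot balance the imposed fluxes
(the condition that triggers their migration) and an
:class:`~matbgc.errors.InfeasibleRatioError` is raised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

from .errors import InfeasibleRatioError, InvalidInputError

__all__ = [
    "Reaction",
    "REACTIONS",
    "SOBPartition",
    "PhotosynthesisBudget",
    "check_reaction_balance",
    "cfix_from_op",
    "cfix_from_ap",
    "sob_partition_from_ratio",
    "ratio_from_partition",
    "sob_cfix",
    "budget",
]

logger = logging.getLogger(__name__)

#: Elemental/charge composition of the species appearing in the reactions.
_COMPOSITION: dict[str, dict[str, float]] = {
    "H2S": {"H": 2, "S": 1},
    "O2": {"O": 2},
    "CO2": {"C": 1, "O": 2},
    "H2O": {"H": 2, "O": 1},
    "S0": {"S": 1},
    "SO4^2-": {"S": 1, "O": 4, "charge": -2},
    "CH2O": {"C": 1, "H": 2, "O": 1},
    "H+": {"H": 1, "charge": 1},
}

_ELEMENTS = ("H", "O", "S", "C", "charge")


@dataclass(frozen=True)
class Reaction:
    """A reaction as signed stoichiometric coefficients (negative = consumed)."""

    label: str
    coefficients: Mapping[str, float]

    def __post_init__(self):
        unknown = set(self.coefficients) - set(_COMPOSITION)
        if unknown:
            raise InvalidInputError(f"unknown species {sorted(unknown)}")
        object.__setattr__(self, "coefficients", dict(self.coefficients))

    def __str__(self) -> str:
        def side(sign):
            parts = []
            for sp, nu in self.coefficients.items():
                if nu * sign > 0:
                    mag = abs(nu)
                    parts.append(sp if mag == 1 else f"{mag:g} {sp}")
            return " + ".join(parts)

        return f"{side(-1)} -> {side(+1)}"


#: The four built-in reactions of the mat carbon budget.
REACTIONS: dict[str, Reaction] = {
    "OP": Reaction("OP", {"H2O": -1, "CO2": -1, "O2": 1, "CH2O": 1}),
    "AP": Reaction("AP", {"H2S": -2, "CO2": -1, "S0": 2, "CH2O": 1, "H2O": 1}),
    "SOB_incomplete": Reaction(
        "SOB_incomplete",
        {"H2S": -1, "O2": -0.4, "CO2": -0.1, "S0": 1, "CH2O": 0.1, "H2O": 0.9},
    ),
    "SOB_complete": Reaction(
        "SOB_complete",
        {"H2S": -1, "O2": -1.5, "CO2": -0.5, "H2O": -0.5,
         "SO4^2-": 1, "CH2O": 0.5, "H+": 2},
    ),
}

# End-member coefficients (per mol H2S oxidized) used by the mixing model.
_O2_INCOMPLETE, _O2_COMPLETE = 0.4, 1.5
_C_INCOMPLETE, _C_COMPLETE = 0.1, 0.5
RATIO_MIN = 1.0 / _O2_COMPLETE  # 2/3: pure complete oxidation
RATIO_MAX = 1.0 / _O2_INCOMPLETE  # 2.5: pure incomplete oxidation

#: Energy conservation efficiency of autotrophic aerobic sulfide oxidation.
DEFAULT_EFFICIENCY = 0.169


def check_reaction_balance(rxn: Reaction) -> dict[str, float]:
    """Per-element and charge residuals of a reaction (all 0 when balanced)."""
    residuals = {}
    for el in _ELEMENTS:
        total = 0.0
        for sp, nu in rxn.coefficients.items():
            total += nu * _COMPOSITION[sp].get(el, 0.0)
        residuals[el] = total
    return residuals


def cfix_from_op(gross_op_areal: float) -> float:
    """Predicted CO₂ fixation (nmol C cm⁻² s⁻¹) from areal gross OP.

    One CO₂ fixed per O₂ released (factor 1)."""
    if gross_op_areal < 0:
        raise InvalidInputError("gross OP rate must be >= 0")
    return 1.0 * gross_op_areal


def cfix_from_ap(gross_ap_areal_sulfide: float, sulfide_to_c: float = 0.5) -> float:
    """Predicted CO₂ fixation (nmol C cm⁻² s⁻¹) from areal gross AP.

    AP oxidizes sulfide only to S⁰, donating 2 electrons per sulfide, so two
    sulfide are consumed per CO₂ fixed: the default multiplier is 0.5 mol C
    per mol sulfide.  The multiplier is configurable (and logged when
    changed) because other electron-accounting conventions exist.
    """
    if gross_ap_areal_sulfide < 0:
        raise InvalidInputError("gross AP rate must be >= 0")
    if sulfide_to_c != 0.5:
        logger.info("cfix_from_ap using non-default multiplier %g", sulfide_to_c)
    return sulfide_to_c * gross_ap_areal_sulfide


@dataclass(frozen=True)
class SOBPartition:
    """Product partition of aerobic sulfide oxidation.

    ``f_s0`` is the fraction of sulfide oxidized only to elemental sulfur;
    ``o2_per_s`` and ``c_yield`` are the f-weighted averages of the
    incomplete/complete end-member coefficients; ``efficiency`` is the
    energy-conservation fraction already embodied in the end-member yields
    (carried as metadata).
    """

    f_s0: float
    o2_per_s: float
    c_yield: float
    efficiency: float = DEFAULT_EFFICIENCY

    def __post_init__(self):
        if not (0.0 <= self.f_s0 <= 1.0):
            raise InvalidInputError(f"f_s0={self.f_s0} outside [0, 1]")
        if not (_O2_INCOMPLETE <= self.o2_per_s <= _O2_COMPLETE):
            raise InvalidInputError(f"o2_per_s={self.o2_per_s} outside [0.4, 1.5]")
        if not (_C_INCOMPLETE <= self.c_yield <= _C_COMPLETE):
            raise InvalidInputError(f"c_yield={self.c_yield} outside [0.1, 0.5]")


def sob_partition_from_ratio(
    r: float, efficiency: float = DEFAULT_EFFICIENCY
) -> SOBPartition:
    """Solve the two-end-member mixing for an observed S_tot:O₂ ratio.

    f is solved from 0.4 f + 1.5 (1 − f) = 1/r; the carbon yield follows as
    0.1 f + 0.5 (1 − f).  r = 2.5 gives the pure-S⁰ end member
    (f = 1, yield 0.1); r = 2/3 the pure-sulfate end member (f = 0,
    yield 0.5).  Ratios outside [2/3, 2.5] raise
    :class:`~matbgc.errors.InfeasibleRatioError` naming the nearest feasible
    end member.
    """
    if r <= 0:
        raise InvalidInputError(f"consumption ratio must be > 0, got {r}")
    if r > RATIO_MAX + 1e-12:
        raise InfeasibleRatioError(r, nearest="SOB_incomplete (f_s0=1, yield 0.1)")
    if r < RATIO_MIN - 1e-12:
        raise InfeasibleRatioError(r, nearest="SOB_complete (f_s0=0, yield 0.5)")
    o2_per_s = 1.0 / r
    f = (_O2_COMPLETE - o2_per_s) / (_O2_COMPLETE - _O2_INCOMPLETE)
    f = min(1.0, max(0.0, f))
    c_yield = _C_INCOMPLETE * f + _C_COMPLETE * (1.0 - f)
    return SOBPartition(f_s0=f, o2_per_s=o2_per_s, c_yield=c_yield,
                        efficiency=efficiency)


def ratio_from_partition(partition: SOBPartition) -> float:
    """Inverse of :func:`sob_partition_from_ratio` (round-trips to 1e-12)."""
    o2 = _O2_INCOMPLETE * partition.f_s0 + _O2_COMPLETE * (1.0 - partition.f_s0)
    return 1.0 / o2


def sob_cfix(j_stot_into_sob: float, partition: SOBPartition) -> float:
    """Predicted CO₂ fixation by SOB from the sulfide flux into their layer.

    C fixed = J(S_tot) × c_yield, both in nmol cm⁻² s⁻¹.
    """
    if j_stot_into_sob < 0:
        raise InvalidInputError("sulfide flux into the SOB layer must be >= 0")
    return j_stot_into_sob * partition.c_yield


@dataclass(frozen=True)
class PhotosynthesisBudget:
    """Predicted carbon-fixation budget of the mat's autotrophs.

    All rates nmol cm⁻² s⁻¹ (C units for the cfix fields); ``ap_fraction``
    is AP/(AP+OP) in carbon-fixation units.
    """

    gross_op_areal: float
    gross_ap_areal: float
    cfix_op: float
    cfix_ap: float
    cfix_sob: float
    ap_fraction: float

    @property
    def cfix_total(self) -> float:
        return self.cfix_op + self.cfix_ap + self.cfix_sob


def budget(
    gross_op_areal: float,
    gross_ap_areal: float,
    j_stot_sob: float = 0.0,
    r: float | None = None,
    partition: SOBPartition | None = None,
    ap_sulfide_to_c: float = 0.5,
    electron_units: bool = False,
) -> PhotosynthesisBudget:
    """Assemble the predicted CO₂-fixation budget.

    ``r`` (observed S_tot:O₂ consumption ratio of the SOB layer) or an
    explicit ``partition`` sets the SOB carbon yield; with neither, the SOB
    term requires ``j_stot_sob == 0``.  ``ap_fraction`` is computed in
    C-fixation units by default; with ``electron_units=True`` it is computed
    on electron equivalents instead (2 e⁻ per sulfide for AP, 4 e⁻ per O₂
    for OP).
    """
    cfix_op = cfix_from_op(gross_op_areal)
    cfix_ap = cfix_from_ap(gross_ap_areal, ap_sulfide_to_c)
    if partition is None:
        if r is not None:
            partition = sob_partition_from_ratio(r)
        elif j_stot_sob != 0.0:
            raise InvalidInputError(
                "a ratio r or an SOBPartition is required when j_stot_sob > 0"
            )
    cfix_sob = sob_cfix(j_stot_sob, partition) if partition is not None else 0.0
    if electron_units:
        ap_term = 2.0 * gross_ap_areal
        op_term = 4.0 * gross_op_areal
    else:
        ap_term, op_term = cfix_ap, cfix_op
    total = ap_term + op_term
    ap_fraction = ap_term / total if total > 0 else 0.0
    return PhotosynthesisBudget(
        gross_op_areal=gross_op_areal,
        gross_ap_areal=gross_ap_areal,
        cfix_op=cfix_op,
        cfix_ap=cfix_ap,
        cfix_sob=cfix_sob,
        ap_fraction=ap_fraction,
    )
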