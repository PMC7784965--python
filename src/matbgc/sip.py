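"""Stable-isotope-probing (¹³C-SIP) arithmetic.

The incubation adds ¹³C-bicarbonate to the water (DIC pool raised to an atom
fraction of ≈6 %), and label flow is then followed into bulk mat biomass,
the porewater DOC pool, and individual fatty acids (FAs).  This module
provides

* δ¹³C ⇄ atom-fraction conversions (VPDB scale),
* bulk CO₂-assimilation fluxes from the rise of mat labeling corrected for
  the DIC-pool labeling,
* relative ¹³C/¹²C enrichment of the (unquantified) DOC pool,
* Δδ¹³C label trajectories per FA and the FA-RUR statistic — each FA's
  labeling rate over an interval normalized by the summed rates of its
  group,
* the fixed FA → guild assignments (cyanobacteria, sulfate/sulfur-reducing
  bacteria (SRB) with three subgroups, sulfur-oxidizing bacteria (SOB)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InvalidInputError, ScaleMismatchError

__all__ = [
    "R_VPDB",
    "SIPSeries",
    "delta_to_atom_fraction",
    "atom_fraction_to_delta",
    "delta_delta",
    "mat_cfix_flux",
    "doc_relative_enrichment",
    "FaRurResult",
    "fa_rur",
    "CYANO_FA",
    "SRB_FA",
    "SOB_FA",
    "SRB_SUBGROUPS",
    "assign_guilds",
]

#: ¹³C/¹²C ratio of the VPDB standard.
R_VPDB = 0.0111802


def delta_to_atom_fraction(delta):
    """Convert δ¹³C (‰ vs VPDB) to ¹³C atom fraction.

    R = R_VPDB (δ/1000 + 1), x = R/(1+R).  Strictly increasing in δ;
    δ = 0 ‰ gives the natural-abundance fraction ≈ 0.011056.
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= -1000.0):
        raise InvalidInputError("delta values must exceed -1000 permil")
    r = R_VPDB * (delta / 1000.0 + 1.0)
    x = r / (1.0 + r)
    return float(x) if x.ndim == 0 else x


def atom_fraction_to_delta(x):
    """Inverse of :func:`delta_to_atom_fraction` (round-trips to 1e-12)."""
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0.0) | (x >= 1.0)):
        raise InvalidInputError("atom fractions must lie in (0, 1)")
    r = x / (1.0 - x)
    delta = (r / R_VPDB - 1.0) * 1000.0
    return float(delta) if delta.ndim == 0 else delta


@dataclass
class SIPSeries:
    """Time series of the isotopic composition of one carbon pool.

    ``pool`` is ``mat_bulk``, ``DIC``, ``DOC`` or ``FA:<name>``; ``scale``
    tags the values as ``"delta"`` (δ¹³C, ‰ vs VPDB), ``"atom_fraction"``
    (0–1) or ``"ratio"`` (a dimensionless ¹³C/¹²C ratio relative to t₀, as
    produced by :func:`doc_relative_enrichment`).  Times are hours since
    incubation start, strictly increasing.
    """

    pool: str
    times_h: np.ndarray
    values: np.ndarray
    scale: str = "delta"

    def __post_init__(self):
        if self.scale not in ("delta", "atom_fraction", "ratio"):
            raise InvalidInputError("scale must be 'delta', 'atom_fraction' or 'ratio'")
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_h.shape != self.values.shape or self.times_h.ndim != 1:
            raise InvalidInputError("times and values must be 1D and congruent")
        if np.any(np.diff(self.times_h) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if self.scale == "atom_fraction" and np.any(
            (self.values <= 0) | (self.values >= 1)
        ):
            raise InvalidInputError("atom fractions must lie in (0, 1)")

    def __len__(self) -> int:
        return len(self.times_h)

    def as_atom_fraction(self) -> "SIPSeries":
        if self.scale == "atom_fraction":
            return self
        if self.scale != "delta":
            raise ScaleMismatchError(
                f"cannot convert a {self.scale!r}-scale series to atom fraction"
            )
        return replace(
            self, values=delta_to_atom_fraction(self.values), scale="atom_fraction"
        )

    def interp(self, times_h) -> np.ndarray:
        times_h = np.asarray(times_h, dtype=float)
        if times_h.min() < self.times_h[0] or times_h.max() > self.times_h[-1]:
            raise InvalidInputError("interpolation times outside the series range")
        return np.interp(times_h, self.times_h, self.values)


def delta_delta(series: SIPSeries) -> SIPSeries:
    """Δδ¹³C: the series minus its own first time point (label increase).

    Requires δ-scale input (atom-fraction series raise a scale mismatch);
    the first element of the result is exactly 0.
    """
    if series.scale != "delta":
        raise ScaleMismatchError(
            f"delta_delta expects a delta-scale series, got {series.scale!r}"
        )
    if len(series) < 2:
        raise InvalidInputError("need at least two time points")
    return replace(series, values=series.values - series.values[0])


def mat_cfix_flux(
    mat: SIPSeries,
    dic: SIPSeries,
    areal_carbon: float,
    interval: tuple[float, float] | None = None,
    method: str = "difference",
) -> float:
    """Bulk CO₂ assimilation flux from the rise of mat ¹³C labeling.

    F = (Δx_mat/Δt) × areal_carbon / mean(x_DIC − x_nat), where x are atom
    fractions, x_nat is the mat's own first time point (natural-abundance
    baseline) and the mean DIC excess is taken over the interval.  With
    ``areal_carbon`` in mmol C m⁻² and times in hours the flux is
    mmol C m⁻² h⁻¹.

    ``method`` is ``"difference"`` (endpoint finite difference, the default)
    or ``"regression"`` (least-squares slope over all points inside the
    interval).  Invariant to a uniform shift of the time axis.
    """
    if areal_carbon <= 0:
        raise InvalidInputError("areal_carbon must be > 0")
    mat = mat.as_atom_fraction()
    dic = dic.as_atom_fraction()
    x_nat = mat.values[0]
    lo = max(mat.times_h[0], dic.times_h[0])
    hi = min(mat.times_h[-1], dic.times_h[-1])
    if interval is not None:
        lo, hi = max(lo, interval[0]), min(hi, interval[1])
    if hi <= lo:
        raise InvalidInputError("mat and DIC series do not overlap on the interval")
    if method == "difference":
        x0, x1 = mat.interp([lo, hi])
        slope = (x1 - x0) / (hi - lo)
    elif method == "regression":
        m = (mat.times_h >= lo) & (mat.times_h <= hi)
        if m.sum() < 2:
            raise InvalidInputError("regression needs >= 2 mat points in interval")
        slope = np.polyfit(mat.times_h[m], mat.values[m], 1)[0]
    else:
        raise InvalidInputError("method must be 'difference' or 'regression'")
    md = (dic.times_h >= lo) & (dic.times_h <= hi)
    dic_t = dic.times_h[md] if md.sum() >= 2 else np.array([lo, hi])
    excess = np.mean(dic.interp(dic_t)) - x_nat
    if excess <= 0:
        raise InvalidInputError(
            "DIC excess labeling is not positive over the interval; "
            "the mat labeling rate is uninterpretable"
        )
    return float(slope * areal_carbon / excess)


def doc_relative_enrichment(doc: SIPSeries) -> SIPSeries:
    """Relative ¹³C/¹²C of the DOC pool, normalized to the first time point.

    DOC is deliberately not quantified (variable oxidation efficiency across
    compounds), so only the isotope-ratio series relative to t₀ is reported;
    the first element is exactly 1 and the output carries the ``"ratio"``
    scale tag.
    """
    if len(doc) < 2:
        raise InvalidInputError("need at least two time points")
    if doc.scale == "ratio":
        ratio = doc.values.copy()
    else:
        x = doc.as_atom_fraction().values
        ratio = x / (1.0 - x)  # 13C/12C
    out = ratio / ratio[0]
    out[0] = 1.0
    return SIPSeries(
        pool=doc.pool, times_h=doc.times_h.copy(), values=out, scale="ratio"
    )


@dataclass(frozen=True)
class FaRurResult:
    """FA-RUR contributions over one interval.

    ``defined`` is False (and ``contributions`` None) when the summed
    labeling rate is not positive — the statistic is reported as undefined
    rather than renormalized, because clipping negative rates would
    fabricate signal.
    """

    interval: tuple[float, float]
    defined: bool
    contributions: dict[str, float] | None
    denominator: float


def fa_rur(
    delta_series: Mapping[str, SIPSeries],
    interval: tuple[float, float],
    members: Sequence[str] | None = None,
) -> FaRurResult:
    """Relative ¹³C uptake-rate contribution of each FA over an interval.

    For each member FA the labeling rate Δδ/Δt is the finite difference of
    its Δδ¹³C (or δ¹³C — the baseline cancels in the difference) between the
    interval endpoints; contributions are each rate divided by the summed
    rates and sum to 1 whenever the sum is positive.  Negative individual
    rates are retained as signed values.
    """
    t0, t1 = interval
    if t1 <= t0:
        raise InvalidInputError("interval end must exceed start")
    names = list(members) if members is not None else list(delta_series)
    missing = [n for n in names if n not in delta_series]
    if missing:
        raise InvalidInputError(f"missing FA series: {missing}")
    rates = {}
    for name in names:
        s = delta_series[name]
        if s.scale != "delta":
            raise ScaleMismatchError(f"{name}: fa_rur expects delta-scale series")
        if t0 < s.times_h[0] or t1 > s.times_h[-1]:
            raise InvalidInputError(
                f"{name}: interval [{t0}, {t1}] h outside the measured times"
            )
        v0, v1 = s.interp([t0, t1])
        rates[name] = (v1 - v0) / (t1 - t0)
    denom = float(sum(rates.values()))
    if denom <= 0:
        return FaRurResult(interval=(t0, t1), defined=False,
                           contributions=None, denominator=denom)
    contributions = {n: r / denom for n, r in rates.items()}
    return FaRurResult(interval=(t0, t1), defined=True,
                       contributions=contributions, denominator=denom)


# ---------------------------------------------------------------------------
# Guild assignment (fixed literature-based tables)

CYANO_FA = ("C16:1ω9", "C18:1ω9", "C16:2", "C18:2")
SRB_FA = (
    "aiC15:0", "iC15:0", "10Me-C16:0", "aiC17:0", "iC17:0", "iC17:1",
    "C15:1", "C17:0", "C17:1",
)
SOB_FA = ("C16:1ω7", "C18:1ω7")
SRB_SUBGROUPS = {
    "SRB-FA1": ("10Me-C16:0", "iC17:1"),
    "SRB-FA2": ("aiC17:0", "iC17:0", "C17:1"),
    "SRB-FA3": ("aiC15:0", "iC15:0", "C15:1", "C17:0"),
}

_GUILD_OF = {name: "cyanobacteria" for name in CYANO_FA}
_GUILD_OF.update({name: "SRB" for name in SRB_FA})
_GUILD_OF.update({name: "SOB" for name in SOB_FA})
_SUBGROUP_OF = {
    name: grp for grp, names in SRB_SUBGROUPS.items() for name in names
}


@dataclass(frozen=True)
class GuildAssignment:
    fa: str
    guild: str  # cyanobacteria | SRB | SOB | other
    subgroup: str  # SRB-FA1/2/3, "ungrouped" for other SRB-FAs, "" otherwise


def assign_guilds(fa_names: Iterable[str]) -> list[GuildAssignment]:
    """Map FA names to guilds and SRB subgroups using the fixed tables.

    Unknown names are assigned guild ``"other"`` with a warning (they are
    kept, not dropped, so downstream totals remain auditable).
    """
    rows = []
    for name in fa_names:
        guild = _GUILD_OF.get(name)
        if guild is None:
            warnings.warn(f"unknown fatty acid {name!r}: assigned guild 'other'",
                          stacklevel=2)
            rows.append(GuildAssignment(fa=name, guild="other", subgroup=""))
            continue
        if guild == "SRB":
            subgroup = _SUBGROUP_OF.get(name, "ungrouped")
        else:
            subgroup = ""
        rows.append(GuildAssignment(fa=name, guild=guild, subgroup=subgroup))
    return rows
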