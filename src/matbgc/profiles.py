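"""Data model, I/O and preprocessing for microsensor depth profiles.

A :class:`DepthProfile` holds one analyte's concentration (or pH) versus
depth at one light state and time; a :class:`ProfileSet` bundles the
co-located O₂ / H₂S / pH profiles from one measurement spot and can derive a
total-sulfide (S_tot) profile from speciation.  A :class:`LayerModel` names
the vertical structure of the mat (water column, diffusive boundary layer,
sulfur-oxidizing-bacteria layer, cyanobacterial layer, sulfide-production
zone) as half-open depth intervals.

Depth convention: 0 at the mat surface, positive downward (mm); overlying
water negative.  File dialect: comma- or tab-delimited tables with
``# key: value`` metadata header lines, either wide (one column per analyte)
or long format (``analyte`` column).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .chem import SpeciationParams, stot_from_h2s
from .errors import FormatError, InvalidInputError, SensorClipWarning

__all__ = [
    "DepthProfile",
    "ProfileSet",
    "LayerModel",
    "read_profiles",
    "write_profiles",
    "correct_depth_for_angle",
    "check_steady_state",
    "align_to_interface",
]

_ANALYTES = {"O2", "H2S", "pH", "S_tot"}

#: Default sensor noise scale (µmol L⁻¹) used for the negative-reading rule.
SENSOR_NOISE_DEFAULT = 1.0


@dataclass
class DepthProfile:
    """One analyte's depth profile at one time/light state.

    depths are mm, strictly increasing, mat surface at 0, positive downward;
    values are µmol L⁻¹ (pH dimensionless).  Small negative concentration
    readings (within −2× ``sensor_noise``) are clipped to zero with a
    warning; larger negatives are rejected as gross errors.
    """

    analyte: str
    depths: np.ndarray
    values: np.ndarray
    light_intensity: float = 0.0  # µmol photons m⁻² s⁻¹
    time_h: float = 0.0
    replicate_id: str = ""
    measurement_angle: float = 0.0  # degrees from vertical
    sensor_noise: float = SENSOR_NOISE_DEFAULT

    def __post_init__(self):
        if self.analyte not in _ANALYTES:
            raise InvalidInputError(
                f"unknown analyte {self.analyte!r}; expected one of {sorted(_ANALYTES)}"
            )
        self.depths = np.asarray(self.depths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.depths.ndim != 1 or self.depths.shape != self.values.shape:
            raise InvalidInputError("depths and values must be 1D arrays of equal length")
        if np.any(~np.isfinite(self.depths)) or np.any(~np.isfinite(self.values)):
            raise InvalidInputError("depths/values must not contain NaN or inf")
        if np.any(np.diff(self.depths) <= 0):
            raise FormatError(f"{self.analyte}: depths must be strictly increasing")
        if self.analyte == "pH":
            if np.any((self.values <= 0) | (self.values >= 14)):
                raise InvalidInputError("pH values must lie within (0, 14)")
        else:
            neg = self.values < 0
            if np.any(self.values < -2.0 * self.sensor_noise):
                raise InvalidInputError(
                    f"{self.analyte}: negative readings beyond -2x sensor noise "
                    f"({-2 * self.sensor_noise:g} µmol/L); refusing to clip"
                )
            if np.any(neg):
                warnings.warn(
                    f"{self.analyte}: clipped {int(neg.sum())} small negative "
                    "reading(s) to 0",
                    SensorClipWarning,
                    stacklevel=2,
                )
                self.values = np.where(neg, 0.0, self.values)

    def __len__(self) -> int:
        return len(self.depths)

    def interp(self, depths_mm) -> np.ndarray:
        """Linear interpolation of values at the requested depths (no
        extrapolation: depths outside the measured range raise)."""
        depths_mm = np.asarray(depths_mm, dtype=float)
        if depths_mm.min() < self.depths[0] or depths_mm.max() > self.depths[-1]:
            raise InvalidInputError(
                "interpolation depths outside the measured range "
                f"[{self.depths[0]}, {self.depths[-1]}] mm"
            )
        return np.interp(depths_mm, self.depths, self.values)

    def window(self, z_min: float, z_max: float) -> "DepthProfile":
        """Sub-profile with z_min ≤ depth ≤ z_max."""
        m = (self.depths >= z_min) & (self.depths <= z_max)
        return replace(self, depths=self.depths[m], values=self.values[m])


@dataclass
class ProfileSet:
    """Co-located O₂, H₂S and pH profiles from one spot, plus derived S_tot."""

    o2: DepthProfile | None = None
    h2s: DepthProfile | None = None
    ph: DepthProfile | None = None
    s_tot: DepthProfile | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        members = [p for p in (self.o2, self.h2s, self.ph, self.s_tot) if p is not None]
        if not members:
            raise InvalidInputError("ProfileSet needs at least one profile")
        rep = {p.replicate_id for p in members}
        t = {p.time_h for p in members}
        if len(rep) > 1 or len(t) > 1:
            raise InvalidInputError(
                "member profiles must share replicate_id and time_h "
                f"(got replicates {rep}, times {t})"
            )

    @property
    def profiles(self) -> dict[str, DepthProfile]:
        out = {}
        for name in ("o2", "h2s", "ph", "s_tot"):
            p = getattr(self, name)
            if p is not None:
                out[p.analyte] = p
        return out

    def derive_stot(self, params: SpeciationParams | None = None) -> "ProfileSet":
        """Return a copy with S_tot computed from H₂S and pH.

        pH is linearly interpolated onto the H₂S depth grid (the sensors sit
        within <1 cm of each other but step independently).
        """
        if self.h2s is None or self.ph is None:
            raise InvalidInputError("deriving S_tot requires both H2S and pH profiles")
        z = self.h2s.depths
        zmin, zmax = self.ph.depths[0], self.ph.depths[-1]
        m = (z >= zmin) & (z <= zmax)
        if not np.any(m):
            raise InvalidInputError("H2S and pH profiles do not overlap in depth")
        ph_on_h2s = self.ph.interp(z[m])
        stot = stot_from_h2s(self.h2s.values[m], ph_on_h2s, params)
        s_tot = replace(self.h2s, analyte="S_tot", depths=z[m], values=stot)
        return replace(self, s_tot=s_tot)


@dataclass(frozen=True)
class LayerModel:
    """Named half-open depth intervals [top, bottom) in mm, ordered by depth.

    The SOB layer may sit above or below the cyanobacterial layer (the
    sulfur oxidizers migrate underneath it once oxygenic photosynthesis
    starts); intervals must not overlap.
    """

    intervals: Mapping[str, tuple[float, float]]

    def __post_init__(self):
        items = sorted(self.intervals.items(), key=lambda kv: kv[1][0])
        prev_bottom = -np.inf
        for name, (top, bottom) in items:
            if bottom <= top:
                raise InvalidInputError(f"layer {name!r}: bottom must exceed top")
            if top < prev_bottom:
                raise InvalidInputError(f"layer {name!r} overlaps the layer above")
            prev_bottom = bottom
        object.__setattr__(self, "intervals", dict(items))

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.intervals[name]

    def boundaries(self) -> np.ndarray:
        """Sorted unique interval edges."""
        edges = set()
        for top, bottom in self.intervals.values():
            edges.update((top, bottom))
        return np.array(sorted(edges))


# ---------------------------------------------------------------------------
# I/O


_META_KEYS = ("light_intensity", "time_h", "replicate_id", "measurement_angle",
              "temperature", "salinity")
_WIDE_COLS = {"o2": "O2", "h2s": "H2S", "ph": "pH", "s_tot": "S_tot"}


def _parse_header(lines: list[str]) -> dict:
    meta = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if not body or ":" not in body:
            continue
        key, _, val = body.partition(":")
        key = key.strip().lower().replace(" ", "_")
        val = val.strip()
        try:
            meta[key] = float(val)
        except ValueError:
            meta[key] = val
    return meta


def read_profiles(source, sensor_noise: float = SENSOR_NOISE_DEFAULT) -> ProfileSet:
    """Read a delimited profile table (path, file object, or string).

    Accepts wide format (columns ``depth_mm`` plus any of ``o2``, ``h2s``,
    ``ph``, ``s_tot``) or long format (columns ``depth_mm``, ``analyte``,
    ``value``).  Metadata come from ``# key: value`` header lines
    (``light_intensity``, ``time_h``, ``replicate_id``,
    ``measurement_angle``).  Rows are sorted by depth; duplicated depths are
    a format error.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    elif hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
    lines = text.splitlines()
    header = [ln for ln in lines if ln.startswith("#")]
    body = "\n".join(ln for ln in lines if not ln.startswith("#") and ln.strip())
    if not body:
        raise FormatError("no data rows found")
    meta = _parse_header(header)
    sep = "\t" if "\t" in body.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(body), sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    if "depth_mm" in df.columns:
        depth_col = "depth_mm"
    elif "depth" in df.columns:
        depth_col = "depth"
    else:
        raise FormatError("missing required depth column 'depth_mm'")
    if df[depth_col].isna().any() or df.drop(columns=[depth_col]).isna().all(axis=None):
        raise FormatError("missing values in depth column")

    prof_kwargs = dict(
        light_intensity=float(meta.get("light_intensity", 0.0)),
        time_h=float(meta.get("time_h", 0.0)),
        replicate_id=str(meta.get("replicate_id", "")),
        measurement_angle=float(meta.get("measurement_angle", 0.0)),
        sensor_noise=sensor_noise,
    )

    def build(analyte: str, depths, values) -> DepthProfile:
        depths = np.asarray(depths, dtype=float)
        values = np.asarray(values, dtype=float)
        order = np.argsort(depths, kind="stable")
        depths, values = depths[order], values[order]
        if np.any(np.diff(depths) <= 0):
            raise FormatError(f"{analyte}: duplicated or non-increasing depths")
        keep = np.isfinite(values)
        return DepthProfile(analyte, depths[keep], values[keep], **prof_kwargs)

    members: dict[str, DepthProfile] = {}
    if "analyte" in df.columns:  # long format
        if "value" not in df.columns:
            raise FormatError("long format requires a 'value' column")
        for analyte, grp in df.groupby("analyte"):
            analyte = str(analyte)
            if analyte not in _ANALYTES:
                raise FormatError(f"unknown analyte {analyte!r} in 'analyte' column")
            members[analyte] = build(analyte, grp[depth_col], grp["value"])
    else:  # wide format
        for col, analyte in _WIDE_COLS.items():
            if col in df.columns:
                members[analyte] = build(analyte, df[depth_col], df[col])
        if not members:
            raise FormatError(
                "no analyte columns found (expected any of o2, h2s, ph, s_tot)"
            )
    return ProfileSet(
        o2=members.get("O2"),
        h2s=members.get("H2S"),
        ph=members.get("pH"),
        s_tot=members.get("S_tot"),
        metadata=meta,
    )


def write_profiles(pset: ProfileSet, path=None, sep: str = ",") -> str:
    """Write a ProfileSet as a wide delimited table with a metadata header.

    All member profiles are written on the union depth grid; analytes not
    measured at a depth are left blank.  Returns the text (and writes it to
    ``path`` if given).  Round-trips with :func:`read_profiles` to 1e-9.
    """
    members = pset.profiles
    ref = next(iter(members.values()))
    meta_lines = [
        f"# light_intensity: {ref.light_intensity:.10g}",
        f"# time_h: {ref.time_h:.10g}",
        f"# replicate_id: {ref.replicate_id}",
        f"# measurement_angle: {ref.measurement_angle:.10g}",
    ]
    for k, v in pset.metadata.items():
        if k not in ("light_intensity", "time_h", "replicate_id", "measurement_angle"):
            meta_lines.append(f"# {k}: {v}")
    grid = np.unique(np.concatenate([p.depths for p in members.values()]))
    frame = pd.DataFrame({"depth_mm": grid})
    inv = {v: k for k, v in _WIDE_COLS.items()}
    for analyte, prof in members.items():
        col = np.full(grid.shape, np.nan)
        idx = np.searchsorted(grid, prof.depths)
        col[idx] = prof.values
        frame[inv[analyte]] = col
    text = "\n".join(meta_lines) + "\n" + frame.to_csv(
        index=False, sep=sep, float_format="%.12g"
    )
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Preprocessing


def correct_depth_for_angle(profile: DepthProfile) -> DepthProfile:
    """Convert along-sensor-axis travel to vertical depth.

    vertical depth = along-axis distance × cos(angle).  The angle metadata is
    reset to 0 afterwards; applying the correction twice therefore warns and
    is a no-op.  Angles ≥ 90° (sensor horizontal or upward) are invalid.
    """
    angle = profile.measurement_angle
    if angle >= 90.0 or angle < 0.0:
        raise InvalidInputError(f"measurement angle {angle}° outside [0°, 90°)")
    if angle == 0.0:
        if profile.measurement_angle == 0.0:
            warnings.warn(
                "angle already 0°: profile treated as vertically corrected",
                stacklevel=2,
            )
        return replace(profile)
    factor = np.cos(np.deg2rad(angle))
    return replace(profile, depths=profile.depths * factor, measurement_angle=0.0)


def check_steady_state(
    a: DepthProfile,
    b: DepthProfile,
    tol: float = 0.05,
    floor: float = 1.0,
) -> tuple[bool, float]:
    """Compare two successive profiles of the same analyte for steadiness.

    Both are interpolated to the common (overlapping) depth range; the
    statistic is max |a−b| / max(max|a|, max|b|, floor), a relative sup-norm
    deviation with a concentration floor that keeps near-zero profiles from
    dividing by ~0.  Symmetric in (a, b).

    Returns ``(steady, deviation)`` with steady = deviation ≤ tol.
    """
    if a.analyte != b.analyte:
        raise InvalidInputError(f"analyte mismatch: {a.analyte} vs {b.analyte}")
    lo = max(a.depths[0], b.depths[0])
    hi = min(a.depths[-1], b.depths[-1])
    if hi <= lo:
        raise InvalidInputError("profiles do not overlap in depth")
    z = np.unique(np.concatenate([
        a.depths[(a.depths >= lo) & (a.depths <= hi)],
        b.depths[(b.depths >= lo) & (b.depths <= hi)],
        [lo, hi],
    ]))
    av, bv = a.interp(z), b.interp(z)
    scale = max(np.max(np.abs(av)), np.max(np.abs(bv)), floor)
    dev = float(np.max(np.abs(av - bv)) / scale)
    return dev <= tol, dev


def align_to_interface(profile: DepthProfile, interface_depth: float) -> DepthProfile:
    """Shift depths so the mat–water interface sits at depth 0.

    ``interface_depth`` is the interface position in the profile's current
    coordinates and must lie within the measured range.
    """
    if not (profile.depths[0] <= interface_depth <= profile.depths[-1]):
        raise InvalidInputError(
            f"interface depth {interface_depth} mm outside the measured range"
        )
    return replace(profile, depths=profile.depths - interface_depth)
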