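"""Surface pressure–area isotherm container, file I/O, and preprocessing.

A Langmuir trough records the surface pressure pi (mN/m) of an insoluble
monolayer while a barrier reduces the area available per molecule
(A, in Angstrom^2/molecule).  This module holds the compression run as a pair
of arrays plus experiment metadata, reads and writes a plain-text dialect
('#'-prefixed ``key: value`` header, two numeric columns ``area, pressure``),
and prepares raw runs for differentiation and interpolation:

* :func:`canonicalize` extracts a strictly monotone compression branch
  (area strictly decreasing, pressure strictly increasing) — raw traces are
  never strictly monotone through first-order plateaus or sensor noise;
* :func:`area_at_pressure` interpolates A(pi) on the canonical branch;
* :func:`smooth` applies local least-squares (Savitzky–Golay) smoothing to
  the pressure channel, off by default everywhere downstream.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import savgol_filter

from .errors import (
    DegenerateIsothermError,
    IsothermFormatError,
    OutOfRangeError,
    ParameterError,
)


@dataclass
class IsothermMeta:
    """Experiment metadata carried alongside an isotherm.

    ``components`` lists (name, molar fraction) pairs summing to 1; the
    subphase is a free-text label (e.g. ``"water"``, ``"DS40"``,
    ``"DS40+Ca2+"``) that the pipeline treats as categorical.  ``extra``
    preserves unrecognized header keys verbatim (as strings).
    """

    components: list[tuple[str, float]] = field(default_factory=list)
    subphase: str = "water"
    temperature_C: float = 20.0
    barrier_speed: float | None = None
    source: str = "synthetic"
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.temperature_C):
            raise ParameterError("temperature_C must be finite")
        if self.components:
            fracs = np.array([f for _, f in self.components], dtype=float)
            if np.any(fracs < -1e-12) or np.any(fracs > 1 + 1e-12):
                raise ParameterError(f"molar fractions must lie in [0, 1], got {fracs}")
            if abs(fracs.sum() - 1.0) > 1e-9:
                raise ParameterError(
                    f"molar fractions must sum to 1 within 1e-9, got sum={fracs.sum()!r}"
                )

    def fraction_of(self, name: str) -> float | None:
        for comp, frac in self.components:
            if comp == name:
                return frac
        return None


@dataclass
class Isotherm:
    """One compression run: paired area/pressure arrays plus metadata.

    Areas are mean molecular areas in Angstrom^2/molecule, pressures are
    surface pressures in mN/m.  Raw point order is preserved; use
    :func:`canonicalize` to obtain a strictly monotone compression branch.
    """

    area: np.ndarray
    pressure: np.ndarray
    meta: IsothermMeta = field(default_factory=IsothermMeta)

    def __post_init__(self) -> None:
        self.area = np.asarray(self.area, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.area.ndim != 1 or self.pressure.ndim != 1:
            raise ParameterError("area and pressure must be 1-D arrays")
        if self.area.size != self.pressure.size:
            raise ParameterError(
                f"area ({self.area.size}) and pressure ({self.pressure.size}) differ in length"
            )
        if self.area.size < 2:
            raise ParameterError("an isotherm needs at least 2 points")
        if not (np.all(np.isfinite(self.area)) and np.all(np.isfinite(self.pressure))):
            raise ParameterError("area and pressure must be finite")
        if np.any(self.area <= 0):
            raise ParameterError("mean molecular areas must be strictly positive")

    @property
    def n(self) -> int:
        return int(self.area.size)

    @property
    def is_canonical(self) -> bool:
        """True when area is strictly decreasing and pressure strictly increasing."""
        return bool(np.all(np.diff(self.area) < 0) and np.all(np.diff(self.pressure) > 0))


@dataclass
class CanonicalizationReport:
    """Bookkeeping for :func:`canonicalize`."""

    n_dropped: int
    reversed: bool
    max_pressure_violation: float  # largest backward pi excursion removed [mN/m]


def _require_canonical(iso: Isotherm, op: str) -> None:
    if not iso.is_canonical:
        raise ParameterError(f"{op} requires a canonicalized isotherm; call canonicalize() first")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _parse_components(text: str) -> list[tuple[str, float]]:
    comps: list[tuple[str, float]] = []
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise IsothermFormatError(f"cannot parse component entry {part!r} (expected name=fraction)")
        name, _, frac = part.partition("=")
        try:
            comps.append((name.strip(), float(frac)))
        except ValueError as exc:
            raise IsothermFormatError(f"bad molar fraction in component entry {part!r}") from exc
    return comps


def read_isotherm(path: str | Path) -> Isotherm:
    """Read an isotherm file (see module docstring for the dialect).

    Header lines are ``# key: value``; the body is two numeric columns
    (area in Angstrom^2/molecule, surface pressure in mN/m), comma- or
    whitespace-delimited.  Unknown header keys are preserved in
    ``meta.extra``.  A malformed numeric row raises
    :class:`IsothermFormatError` naming the line.
    """
    path = Path(path)
    header: dict[str, str] = {}
    areas: list[float] = []
    pressures: list[float] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    header[key.strip()] = value.strip()
                continue
            fields = line.replace(",", " ").split()
            if len(fields) < 2:
                raise IsothermFormatError(
                    f"{path.name}, line {lineno}: expected two columns (area, pressure), got {line!r}"
                )
            try:
                areas.append(float(fields[0]))
                pressures.append(float(fields[1]))
            except ValueError as exc:
                raise IsothermFormatError(
                    f"{path.name}, line {lineno}: malformed numeric row {line!r}"
                ) from exc
    if not areas:
        raise IsothermFormatError(f"{path.name}: no data rows found")

    meta_kwargs: dict = {"source": str(path)}
    extra: dict[str, str] = {}
    for key, value in header.items():
        if key == "components":
            meta_kwargs["components"] = _parse_components(value)
        elif key == "subphase":
            meta_kwargs["subphase"] = value
        elif key == "temperature_C":
            meta_kwargs["temperature_C"] = float(value)
        elif key == "barrier_speed":
            meta_kwargs["barrier_speed"] = float(value)
        elif key == "source":
            meta_kwargs["source"] = value
        else:
            extra[key] = value
    meta = IsothermMeta(**meta_kwargs, extra=extra)
    return Isotherm(np.array(areas), np.array(pressures), meta)


def write_isotherm(iso: Isotherm, path: str | Path) -> None:
    """Write an isotherm in the dialect read by :func:`read_isotherm`.

    Numeric values use 12 significant digits so a write/read cycle
    round-trips points to at least 10 significant digits.
    """
    path = Path(path)
    lines: list[str] = []
    m = iso.meta
    if m.components:
        comp = ", ".join(f"{name}={frac:.12g}" for name, frac in m.components)
        lines.append(f"# components: {comp}")
    lines.append(f"# subphase: {m.subphase}")
    lines.append(f"# temperature_C: {m.temperature_C:.12g}")
    if m.barrier_speed is not None:
        lines.append(f"# barrier_speed: {m.barrier_speed:.12g}")
    lines.append(f"# source: {m.source}")
    for key, value in m.extra.items():
        lines.append(f"# {key}: {value}")
    lines.append("# columns: area_A2,pressure_mN_m")
    for a, p in zip(iso.area, iso.pressure):
        lines.append(f"{a:.12g},{p:.12g}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# canonicalization and interpolation
# ---------------------------------------------------------------------------

def canonicalize(
    iso: Isotherm, pressure_tolerance: float = 0.0
) -> tuple[Isotherm, CanonicalizationReport]:
    """Extract a strictly monotone compression branch.

    Points are sorted by decreasing area (stable), then swept in order: a
    point survives only when its pressure exceeds the last kept pressure by
    more than ``pressure_tolerance``.  The first (largest-area) point of each
    pressure level is therefore kept — inside a first-order plateau dpi ~ 0,
    so the choice contributes negligibly to downstream pressure integrals
    while preserving the expanded-side plateau boundary.

    Raises :class:`DegenerateIsothermError` when fewer than 4 points survive.
    """
    if pressure_tolerance < 0:
        raise ParameterError("pressure_tolerance must be >= 0")
    order = np.argsort(-iso.area, kind="stable")
    was_reversed = bool(iso.area[0] < iso.area[-1])
    a = iso.area[order]
    p = iso.pressure[order]

    keep = [0]
    last = p[0]
    max_violation = 0.0
    for i in range(1, a.size):
        if p[i] > last + pressure_tolerance:
            keep.append(i)
            last = p[i]
        else:
            max_violation = max(max_violation, max(0.0, last - p[i]))
    if len(keep) < 4:
        raise DegenerateIsothermError(
            f"only {len(keep)} points survive canonicalization (need >= 4)"
        )
    idx = np.array(keep)
    out = Isotherm(a[idx], p[idx], iso.meta)
    report = CanonicalizationReport(
        n_dropped=iso.n - len(keep),
        reversed=was_reversed,
        max_pressure_violation=float(max_violation),
    )
    return out, report


def area_at_pressure(iso: Isotherm, pi):
    """Mean molecular area at surface pressure ``pi`` by linear interpolation.

    ``pi`` may be a scalar or array; it must lie within the recorded pressure
    range (no extrapolation).  Exact at grid nodes.
    """
    _require_canonical(iso, "area_at_pressure")
    p, a = iso.pressure, iso.area
    pi_arr = np.asarray(pi, dtype=float)
    eps = 1e-9
    if np.any(pi_arr < p[0] - eps) or np.any(pi_arr > p[-1] + eps):
        raise OutOfRangeError(
            f"pressure {pi!r} outside recorded range [{p[0]:.4g}, {p[-1]:.4g}] mN/m"
        )
    out = np.interp(pi_arr, p, a)
    if pi_arr.ndim == 0:
        return float(out)
    return out


def smooth(iso: Isotherm, window_points: int = 11, poly_order: int = 2) -> Isotherm:
    """Savitzky–Golay smoothing of pressure against point index.

    Areas are left unchanged.  Near the ends the window shrinks symmetrically
    (down to a single point), so polynomial data of degree <= ``poly_order``
    are reproduced exactly everywhere.  The result is re-canonicalized, so the
    output may contain fewer points than the input.

    The input may be raw (not yet canonical): points are first sorted by
    decreasing area.  Denoising the full trace *before* the monotone
    compression branch is extracted is preferable for noisy data — the
    canonical branch keeps only running-maximum pressures, which biases the
    kept pressures upward when selected from unsmoothed noise.
    """
    if not iso.is_canonical:
        order = np.argsort(-iso.area, kind="stable")
        iso = Isotherm(iso.area[order], iso.pressure[order], iso.meta)
    n = iso.n
    if window_points % 2 == 0:
        raise ParameterError("window_points must be odd")
    if poly_order < 0 or window_points <= poly_order:
        raise ParameterError("window_points must exceed poly_order")
    if window_points >= n:
        raise ParameterError(f"window_points ({window_points}) must be smaller than n ({n})")

    y = iso.pressure
    half = window_points // 2
    sm = savgol_filter(y, window_points, poly_order, mode="interp")
    # shrinking symmetric windows at both edges
    x = np.arange(n, dtype=float)
    for i in range(half):
        for idx in (i, n - 1 - i):
            w = 2 * min(idx, n - 1 - idx) + 1
            if w == 1:
                sm[idx] = y[idx]
                continue
            lo = idx - (w - 1) // 2
            deg = min(poly_order, w - 1)
            coeffs = np.polyfit(x[lo : lo + w], y[lo : lo + w], deg)
            sm[idx] = np.polyval(coeffs, x[idx])
    out, _ = canonicalize(Isotherm(iso.area.copy(), sm, iso.meta))
    return out
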