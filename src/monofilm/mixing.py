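"""Two-component mixed-monolayer thermodynamics.

For a binary mixed film at surface pressure pi, the additivity rule gives the
ideal mean molecular area

    A_ideal(pi) = X1 A1(pi) + X2 A2(pi),

where A1, A2 are the pure-component areas at the same pressure and X1, X2 the
molar fractions.  Deviations A_exc = A12 - A_ideal of the measured mixed-film
area A12 indicate miscibility with non-ideal interactions, quantified by the
excess free enthalpy of mixing

    dG_exc(X1, pi) = N_A * integral_0^pi A_exc(X1, pi') dpi'   [J/mol],

with N_A the Avogadro constant; negative values mean attractive, stabilizing
interactions (e.g. sterol/phospholipid hydrogen bonding), and the composition
of the deepest minimum marks maximum thermodynamic stability.

Units at the boundary are Angstrom^2/molecule and mN/m; the conversion
1 A^2 * mN/m = 1e-23 J per molecule makes N_A * 1e-23 ~ 6022.14 J/mol per
(A^2 * mN/m) the single conversion factor.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.constants import Avogadro

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    OutOfRangeError,
    ParameterError,
)
from .isotherm import Isotherm, area_at_pressure, canonicalize, read_isotherm

#: J/mol per (Angstrom^2 * mN/m) per molecule.
J_PER_MOL_PER_A2_MN_M = Avogadro * 1e-23

#: Default evaluation pressures for the mixing analysis [mN/m].
DEFAULT_PRESSURES = (10.0, 15.0, 20.0, 25.0, 30.0)

TABLE_COLUMNS = ("X1", "pressure_mN_m", "A12_A2", "A_ideal_A2", "A_excess_A2", "dG_excess_J_mol")


@dataclass
class MixtureSeries:
    """Canonical isotherms for a composition series of a binary film.

    ``fractions`` are the molar fractions X1 of component 1 (the sterol-like
    condenser by convention), strictly increasing and including both pure
    endpoints 0 and 1.  All member isotherms must share subphase and
    temperature.
    """

    fractions: np.ndarray
    isotherms: list[Isotherm]

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.size != len(self.isotherms):
            raise ParameterError("fractions and isotherms differ in length")
        if self.fractions.size < 2:
            raise ParameterError("a mixture series needs at least the two pure endpoints")
        if np.any(np.diff(self.fractions) <= 0):
            raise ParameterError("fractions must be strictly increasing")
        if abs(self.fractions[0]) > 1e-9 or abs(self.fractions[-1] - 1.0) > 1e-9:
            raise ParameterError("fractions must include the pure endpoints X1=0 and X1=1")
        for x, iso in zip(self.fractions, self.isotherms):
            if not iso.is_canonical:
                raise ParameterError(f"isotherm at X1={x} is not canonical")
        subs = {iso.meta.subphase for iso in self.isotherms}
        if len(subs) > 1:
            raise ParameterError(f"isotherms mix subphases {sorted(subs)}")
        temps = {round(iso.meta.temperature_C, 6) for iso in self.isotherms}
        if len(temps) > 1:
            raise ParameterError(f"isotherms mix temperatures {sorted(temps)}")

    @property
    def n_compositions(self) -> int:
        return int(self.fractions.size)

    def isotherm_at(self, x1: float) -> Isotherm:
        idx = int(np.argmin(np.abs(self.fractions - x1)))
        if abs(self.fractions[idx] - x1) > 1e-9:
            raise ParameterError(f"no isotherm at X1={x1}")
        return self.isotherms[idx]

    def pressure_range(self) -> tuple[float, float]:
        """Pressure interval reachable by every film in the series."""
        lo = max(iso.pressure[0] for iso in self.isotherms)
        hi = min(iso.pressure[-1] for iso in self.isotherms)
        return float(lo), float(hi)


@dataclass
class StabilityMinimum:
    X1: float
    dG_excess_J_mol: float
    pressure: float  # [mN/m]


@dataclass
class ExcessAnalysis:
    """Tidy per-(X1, pressure) mixing table plus located stability minimum.

    ``table`` has columns X1, pressure_mN_m, A12_A2, A_ideal_A2, A_excess_A2
    and dG_excess_J_mol (NaN when only areas were requested).
    """

    table: pd.DataFrame
    pressures: np.ndarray
    minimum: StabilityMinimum | None = None
    flags: list[str] = field(default_factory=list)

    def at(self, pressure: float) -> pd.DataFrame:
        sub = self.table[np.isclose(self.table["pressure_mN_m"], pressure)]
        return sub.sort_values("X1").reset_index(drop=True)


@dataclass
class CondensingReport:
    """Monotonic-condensation check of A12(X1) at fixed pressure."""

    pressure: float
    fractions: np.ndarray
    a12: np.ndarray
    pair_decreasing: np.ndarray  # bool per adjacent composition pair
    monotone: bool
    offending_pairs: list[tuple[float, float]]


# ---------------------------------------------------------------------------
# additivity and excess areas
# ---------------------------------------------------------------------------

def ideal_area(x1: float, a1: float, a2: float) -> float:
    """Additivity-rule area X1*A1 + (1-X1)*A2 of an ideal (or immiscible) mixed film."""
    if not 0.0 <= x1 <= 1.0:
        raise ParameterError(f"molar fraction X1={x1} outside [0, 1]")
    if a1 <= 0 or a2 <= 0:
        raise ParameterError("areas must be strictly positive")
    return x1 * a1 + (1.0 - x1) * a2


def _reachable(series: MixtureSeries, pi: float) -> str | None:
    """None when pi is reachable by every film, else a message naming the film."""
    for x, iso in zip(series.fractions, series.isotherms):
        if pi < iso.pressure[0] - 1e-9 or pi > iso.pressure[-1] + 1e-9:
            return (
                f"pressure {pi:g} mN/m unreachable for film X1={x:g} "
                f"(recorded range [{iso.pressure[0]:.3g}, {iso.pressure[-1]:.3g}])"
            )
    return None


def excess_area_table(series: MixtureSeries, pressures=DEFAULT_PRESSURES) -> ExcessAnalysis:
    """Measured, ideal, and excess areas for every (X1, pressure).

    Pressures that some film cannot reach (it collapses or lifts off
    elsewhere) are excluded and flagged rather than extrapolated.
    """
    pressures = np.atleast_1d(np.asarray(pressures, dtype=float))
    pure2, pure1 = series.isotherms[0], series.isotherms[-1]
    rows = []
    flags: list[str] = []
    kept = []
    for pi in pressures:
        msg = _reachable(series, pi)
        if msg is not None:
            flags.append(f"excluded: {msg}")
            continue
        kept.append(pi)
        a1 = area_at_pressure(pure1, pi)
        a2 = area_at_pressure(pure2, pi)
        for x, iso in zip(series.fractions, series.isotherms):
            a12 = area_at_pressure(iso, pi)
            aid = ideal_area(x, a1, a2)
            rows.append((x, pi, a12, aid, a12 - aid, np.nan))
    table = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    return ExcessAnalysis(table=table, pressures=np.asarray(kept), flags=flags)


# ---------------------------------------------------------------------------
# excess free enthalpy of mixing
# ---------------------------------------------------------------------------

def _quad_grid(lo: float, hi: float, step: float) -> np.ndarray:
    """Integration nodes: lo, hi, and all lattice multiples of ``step`` between.

    Snapping interior nodes to the global step lattice makes the trapezoid
    integral exactly additive across any split at a lattice pressure.
    """
    if hi <= lo:
        raise ParameterError(f"empty integration interval [{lo}, {hi}]")
    k0 = math.floor(lo / step) + 1
    k1 = math.ceil(hi / step) - 1
    inner = step * np.arange(k0, k1 + 1) if k1 >= k0 else np.empty(0)
    inner = inner[(inner > lo + 1e-9) & (inner < hi - 1e-9)]
    return np.concatenate(([lo], inner, [hi]))


def _excess_area_on_grid(series: MixtureSeries, x1: float, grid: np.ndarray) -> np.ndarray:
    pure2, pure1 = series.isotherms[0], series.isotherms[-1]
    iso = series.isotherm_at(x1)
    a12 = area_at_pressure(iso, grid)
    a1 = area_at_pressure(pure1, grid)
    a2 = area_at_pressure(pure2, grid)
    return a12 - (x1 * a1 + (1.0 - x1) * a2)


def _with_breakpoints(series: MixtureSeries, x1: float, grid: np.ndarray) -> np.ndarray:
    """Integration nodes augmented with the involved films' recorded pressures.

    A_exc(pi) is piecewise linear with breakpoints at the data pressures of
    the mixed film and both pure films; adding those breakpoints makes the
    trapezoidal rule exact for the interpolated curves.  This matters most
    across a first-order LE-LC area jump, where the interpolants of different
    films disagree over a window narrower than any fixed quadrature step.
    """
    lo, hi = grid[0], grid[-1]
    extras = []
    for iso in (series.isotherm_at(x1), series.isotherms[0], series.isotherms[-1]):
        p = iso.pressure
        extras.append(p[(p > lo + 1e-12) & (p < hi - 1e-12)])
    return np.unique(np.concatenate([grid, *extras]))


def _gibbs_for_fraction(
    series: MixtureSeries,
    x1: float,
    pi_target: float,
    pi_start: float | None,
    step: float,
    flags: list[str],
) -> float:
    """Trapezoidal N_A * integral of A_exc dpi for one composition [J/mol]."""
    if x1 in (0.0, 1.0) or abs(x1) < 1e-12 or abs(x1 - 1.0) < 1e-12:
        return 0.0  # pure films are exactly ideal
    lo_film, hi_film = series.pressure_range()
    if pi_target > hi_film + 1e-9:
        raise OutOfRangeError(_reachable(series, pi_target))
    head = 0.0
    if pi_start is None:
        lift = max(lo_film, 0.0)
        grid = _with_breakpoints(series, x1, _quad_grid(lift, pi_target, step))
        aex = _excess_area_on_grid(series, x1, grid)
        # The integral of dG_exc formally starts at pi = 0, but films lift off
        # at a small positive pressure.  Bridge the gap by linear
        # extrapolation of A_exc only when it is small; otherwise report it.
        if lift > 0 and lift < 1.0:
            # slope of A_exc near lift-off from a least-squares fit over the
            # first ~1 mN/m (robust against closely spaced noisy nodes)
            sel = grid <= lift + max(1.0, 4 * step)
            if sel.sum() >= 2 and grid[sel][-1] > grid[0] + 1e-9:
                slope, intercept = np.polyfit(grid[sel], aex[sel], 1)
                aex0 = intercept  # value extrapolated to pi = 0
            else:
                aex0 = aex[0]
            head = 0.5 * (aex0 + aex[0]) * lift
            msg = f"A_excess linearly extrapolated over [0, {lift:.3g}) mN/m"
            if msg not in flags:
                flags.append(msg)
        elif lift >= 1.0:
            msg = f"integration starts at lift-off {lift:.3g} mN/m (gap >= 1 mN/m not extrapolated)"
            if msg not in flags:
                flags.append(msg)
    else:
        if pi_start >= pi_target:
            raise ParameterError(f"pi_start ({pi_start}) must be below pi_target ({pi_target})")
        if pi_start < lo_film - 1e-9:
            raise OutOfRangeError(_reachable(series, pi_start))
        grid = _with_breakpoints(series, x1, _quad_grid(pi_start, pi_target, step))
        aex = _excess_area_on_grid(series, x1, grid)
    return float((np.trapezoid(aex, grid) + head) * J_PER_MOL_PER_A2_MN_M)


def excess_analysis(
    series: MixtureSeries,
    pressures=DEFAULT_PRESSURES,
    pi_start: float | None = None,
    step: float = 0.25,
    minimum_tolerance_J_mol: float = 1.0,
) -> ExcessAnalysis:
    """Full mixing analysis: areas and dG_exc per (X1, pressure), plus minimum.

    ``pi_start=None`` (default) integrates from the common lift-off pressure
    with the small-gap extrapolation policy described in
    :func:`excess_gibbs`; the stability minimum is located at the highest
    evaluated pressure.  For noisy traces, smooth the raw isotherms before
    building the series (see :func:`monofilm.isotherm.smooth`).
    """
    analysis = excess_area_table(series, pressures)
    table = analysis.table
    dg = np.full(len(table), np.nan)
    cache: dict[tuple[float, float], float] = {}
    for i, (x, pi) in enumerate(zip(table["X1"], table["pressure_mN_m"])):
        key = (float(x), float(pi))
        if key not in cache:
            cache[key] = _gibbs_for_fraction(series, float(x), float(pi), pi_start, step, analysis.flags)
        dg[i] = cache[key]
    table["dG_excess_J_mol"] = dg
    if analysis.pressures.size:
        top = float(analysis.pressures.max())
        try:
            analysis.minimum = find_stability_minimum(
                analysis, top, tolerance_J_mol=minimum_tolerance_J_mol
            )
        except InsufficientDataError:
            analysis.minimum = None
    return analysis


def excess_gibbs(
    series: MixtureSeries,
    pi_target: float,
    pi_start: float | None = None,
    step: float = 0.25,
) -> ExcessAnalysis:
    """Excess free enthalpy of mixing dG_exc(X1) at one target pressure.

    dG_exc = N_A * integral of A_exc(X1, pi) dpi over [pi_start, pi_target],
    by the trapezoidal rule on a dense pressure grid (default step
    0.25 mN/m).  With ``pi_start=None`` the integral starts at the common
    lift-off pressure of the series; when that lift-off is below 1 mN/m the
    remaining gap down to pi = 0 is bridged by linear extrapolation of
    A_exc (flagged in the report), otherwise the gap is reported and not
    extrapolated.  Pure endpoints return exactly 0.  A film that collapses
    (or lifts off) short of the requested interval raises
    :class:`OutOfRangeError` naming the film.
    """
    msg = _reachable(series, pi_target)
    if msg is not None:
        raise OutOfRangeError(msg)
    return excess_analysis(series, pressures=[pi_target], pi_start=pi_start, step=step)


def find_stability_minimum(
    analysis: ExcessAnalysis,
    at_pressure: float,
    tolerance_J_mol: float = 1.0,
) -> StabilityMinimum | None:
    """Composition of maximum thermodynamic stability at one pressure.

    Fits a quadratic through the lowest dG_exc point and its neighbours and
    returns the interpolated minimizing X1 and value; returns ``None`` ("no
    stabilizing minimum") when no dG_exc falls below ``-tolerance_J_mol``.
    Requires at least 5 compositions at that pressure.
    """
    sub = analysis.at(at_pressure)
    if len(sub) == 0:
        raise OutOfRangeError(f"no analysis rows at pressure {at_pressure} mN/m")
    if len(sub) < 5:
        raise InsufficientDataError(
            f"{len(sub)} compositions at {at_pressure} mN/m; need >= 5 to locate a minimum"
        )
    x = sub["X1"].to_numpy()
    dg = sub["dG_excess_J_mol"].to_numpy()
    if np.any(np.isnan(dg)):
        raise InsufficientDataError("dG_excess not computed; run excess_analysis/excess_gibbs first")
    if dg.min() >= -tolerance_J_mol:
        return None
    i = int(np.clip(np.argmin(dg), 1, len(x) - 2))
    xs, ys = x[i - 1 : i + 2], dg[i - 1 : i + 2]
    a, b, c = np.polyfit(xs, ys, 2)
    if a > 0:
        xv = float(np.clip(-b / (2 * a), xs[0], xs[2]))
    else:  # degenerate curvature: fall back to the grid argmin
        xv = float(x[i])
    val = float(np.polyval([a, b, c], xv))
    return StabilityMinimum(X1=xv, dG_excess_J_mol=val, pressure=float(at_pressure))


def condensing_effect_check(
    series: MixtureSeries, pi: float, atol: float = 0.0
) -> CondensingReport:
    """Check the condensing effect: A12 non-increasing with sterol fraction X1."""
    msg = _reachable(series, pi)
    if msg is not None:
        raise OutOfRangeError(msg)
    a12 = np.array([area_at_pressure(iso, pi) for iso in series.isotherms])
    dec = np.diff(a12) <= atol
    offending = [
        (float(series.fractions[j]), float(series.fractions[j + 1]))
        for j in np.flatnonzero(~dec)
    ]
    return CondensingReport(
        pressure=float(pi),
        fractions=series.fractions.copy(),
        a12=a12,
        pair_decreasing=dec,
        monotone=bool(dec.all()),
        offending_pairs=offending,
    )


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def load_manifest(path: str | Path, pressure_tolerance: float = 0.0):
    """Load a mixing-analysis manifest (YAML) into a MixtureSeries + config.

    Expected structure::

        pressures: [10, 15, 20, 25, 30]   # optional
        pi_start: null                    # optional
        step: 0.25                        # optional
        smoothing: {window_points: 21, poly_order: 2}   # optional
        isotherms:
          - {path: chol_1.00.txt, X1: 1.0}
          - {path: mix_0.50.txt,  X1: 0.5}
          - {path: dppc_0.00.txt, X1: 0.0}

    Relative paths resolve against the manifest's directory.  Both pure
    endpoints must be declared; their absence is a configuration error raised
    before any file is read.
    """
    path = Path(path)
    try:
        cfg = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{path.name}: invalid YAML ({exc})") from exc
    if not isinstance(cfg, dict) or "isotherms" not in cfg:
        raise ConfigurationError(f"{path.name}: manifest must define an 'isotherms' list")
    entries = cfg["isotherms"]
    if not isinstance(entries, list) or not entries:
        raise ConfigurationError(f"{path.name}: 'isotherms' must be a non-empty list")
    for e in entries:
        if not isinstance(e, dict) or "path" not in e or "X1" not in e:
            raise ConfigurationError(f"{path.name}: each isotherm entry needs 'path' and 'X1'")
    fracs = np.array([float(e["X1"]) for e in entries])
    if not (np.any(np.isclose(fracs, 0.0)) and np.any(np.isclose(fracs, 1.0))):
        raise ConfigurationError(
            f"{path.name}: manifest must include both pure endpoints X1=0 and X1=1"
        )
    smoothing = cfg.get("smoothing")
    if smoothing is not None and not isinstance(smoothing, dict):
        raise ConfigurationError(f"{path.name}: 'smoothing' must be a mapping of smooth() options")
    order = np.argsort(fracs)
    isotherms = []
    for idx in order:
        fpath = Path(entries[int(idx)]["path"])
        if not fpath.is_absolute():
            fpath = path.parent / fpath
        raw = read_isotherm(fpath)
        if smoothing:
            from .isotherm import smooth

            iso = smooth(raw, **smoothing)
        else:
            iso, _ = canonicalize(raw, pressure_tolerance)
        isotherms.append(iso)
    series = MixtureSeries(fractions=fracs[order], isotherms=isotherms)
    config = {
        "pressures": list(cfg.get("pressures", DEFAULT_PRESSURES)),
        "pi_start": cfg.get("pi_start"),
        "step": float(cfg.get("step", 0.25)),
        "smoothing": smoothing,
    }
    return series, config
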