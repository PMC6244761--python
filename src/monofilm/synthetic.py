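"""Synthetic isotherm generator with embedded ground truth.

Generates single-film and mixture-series compression isotherms from simple
two-dimensional equations of state, so every pipeline stage can be tested
against known transition pressures, collapse pressures, and a closed-form
excess free enthalpy of mixing:

* ``CondensedEOS`` — a steep, solid-like film (sterol phenomenology): linear
  condensed branch pi = b (A0 - A) up to a collapse pressure pi_c, after
  which the slope drops twenty-fold (the collapse kink).
* ``LeLcEOS`` — an expanded film with a first-order LE-LC transition
  (phosphatidylcholine phenomenology): a Volmer liquid-expanded branch
  pi = kT/(A - omega) - Pi_coh, a flat plateau at the transition pressure
  pi_t (optionally tilted), a linear liquid-condensed branch, and a collapse
  kink.

Mixture series follow a two-term Redlich-Kister construction: at every
pressure the mixed-film area is

    A12(pi) = X1 A1(pi) + X2 A2(pi) + X1 X2 (a0 + a1 (2 X1 - 1)) h(pi),

with h a non-negative piecewise-linear pressure shape, so the excess area
and hence dG_exc are available in closed form (:func:`analytic_excess_gibbs`).
Gaussian noise is applied to the pressure channel only (the trough's pressure
sensor dominates the error budget; the dosed amount of material is treated as
exact).  Every generated isotherm embeds its ground truth in the metadata.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.constants import Boltzmann

from .errors import ParameterError
from .isotherm import Isotherm, IsothermMeta, canonicalize
from .mixing import J_PER_MOL_PER_A2_MN_M, MixtureSeries

#: Post-collapse branches keep 1/20 of the pre-collapse slope (a clear kink).
_POST_COLLAPSE_SLOPE_RATIO = 20.0
#: Pressure rise rendered past the collapse point [mN/m].
_POST_COLLAPSE_RISE = 1.5
#: Default water-subphase interaction coefficient [A^2]; gives a symmetric
#: stabilization depth of -1.0 kJ/mol at 30 mN/m (0.25 * a0 * 30 * N_A * 1e-23).
DEFAULT_A0 = -22.14


def _kt_2d(temperature_C: float) -> float:
    """k_B T expressed in (Angstrom^2 * mN/m) per molecule."""
    return Boltzmann * (temperature_C + 273.15) / 1e-23


@dataclass(frozen=True)
class CondensedEOS:
    """Solid-like condensed film: pi = slope * (limiting_area - A)."""

    limiting_area: float = 40.0  # A0 [Angstrom^2/molecule]
    slope: float = 12.0  # b [mN m^-1 Angstrom^-2]
    collapse_pressure: float = 45.0  # pi_c [mN/m]
    temperature_C: float = 20.0

    kind = "condensed"

    def __post_init__(self) -> None:
        if self.limiting_area <= 0 or self.slope <= 0 or self.collapse_pressure <= 0:
            raise ParameterError("CondensedEOS parameters must be strictly positive")

    @property
    def collapse_area(self) -> float:
        return self.limiting_area - self.collapse_pressure / self.slope

    def pressure_of_area(self, area: np.ndarray) -> np.ndarray:
        a = np.asarray(area, dtype=float)
        pi = np.where(a >= self.limiting_area, 0.0, self.slope * (self.limiting_area - a))
        post = self.collapse_pressure + (self.slope / _POST_COLLAPSE_SLOPE_RATIO) * (
            self.collapse_area - a
        )
        return np.where(a < self.collapse_area, post, pi)

    def area_of_pressure(self, pi: np.ndarray) -> np.ndarray:
        pi = np.asarray(pi, dtype=float)
        if np.any(pi < 0) or np.any(pi > self.collapse_pressure + 1e-9):
            raise ParameterError(
                f"pressure outside condensed branch [0, {self.collapse_pressure}] mN/m"
            )
        return self.limiting_area - pi / self.slope

    def sampling_range(self) -> tuple[float, float]:
        start = self.limiting_area + 4.0
        stop = self.collapse_area - _POST_COLLAPSE_RISE / (
            self.slope / _POST_COLLAPSE_SLOPE_RATIO
        )
        return start, stop


@dataclass(frozen=True)
class LeLcEOS:
    """Expanded film with a first-order LE-LC transition.

    LE branch: Volmer equation pi = kT/(A - co_area) - cohesion_pressure.
    At ``transition_pressure`` the film crosses a plateau (flat, or tilted by
    ``plateau_tilt`` mN/m across its width) to the liquid-condensed branch
    pi = pi_t + lc_slope * (lc_onset_area - A), which collapses at
    ``collapse_pressure``.
    """

    co_area: float = 42.0  # omega [Angstrom^2/molecule]
    cohesion_pressure: float = 7.5  # Pi_coh [mN/m]
    transition_pressure: float = 5.0  # pi_t [mN/m]
    lc_onset_area: float = 52.0  # [Angstrom^2/molecule]
    lc_slope: float = 4.0  # [mN m^-1 Angstrom^-2]
    collapse_pressure: float = 55.0  # pi_c [mN/m]
    plateau_tilt: float = 0.0  # [mN/m] rise across the plateau
    temperature_C: float = 20.0

    kind = "le_lc"

    def __post_init__(self) -> None:
        if min(self.co_area, self.lc_onset_area, self.lc_slope) <= 0:
            raise ParameterError("LeLcEOS areas and slopes must be strictly positive")
        if self.cohesion_pressure <= 0:
            raise ParameterError("cohesion_pressure must be strictly positive")
        if not 0 < self.transition_pressure < self.collapse_pressure:
            raise ParameterError("need 0 < transition_pressure < collapse_pressure")
        if self.le_transition_area <= self.lc_onset_area:
            raise ParameterError(
                "LE area at the transition must exceed the LC onset area (first-order jump)"
            )

    @property
    def kt(self) -> float:
        return _kt_2d(self.temperature_C)

    @property
    def liftoff_area(self) -> float:
        return self.co_area + self.kt / self.cohesion_pressure

    @property
    def le_transition_area(self) -> float:
        return self.co_area + self.kt / (self.transition_pressure + self.cohesion_pressure)

    @property
    def collapse_area(self) -> float:
        return self.lc_onset_area - (self.collapse_pressure - self.transition_pressure) / self.lc_slope

    def pressure_of_area(self, area: np.ndarray) -> np.ndarray:
        a = np.asarray(area, dtype=float)
        le = np.maximum(self.kt / (a - self.co_area) - self.cohesion_pressure, 0.0)
        width = self.le_transition_area - self.lc_onset_area
        frac = np.clip((self.le_transition_area - a) / width, 0.0, 1.0)
        plateau = self.transition_pressure + self.plateau_tilt * frac
        lc = (
            self.transition_pressure
            + self.plateau_tilt
            + self.lc_slope * (self.lc_onset_area - a)
        )
        post = self.collapse_pressure + (self.lc_slope / _POST_COLLAPSE_SLOPE_RATIO) * (
            self.collapse_area - a
        )
        pi = np.where(a >= self.le_transition_area, le, plateau)
        pi = np.where(a < self.lc_onset_area, lc, pi)
        pi = np.where(a < self.collapse_area, post, pi)
        return pi

    def area_of_pressure(self, pi: np.ndarray) -> np.ndarray:
        pi = np.asarray(pi, dtype=float)
        if np.any(pi < 0) or np.any(pi > self.collapse_pressure + 1e-9):
            raise ParameterError(
                f"pressure outside film branch [0, {self.collapse_pressure}] mN/m"
            )
        le = self.co_area + self.kt / (pi + self.cohesion_pressure)
        lc = self.lc_onset_area - (pi - self.transition_pressure - self.plateau_tilt) / self.lc_slope
        return np.where(pi < self.transition_pressure, le, np.minimum(lc, self.lc_onset_area))

    def sampling_range(self) -> tuple[float, float]:
        start = self.liftoff_area + 6.0
        stop = self.collapse_area - _POST_COLLAPSE_RISE / (
            self.lc_slope / _POST_COLLAPSE_SLOPE_RATIO
        )
        return start, stop


ComponentEOS = CondensedEOS | LeLcEOS


def cholesterol_like(collapse_pressure: float = 45.0) -> CondensedEOS:
    """Sterol-like condensed film (solid state, collapse near 45 mN/m)."""
    return CondensedEOS(collapse_pressure=collapse_pressure)


def dppc_like(transition_pressure: float = 5.0, collapse_pressure: float = 55.0) -> LeLcEOS:
    """Phosphatidylcholine-like film with an LE-LC plateau (default 5 mN/m)."""
    return LeLcEOS(transition_pressure=transition_pressure, collapse_pressure=collapse_pressure)


def ground_truth(iso: Isotherm) -> dict:
    """Decode the ground-truth sidecar embedded in a synthetic isotherm."""
    try:
        return json.loads(iso.meta.extra["ground_truth"])
    except KeyError as exc:
        raise ParameterError("isotherm carries no embedded ground truth") from exc


def make_isotherm(
    comp: ComponentEOS,
    noise_sigma: float = 0.05,
    n_points: int = 800,
    seed: int = 0,
    name: str | None = None,
    subphase: str = "water",
) -> Isotherm:
    """Sample a raw (uncanonicalized) compression run from one EOS.

    Areas are placed on a uniform decreasing grid from a gas-like tail above
    lift-off down past the collapse kink; pressures come from the EOS branch
    map plus additive Gaussian noise of standard deviation ``noise_sigma``
    (mN/m).  The same seed reproduces the run bit for bit.
    """
    if n_points < 100:
        raise ParameterError(f"n_points must be >= 100, got {n_points}")
    if noise_sigma < 0:
        raise ParameterError("noise_sigma must be >= 0")
    start, stop = comp.sampling_range()
    areas = np.linspace(start, stop, n_points)
    pressures = comp.pressure_of_area(areas)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        pressures = pressures + rng.normal(0.0, noise_sigma, size=n_points)
    truth = {"kind": comp.kind, "collapse_pressure": comp.collapse_pressure}
    if comp.kind == "le_lc":
        truth["transition_pressure"] = comp.transition_pressure
    if name is None:
        name = "component"
    meta = IsothermMeta(
        components=[(name, 1.0)],
        subphase=subphase,
        temperature_C=comp.temperature_C,
        source="synthetic",
        extra={"ground_truth": json.dumps(truth, sort_keys=True)},
    )
    return Isotherm(areas, pressures, meta)


# ---------------------------------------------------------------------------
# mixture model
# ---------------------------------------------------------------------------

def _validate_h_knots(knots) -> tuple[tuple[float, float], ...]:
    knots = tuple((float(x), float(y)) for x, y in knots)
    if len(knots) < 2:
        raise ParameterError("h(pi) needs at least two knots")
    xs = np.array([x for x, _ in knots])
    ys = np.array([y for _, y in knots])
    if np.any(np.diff(xs) <= 0):
        raise ParameterError("h(pi) knot pressures must be strictly increasing")
    if np.any(ys < 0):
        raise ParameterError("h(pi) must be non-negative")
    return knots


def _h_values(knots, pi: np.ndarray) -> np.ndarray:
    xs = np.array([x for x, _ in knots])
    ys = np.array([y for _, y in knots])
    return np.interp(pi, xs, ys)  # constant extension outside the knot range


def _h_integral(knots, pi: float) -> float:
    """Exact integral of the piecewise-linear h over [0, pi]."""
    xs = np.array([x for x, _ in knots])
    inner = xs[(xs > 0.0) & (xs < pi)]
    nodes = np.concatenate(([0.0], inner, [pi]))
    return float(np.trapezoid(_h_values(knots, nodes), nodes))


@dataclass(frozen=True)
class SyntheticModel:
    """Two-component mixture model with a prescribed excess-area function.

    ``a0`` and ``a1`` (Angstrom^2) are the symmetric and skew Redlich-Kister
    coefficients of the excess area X1 X2 (a0 + a1 (2 X1 - 1)) h(pi); the
    defaults reproduce a water-subphase sterol/phospholipid series whose
    stabilization minimum at 30 mN/m is -1.0 kJ/mol at X1 = 0.5.  The default
    pressure shape h is constant: a decaying shape is supported, but its
    slope is bounded by the films' compressibilities — if the excess area
    relaxes faster than the mixed film compresses, the constructed A12(pi)
    is no longer monotone and the series stops being a valid compression run.
    """

    comp1: ComponentEOS = field(default_factory=cholesterol_like)
    comp2: ComponentEOS = field(default_factory=dppc_like)
    a0: float = DEFAULT_A0  # [Angstrom^2]
    a1: float = 0.0  # [Angstrom^2]
    h_knots: tuple = ((0.0, 1.0), (60.0, 1.0))
    noise_sigma_pressure: float = 0.05  # [mN/m]
    n_points: int = 800
    seed: int = 0
    name1: str = "cholesterol-like"
    name2: str = "DPPC-like"
    subphase: str = "water"

    def __post_init__(self) -> None:
        object.__setattr__(self, "h_knots", _validate_h_knots(self.h_knots))
        if self.n_points < 100:
            raise ParameterError(f"n_points must be >= 100, got {self.n_points}")
        if self.noise_sigma_pressure < 0:
            raise ParameterError("noise_sigma_pressure must be >= 0")

    def interaction(self, x1: float) -> float:
        """Redlich-Kister excess-area amplitude X1 X2 (a0 + a1 (2 X1 - 1)) [A^2]."""
        return x1 * (1.0 - x1) * (self.a0 + self.a1 * (2.0 * x1 - 1.0))

    def excess_area(self, x1: float, pi) -> np.ndarray:
        return self.interaction(x1) * _h_values(self.h_knots, np.asarray(pi, dtype=float))

    def pressure_grid(self) -> np.ndarray:
        hi = min(self.comp1.collapse_pressure, self.comp2.collapse_pressure)
        return np.linspace(0.2, hi, self.n_points)


def make_mixture_isotherms(model: SyntheticModel, fractions) -> list[Isotherm]:
    """Raw isotherms of a composition series (see :func:`make_mixture_series`)."""
    fractions = np.asarray(fractions, dtype=float)
    if fractions.ndim != 1 or fractions.size < 2 or np.any(np.diff(fractions) <= 0):
        raise ParameterError("fractions must be a strictly increasing 1-D array")
    if abs(fractions[0]) > 1e-9 or abs(fractions[-1] - 1.0) > 1e-9:
        raise ParameterError("fractions must include the pure endpoints X1=0 and X1=1")
    pi = model.pressure_grid()
    a1 = model.comp1.area_of_pressure(pi)
    a2 = model.comp2.area_of_pressure(pi)
    children = np.random.SeedSequence(model.seed).spawn(fractions.size)
    isotherms = []
    for x1, child in zip(fractions, children):
        a12 = x1 * a1 + (1.0 - x1) * a2 + model.excess_area(x1, pi)
        p = pi.copy()
        if model.noise_sigma_pressure > 0:
            rng = np.random.default_rng(child)
            p = p + rng.normal(0.0, model.noise_sigma_pressure, size=p.size)
        truth = {
            "X1": x1,
            "a0": model.a0,
            "a1": model.a1,
            "h_knots": [list(k) for k in model.h_knots],
            "collapse_pressure_1": model.comp1.collapse_pressure,
            "collapse_pressure_2": model.comp2.collapse_pressure,
        }
        meta = IsothermMeta(
            components=[(model.name1, float(x1)), (model.name2, float(1.0 - x1))],
            subphase=model.subphase,
            temperature_C=model.comp1.temperature_C,
            source="synthetic",
            extra={"ground_truth": json.dumps(truth, sort_keys=True)},
        )
        isotherms.append(Isotherm(a12, p, meta))
    return isotherms


def make_mixture_series(
    model: SyntheticModel, fractions, smoothing: dict | None = None
) -> MixtureSeries:
    """Canonical mixture series built pointwise in pressure.

    Endpoint films come from the pure-component equations of state; each
    mixed film adds the prescribed Redlich-Kister excess area before the
    (area, pressure) samples receive independent pressure noise per film.
    Ground truth (a0, a1, h knots, collapse pressures) is embedded in each
    film's metadata.

    ``smoothing`` (keyword arguments for :func:`monofilm.isotherm.smooth`) is
    applied to the raw traces before the compression branch is extracted —
    recommended whenever ``noise_sigma_pressure > 0``, since extracting the
    monotone branch from unsmoothed noise biases the kept pressures and
    misaligns first-order transitions across films.
    """
    from .isotherm import smooth  # local import: isotherm does not import synthetic

    raw = make_mixture_isotherms(model, fractions)
    if smoothing:
        canon = [smooth(iso, **smoothing) for iso in raw]
    else:
        canon = [canonicalize(iso)[0] for iso in raw]
    return MixtureSeries(fractions=np.asarray(fractions, dtype=float), isotherms=canon)


def analytic_excess_gibbs(model: SyntheticModel, x1: float, pi_target: float) -> float:
    """Closed-form dG_exc(X1, pi_target) of the generator's construction [J/mol].

    N_A * X1 X2 (a0 + a1 (2 X1 - 1)) * integral_0^pi h(pi') dpi', with the
    piecewise-linear integral evaluated exactly and the same unit conversion
    as the pipeline (1 Angstrom^2 * mN/m = 1e-23 J per molecule).
    """
    if not 0.0 <= x1 <= 1.0:
        raise ParameterError(f"molar fraction X1={x1} outside [0, 1]")
    return model.interaction(x1) * _h_integral(model.h_knots, pi_target) * J_PER_MOL_PER_A2_MN_M
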