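"""Single-film thermodynamic characterization.

The in-plane compression modulus (also called surface elasticity)

    Cs^-1 = -A (dpi/dA)_T   [mN/m]

distinguishes monolayer phase states: it is low in gaseous and
liquid-expanded (LE) films, passes through a pronounced minimum across a
first-order LE–LC plateau, reaches 100–250 mN/m in liquid-condensed (LC)
films, and exceeds 250 mN/m in solid (S) films.  This module computes the
Cs^-1(pi) profile by centered finite differences on the canonical compression
branch, classifies the phase state from configurable modulus thresholds
(Davies–Rideal convention), and detects the two transition features of a
compression run: the LE–LC plateau (an interior minimum of Cs^-1) and the
collapse pressure pi_c (a sustained kink where the isotherm slope drops).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, medfilt

from .errors import OutOfRangeError, ParameterError
from .isotherm import Isotherm, IsothermMeta, _require_canonical, smooth

#: Davies–Rideal style phase boundaries on Cs^-1 [mN/m]; configurable, not constants.
DEFAULT_PHASE_BOUNDS = {
    "le_lower": 12.5,
    "le_upper": 50.0,
    "lc_lower": 100.0,
    "lc_upper": 250.0,
}

PHASE_LABELS = ("gas/LE-coexistence", "LE", "LE/LC-intermediate", "LC", "S")


@dataclass
class ElasticityProfile:
    """Cs^-1 evaluated on a strictly increasing surface-pressure grid."""

    pressure_grid: np.ndarray  # [mN/m]
    cs_inverse: np.ndarray  # [mN/m]
    max_cs_inverse: tuple[float, float]  # (value, at pressure) [mN/m]
    source_meta: IsothermMeta = field(default_factory=IsothermMeta)

    def value_at(self, pi: float) -> float:
        g = self.pressure_grid
        if pi < g[0] - 1e-9 or pi > g[-1] + 1e-9:
            raise OutOfRangeError(f"pressure {pi} outside profile grid [{g[0]:.4g}, {g[-1]:.4g}]")
        return float(np.interp(pi, g, self.cs_inverse))


@dataclass
class PhaseLabel:
    label: str  # one of PHASE_LABELS
    basis: float  # the Cs^-1 value used [mN/m]


@dataclass
class TransitionFeature:
    kind: str  # "plateau" or "collapse"
    pressure: float  # [mN/m]
    strength: float  # prominence of the Cs^-1 minimum (plateau) or slope-drop ratio (collapse)


def _one_sided_slope(x0, x1, x2, f0, f1, f2) -> float:
    """Second-order one-sided derivative at x0 on a non-uniform 3-point stencil."""
    return (
        f0 * (2 * x0 - x1 - x2) / ((x0 - x1) * (x0 - x2))
        + f1 * (x0 - x2) / ((x1 - x0) * (x1 - x2))
        + f2 * (x0 - x1) / ((x2 - x0) * (x2 - x1))
    )


def compression_modulus_profile(
    iso: Isotherm,
    grid: np.ndarray | None = None,
    smoothing: dict | None = None,
    grid_step: float = 0.5,
) -> ElasticityProfile:
    """Compression-modulus profile Cs^-1(pi) = -A (dpi/dA) of a canonical isotherm.

    The derivative uses centered finite differences on the recorded (A, pi)
    pairs (one-sided at the ends), then Cs^-1 is linearly interpolated onto
    the requested pressure grid (default: ``grid_step`` = 0.5 mN/m steps over
    the recorded range).  ``smoothing`` is an optional dict of keyword
    arguments for :func:`monofilm.isotherm.smooth` (e.g. ``{"window_points":
    31, "poly_order": 2}``), applied before differentiation; raw data are
    used by default.  When smoothing is requested, the default grid excludes
    the first and last half-window of points, whose shrunken smoothing
    windows leave residual noise that differentiation amplifies.
    """
    trim = 0
    if smoothing:
        trim = int(smoothing.get("window_points", 11)) // 2
        iso = smooth(iso, **smoothing)
    _require_canonical(iso, "compression_modulus_profile")
    a, p = iso.area, iso.pressure
    n = iso.n
    cs = np.empty(n)
    cs[1:-1] = -a[1:-1] * (p[2:] - p[:-2]) / (a[2:] - a[:-2])
    cs[0] = -a[0] * _one_sided_slope(a[0], a[1], a[2], p[0], p[1], p[2])
    cs[-1] = -a[-1] * _one_sided_slope(a[-1], a[-2], a[-3], p[-1], p[-2], p[-3])

    if grid is None:
        if grid_step <= 0:
            raise ParameterError("grid_step must be > 0")
        lo = p[min(trim, n - 2)]
        hi = p[max(n - 1 - trim, 1)]
        n_steps = int(np.floor((hi - lo) / grid_step + 1e-12))
        grid = lo + grid_step * np.arange(n_steps + 1)
    else:
        grid = np.asarray(grid, dtype=float)
        if np.any(np.diff(grid) <= 0):
            raise ParameterError("pressure grid must be strictly increasing")
        if grid[0] < p[0] - 1e-9 or grid[-1] > p[-1] + 1e-9:
            raise OutOfRangeError(
                f"grid [{grid[0]:.4g}, {grid[-1]:.4g}] outside recorded pressure range "
                f"[{p[0]:.4g}, {p[-1]:.4g}] mN/m"
            )
    cs_grid = np.interp(grid, p, cs)
    imax = int(np.argmax(cs_grid))
    return ElasticityProfile(
        pressure_grid=grid,
        cs_inverse=cs_grid,
        max_cs_inverse=(float(cs_grid[imax]), float(grid[imax])),
        source_meta=iso.meta,
    )


def classify_phase(
    profile: ElasticityProfile,
    at_pressure: float | None = None,
    bounds: dict | None = None,
) -> PhaseLabel:
    """Phase state of the film from its compression modulus.

    The basis is Cs^-1 at ``at_pressure`` when given, otherwise the profile
    maximum.  Boundaries follow the Davies–Rideal convention by default
    (LE: 12.5–50, LC: 100–250, S: > 250 mN/m; the gaps are labelled
    coexistence/intermediate) and are fully configurable.
    """
    b = dict(DEFAULT_PHASE_BOUNDS)
    if bounds:
        b.update(bounds)
    basis = profile.max_cs_inverse[0] if at_pressure is None else profile.value_at(at_pressure)
    if basis < b["le_lower"]:
        label = "gas/LE-coexistence"
    elif basis <= b["le_upper"]:
        label = "LE"
    elif basis < b["lc_lower"]:
        label = "LE/LC-intermediate"
    elif basis <= b["lc_upper"]:
        label = "LC"
    else:
        label = "S"
    return PhaseLabel(label=label, basis=float(basis))


def detect_collapse(
    iso: Isotherm,
    slope_drop_factor: float = 5.0,
    persistence: int = 3,
    baseline_window: int = 20,
    min_baseline: float = 0.05,
) -> TransitionFeature:
    """Collapse pressure pi_c of a compression run.

    A collapse is a kink after which the isotherm flattens (or falls) and
    never recovers: scanning the run resampled uniformly in area, the first
    point where the local |dpi/dA| stays below ``baseline/slope_drop_factor``
    for at least ``persistence`` samples *and* on average until the end of
    the run marks the kink (the mean-to-the-end condition distinguishes a
    collapse from an LE–LC plateau, after which the slope recovers).  The
    returned pressure is refined by intersecting straight-line fits of the
    branches on either side of the kink.  When no kink qualifies, the maximum
    recorded pressure is returned with ``strength = 0`` ("collapse not
    reached").
    """
    _require_canonical(iso, "detect_collapse")
    a, p = iso.area, iso.pressure
    n_rs = int(min(2000, max(200, 2 * iso.n)))
    grid = np.linspace(a[0], a[-1], n_rs)  # descending area
    pg = np.interp(grid[::-1], a[::-1], p[::-1])[::-1]
    da = (a[0] - a[-1]) / (n_rs - 1)
    m = np.diff(pg) / da  # |dpi/dA| on the compression branch (>= 0)
    m = medfilt(m, kernel_size=5)
    nm = m.size
    suffix_mean = np.cumsum(m[::-1])[::-1] / np.arange(nm, 0, -1)

    kink = None
    base_at_kink = 0.0
    for k in range(baseline_window, nm - persistence + 1):
        base = float(np.median(m[k - baseline_window : k]))
        if base < min_baseline:
            continue
        thr = base / slope_drop_factor
        if np.all(m[k : k + persistence] < thr) and suffix_mean[k] < thr:
            kink = k
            base_at_kink = base
            break
    if kink is None:
        return TransitionFeature(kind="collapse", pressure=float(p[-1]), strength=0.0)

    # refine pi_c as the intersection of pre- and post-kink line fits
    k = kink
    w_pre = min(baseline_window, k)
    w_post = min(baseline_window, n_rs - 1 - k)
    pi_c = float(pg[k])
    if w_pre >= 2 and w_post >= 2:
        m1, c1 = np.polyfit(grid[k - w_pre : k + 1], pg[k - w_pre : k + 1], 1)
        m2, c2 = np.polyfit(grid[k : k + w_post + 1], pg[k : k + w_post + 1], 1)
        if abs(m1 - m2) > 1e-12:
            a_star = (c2 - c1) / (m1 - m2)
            cand = m1 * a_star + c1
            lo = pg[max(k - 3, 0)] - 1.0
            hi = pg[min(k + 3, n_rs - 1)] + 1.0
            if lo <= cand <= hi:
                pi_c = float(cand)
    strength = base_at_kink / max(float(np.mean(m[k:])), 1e-12)
    return TransitionFeature(kind="collapse", pressure=pi_c, strength=float(strength))


def detect_plateau(
    profile: ElasticityProfile,
    ceiling: float = 20.0,
    prominence: float = 5.0,
) -> TransitionFeature | None:
    """LE–LC transition pressure from the Cs^-1(pi) profile, if present.

    The plateau of a first-order LE–LC transition appears as an interior
    minimum of Cs^-1 versus pi.  A qualifying minimum must (i) fall below
    ``ceiling`` (default 20 mN/m — genuine LE–LC minima sit near zero),
    (ii) be preceded by a liquid-expanded branch, i.e. the modulus reaches at
    least ``ceiling`` somewhere at lower pressure (this rejects dips inside
    the gaseous lift-off region), and (iii) be followed by condensation: the
    modulus recovers by at least ``prominence`` at higher pressure (this
    rejects the terminal modulus drop past a collapse, after which Cs^-1
    never recovers).  Only minima below the pressure of the film's global
    modulus maximum are considered — condensation through the LE-LC
    transition always precedes the film's stiffest state, whereas the noisy
    modulus drop beyond a collapse follows it.  The strongest qualifying
    minimum is returned — strength is the smaller of the two flanking rises;
    ``None`` means no plateau (a condensed film).
    """
    cs = profile.cs_inverse
    # locate the film's stiffest region on a median-despiked curve (isolated
    # modulus spikes from residual noise would corrupt the argmax); the dip
    # search itself runs on the raw profile, since a flat plateau's modulus
    # minimum can be only one or two grid points wide
    csf = medfilt(cs, kernel_size=9) if cs.size >= 9 else cs
    top = min(int(np.argmax(csf)) + 4, cs.size - 1)
    candidates, _ = find_peaks(-cs[: top + 1])
    # pressures at which an LE branch has been sustained: >= ceiling over
    # 3 consecutive grid points (a single noisy spike does not qualify)
    high = cs >= ceiling
    run = 0
    sustained = np.zeros(cs.size, dtype=bool)
    for j, h in enumerate(high):
        run = run + 1 if h else 0
        sustained[j] = sustained[j - 1] if j else False
        if run >= 3:
            sustained[j] = True
    best: tuple[float, int] | None = None  # (strength, index)
    for i in candidates:
        v = float(cs[i])
        if v >= ceiling:
            continue
        # flanking rises measured on the despiked curve: a lone noise spike
        # must not masquerade as an LE shoulder or a condensed branch
        left_max = float(np.max(csf[:i])) if i > 0 else -np.inf
        right_max = float(np.max(csf[i + 1 : top + 1])) if i < top else -np.inf
        if not sustained[i]:
            continue  # never sustained an LE state before the dip
        if left_max - v < prominence or right_max - v < prominence:
            continue
        strength = min(left_max, right_max) - v
        if best is None or strength > best[0]:
            best = (strength, int(i))
    if best is None:
        return None
    return TransitionFeature(
        kind="plateau",
        pressure=float(profile.pressure_grid[best[1]]),
        strength=float(best[0]),
    )
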