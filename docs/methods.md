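# Methods

## Data model and canonicalization

An isotherm is a pair of equal-length arrays — mean molecular area
(Å²/molecule, strictly positive) and surface pressure (mN/m) — plus
metadata (components with molar fractions summing to 1, a categorical
subphase label, temperature in °C, optional barrier speed). Raw traces are
never strictly monotone: sensor noise (the emulated instrument precision is
±0.1 mN/m) and first-order plateaus produce flat or backward pressure
excursions. `canonicalize` sorts by decreasing area (stable sort, so
duplicate areas keep acquisition order) and keeps a point only when its
pressure exceeds the last kept pressure by more than a tolerance (default
0; the first, largest-area point of each pressure level always survives).
Keeping the expanded-side point of a flat level is deliberate: inside a
true first-order plateau dπ ≈ 0, so the choice contributes nothing to
pressure integrals while preserving the LE-side plateau boundary. The sweep
is idempotent, and fewer than 4 survivors is an error rather than a silent
degenerate result.

A(π) is evaluated by piecewise-linear interpolation on the canonical
branch, exact at nodes, with no extrapolation outside the recorded range.

## Smoothing

`smooth` applies Savitzky–Golay local least-squares smoothing to the
pressure channel against point index (areas are dosed by syringe and
treated as exact). Edge windows shrink symmetrically down to one point, so
polynomial data of degree ≤ the fit order are reproduced exactly
everywhere. Smoothing is **off by default** in every downstream operation.

Order matters for noisy data: `smooth` accepts raw (area-sorted but
non-monotone) traces and canonicalizes afterwards. Extracting the monotone
branch first would select running-maximum "records" from raw noise, biasing
kept pressures upward by O(σ) and — more damagingly — shifting the apparent
position of a first-order area jump differently in different films of a
series. The recommended setting for σ ≈ 0.05 mN/m traces is a window of 21
points with a quadratic fit, spanning roughly 1 mN/m of the pressure
channel: wide enough to suppress record bias, narrow enough not to distort
the LE–LC corner. When a profile is computed with smoothing, the default
pressure grid drops the first and last half-window of points, whose
shrunken windows retain nearly raw noise that differentiation amplifies.

## Compression modulus and phase state

Cs⁻¹ = −A (dπ/dA)_T is computed by centered finite differences on the
canonical (A, π) points (second-order one-sided stencils at the ends) and
interpolated onto a pressure grid, by default 0.5 mN/m steps over the
recorded range. The sign convention makes compression positive; on any
canonical branch Cs⁻¹ > 0, and it is invariant under rescaling of all
areas. Two analytic limits anchor the implementation: ideal 2-D gas data
π = c/A give Cs⁻¹(π) = π, and a linear condensed branch π = a − bA gives
Cs⁻¹ = bA.

Phase labels follow the conventional compression-modulus bands
(LE 12.5–50, LC 100–250, S > 250 mN/m; gaps labelled coexistence or
intermediate). These are configuration values, not constants; the basis is
the profile maximum unless a pressure is specified. For feature work on
noisy data the profile is computed at 0.1 mN/m steps or finer (0.05 in the
bundled analyses): a flat plateau's modulus minimum can be narrower than
0.5 mN/m and a coarse grid can interpolate straight across it.

## Collapse detection

Collapse is a kink after which the isotherm flattens and never recovers.
The run is resampled uniformly in area, local slopes are median-filtered,
and the first point is sought where |dπ/dA| stays below `baseline/5`
(baseline = median slope over the preceding window) for at least 3 samples
*and* on average to the end of the run. The mean-to-the-end condition is
what distinguishes collapse from an LE–LC plateau, after which the slope
recovers. π_c is refined by intersecting straight-line fits of the branches
flanking the kink; if no kink qualifies, the maximum recorded pressure is
returned with strength 0 ("collapse not reached"). The synthetic generator
renders the post-collapse branch with 1/20 of the pre-collapse slope, a
20-fold drop comfortably past the 5× detection threshold.

## Plateau detection

The LE–LC transition appears as an interior minimum of Cs⁻¹(π). A
qualifying minimum must lie below an absolute ceiling (default 20 mN/m —
genuine LE–LC minima sit near zero), must be preceded by a sustained
liquid-expanded branch (Cs⁻¹ ≥ ceiling over 3 consecutive grid points —
rejects dips inside the gaseous lift-off corner), must be followed by a
recovery of at least the prominence floor (default 5 mN/m), and must
precede the film's global modulus maximum, located on a median-despiked
copy of the profile. The last condition rejects the terminal modulus drop
past a collapse: condensation through the LE–LC transition always precedes
the film's stiffest state, whereas the (extremely noisy) post-collapse
modulus follows it. At σ = 0.05 mN/m the detected plateau pressure carries
a small upward bias (≈ +0.3 mN/m) because the canonical branch keeps noise
records on the flat segment; this is well inside the 0.5 mN/m resolution
claimed for the feature.

## Mixed-film thermodynamics

For a series of canonical isotherms at molar fractions X₁ (both pure
endpoints required), the ideal area is X₁A₁(π) + X₂A₂(π) from the endpoint
films at the same pressure, and the excess area is the measured deviation.
Pressures that any film cannot reach are excluded and flagged, never
extrapolated; requesting a single unreachable target is an error naming the
film.

ΔG_exc(X₁, π) = N_A ∫ A_exc dπ′ is computed by the trapezoidal rule on a
0.25 mN/m lattice **augmented with every recorded pressure of the three
films involved**. A_exc is piecewise linear with breakpoints at those data
pressures, so the augmented trapezoid is exact for the interpolated curves;
this matters across a first-order area jump, where the interpolants of
different films disagree over a window narrower than any fixed step and a
plain fixed-step rule can give that window a full node weight. Lattice
alignment of interior nodes makes the integral exactly additive across any
split at a lattice pressure. The conversion is
1 Å²·mN/m = 10⁻²³ J per molecule, i.e. N_A × 10⁻²³ ≈ 6.0221 J/mol per
Å²·mN/m; results are J/mol internally and kJ/mol in reports.

The formal lower limit of the integral is π = 0, but real films lift off at
a small positive pressure. By default integration starts at the largest
per-film minimum pressure; when that lift-off is below 1 mN/m the remaining
gap is bridged by linear extrapolation of A_exc (slope from a least-squares
fit over the first ~1 mN/m of the grid, robust to closely spaced noisy
nodes) and the report is flagged; a larger gap is reported and not
extrapolated — silently manufacturing data over a wide gap would be worse
than a documented truncation. Pure endpoints return exactly 0 by identity,
not by quadrature.

The stability minimum is located by a quadratic fit through the lowest
ΔG_exc point and its neighbours (at least 5 compositions required),
mirroring how a smooth minimum is read off a coarse composition grid; if no
value falls below −1 J/mol (configurable), "no stabilizing minimum" is
reported. The condensing-effect check reports A₁₂(X₁) at fixed pressure
with per-pair decrease flags.

## Synthetic generator

The generator emulates the study conditions: 20 °C; pressure noise
σ = 0.05 mN/m (the scale of a ±0.1 mN/m instrument), applied to the
pressure channel only; 800–1500 points per run.

* **Condensed (sterol-like) film**: linear branch π = b(A₀ − A) with
  A₀ = 40 Å², b = 12 mN·m⁻¹·Å⁻², collapse at 45 mN/m (47 for the
  Ca²⁺-like condition). Maximum modulus ≈ 480 mN/m — a solid film.
* **LE–LC (phosphatidylcholine-like) film**: Volmer LE branch
  π = kT/(A − ω) − Π_coh with ω = 42 Å², Π_coh = 7.5 mN/m (lift-off near
  96 Å²); a flat first-order plateau at π_t (default 5 mN/m; a tilted
  plateau is available for robustness work); a linear LC branch from
  52 Å² with slope 4 mN·m⁻¹·Å⁻²; collapse at 55 mN/m.
* **Mixtures**: built pointwise in pressure as
  A₁₂(π) = X₁A₁(π) + X₂A₂(π) + X₁X₂(a₀ + a₁(2X₁−1))·h(π) — a two-term
  Redlich–Kister excess, the simplest family giving both a symmetric
  equimolar minimum and skewed or weakened minima. The default
  a₀ = −22.14 Å² makes the symmetric stabilization depth at 30 mN/m equal
  to −1.0 kJ/mol; halving a₀ halves it. h(π) is piecewise linear
  (default constant); its closed-form integral gives
  `analytic_excess_gibbs` for exact cross-checks. A decaying h is
  admissible only while |interaction × h′| stays below the mixed film's
  compressibility — beyond that the constructed A₁₂(π) is no longer a
  monotone compression run.

Every generated isotherm embeds its ground truth (transition and collapse
pressures, a₀, a₁, h knots) as JSON in the metadata, surviving the file
round trip. Identical seeds reproduce runs bit for bit; mixture films
receive independent noise streams spawned from the model seed.

What the generator does *not* emulate: expansion/hysteresis branches,
adsorption kinetics, area-channel noise, domain morphology, or any subphase
chemistry — subphase is a label. Passing tests therefore demonstrate the
correctness and noise robustness of the analysis pipeline on
trough-realistic traces, not the biology of any particular system.

## Numerical error budget under noise

With σ = 0.05 mN/m and smoothing window 21, the dominant residual error in
ΔG_exc is the alignment uncertainty of the first-order area jump across
films: each film's measured jump position is uncertain by the residual
pressure noise (~0.01 mN/m), and the resulting error is roughly
(jump size) × (misalignment) ≈ 1–3 J/mol per composition. This is a
metrological limit of the data, not a quadrature artifact; compositions
with small |ΔG_exc| are proportionally most affected. Located minima are
far more robust (X₁ stable to ±0.005, depth to ±1%) because the alignment
error is nearly common across neighbouring compositions.

## Problem sizes

The bundled analyses use 1500 points per isotherm and 11 compositions
(2000 points for noiseless single-film characterization), enough that
quadrature and interpolation errors sit well below the noise-driven limits
above while the entire validation suite runs in seconds.
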