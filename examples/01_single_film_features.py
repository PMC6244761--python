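"""Single-film characterization: compression modulus, phase, collapse, plateau.

Generates two synthetic compression isotherms at 20 C — a sterol-like
condensed film and a phospholipid-like film with a first-order LE-LC
transition — and extracts the thermodynamic features a trough experiment
would be read for: the compression-modulus profile Cs^-1(pi) = -A (dpi/dA),
the phase state it implies, the collapse pressure, and the LE-LC plateau.
"""
import monofilm as mf

SMOOTHING = {"window_points": 21, "poly_order": 2}  # for noisy traces

for name, eos in [
    ("cholesterol-like (condensed)", mf.cholesterol_like(collapse_pressure=45.0)),
    ("DPPC-like (LE-LC)", mf.dppc_like(transition_pressure=5.0)),
]:
    raw = mf.make_isotherm(eos, noise_sigma=0.05, n_points=1500, seed=0, name=name)
    canonical, report = mf.canonicalize(raw)
    profile = mf.compression_modulus_profile(
        canonical, smoothing=SMOOTHING, grid_step=0.05
    )
    phase = mf.classify_phase(profile)
    collapse = mf.detect_collapse(canonical)
    plateau = mf.detect_plateau(profile)

    print(f"{name}:")
    print(f"  canonical points: {canonical.n} ({report.n_dropped} dropped)")
    print(f"  max Cs^-1: {profile.max_cs_inverse[0]:.0f} mN/m "
          f"at {profile.max_cs_inverse[1]:.1f} mN/m")
    print(f"  phase state: {phase.label}  (basis {phase.basis:.0f} mN/m)")
    if collapse.strength > 0:
        print(f"  collapse pressure: {collapse.pressure:.1f} mN/m")
    else:
        print(f"  collapse not reached (max pi {collapse.pressure:.1f} mN/m)")
    if plateau is None:
        print("  LE-LC plateau: none (condensed film)")
    else:
        print(f"  LE-LC plateau: {plateau.pressure:.1f} mN/m "
              f"(Cs^-1 minimum, strength {plateau.strength:.0f} mN/m)")
    print()

print("A solid (S) film has Cs^-1 > 250 mN/m; the plateau pressure marks the")
print("first-order transition between liquid-expanded and liquid-condensed states.")
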