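"""File workflow: isotherm dialect, ground-truth sidecars, mixing manifests.

Writes a composition series to plain-text isotherm files (the same dialect
the `monofilm` command-line tool reads), builds a YAML manifest, and re-runs
the mixing analysis from disk — the round trip a lab would follow with real
trough exports.
"""
import tempfile
from pathlib import Path

import numpy as np
import yaml

import monofilm as mf

fractions = np.round(np.arange(0.0, 1.0001, 0.1), 10)
model = mf.SyntheticModel(a0=-8.0, a1=0.0, noise_sigma_pressure=0.0, n_points=800)

workdir = Path(tempfile.mkdtemp(prefix="monofilm_"))
entries = []
for x1, iso in zip(fractions, mf.make_mixture_isotherms(model, fractions)):
    name = f"mix_X1_{x1:.2f}.txt"
    mf.write_isotherm(iso, workdir / name)
    entries.append({"path": name, "X1": float(x1)})

manifest = workdir / "manifest.yaml"
manifest.write_text(yaml.safe_dump({"pressures": [10, 20, 30], "isotherms": entries}))
print(f"wrote {len(entries)} isotherm files + manifest under {workdir}")

# one file, inspected
first = mf.read_isotherm(workdir / "mix_X1_0.50.txt")
truth = mf.ground_truth(first)
print(f"mix_X1_0.50.txt: {first.n} points, subphase {first.meta.subphase!r}, "
      f"embedded ground truth a0 = {truth['a0']} A^2")

# analysis from disk
series, config = mf.load_manifest(manifest)
analysis = mf.excess_analysis(series, pressures=config["pressures"])
row = analysis.at(30.0)
a_exc_half = row[np.isclose(row["X1"], 0.5)]["A_excess_A2"].iloc[0]
print(f"excess area at X1 = 0.5, 30 mN/m: {a_exc_half:.3f} A^2 "
      f"(construction: 0.25 * a0 = {0.25 * model.a0:.2f})")
print(f"stability minimum from files: X1 = {analysis.minimum.X1:.3f}, "
      f"{analysis.minimum.dG_excess_J_mol / 1000:.3f} kJ/mol")

condensing = mf.condensing_effect_check(series, 30.0)
print(f"condensing effect (A12 decreasing with sterol fraction): {condensing.monotone}")
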