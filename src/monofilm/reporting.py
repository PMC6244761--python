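"""Tidy TSV/JSON report writers used by the command-line interface."""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .elasticity import ElasticityProfile, PhaseLabel, TransitionFeature
from .mixing import ExcessAnalysis


def config_hash(config: dict) -> str:
    """Stable short hash of a resolved configuration, for report traceability."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def profile_frame(profile: ElasticityProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pressure_mN_m": profile.pressure_grid,
            "cs_inverse_mN_m": profile.cs_inverse,
        }
    )


def write_profile_tsv(profile: ElasticityProfile, path: str | Path) -> None:
    profile_frame(profile).to_csv(path, sep="\t", index=False, float_format="%.6g")


def feature_summary(
    profile: ElasticityProfile,
    collapse: TransitionFeature,
    plateau: TransitionFeature | None,
    phase: PhaseLabel,
) -> dict:
    """One-line JSON-ready feature summary of a single-film analysis.

    Reports both the global maximum modulus and, when reachable, the modulus
    at 30 mN/m (the two readings of a 'maximum modulus at 30 mN/m').
    """
    grid = profile.pressure_grid
    cs_at_30 = None
    if grid[0] - 1e-9 <= 30.0 <= grid[-1] + 1e-9:
        cs_at_30 = float(np.interp(30.0, grid, profile.cs_inverse))
    return {
        "phase": phase.label,
        "phase_basis_cs_inverse_mN_m": phase.basis,
        "max_cs_inverse_mN_m": profile.max_cs_inverse[0],
        "max_cs_inverse_at_pressure_mN_m": profile.max_cs_inverse[1],
        "cs_inverse_at_30_mN_m": cs_at_30,
        "collapse_pressure_mN_m": collapse.pressure,
        "collapse_strength": collapse.strength,
        "collapse_reached": collapse.strength > 0,
        "plateau_pressure_mN_m": None if plateau is None else plateau.pressure,
        "plateau_prominence_mN_m": None if plateau is None else plateau.strength,
        "subphase": profile.source_meta.subphase,
        "components": [list(c) for c in profile.source_meta.components],
    }


def mixing_frame(analysis: ExcessAnalysis) -> pd.DataFrame:
    """Mixing table with the user-facing kJ/mol column added."""
    table = analysis.table.copy()
    table["dG_excess_kJ_mol"] = table["dG_excess_J_mol"] / 1000.0
    return table


def write_mixing_tsv(analysis: ExcessAnalysis, path: str | Path) -> None:
    mixing_frame(analysis).to_csv(path, sep="\t", index=False, float_format="%.6g")


def mixing_summary(analysis: ExcessAnalysis) -> dict:
    minimum = analysis.minimum
    return {
        "pressures_mN_m": [float(p) for p in analysis.pressures],
        "flags": list(analysis.flags),
        "stability_minimum": None
        if minimum is None
        else {
            "X1": minimum.X1,
            "dG_excess_kJ_mol": minimum.dG_excess_J_mol / 1000.0,
            "pressure_mN_m": minimum.pressure,
        },
    }


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")
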