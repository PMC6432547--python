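"""Configuration files, trajectory persistence, result tables, manifests.

Config files are YAML with the exact field names of SimulationConfig; unknown
keys are rejected by name.  Trajectories persist to a self-describing HDF5
container (plus an optional extended-XYZ-style text dump for visualization);
result tables are tidy TSV.  Lengths in all files are in units of d, with d in
Angstrom recorded once per file; energies in k_B T.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .energy import SPECIES_NAMES
from .engine import SimulationConfig, Trajectory

_CONFIG_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}


def load_config(path) -> SimulationConfig:
    """Read a YAML run configuration; missing keys take the model defaults,
    unknown keys and out-of-range values raise with every offense listed."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    problems = [f"unknown key: {k!r}" for k in raw if k not in _CONFIG_FIELDS]
    if problems:
        raise ValueError("invalid config:\n  " + "\n  ".join(sorted(problems)))
    try:
        return SimulationConfig(**raw)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"invalid config: {exc}") from exc


def save_config(config: SimulationConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(dataclasses.asdict(config), sort_keys=False)
    )


def save_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))


def load_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def save_trajectory(traj: Trajectory, path) -> None:
    with h5py.File(path, "w") as h5:
        for name in (
            "step_index", "positions", "species", "lipid_sites",
            "charged_species", "energy", "site_xy",
        ):
            h5.create_dataset(name, data=getattr(traj, name))
        h5.attrs["analysis_interval"] = traj.analysis_interval
        h5.attrs["segment_diameter"] = traj.segment_diameter
        h5.attrs["has_box"] = traj.box is not None
        if traj.box is not None:
            h5.attrs["box"] = traj.box


def load_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as h5:
        data = {
            name: h5[name][...]
            for name in (
                "step_index", "positions", "species", "lipid_sites",
                "charged_species", "energy", "site_xy",
            )
        }
        box = tuple(h5.attrs["box"]) if h5.attrs["has_box"] else None
        return Trajectory(
            box=box,
            analysis_interval=int(h5.attrs["analysis_interval"]),
            segment_diameter=float(h5.attrs["segment_diameter"]),
            **data,
        )


def dump_xyz(traj: Trajectory, path) -> None:
    """Extended-XYZ-like text dump: polymer segments as P, lipids by species."""
    lines = []
    n_chains, n_beads = traj.positions.shape[1:3]
    for f in range(traj.n_frames):
        n_atoms = n_chains * n_beads + traj.species.shape[1]
        lines.append(str(n_atoms))
        lines.append(
            f"step={traj.step_index[f]} energy={traj.energy[f]:.6f} "
            f"lengths_in_d=1 d_angstrom={traj.segment_diameter}"
        )
        for c in range(n_chains):
            for pos in traj.positions[f, c]:
                lines.append(f"P {pos[0]:.5f} {pos[1]:.5f} {pos[2]:.5f}")
        for s, xy in zip(traj.species[f], traj.site_xy):
            lines.append(
                f"{SPECIES_NAMES[int(s)]} {xy[0]:.5f} {xy[1]:.5f} 0.00000"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# tidy result tables
# --------------------------------------------------------------------------


def sequestration_table(aggregated: dict) -> pd.DataFrame:
    rows = []
    radii = aggregated["zone_radii"]
    for species in ("PIP2", "PS"):
        block = aggregated[species]
        for i, k in enumerate(radii):
            rows.append(
                {
                    "zone": int(k),
                    "species": species,
                    "phi_mean": block["phi_mean"][i],
                    "phi_se": block["phi_se"][i],
                    "M_mean": block["M_mean"][i],
                    "M_se": block["M_se"][i],
                }
            )
    return pd.DataFrame(rows)


def rdf_table(aggregated: dict) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "r": aggregated["r_centers"],
            "g_mean": aggregated["g_mean"],
            "g_se": aggregated["g_se"],
        }
    )


def mobility_table(results) -> pd.DataFrame:
    """One row per (zone, species) with replica mean +/- SE of m_d and m_l,
    plus zone-independent m_pc rows."""
    from .observables import replica_mean_se

    rows = []
    radii = results[0].zone_radii
    m_pc_mean, m_pc_se = replica_mean_se([[r.m_pc] for r in results])
    rows.append(
        {
            "zone": 0, "species": "chain_com",
            "m_d_mean": np.nan, "m_d_se": np.nan,
            "m_l_mean": np.nan, "m_l_se": np.nan,
            "m_pc_mean": float(m_pc_mean[0]), "m_pc_se": float(m_pc_se[0]),
        }
    )
    for species in ("PIP2", "PS"):
        d_mean, d_se = replica_mean_se([r.m_d[species] for r in results])
        l_mean, l_se = replica_mean_se([r.m_l[species] for r in results])
        for i, k in enumerate(radii):
            rows.append(
                {
                    "zone": int(k), "species": species,
                    "m_d_mean": d_mean[i], "m_d_se": d_se[i],
                    "m_l_mean": l_mean[i], "m_l_se": l_se[i],
                    "m_pc_mean": np.nan, "m_pc_se": np.nan,
                }
            )
    return pd.DataFrame(rows)


def save_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
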