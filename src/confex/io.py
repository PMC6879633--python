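"""Readers and writers for the plain-text formats the pipeline exchanges.

All tabular formats are TSV/CSV with fixed header columns (documented on
each function); trajectories travel as multi-model PDB files (MODEL/ENDMDL
records, parsed with Biopython) or as per-frame dihedral TSVs that bypass
coordinate processing.  Generators write ground truth as a sidecar JSON file
next to the data file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import CELSIUS_OFFSET
from .dimer import DimerTitration
from .exceptions import InvalidModelError
from .mddihedral import DihedralSeries, Trajectory
from .ratethermo import RateSeries
from .shifts import ShiftPair
from .stability import DenatCurve, MeltCurve
from .zz import ZZDataset

__all__ = [
    "read_zz_tsv", "write_zz_tsv",
    "read_rate_tsv", "write_rate_tsv",
    "read_titration_tsv", "write_titration_tsv",
    "read_shifts_tsv", "write_shifts_tsv",
    "read_melt_csv", "write_melt_csv",
    "read_denat_csv", "write_denat_csv",
    "read_dihedral_tsv", "write_dihedral_tsv",
    "read_multimodel_pdb", "write_multimodel_pdb",
    "write_truth_json",
]


def write_truth_json(path, truth: dict) -> None:
    """Ground-truth sidecar for a generated dataset."""
    Path(path).write_text(json.dumps(truth, indent=2, default=float) + "\n")


# -- ZZ datasets -------------------------------------------------------------

_ZZ_COLS = ["residue", "temperature_K", "tmix_s", "I_AA", "I_BB", "I_AB", "I_BA", "sigma"]


def write_zz_tsv(path, dataset: ZZDataset) -> None:
    """Columns: residue, temperature_K, tmix_s, I_AA, I_BB, I_AB, I_BA, sigma."""
    n = len(dataset.mixing_times)
    df = pd.DataFrame({
        "residue": [dataset.residue_label] * n,
        "temperature_K": dataset.temperature,
        "tmix_s": dataset.mixing_times,
        "I_AA": dataset.I_AA, "I_BB": dataset.I_BB,
        "I_AB": dataset.I_AB, "I_BA": dataset.I_BA,
        "sigma": dataset.sigma if dataset.sigma is not None else [""] * n,
    })
    df.to_csv(path, sep="\t", index=False)


def read_zz_tsv(path) -> list[ZZDataset]:
    """One ZZDataset per (residue, temperature) group in the file."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_ZZ_COLS[:-1]) - set(df.columns)
    if missing:
        raise InvalidModelError(f"ZZ TSV missing columns: {sorted(missing)}")
    out = []
    for (res, temp), g in df.groupby(["residue", "temperature_K"], sort=False):
        g = g.sort_values("tmix_s")
        sigma = None
        if "sigma" in g.columns and g["sigma"].notna().all():
            s = pd.to_numeric(g["sigma"], errors="coerce")
            if s.notna().all():
                sigma = s.to_numpy()
        out.append(ZZDataset(
            residue_label=str(res), temperature=float(temp),
            mixing_times=g["tmix_s"].to_numpy(),
            I_AA=g["I_AA"].to_numpy(), I_BB=g["I_BB"].to_numpy(),
            I_AB=g["I_AB"].to_numpy(), I_BA=g["I_BA"].to_numpy(),
            sigma=sigma,
        ))
    return out


# -- rate series -------------------------------------------------------------

def write_rate_tsv(path, series_list: list[RateSeries]) -> None:
    """Columns: residue, direction, temperature_K, k_per_s, k_stderr."""
    rows = []
    for s in series_list:
        for i in range(len(s.temperatures)):
            rows.append({
                "residue": s.residue_label, "direction": s.direction,
                "temperature_K": s.temperatures[i], "k_per_s": s.k[i],
                "k_stderr": s.k_stderr[i] if s.k_stderr is not None else "",
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_rate_tsv(path) -> list[RateSeries]:
    """Accepts temperature_K or temperature_C (converted to K on read)."""
    df = pd.read_csv(path, sep="\t")
    if "temperature_K" in df.columns:
        df["_T"] = df["temperature_K"].astype(float)
    elif "temperature_C" in df.columns:
        df["_T"] = df["temperature_C"].astype(float) + CELSIUS_OFFSET
    else:
        raise InvalidModelError("rate TSV needs temperature_K or temperature_C")
    out = []
    for (res, direction), g in df.groupby(["residue", "direction"], sort=False):
        g = g.sort_values("_T")
        stderr = None
        if "k_stderr" in g.columns:
            s = pd.to_numeric(g["k_stderr"], errors="coerce")
            if s.notna().all():
                stderr = s.to_numpy()
        out.append(RateSeries(
            residue_label=str(res), direction=str(direction),
            temperatures=g["_T"].to_numpy(), k=g["k_per_s"].to_numpy(),
            k_stderr=stderr,
        ))
    return out


# -- titrations --------------------------------------------------------------

def write_titration_tsv(path, t: DimerTitration) -> None:
    """Columns: conc_M, V_monomer, V_dimer."""
    pd.DataFrame({
        "conc_M": t.concentrations, "V_monomer": t.V_monomer, "V_dimer": t.V_dimer,
    }).to_csv(path, sep="\t", index=False)


def read_titration_tsv(path) -> DimerTitration:
    df = pd.read_csv(path, sep="\t").sort_values("conc_M")
    return DimerTitration(
        concentrations=df["conc_M"].to_numpy(),
        V_monomer=df["V_monomer"].to_numpy(),
        V_dimer=df["V_dimer"].to_numpy(),
    )


# -- chemical shift pairs ----------------------------------------------------

def write_shifts_tsv(path, pairs: list[ShiftPair]) -> None:
    """Columns: residue, dH_major, dN_major, dH_minor, dN_minor (minor may be empty)."""
    rows = []
    for p in pairs:
        rows.append({
            "residue": p.residue_label,
            "dH_major": p.dH_major, "dN_major": p.dN_major,
            "dH_minor": p.dH_minor if p.has_minor else "",
            "dN_minor": p.dN_minor if p.has_minor else "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_shifts_tsv(path) -> list[ShiftPair]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        dh_min = pd.to_numeric(pd.Series([r.get("dH_minor")]), errors="coerce").iloc[0]
        dn_min = pd.to_numeric(pd.Series([r.get("dN_minor")]), errors="coerce").iloc[0]
        has_minor = not (pd.isna(dh_min) or pd.isna(dn_min))
        out.append(ShiftPair(
            residue_label=str(r["residue"]),
            dH_major=float(r["dH_major"]), dN_major=float(r["dN_major"]),
            dH_minor=float(dh_min) if has_minor else None,
            dN_minor=float(dn_min) if has_minor else None,
        ))
    return out


# -- denaturation curves -----------------------------------------------------

def write_melt_csv(path, curve: MeltCurve) -> None:
    """Columns: temperature_C, ellipticity_mdeg."""
    pd.DataFrame({
        "temperature_C": curve.temperatures, "ellipticity_mdeg": curve.ellipticity,
    }).to_csv(path, index=False)


def read_melt_csv(path) -> MeltCurve:
    df = pd.read_csv(path).sort_values("temperature_C")
    return MeltCurve(
        temperatures=df["temperature_C"].to_numpy(),
        ellipticity=df["ellipticity_mdeg"].to_numpy(),
    )


def write_denat_csv(path, curve: DenatCurve) -> None:
    """Columns: conc_M, fraction_unfolded."""
    pd.DataFrame({
        "conc_M": curve.denaturant, "fraction_unfolded": curve.response,
    }).to_csv(path, index=False)


def read_denat_csv(path) -> DenatCurve:
    df = pd.read_csv(path).sort_values("conc_M")
    return DenatCurve(
        denaturant=df["conc_M"].to_numpy(),
        response=df["fraction_unfolded"].to_numpy(),
    )


# -- dihedral series ---------------------------------------------------------

def write_dihedral_tsv(path, series: DihedralSeries) -> None:
    """Columns: frame, time_ns, chi1_deg, chi2_deg."""
    pd.DataFrame({
        "frame": np.arange(len(series.chi1)),
        "time_ns": series.times,
        "chi1_deg": series.chi1, "chi2_deg": series.chi2,
    }).to_csv(path, sep="\t", index=False)


def read_dihedral_tsv(path, residue_label: str = "") -> DihedralSeries:
    df = pd.read_csv(path, sep="\t").sort_values("frame")
    return DihedralSeries(
        residue_label=residue_label or str(Path(path).stem),
        chi1=df["chi1_deg"].to_numpy(), chi2=df["chi2_deg"].to_numpy(),
        times=df["time_ns"].to_numpy(),
    )


# -- multi-model PDB ---------------------------------------------------------

def write_multimodel_pdb(path, traj: Trajectory) -> None:
    """Write a Trajectory as MODEL/ENDMDL records (one model per frame)."""
    lines = []
    for f in range(traj.coords.shape[0]):
        lines.append(f"MODEL     {f + 1:4d}")
        for a in range(traj.coords.shape[1]):
            x, y, z = traj.coords[f, a]
            name = traj.atom_names[a]
            pad = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {a + 1:5d} {pad}{'':1s}{traj.residue_names[a]:>3s} A"
                f"{traj.residue_indices[a]:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {name[0]:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_multimodel_pdb(path, frame_interval: float = 1.0) -> Trajectory:
    """Parse MODEL/ENDMDL records with Biopython into a Trajectory."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("traj", str(path))
    models = list(structure)
    if len(models) < 2:
        raise InvalidModelError("multi-model PDB needs at least 2 MODEL records")

    atom_names: list[str] = []
    res_idx: list[int] = []
    res_names: list[str] = []
    frames = []
    for mi, model in enumerate(models):
        coords = []
        names = []
        ridx = []
        rnames = []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    coords.append(atom.coord)
                    names.append(atom.get_name())
                    ridx.append(residue.id[1])
                    rnames.append(residue.get_resname())
        if mi == 0:
            atom_names, res_idx, res_names = names, ridx, rnames
        elif names != atom_names:
            raise InvalidModelError("atom count/order differs between models")
        frames.append(np.asarray(coords, dtype=float))
    return Trajectory(
        coords=np.stack(frames), atom_names=atom_names,
        residue_indices=np.asarray(res_idx), residue_names=res_names,
        frame_interval=frame_interval,
    )
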