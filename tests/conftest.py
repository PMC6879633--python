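"""Shared fixtures: a small synthetic two-variant study on disk."""

import numpy as np
import pytest
import yaml

from confex import io as cio
from confex import synthetic as syn
from confex.shifts import ShiftPair
from confex.zz import ZZParams


@pytest.fixture(scope="session")
def variant_fixture(tmp_path_factory):
    """Two synthetic variants: a conformational exchanger with full NMR data
    and a static variant with a melt plus MD observables."""
    root = tmp_path_factory.mktemp("variants")

    cio.write_shifts_tsv(root / "v1_shifts.tsv",
                         [ShiftPair("W43e", 10.1, 129.3, 10.5, 133.8)])
    law = syn.DimerCoupledRateLaw(k0=5.0, Ea_intrinsic=9.0, Kd0=100e-6,
                                  dH_assoc=30.0, Ctot=1e-3)
    temps = syn.DEFAULT_TEMPERATURES
    series = [
        syn.gen_rate_series(syn.SynthSpec(2, 0.0, temps, {"k0": 3.0, "Ea": 9.0}),
                            "arrhenius", "W43e", "1→2"),
        syn.gen_rate_series(syn.SynthSpec(1, 0.0, temps, law),
                            "dimer_coupled", "W43e", "2→1"),
        syn.gen_rate_series(syn.SynthSpec(3, 0.0, temps, {"k0": 8.0, "Ea": 10.0}),
                            "arrhenius", "T17", "1→2"),
        syn.gen_rate_series(syn.SynthSpec(4, 0.0, temps, {"k0": 6.0, "Ea": 12.0}),
                            "arrhenius", "T17", "2→1"),
    ]
    cio.write_rate_tsv(root / "v1_rates.tsv", series)
    cio.write_titration_tsv(
        root / "v1_titration.tsv",
        syn.gen_titration(syn.SynthSpec(5, 0.0, [20e-6, 100e-6, 500e-6, 1e-3], 116e-6)))
    cio.write_denat_csv(
        root / "v1_chem.csv",
        syn.gen_denaturation(syn.SynthSpec(6, 0.0, np.linspace(0, 5, 12),
                                           {"Cm": 1.34, "m": 2.24}), "chemical"))

    cio.write_shifts_tsv(root / "v2_shifts.tsv", [ShiftPair("W43e", 10.1, 129.3)])
    cio.write_melt_csv(
        root / "v2_melt.csv",
        syn.gen_denaturation(syn.SynthSpec(7, 0.0, np.arange(25.0, 99.0, 2.0),
                                           {"Tm": 84.0, "dH_vH": 60.0}), "thermal"))
    Q = syn.single_dihedral_rate_matrix(0.02, 0.02)
    sample = syn.gen_rotamer_traj(syn.SynthSpec(8, 0.0, np.arange(0.0, 1000.0, 1.0), Q),
                                  angular_noise_sd=10.0)
    cio.write_dihedral_tsv(root / "v2_dihedrals.tsv", sample.series)
    cio.write_multimodel_pdb(
        root / "v2_traj.pdb",
        syn.gen_backbone_ensemble(syn.SynthSpec(9, 0.0, np.arange(60), np.full(10, 0.5))))

    cfg = {
        "seed": 1,
        "variants": [
            {"name": "VarA", "mutations": "A34F,V39L", "shifts": "v1_shifts.tsv",
             "rates": "v1_rates.tsv", "probe_residue": "W43e", "reporter_residue": "T17",
             "titration": "v1_titration.tsv", "chemical": "v1_chem.csv"},
            {"name": "VarB", "mutations": "", "shifts": "v2_shifts.tsv",
             "thermal": "v2_melt.csv", "dihedrals": "v2_dihedrals.tsv",
             "trajectory": "v2_traj.pdb"},
        ],
    }
    cfg_path = root / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg))
    return {"root": root, "config": cfg_path, "sample": sample}
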