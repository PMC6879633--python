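"""End-to-end per-variant orchestration.

A config (YAML or JSON) lists variants, each with optional paths to the raw
data types (chemical-shift pairs, ZZ-exchange curves, rate tables, dimer
titrations, denaturation curves, dihedral series or multi-model PDB
trajectories) and per-stage parameter overrides.  `run_pipeline` executes
every configured stage in dependency order, collects one `VariantReport`
per variant (absent inputs are marked "not measured", stage failures are
recorded and the remaining variants still run), and writes TSV + JSON
reports plus a JSON-lines run log.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import io as cio
from .exceptions import ConfexError, InvalidModelError
from .mddihedral import assign_rotamer_states, compute_rmsf, count_transitions
from .ratethermo import classify_behavior, fit_arrhenius
from .shifts import DEFAULT_THRESHOLD_PPM, classify_mode
from .stability import fit_chemical, fit_thermal
from .dimer import fit_kd
from .zz import fit_zz

__all__ = ["VariantReport", "run_pipeline", "write_report", "load_config"]

log = logging.getLogger("confex")

NOT_MEASURED = "not measured"


@dataclass
class VariantReport:
    """One row of the per-variant summary (Fig. 1c/Table 1/Table 2 layout)."""

    name: str
    mutations: str = ""
    exchange_mode: str = NOT_MEASURED
    delta_delta_ppm: float | None = None
    Ea_fwd: float | None = None
    Ea_fwd_stderr: float | None = None
    Ea_rev: float | None = None
    Ea_rev_stderr: float | None = None
    behavior: str = NOT_MEASURED
    reporter_consistent: str = NOT_MEASURED
    Kd_M: float | None = None
    Kd_stderr_M: float | None = None
    Tm_C: float | None = None
    Cm_M: float | None = None
    m_value: float | None = None
    dG_U: float | None = None
    md_transitions_combined: int | None = None
    md_transitions_chi1: int | None = None
    rmsf_mean_A: float | None = None
    errors: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {}
        for k, v in self.__dict__.items():
            if k == "errors":
                d[k] = "; ".join(v)
            elif v is None:
                d[k] = NOT_MEASURED
            else:
                d[k] = v
        return d


REPORT_COLUMNS = [
    "name", "mutations", "exchange_mode", "delta_delta_ppm",
    "Ea_fwd", "Ea_fwd_stderr", "Ea_rev", "Ea_rev_stderr", "behavior",
    "reporter_consistent", "Kd_M", "Kd_stderr_M", "Tm_C", "Cm_M",
    "m_value", "dG_U", "md_transitions_combined", "md_transitions_chi1",
    "rmsf_mean_A", "errors",
]


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _resolve(base: Path, rel: str) -> Path:
    p = Path(rel)
    if not p.is_absolute():
        p = base / p
    if not p.exists():
        raise FileNotFoundError(f"input file not found: {p}")
    return p


def _fmt_float(v) -> str:
    if isinstance(v, bool):
        return str(v)
    if isinstance(v, float):
        return f"{v:.4g}"
    return str(v)


def _run_variant(vcfg: dict, base: Path, defaults: dict) -> VariantReport:
    rep = VariantReport(name=vcfg["name"], mutations=str(vcfg.get("mutations", "")))
    threshold = float(vcfg.get("threshold_ppm", defaults.get("threshold_ppm", DEFAULT_THRESHOLD_PPM)))
    min_dwell = int(vcfg.get("min_dwell", defaults.get("min_dwell", 1)))
    burn_in = float(vcfg.get("burn_in", defaults.get("burn_in", 1.0 / 3.0)))

    def stage(label, fn):
        t0 = time.perf_counter()
        try:
            fn()
            log.info("%s: %s done in %.3f s", rep.name, label, time.perf_counter() - t0)
        except (ConfexError, FileNotFoundError, KeyError, ValueError) as e:
            rep.errors.append(f"{label}: {e}")
            log.warning("%s: %s failed: %s", rep.name, label, e)

    if "shifts" in vcfg:
        def do_shifts():
            pairs = cio.read_shifts_tsv(_resolve(base, vcfg["shifts"]))
            call = classify_mode(pairs[0], threshold=threshold)
            rep.exchange_mode = call.mode
            rep.delta_delta_ppm = call.delta_delta
        stage("shift classification", do_shifts)

    if "zz" in vcfg:
        def do_zz():
            from .ratethermo import RateSeries
            import numpy as np
            temps, k12s, k21s = [], [], []
            for p in vcfg["zz"]:
                for ds in cio.read_zz_tsv(_resolve(base, p)):
                    res = fit_zz(ds)
                    temps.append(ds.temperature)
                    k12s.append(res.params.k_12)
                    k21s.append(res.params.k_21)
            order = np.argsort(temps)
            fwd = RateSeries("probe", "1→2", np.asarray(temps)[order], np.asarray(k12s)[order])
            rev = RateSeries("probe", "2→1", np.asarray(temps)[order], np.asarray(k21s)[order])
            _classify_rates(rep, fwd, rev, None, None)
        stage("ZZ-exchange fitting", do_zz)

    if "rates" in vcfg:
        def do_rates():
            series = cio.read_rate_tsv(_resolve(base, vcfg["rates"]))
            probe_res = vcfg.get("probe_residue")
            reporter_res = vcfg.get("reporter_residue")
            by_key = {(s.residue_label, s.direction): s for s in series}
            labels = sorted({s.residue_label for s in series})
            if probe_res is None:
                probe_res = labels[0]
            fwd = by_key.get((probe_res, "1→2"))
            rev = by_key.get((probe_res, "2→1"))
            if fwd is None or rev is None:
                raise InvalidModelError(f"need both directions for probe residue {probe_res!r}")
            rfwd = by_key.get((reporter_res, "1→2")) if reporter_res else None
            rrev = by_key.get((reporter_res, "2→1")) if reporter_res else None
            _classify_rates(rep, fwd, rev, rfwd, rrev)
        stage("rate/temperature analysis", do_rates)

    if "titration" in vcfg:
        def do_kd():
            t = cio.read_titration_tsv(_resolve(base, vcfg["titration"]))
            fit = fit_kd(t)
            if fit.identifiable:
                rep.Kd_M = fit.Kd
                rep.Kd_stderr_M = fit.Kd_stderr
            else:
                rep.errors.append("Kd not identifiable from titration")
        stage("Kd fitting", do_kd)

    if "thermal" in vcfg:
        def do_thermal():
            fit = fit_thermal(cio.read_melt_csv(_resolve(base, vcfg["thermal"])))
            rep.Tm_C = fit.midpoint
        stage("thermal stability fit", do_thermal)

    if "chemical" in vcfg:
        def do_chemical():
            fit = fit_chemical(cio.read_denat_csv(_resolve(base, vcfg["chemical"])))
            rep.Cm_M = fit.midpoint
            rep.m_value = fit.m_value
            rep.dG_U = fit.dG_U
        stage("chemical stability fit", do_chemical)

    if "dihedrals" in vcfg:
        def do_dihedrals():
            series = cio.read_dihedral_tsv(_resolve(base, vcfg["dihedrals"]))
            states = assign_rotamer_states(series)
            counts = count_transitions(states, min_dwell=min_dwell)
            rep.md_transitions_combined = counts.combined
            rep.md_transitions_chi1 = counts.chi1_only
        stage("rotamer transition counting", do_dihedrals)

    if "trajectory" in vcfg:
        def do_rmsf():
            traj = cio.read_multimodel_pdb(_resolve(base, vcfg["trajectory"]))
            prof = compute_rmsf(traj, burn_in_fraction=burn_in)
            rep.rmsf_mean_A = float(prof.rmsf.mean())
        stage("RMSF analysis", do_rmsf)

    return rep


def _classify_rates(rep: VariantReport, fwd, rev, rfwd, rrev) -> None:
    f_fwd = fit_arrhenius(fwd)
    f_rev = fit_arrhenius(rev)
    rep.Ea_fwd, rep.Ea_fwd_stderr = f_fwd.Ea_app, f_fwd.Ea_stderr
    rep.Ea_rev, rep.Ea_rev_stderr = f_rev.Ea_app, f_rev.Ea_stderr
    r_f = fit_arrhenius(rfwd) if rfwd is not None else None
    r_r = fit_arrhenius(rrev) if rrev is not None else None
    call = classify_behavior(f_fwd, f_rev, r_f, r_r)
    rep.behavior = call.behavior
    if call.reporter_consistent is not None:
        rep.reporter_consistent = "yes" if call.reporter_consistent else "no"


def run_pipeline(config_path, out_dir=None) -> list[VariantReport]:
    """Run all configured stages for every variant; write reports and a log."""
    config_path = Path(config_path)
    cfg = load_config(config_path)
    base = config_path.parent
    out = Path(out_dir) if out_dir else base / cfg.get("out_dir", "confex_out")
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    defaults = {k: cfg[k] for k in ("threshold_ppm", "min_dwell", "burn_in") if k in cfg}

    reports = []
    log_lines = [json.dumps({
        "event": "start", "version": __version__, "seed": seed,
        "config": str(config_path),
    })]
    for vcfg in cfg.get("variants", []):
        t0 = time.perf_counter()
        rep = _run_variant(vcfg, base, defaults)
        reports.append(rep)
        log_lines.append(json.dumps({
            "event": "variant", "name": rep.name,
            "elapsed_s": round(time.perf_counter() - t0, 4),
            "errors": rep.errors,
        }))
    if not reports:
        raise InvalidModelError("config lists no variants")

    write_report(reports, "tsv", out / "report.tsv")
    write_report(reports, "json", out / "report.json")
    (out / "run_log.jsonl").write_text("\n".join(log_lines) + "\n")
    return reports


def write_report(reports: list[VariantReport], format: str, path) -> None:
    """Serialize reports; TSV has a stable column order, floats at 4 sig figs."""
    if not reports:
        raise InvalidModelError("empty report collection")
    path = Path(path)
    if format == "tsv":
        lines = ["\t".join(REPORT_COLUMNS)]
        for rep in reports:
            d = rep.to_dict()
            lines.append("\t".join(_fmt_float(d[c]) for c in REPORT_COLUMNS))
        path.write_text("\n".join(lines) + "\n")
    elif format == "json":
        payload = [r.to_dict() for r in reports]
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        raise InvalidModelError(f"unknown report format {format!r}")
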