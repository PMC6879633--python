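"""Temperature dependence of exchange rates: Arrhenius and Eyring analysis.

Exchange rate constants measured at several temperatures are fitted to

    Arrhenius:  ln k = ln A − Ea/(R·T)
    Eyring:     ln(k/T) = ln(κ·k_B/h) + ΔS‡/R − ΔH‡/(R·T),  κ = 1

by (optionally error-weighted) linear least squares in 1/T.  A residue's
exchange is classified as Arrhenius when the apparent activation energy is
strictly positive in both transition directions; a negative apparent Ea is a
diagnostic of a composed (non-two-state) process, such as exchange gated by
a temperature-dependent monomer–dimer equilibrium.  When a dimer-interface
reporter residue is supplied, the probe's activation energies are also
compared against the reporter's to decide whether both report on the same
underlying process.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KB_OVER_H, R_CAL, R_KCAL
from .exceptions import InsufficientDataError, InvalidModelError

__all__ = [
    "RateSeries",
    "ArrheniusFit",
    "EyringFit",
    "BehaviorCall",
    "fit_arrhenius",
    "fit_eyring",
    "classify_behavior",
]


@dataclass
class RateSeries:
    """Exchange rate constants vs temperature for one transition direction."""

    residue_label: str
    direction: str  # "1→2" (major→minor) or "2→1"
    temperatures: np.ndarray  # K, strictly increasing
    k: np.ndarray  # s⁻¹
    k_stderr: np.ndarray | None = None

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        if self.k.shape != self.temperatures.shape:
            raise InvalidModelError("k not aligned with temperatures")
        if np.any(np.diff(self.temperatures) <= 0):
            raise InvalidModelError("temperatures must be strictly increasing")
        if np.any(self.k <= 0):
            raise InvalidModelError("rates must be positive")
        if self.k_stderr is not None:
            self.k_stderr = np.asarray(self.k_stderr, dtype=float)
            if self.k_stderr.shape != self.k.shape:
                raise InvalidModelError("k_stderr not aligned with k")


@dataclass
class ArrheniusFit:
    Ea_app: float  # kcal/mol
    lnA: float
    Ea_stderr: float  # kcal/mol
    r_squared: float


@dataclass
class EyringFit:
    dH_act: float  # ΔH‡, kcal/mol
    dS_act: float  # ΔS‡, cal/(mol·K)
    dH_stderr: float
    dS_stderr: float
    transmission_coefficient: float = 1.0


@dataclass
class BehaviorCall:
    behavior: str  # "Arrhenius" | "non-Arrhenius"
    reporter_consistent: bool | None
    notes: str = ""


def _weighted_line(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least-squares line y = a + b·x; returns (a, b, se_a, se_b, r2)."""
    W = np.sum(w)
    xb = np.sum(w * x) / W
    yb = np.sum(w * y) / W
    sxx = np.sum(w * (x - xb) ** 2)
    sxy = np.sum(w * (x - xb) * (y - yb))
    b = sxy / sxx
    a = yb - b * xb
    resid = y - (a + b * x)
    sst = np.sum(w * (y - yb) ** 2)
    ssr = np.sum(w * resid**2)
    # constant y: the flat line fits perfectly
    r2 = 1.0 if sst == 0 else max(0.0, 1.0 - ssr / sst)
    dof = max(len(x) - 2, 1)
    s2 = ssr / dof
    se_b = np.sqrt(s2 / sxx)
    se_a = np.sqrt(s2 * (1.0 / W + xb**2 / sxx))
    return a, b, se_a, se_b, r2


def _prep(series: RateSeries, weighted: bool):
    if len(series.temperatures) < 3:
        raise InsufficientDataError("need at least 3 temperatures")
    x = 1.0 / series.temperatures
    if weighted:
        if series.k_stderr is None:
            raise InvalidModelError("weighted fit requested without k_stderr")
        # δ(ln k) = k_stderr / k
        w = (series.k / series.k_stderr) ** 2
    else:
        w = np.ones_like(x)
    return x, w


def fit_arrhenius(series: RateSeries, weighted: bool = False) -> ArrheniusFit:
    """Fit ln k vs 1/T; Ea_app = −slope·R (kcal/mol)."""
    x, w = _prep(series, weighted)
    y = np.log(series.k)
    a, b, _se_a, se_b, r2 = _weighted_line(x, y, w)
    return ArrheniusFit(
        Ea_app=float(-b * R_KCAL),
        lnA=float(a),
        Ea_stderr=float(se_b * R_KCAL),
        r_squared=float(r2),
    )


def fit_eyring(series: RateSeries, weighted: bool = False) -> EyringFit:
    """Fit ln(k/T) vs 1/T; ΔH‡ = −slope·R, ΔS‡ = R·(intercept − ln(k_B/h))."""
    x, w = _prep(series, weighted)
    y = np.log(series.k / series.temperatures)
    a, b, se_a, se_b, _r2 = _weighted_line(x, y, w)
    return EyringFit(
        dH_act=float(-b * R_KCAL),
        dS_act=float(R_CAL * (a - np.log(KB_OVER_H))),
        dH_stderr=float(se_b * R_KCAL),
        dS_stderr=float(R_CAL * se_a),
    )


def classify_behavior(
    fit_fwd: ArrheniusFit,
    fit_rev: ArrheniusFit,
    reporter_fwd: ArrheniusFit | None = None,
    reporter_rev: ArrheniusFit | None = None,
) -> BehaviorCall:
    """Classify exchange as Arrhenius (both directional Ea strictly > 0) or not.

    With a dimer-interface reporter supplied, `reporter_consistent` is true
    when the probe and reporter activation energies agree within two combined
    standard errors in both directions; disagreement with both probe energies
    positive flags that the probe senses a dynamic process distinct from
    dimerization.
    """
    arrhenius = fit_fwd.Ea_app > 0 and fit_rev.Ea_app > 0
    behavior = "Arrhenius" if arrhenius else "non-Arrhenius"
    notes = []
    if not arrhenius:
        neg = [d for d, f in (("1→2", fit_fwd), ("2→1", fit_rev)) if f.Ea_app <= 0]
        notes.append(f"nonpositive apparent Ea for direction(s): {', '.join(neg)}")

    reporter_consistent: bool | None = None
    if reporter_fwd is not None and reporter_rev is not None:
        def agree(p: ArrheniusFit, r: ArrheniusFit) -> bool:
            tol = 2.0 * np.sqrt(p.Ea_stderr**2 + r.Ea_stderr**2)
            return bool(abs(p.Ea_app - r.Ea_app) <= tol)

        reporter_consistent = agree(fit_fwd, reporter_fwd) and agree(fit_rev, reporter_rev)
        if arrhenius and not reporter_consistent:
            notes.append(
                "both activation energies positive but inconsistent with the "
                "dimer-interface reporter: a different dynamic process is sensed"
            )
    return BehaviorCall(
        behavior=behavior,
        reporter_consistent=reporter_consistent,
        notes="; ".join(notes),
    )
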