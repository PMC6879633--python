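"""Monomer–dimer equilibrium analysis from NMR peak-volume titrations.

For the association 2M ⇌ M₂ with dissociation constant Kd = [M]²/[D]
(concentrations in monomer equivalents), mass action at total concentration
Ctot gives the monomer concentration as the positive root of
2[M]² /Kd + [M] − Ctot = 0:

    [M] = (−Kd + √(Kd² + 8·Kd·Ctot)) / 4

Each dimer carries two copies of a reporter residue, so the minor (dimer)
peak volume is taken proportional to 2[D] and the observed monomer fraction
is f = V_M / (V_M + V_D).  `fit_kd` fits that fraction across a titration by
least squares over log Kd.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .exceptions import ConvergenceError, InsufficientDataError, InvalidModelError

__all__ = ["DimerTitration", "KdFit", "monomer_fraction", "fit_kd"]

_LOG10_KD_BOUNDS = (-9.0, -1.0)


@dataclass
class DimerTitration:
    """Major (monomer) and minor (dimer) peak volumes across total concentrations."""

    concentrations: np.ndarray  # M, total protein in monomer equivalents
    V_monomer: np.ndarray
    V_dimer: np.ndarray

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.V_monomer = np.asarray(self.V_monomer, dtype=float)
        self.V_dimer = np.asarray(self.V_dimer, dtype=float)
        if np.any(self.concentrations <= 0):
            raise InvalidModelError("concentrations must be positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise InvalidModelError("concentrations must be strictly increasing")
        if self.V_monomer.shape != self.concentrations.shape or self.V_dimer.shape != self.concentrations.shape:
            raise InvalidModelError("volumes not aligned with concentrations")
        if np.any(self.V_monomer < 0) or np.any(self.V_dimer < 0):
            raise InvalidModelError("volumes must be nonnegative")


@dataclass
class KdFit:
    Kd: float  # M
    Kd_stderr: float  # M
    rss: float  # on the fraction scale
    identifiable: bool


def monomer_fraction(Ctot, Kd):
    """Equilibrium monomer fraction [M]/Ctot for 2M ⇌ M₂ at total Ctot.

    Accepts scalars or arrays; both arguments must be positive.
    """
    Ctot = np.asarray(Ctot, dtype=float)
    Kd = np.asarray(Kd, dtype=float)
    if np.any(Ctot <= 0) or np.any(Kd <= 0):
        raise InvalidModelError("Ctot and Kd must be positive")
    M = (-Kd + np.sqrt(Kd**2 + 8.0 * Kd * Ctot)) / 4.0
    f = M / Ctot
    if f.ndim == 0:
        return float(f)
    return f


def fit_kd(titration: DimerTitration, response_factor: float = 1.0) -> KdFit:
    """Fit Kd to observed monomer fractions f = V_M/(V_M + r·V_D).

    `response_factor` r rescales the dimer-peak volume for per-state response
    differences (default 1: dimer volume already proportional to 2[D]).
    Fitted over log₁₀ Kd within [1e−9, 1e−1] M.  `identifiable` is false when
    the observed fractions never leave the flat extremes (all > 0.98 or all
    < 0.02), in which case Kd is not meaningful.
    """
    Vtot = titration.V_monomer + response_factor * titration.V_dimer
    ok = Vtot > 0
    if np.count_nonzero(ok) < 2:
        raise InsufficientDataError("need at least 2 concentrations with nonzero total volume")
    C = titration.concentrations[ok]
    f_obs = titration.V_monomer[ok] / Vtot[ok]

    if np.all(f_obs > 0.98) or np.all(f_obs < 0.02):
        return KdFit(Kd=float("nan"), Kd_stderr=float("nan"), rss=float("nan"), identifiable=False)

    def residuals(x):
        return monomer_fraction(C, 10.0 ** x[0]) - f_obs

    # coarse deterministic scan, then local refinement
    grid = np.arange(_LOG10_KD_BOUNDS[0], _LOG10_KD_BOUNDS[1] + 1e-9, 0.25)
    rss_grid = [float(np.sum(residuals([g]) ** 2)) for g in grid]
    x0 = grid[int(np.argmin(rss_grid))]
    sol = least_squares(
        residuals, [x0], bounds=([_LOG10_KD_BOUNDS[0]], [_LOG10_KD_BOUNDS[1]]),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    if not sol.success:
        raise ConvergenceError("Kd fit did not converge")
    rss = float(np.sum(sol.fun**2))
    Kd = float(10.0 ** sol.x[0])
    dof = max(len(C) - 1, 1)
    jtj = float(np.squeeze(sol.jac.T @ sol.jac))
    if jtj > 0:
        se_log10 = np.sqrt(rss / dof / jtj)
        Kd_stderr = float(Kd * np.log(10.0) * se_log10)
    else:
        Kd_stderr = float("nan")
    return KdFit(Kd=Kd, Kd_stderr=Kd_stderr, rss=rss, identifiable=True)
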