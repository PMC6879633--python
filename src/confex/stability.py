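"""Two-state protein stability fits: thermal melts and chemical denaturation.

Both fits use the standard two-state model with linear folded/unfolded
baselines,

    signal(x) = (b_f + s_f·x)·(1 − p_U(x)) + (b_u + s_u·x)·p_U(x),

where p_U is the unfolded population.  For chemical denaturation in
denaturant D (linear extrapolation model, LEM)

    p_U(D) = 1 / (1 + exp(m·(Cm − D)/(R·T))),   ΔG_U = m·Cm at D = 0,

with T fixed at 298.15 K (25 °C).  For thermal melts the sigmoid is the
van't Hoff form

    p_U(T) = 1 / (1 + exp(ΔH_vH/R·(1/T − 1/Tm)))   (T in kelvin),

whose slope parameter ΔH_vH is fitted but not reported as a thermodynamic
enthalpy.  ΔΔG between variants is referenced so that a positive value means
the variant is destabilized relative to the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .constants import CELSIUS_OFFSET, R_KCAL, T_REF
from .exceptions import ConvergenceError, InvalidModelError, NoTransitionError

__all__ = [
    "MeltCurve",
    "DenatCurve",
    "StabilityFit",
    "fluorescence_to_fraction",
    "fit_chemical",
    "fit_thermal",
    "delta_delta_g",
    "chemical_two_state",
    "thermal_two_state",
]


@dataclass
class MeltCurve:
    """Thermal denaturation: ellipticity at 208 nm vs temperature (°C)."""

    temperatures: np.ndarray  # °C, strictly increasing
    ellipticity: np.ndarray  # mdeg

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)
        if self.ellipticity.shape != self.temperatures.shape:
            raise InvalidModelError("ellipticity not aligned with temperatures")
        if len(self.temperatures) < 8:
            raise InvalidModelError("need at least 8 points spanning the transition")
        if np.any(np.diff(self.temperatures) <= 0):
            raise InvalidModelError("temperatures must be strictly increasing")


@dataclass
class DenatCurve:
    """Chemical denaturation: response vs denaturant concentration (M)."""

    denaturant: np.ndarray  # M, strictly increasing, >= 0
    response: np.ndarray  # fraction unfolded (or raw signal)

    def __post_init__(self):
        self.denaturant = np.asarray(self.denaturant, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.response.shape != self.denaturant.shape:
            raise InvalidModelError("response not aligned with denaturant")
        if len(self.denaturant) < 6:
            raise InvalidModelError("need at least 6 points")
        if np.any(self.denaturant < 0) or np.any(np.diff(self.denaturant) <= 0):
            raise InvalidModelError("denaturant must be nonnegative and strictly increasing")


@dataclass
class StabilityFit:
    kind: str  # "thermal" | "chemical"
    midpoint: float  # Tm (°C) or Cm (M)
    m_value: float | None  # kcal/(mol·M), chemical only
    dG_U: float | None  # kcal/mol, chemical only (= m·Cm)
    baselines: dict  # folded/unfolded intercepts and slopes
    stderr: dict


def chemical_two_state(D, Cm, m, b_f, s_f, b_u, s_u, T=T_REF):
    """Two-state LEM signal at denaturant D (M)."""
    D = np.asarray(D, dtype=float)
    p_u = 1.0 / (1.0 + np.exp(m * (Cm - D) / (R_KCAL * T)))
    return (b_f + s_f * D) * (1.0 - p_u) + (b_u + s_u * D) * p_u


def thermal_two_state(T_C, Tm_C, dH_vH, b_f, s_f, b_u, s_u):
    """Two-state van't Hoff signal at temperature T (°C)."""
    T_C = np.asarray(T_C, dtype=float)
    T_K = T_C + CELSIUS_OFFSET
    Tm_K = Tm_C + CELSIUS_OFFSET
    p_u = 1.0 / (1.0 + np.exp(dH_vH / R_KCAL * (1.0 / T_K - 1.0 / Tm_K)))
    return (b_f + s_f * T_C) * (1.0 - p_u) + (b_u + s_u * T_C) * p_u


def fluorescence_to_fraction(denaturant, spectra, wavelengths=None, n_baseline: int = 2) -> DenatCurve:
    """Convert per-denaturant emission spectra to fraction unfolded.

    `spectra` is an (n_denaturant, n_wavelength) array of emission
    intensities; each spectrum is integrated (trapezoid over wavelength) and
    normalized between linear folded/unfolded baselines fitted to the lowest
    and highest `n_baseline` denaturant points:

        fraction(D) = (S(D) − S_f(D)) / (S_u(D) − S_f(D))
    """
    D = np.asarray(denaturant, dtype=float)
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    if spectra.shape[0] != len(D):
        raise InvalidModelError("one spectrum required per denaturant point")
    if spectra.shape[0] < 2 * n_baseline:
        raise InvalidModelError("too few spectra to identify both baselines")
    if wavelengths is None:
        S = np.trapezoid(spectra, axis=1)
    else:
        S = np.trapezoid(spectra, x=np.asarray(wavelengths, dtype=float), axis=1)

    def line(idx):
        if len(idx) == 1:
            return float(S[idx[0]]), 0.0
        slope, intercept = np.polyfit(D[idx], S[idx], 1)
        return float(intercept), float(slope)

    bf, sf = line(np.arange(n_baseline))
    bu, su = line(np.arange(len(D) - n_baseline, len(D)))
    S_f = bf + sf * D
    S_u = bu + su * D
    denom = S_u - S_f
    if np.any(np.abs(denom) < 1e-12 * max(1.0, float(np.max(np.abs(S))))):
        raise InvalidModelError("degenerate baselines: folded and unfolded signals coincide")
    return DenatCurve(denaturant=D, response=(S - S_f) / denom)


def _fit_two_state(x, y, model, mid0, slope0, kind):
    """Shared machinery: fit (mid, slope, b_f, s_f, b_u, s_u)."""
    span = float(np.max(y) - np.min(y))
    if span <= 1e-12 * max(1.0, float(np.max(np.abs(y))) if np.any(y) else 1.0):
        raise NoTransitionError("no transition detected: flat response")
    nb = max(2, len(x) // 6)
    bf0, sf0 = np.polyfit(x[:nb], y[:nb], 1)[::-1]
    bu0, su0 = np.polyfit(x[-nb:], y[-nb:], 1)[::-1]

    def residuals(theta):
        return model(x, *theta) - y

    sol = least_squares(
        residuals, [mid0, slope0, bf0, sf0, bu0, su0],
        method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=10000,
    )
    if not sol.success:
        raise ConvergenceError(f"{kind} two-state fit did not converge")
    mid, slope, bf, sf, bu, su = (float(v) for v in sol.x)
    if not (x[0] <= mid <= x[-1]):
        raise NoTransitionError(f"fitted midpoint {mid:.3g} outside data range")
    # a real transition separates the baselines at the midpoint
    gap = abs((bu + su * mid) - (bf + sf * mid))
    if gap < 1e-3 * span:
        raise NoTransitionError("no transition detected: baselines coincide")
    rss = float(np.sum(sol.fun**2))
    dof = max(len(x) - 6, 1)
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * rss / dof
        se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(6, np.nan)
    names = ("midpoint", "slope", "b_f", "s_f", "b_u", "s_u")
    stderr = dict(zip(names, (float(s) for s in se)))
    baselines = {"b_f": bf, "s_f": sf, "b_u": bu, "s_u": su}
    return mid, slope, baselines, stderr


def fit_chemical(curve: DenatCurve, T: float = T_REF) -> StabilityFit:
    """Fit the LEM two-state model; returns Cm (M), m (kcal/mol/M), ΔG_U = m·Cm."""
    x, y = curve.denaturant, curve.response
    # midpoint guess: where the response crosses halfway between the ends
    mid_level = 0.5 * (np.mean(y[:2]) + np.mean(y[-2:]))
    mid0 = float(x[np.argmin(np.abs(y - mid_level))])
    mid, m, baselines, stderr = _fit_two_state(
        x, y, lambda D, Cm, mm, bf, sf, bu, su: chemical_two_state(D, Cm, mm, bf, sf, bu, su, T=T),
        mid0, 2.0, "chemical",
    )
    if m < 0:  # sign ambiguity when baselines swap roles
        raise NoTransitionError("fitted m-value negative: not a two-state unfolding transition")
    stderr["m_value"] = stderr.pop("slope")
    stderr["Cm"] = stderr.pop("midpoint")
    return StabilityFit(
        kind="chemical", midpoint=mid, m_value=m, dG_U=m * mid,
        baselines=baselines, stderr=stderr,
    )


def fit_thermal(curve: MeltCurve) -> StabilityFit:
    """Fit the van't Hoff two-state melt; returns Tm (°C)."""
    x, y = curve.temperatures, curve.ellipticity
    mid_level = 0.5 * (np.mean(y[:2]) + np.mean(y[-2:]))
    mid0 = float(x[np.argmin(np.abs(y - mid_level))])
    mid, dh, baselines, stderr = _fit_two_state(x, y, thermal_two_state, mid0, 50.0, "thermal")
    if dh < 0:
        raise NoTransitionError("fitted van't Hoff slope negative: no unfolding transition")
    stderr["dH_vH"] = stderr.pop("slope")
    stderr["Tm"] = stderr.pop("midpoint")
    return StabilityFit(
        kind="thermal", midpoint=mid, m_value=None, dG_U=None,
        baselines=baselines, stderr=stderr,
    )


def delta_delta_g(variant_dG: float, reference_dG: float) -> float:
    """ΔΔG = reference − variant (kcal/mol); positive ⇒ variant destabilized."""
    if not (np.isfinite(variant_dG) and np.isfinite(reference_dG)):
        raise InvalidModelError("free energies must be finite")
    return float(reference_dG - variant_dG)
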