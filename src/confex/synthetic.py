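"""Synthetic-data generators with known ground truth for every pipeline input.

Each generator emulates one class of raw observable the analysis modules
consume — noisy two-site ZZ-exchange intensity curves, rate-vs-temperature
series under an Arrhenius or a dimerization-coupled non-Arrhenius law,
monomer/dimer peak-volume titrations at a stated Kd, two-state denaturation
curves with sloped baselines, continuous-time-Markov rotamer trajectories
with angular noise, and backbone coordinate ensembles with a prescribed
per-residue fluctuation profile.  Noise models: additive Gaussian for
intensities / ellipticity / fraction-scale observables; multiplicative
lognormal for strictly positive observables (volumes, rates).  All
randomness flows from the `SynthSpec.seed` through one `numpy` Generator, so
a fixed seed yields bit-identical output and `noise_sd = 0` yields the exact
noiseless model prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy.linalg import null_space

from .constants import R_KCAL, T_REF
from .dimer import DimerTitration, monomer_fraction
from .exceptions import InvalidModelError
from .mddihedral import (
    CHI1_CENTERS,
    CHI2_CENTERS,
    DihedralSeries,
    RotamerStateSeries,
    Trajectory,
    wrap_angle,
)
from .ratethermo import RateSeries
from .stability import DenatCurve, MeltCurve, chemical_two_state, thermal_two_state
from .zz import ZZDataset, ZZParams, predict_zz

__all__ = [
    "SynthSpec",
    "DimerCoupledRateLaw",
    "RotamerTrajSample",
    "CTMC_STATES",
    "DEFAULT_MIXING_TIMES",
    "DEFAULT_TEMPERATURES",
    "arrhenius_rate",
    "dimer_coupled_rate",
    "single_dihedral_rate_matrix",
    "ctmc_stationary",
    "gen_zz_dataset",
    "gen_rate_series",
    "gen_titration",
    "gen_denaturation",
    "gen_rotamer_traj",
    "gen_backbone_ensemble",
]

#: default mixing-time grid: 8 points over 0–0.4 s
DEFAULT_MIXING_TIMES = tuple(np.linspace(0.0, 0.4, 8))
#: default temperature grid: 278–303 K (the 5–30 °C experimental window)
DEFAULT_TEMPERATURES = tuple(np.linspace(278.0, 303.0, 6))


@dataclass
class SynthSpec:
    """Recipe for one synthetic dataset.

    grid holds the sampling points in the generator's natural units (mixing
    times in s, temperatures in K, concentrations in M, frame times in ns);
    truth holds the target model's ground-truth parameters (documented per
    generator); noise_sd is in units of the generated observable (sd of the
    log for lognormal noise).
    """

    seed: int
    noise_sd: float
    grid: Any
    truth: Any

    def __post_init__(self):
        if self.noise_sd < 0:
            raise InvalidModelError("noise_sd must be nonnegative")
        g = np.asarray(self.grid, dtype=float)
        if g.size == 0:
            raise InvalidModelError("empty grid")
        self.grid = g

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class DimerCoupledRateLaw:
    """Observed-rate law for exchange that only the monomer can undergo.

    k_obs(T) = f_M(T) · k_intrinsic(T): the intrinsic (monomer) exchange rate
    follows Arrhenius with activation energy Ea_intrinsic, while the monomer
    fraction f_M follows mass action with a van't Hoff temperature-dependent
    Kd.  A positive association enthalpy dH_assoc means dimerization is
    favored at high temperature, so f_M falls as T rises and can overwhelm
    the intrinsic rate increase, producing a negative apparent activation
    energy.
    """

    k0: float  # intrinsic rate at T0 (s⁻¹)
    Ea_intrinsic: float  # kcal/mol
    Kd0: float  # M, at T0
    dH_assoc: float  # kcal/mol; positive ⇒ dimer favored at high temperature
    Ctot: float  # M, total protein (monomer equivalents)
    T0: float = T_REF

    def __post_init__(self):
        if self.k0 <= 0 or self.Kd0 <= 0 or self.Ctot <= 0:
            raise InvalidModelError("k0, Kd0 and Ctot must be positive")


def arrhenius_rate(T, k0: float, Ea: float, T0: float = T_REF):
    """k(T) = k0 · exp(−Ea/R · (1/T − 1/T0))."""
    T = np.asarray(T, dtype=float)
    return k0 * np.exp(-Ea / R_KCAL * (1.0 / T - 1.0 / T0))


def dimer_coupled_rate(T, law: DimerCoupledRateLaw):
    """k_obs(T) = f_M(T; Kd(T), Ctot) · k_intrinsic(T) with van't Hoff Kd(T)."""
    T = np.asarray(T, dtype=float)
    k_int = arrhenius_rate(T, law.k0, law.Ea_intrinsic, law.T0)
    # Ka = 1/Kd increases with T when dH_assoc > 0 (van't Hoff)
    Kd_T = law.Kd0 * np.exp(law.dH_assoc / R_KCAL * (1.0 / T - 1.0 / law.T0))
    f_M = monomer_fraction(np.full_like(T, law.Ctot), Kd_T)
    return f_M * k_int


def gen_zz_dataset(spec: SynthSpec, residue_label: str = "W43e", temperature: float = T_REF) -> ZZDataset:
    """Noisy two-site ZZ-exchange curves; truth = ZZParams.

    Intensities are the two-site model prediction plus i.i.d. Gaussian noise
    of sd `noise_sd` on each of the four curves.
    """
    times = np.asarray(spec.grid, dtype=float)
    if times.size < 4:
        raise InvalidModelError("need at least 4 mixing times")
    if np.any(times < 0):
        raise InvalidModelError("mixing times must be nonnegative")
    params: ZZParams = spec.truth
    params.validate()
    I_AA, I_BB, I_AB, I_BA = predict_zz(params, times)
    rng = spec.rng()
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=(4, times.size))
        I_AA = I_AA + noise[0]
        I_BB = I_BB + noise[1]
        I_AB = I_AB + noise[2]
        I_BA = I_BA + noise[3]
    sigma = np.full(times.size, spec.noise_sd) if spec.noise_sd > 0 else None
    return ZZDataset(
        residue_label=residue_label, temperature=temperature, mixing_times=times,
        I_AA=I_AA, I_BB=I_BB, I_AB=I_AB, I_BA=I_BA, sigma=sigma,
    )


def gen_rate_series(
    spec: SynthSpec, law: str, residue_label: str = "W43e", direction: str = "2→1"
) -> RateSeries:
    """Rate-vs-temperature series; noise is multiplicative lognormal.

    law = "arrhenius": truth = dict(k0, Ea[, T0]).
    law = "dimer_coupled": truth = DimerCoupledRateLaw.
    """
    T = np.asarray(spec.grid, dtype=float)
    if T.size < 3:
        raise InvalidModelError("need at least 3 temperatures")
    if np.any(T < 273.0) or np.any(T > 313.0):
        raise InvalidModelError("temperatures must lie in 273–313 K")
    if law == "arrhenius":
        tr = spec.truth
        k = arrhenius_rate(T, tr["k0"], tr["Ea"], tr.get("T0", T_REF))
    elif law == "dimer_coupled":
        k = dimer_coupled_rate(T, spec.truth)
    else:
        raise InvalidModelError(f"unknown rate law {law!r}")
    rng = spec.rng()
    if spec.noise_sd > 0:
        k = k * np.exp(rng.normal(0.0, spec.noise_sd, size=T.size))
    return RateSeries(residue_label=residue_label, direction=direction, temperatures=T, k=k)


def gen_titration(spec: SynthSpec, scale: float = 1.0) -> DimerTitration:
    """Monomer/dimer peak volumes across total concentrations; truth = Kd (M).

    Volumes are proportional to [M] and 2[D] at mass-action equilibrium,
    each multiplied by lognormal noise of log-sd `noise_sd`.
    """
    C = np.asarray(spec.grid, dtype=float)
    if C.size < 2:
        raise InvalidModelError("need at least 2 total concentrations")
    if np.any(C <= 0):
        raise InvalidModelError("concentrations must be positive")
    Kd = float(spec.truth)
    f = monomer_fraction(C, Kd)
    M = f * C
    D = (C - M) / 2.0
    V_M = scale * M
    V_D = scale * 2.0 * D
    rng = spec.rng()
    if spec.noise_sd > 0:
        V_M = V_M * np.exp(rng.normal(0.0, spec.noise_sd, size=C.size))
        V_D = V_D * np.exp(rng.normal(0.0, spec.noise_sd, size=C.size))
    return DimerTitration(concentrations=C, V_monomer=V_M, V_dimer=V_D)


def gen_denaturation(spec: SynthSpec, mode: str):
    """Two-state denaturation curve with linear baselines and Gaussian noise.

    mode = "chemical": grid in M; truth = dict(Cm, m[, b_f, s_f, b_u, s_u]);
    defaults put the response on the fraction-unfolded scale (0→1 baselines).
    mode = "thermal": grid in °C; truth = dict(Tm, dH_vH[, baselines]);
    defaults mimic a CD melt (folded −10 mdeg → unfolded −2 mdeg).
    """
    x = np.asarray(spec.grid, dtype=float)
    tr = dict(spec.truth)
    if mode == "chemical":
        mid = tr["Cm"]
        if not (x.min() <= mid <= x.max()):
            raise InvalidModelError("midpoint Cm outside grid range")
        y = chemical_two_state(
            x, tr["Cm"], tr["m"],
            tr.get("b_f", 0.0), tr.get("s_f", 0.0), tr.get("b_u", 1.0), tr.get("s_u", 0.0),
        )
        rng = spec.rng()
        if spec.noise_sd > 0:
            y = y + rng.normal(0.0, spec.noise_sd, size=x.size)
        return DenatCurve(denaturant=x, response=y)
    if mode == "thermal":
        mid = tr["Tm"]
        if not (x.min() <= mid <= x.max()):
            raise InvalidModelError("midpoint Tm outside grid range")
        y = thermal_two_state(
            x, tr["Tm"], tr.get("dH_vH", 50.0),
            tr.get("b_f", -10.0), tr.get("s_f", 0.0), tr.get("b_u", -2.0), tr.get("s_u", 0.0),
        )
        rng = spec.rng()
        if spec.noise_sd > 0:
            y = y + rng.normal(0.0, spec.noise_sd, size=x.size)
        return MeltCurve(temperatures=x, ellipticity=y)
    raise InvalidModelError(f"unknown denaturation mode {mode!r}")


# ---------------------------------------------------------------------------
# rotamer CTMC

#: combined rotamer state space: χ1 ∈ {g+, g−, t} × χ2 ∈ {−90, +90}
CTMC_STATES = tuple(
    (c1, c2) for c1 in ("g+", "g-", "t") for c2 in ("-90", "+90")
)
_STATE_CENTERS = np.array(
    [[CHI1_CENTERS[c1], CHI2_CENTERS[c2]] for (c1, c2) in CTMC_STATES]
)


def single_dihedral_rate_matrix(chi1_rate: float, chi2_rate: float) -> np.ndarray:
    """Build a 6×6 CTMC generator where jumps change one dihedral at a time.

    chi1_rate is the rate of each allowed χ1 bin change (g+↔g−↔t↔g+, all
    pairs connected), chi2_rate the rate of flipping χ2.
    """
    n = len(CTMC_STATES)
    Q = np.zeros((n, n))
    for i, (a1, a2) in enumerate(CTMC_STATES):
        for j, (b1, b2) in enumerate(CTMC_STATES):
            if i == j:
                continue
            if a2 == b2 and a1 != b1:
                Q[i, j] = chi1_rate
            elif a1 == b1 and a2 != b2:
                Q[i, j] = chi2_rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _validate_rate_matrix(Q: np.ndarray) -> np.ndarray:
    Q = np.asarray(Q, dtype=float)
    n = len(CTMC_STATES)
    if Q.shape != (n, n):
        raise InvalidModelError(f"rate matrix must be {n}×{n}")
    off = Q - np.diag(np.diag(Q))
    if np.any(off < 0):
        raise InvalidModelError("off-diagonal rates must be nonnegative")
    if np.any(np.abs(Q.sum(axis=1)) > 1e-10 * max(1.0, float(np.max(np.abs(Q))))):
        raise InvalidModelError("rate-matrix rows must sum to zero")
    return Q


def ctmc_stationary(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution π with πQ = 0, Σπ = 1."""
    ns = null_space(Q.T)
    if ns.shape[1] == 0:
        raise InvalidModelError("rate matrix has no stationary distribution")
    pi = np.abs(ns[:, 0])
    return pi / pi.sum()


@dataclass
class RotamerTrajSample:
    """A sampled rotamer trajectory plus its exact jump log (the oracle)."""

    series: DihedralSeries
    true_states: RotamerStateSeries  # discretized onto the frame grid
    jump_times: np.ndarray  # s (continuous-time log, includes t=0 entry)
    jump_states: np.ndarray  # state indices into CTMC_STATES
    dwell_times: np.ndarray  # completed dwells, aligned with jump_states[:-1]

    @property
    def true_transition_count(self) -> int:
        s = self.true_states.combined
        return int(np.count_nonzero(s[1:] != s[:-1]))


def gen_rotamer_traj(
    spec: SynthSpec, angular_noise_sd: float = 0.0, residue_label: str = "W43"
) -> RotamerTrajSample:
    """Continuous-time Markov rotamer trajectory sampled onto a frame grid.

    truth = 6×6 rate matrix over χ1 × χ2 (order `CTMC_STATES`); grid = frame
    times (ns, used as the CTMC's time axis).  Emitted angles are the state
    centers plus wrapped Gaussian noise of sd `angular_noise_sd` degrees.
    The exact jump log is returned for oracle tests.
    """
    Q = _validate_rate_matrix(spec.truth)
    frame_times = np.asarray(spec.grid, dtype=float)
    if frame_times.size < 1 or np.any(np.diff(frame_times) <= 0):
        raise InvalidModelError("frame times must be strictly increasing")
    if angular_noise_sd < 0:
        raise InvalidModelError("angular noise sd must be nonnegative")
    rng = spec.rng()
    t_end = float(frame_times[-1])

    pi = ctmc_stationary(Q)
    state = int(rng.choice(len(CTMC_STATES), p=pi))
    times = [0.0]
    states = [state]
    dwells = []
    t = 0.0
    while True:
        q = -Q[state, state]
        if q <= 0:
            break
        dt = rng.exponential(1.0 / q)
        if t + dt >= t_end:
            break
        t += dt
        dwells.append(dt)
        p = Q[state].copy()
        p[state] = 0.0
        p /= q
        state = int(rng.choice(len(CTMC_STATES), p=p))
        times.append(t)
        states.append(state)

    jump_times = np.asarray(times)
    jump_states = np.asarray(states, dtype=int)
    frame_state = jump_states[np.searchsorted(jump_times, frame_times, side="right") - 1]

    centers = _STATE_CENTERS[frame_state]
    chi1 = centers[:, 0].copy()
    chi2 = centers[:, 1].copy()
    if angular_noise_sd > 0:
        chi1 = wrap_angle(chi1 + rng.normal(0.0, angular_noise_sd, size=chi1.size))
        chi2 = wrap_angle(chi2 + rng.normal(0.0, angular_noise_sd, size=chi2.size))
    else:
        chi1 = wrap_angle(chi1)
        chi2 = wrap_angle(chi2)

    series = DihedralSeries(residue_label, chi1, chi2, frame_times)
    c1 = np.array([CTMC_STATES[s][0] for s in frame_state])
    c2 = np.array([CTMC_STATES[s][1] for s in frame_state])
    true_states = RotamerStateSeries(residue_label, c1, c2)
    return RotamerTrajSample(
        series=series, true_states=true_states,
        jump_times=jump_times, jump_states=jump_states,
        dwell_times=np.asarray(dwells),
    )


# ---------------------------------------------------------------------------
# backbone ensembles

def _ideal_backbone(n_residues: int) -> tuple[np.ndarray, list[str], np.ndarray, list[str]]:
    """Synthetic idealized backbone (N, CA, C, O per residue) along a
    gently zig-zagged chain; a stand-in mean structure, not a real protein."""
    coords = []
    names = []
    res_idx = []
    res_names = []
    offsets = {
        "N": np.array([-1.2, 0.8, 0.1]),
        "CA": np.array([0.0, 0.0, 0.0]),
        "C": np.array([1.2, 0.8, -0.1]),
        "O": np.array([1.4, 1.9, 0.3]),
    }
    for i in range(n_residues):
        ca = np.array([3.8 * i, 1.5 * ((-1) ** i), 0.3 * i])
        for name, off in offsets.items():
            coords.append(ca + off)
            names.append(name)
            res_idx.append(i + 1)
            res_names.append("ALA")
    return np.asarray(coords), names, np.asarray(res_idx), res_names


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1.0
    return Q


def gen_backbone_ensemble(
    spec: SynthSpec, rigid_body: bool = False, frame_interval: float = 1.0
) -> Trajectory:
    """Coordinate ensemble with a prescribed per-residue fluctuation profile.

    truth = per-residue displacement sd (Å per axis); grid = frame times
    (defines the number of frames).  Each frame adds one isotropic Gaussian
    displacement vector per residue (applied to all of that residue's
    backbone atoms) to the synthetic mean structure; with `rigid_body=True`
    the whole frame is additionally rotated and translated at random, which
    superposition-based analysis must undo.
    """
    sd = np.asarray(spec.truth, dtype=float)
    n_res = sd.size
    if n_res < 2:
        raise InvalidModelError("need at least 2 residues")
    if np.any(sd < 0):
        raise InvalidModelError("fluctuation sd must be nonnegative")
    n_frames = np.asarray(spec.grid).size
    if n_frames < 2:
        raise InvalidModelError("need at least 2 frames")
    mean, names, res_idx, res_names = _ideal_backbone(n_res)
    if np.allclose(mean, mean[0]):
        raise InvalidModelError("degenerate mean structure")
    rng = spec.rng()
    # draw all internal displacements first so the internal motion is
    # identical with and without the optional rigid-body overlay
    disp = rng.normal(0.0, 1.0, size=(n_frames, n_res, 3)) * sd[None, :, None]
    frames = np.empty((n_frames, mean.shape[0], 3))
    for f in range(n_frames):
        frame = mean + disp[f, res_idx - 1]
        if rigid_body:
            R = _random_rotation(rng)
            t = rng.normal(0.0, 20.0, size=3)
            frame = frame @ R.T + t
        frames[f] = frame
    return Trajectory(
        coords=frames, atom_names=names, residue_indices=res_idx,
        residue_names=res_names, frame_interval=frame_interval,
    )
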