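"""Two-site ZZ-exchange kinetics: peak quantification and rate fitting.

A ZZ-exchange experiment reports on slow (ms–s) interconversion between two
conformational states.  During the mixing time, longitudinal magnetization
prepared on one state either stays put (auto peaks AA, BB) or is carried to
the other state by exchange (cross peaks AB, BA).  The four intensity curves
follow the two-site first-order kinetic system

    dM/dt = -K M,   K = [[R1_1 + k_12, -k_21],
                         [-k_12,       R1_2 + k_21]]

where k_12/k_21 are the forward/reverse exchange rate constants and R1_1/R1_2
the longitudinal relaxation rates of the two states.  Auto and cross curves
are the matrix exponential of -K applied to the initial conditions
(I0_1, 0) and (0, I0_2).

`predict_zz` evaluates the eigenvalue closed form of this 2×2 exponential;
`fit_zz` fits all six parameters jointly to the four curves by nonlinear
least squares; `quantify_peaks` reproduces the volume-extraction step
(sum-of-2-D-Gaussians plus a flat baseline fitted to a spectral cluster).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm
from scipy.optimize import least_squares

from .exceptions import ConvergenceError, InsufficientDataError, InvalidModelError, NoPeakError

__all__ = [
    "ZZParams",
    "ZZDataset",
    "ZZFitResult",
    "PeakCluster",
    "predict_zz",
    "fit_zz",
    "quantify_peaks",
]


@dataclass
class ZZParams:
    """Parameters of the two-site longitudinal exchange model.

    k_12 : major→minor exchange rate (s⁻¹)
    k_21 : minor→major exchange rate (s⁻¹)
    R1_1, R1_2 : longitudinal relaxation rates of each state (s⁻¹)
    I0_1, I0_2 : initial auto-peak intensities (arbitrary units)
    """

    k_12: float
    k_21: float
    R1_1: float
    R1_2: float
    I0_1: float
    I0_2: float

    def validate(self) -> None:
        if self.k_12 < 0 or self.k_21 < 0:
            raise InvalidModelError("exchange rates must be nonnegative")
        if self.R1_1 <= 0 or self.R1_2 <= 0:
            raise InvalidModelError("relaxation rates must be positive")
        if self.I0_1 <= 0 or self.I0_2 <= 0:
            raise InvalidModelError("initial intensities must be positive")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.k_12, self.k_21, self.R1_1, self.R1_2, self.I0_1, self.I0_2]
        )

    @classmethod
    def from_array(cls, a) -> "ZZParams":
        return cls(*(float(x) for x in a))


@dataclass
class ZZDataset:
    """Mixing-time-resolved intensities of the four exchange peak classes.

    AA = major-state auto peak, BB = minor-state auto peak,
    AB = major→minor cross peak, BA = minor→major cross peak.
    """

    residue_label: str
    temperature: float  # K
    mixing_times: np.ndarray  # s
    I_AA: np.ndarray
    I_BB: np.ndarray
    I_AB: np.ndarray
    I_BA: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.mixing_times = np.asarray(self.mixing_times, dtype=float)
        for name in ("I_AA", "I_BB", "I_AB", "I_BA"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.mixing_times.shape:
                raise InvalidModelError(f"{name} not aligned with mixing_times")
            setattr(self, name, arr)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.mixing_times < 0):
            raise InvalidModelError("mixing times must be nonnegative")
        if np.any(np.diff(self.mixing_times) <= 0):
            raise InvalidModelError("mixing times must be strictly increasing")


@dataclass
class ZZFitResult:
    params: ZZParams
    stderr: dict[str, float] | None
    rss: float
    converged: bool
    n_points: int


def _rate_matrix(p: ZZParams) -> np.ndarray:
    return np.array(
        [[p.R1_1 + p.k_12, -p.k_21], [-p.k_12, p.R1_2 + p.k_21]]
    )


def predict_zz(params: ZZParams, times) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Predict (I_AA, I_BB, I_AB, I_BA) at the given mixing times.

    Uses the eigenvalue closed form
    λ± = ½[(a₁₁+a₂₂) ± √((a₁₁−a₂₂)² + 4·k_12·k_21)]
    and spectral projectors of the 2×2 rate matrix; falls back to a numerical
    matrix exponential when the eigenvalues are (near-)degenerate.
    """
    params.validate()
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise InvalidModelError("mixing times must be nonnegative")

    K = _rate_matrix(params)
    a11, a22 = K[0, 0], K[1, 1]
    disc = np.sqrt((a11 - a22) ** 2 + 4.0 * params.k_12 * params.k_21)
    tr = a11 + a22

    if disc <= 1e-12 * max(1.0, abs(tr)):
        # degenerate eigenvalues: closed form is ill-conditioned
        E = np.stack([expm(-K * ti) for ti in np.atleast_1d(t)], axis=0)
        E11, E12 = E[..., 0, 0], E[..., 0, 1]
        E21, E22 = E[..., 1, 0], E[..., 1, 1]
        if t.ndim == 0:
            E11, E12, E21, E22 = (x[0] for x in (E11, E12, E21, E22))
    else:
        lam1 = 0.5 * (tr + disc)
        lam2 = 0.5 * (tr - disc)
        # expm(-K t) = e^{-λ1 t} P1 + e^{-λ2 t} P2
        P1 = (K - lam2 * np.eye(2)) / disc
        P2 = (lam1 * np.eye(2) - K) / disc
        e1 = np.exp(-lam1 * t)
        e2 = np.exp(-lam2 * t)
        E11 = e1 * P1[0, 0] + e2 * P2[0, 0]
        E12 = e1 * P1[0, 1] + e2 * P2[0, 1]
        E21 = e1 * P1[1, 0] + e2 * P2[1, 0]
        E22 = e1 * P1[1, 1] + e2 * P2[1, 1]

    I_AA = params.I0_1 * E11
    I_AB = params.I0_1 * E21
    I_BB = params.I0_2 * E22
    I_BA = params.I0_2 * E12
    return I_AA, I_BB, I_AB, I_BA


_PARAM_NAMES = ("k_12", "k_21", "R1_1", "R1_2", "I0_1", "I0_2")

# deterministic multi-start grid: both rates over three decades, both
# relaxation rates tied to one grid value, intensities from the data
_K_GRID = (0.1, 1.0, 10.0)
_R1_GRID = (0.5, 2.0)


def fit_zz(dataset: ZZDataset, init: ZZParams | None = None, weighted: bool = False) -> ZZFitResult:
    """Jointly fit the four ZZ-exchange curves by nonlinear least squares.

    All six parameters are fitted on a log scale (positivity without bound
    constraints).  Without `init` a deterministic multi-start over a coarse
    grid is run and the best residual sum of squares wins (ties by first).
    With `weighted=True` and per-point sigma present, residuals are divided
    by sigma.
    """
    t = dataset.mixing_times
    if len(np.unique(t)) < 6:
        raise InsufficientDataError("need at least 6 distinct mixing times for 6 parameters")
    obs = np.stack([dataset.I_AA, dataset.I_BB, dataset.I_AB, dataset.I_BA])
    if not np.any(obs != 0):
        raise InvalidModelError("all-zero intensity data")
    if weighted and dataset.sigma is not None:
        w = 1.0 / np.asarray(dataset.sigma, dtype=float)
    else:
        w = np.ones_like(t)

    def residuals(theta):
        p = ZZParams.from_array(np.exp(theta))
        pred = np.stack(predict_zz(p, t))
        return ((pred - obs) * w).ravel()

    def run(theta0):
        return least_squares(
            residuals, theta0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15,
            max_nfev=2000,
        )

    starts = []
    if init is not None:
        init.validate()
        starts.append(np.log(init.as_array()))
    else:
        i0_1 = max(float(np.max(dataset.I_AA)), 1e-6)
        i0_2 = max(float(np.max(dataset.I_BB)), 1e-6)
        for k12 in _K_GRID:
            for k21 in _K_GRID:
                for r1 in _R1_GRID:
                    starts.append(
                        np.log([k12, k21, r1, r1, i0_1, i0_2])
                    )

    best = None
    for theta0 in starts:
        try:
            sol = run(theta0)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0] - 1e-15 * max(1.0, best[0]):
            best = (rss, sol)
    if best is None:
        raise ConvergenceError("ZZ fit failed from every start")
    rss, sol = best

    params = ZZParams.from_array(np.exp(sol.x))
    converged = bool(sol.success)
    stderr = None
    if converged:
        n, p = obs.size, 6
        dof = max(n - p, 1)
        try:
            JtJ = sol.jac.T @ sol.jac
            cov_log = np.linalg.inv(JtJ) * rss / dof
            se_log = np.sqrt(np.clip(np.diag(cov_log), 0, np.inf))
            # delta method: θ is log-scale, se(param) = param · se(log param)
            se = np.exp(sol.x) * se_log
            stderr = dict(zip(_PARAM_NAMES, (float(s) for s in se)))
        except np.linalg.LinAlgError:
            stderr = None
            converged = False
    return ZZFitResult(params=params, stderr=stderr, rss=rss, converged=converged, n_points=obs.size)


@dataclass
class PeakCluster:
    """A rectangular spectral sub-region holding one cluster of peaks.

    grid[i, j] is the intensity at (x_axis[j], y_axis[i]); axes are in ppm.
    After `quantify_peaks`, `fitted` holds one
    (center_x, center_y, sd_x, sd_y, amplitude, volume) tuple per seed,
    with volume = 2π·amplitude·sd_x·sd_y.
    """

    x_axis: np.ndarray
    y_axis: np.ndarray
    grid: np.ndarray
    peak_seeds: list[tuple[float, float]]
    fitted: list[tuple[float, float, float, float, float, float]] = field(default_factory=list)
    baseline: float = 0.0
    converged: bool = True

    def __post_init__(self):
        self.x_axis = np.asarray(self.x_axis, dtype=float)
        self.y_axis = np.asarray(self.y_axis, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != (len(self.y_axis), len(self.x_axis)):
            raise InvalidModelError("grid shape must be (len(y_axis), len(x_axis))")

    @property
    def volumes(self) -> list[float]:
        return [f[5] for f in self.fitted]


def quantify_peaks(cluster: PeakCluster) -> PeakCluster:
    """Fit a sum of 2-D Gaussians plus a flat baseline to the cluster.

    Each seed contributes one elliptical (axis-aligned) Gaussian; the peak
    volume is the analytic integral 2π·A·σx·σy.  Raises NoPeakError when a
    seed sits on no signal above the baseline.
    """
    if not np.all(np.isfinite(cluster.grid)):
        raise InvalidModelError("grid contains non-finite values")
    if len(cluster.peak_seeds) < 1:
        raise InvalidModelError("need at least one peak seed")
    x, y, Z = cluster.x_axis, cluster.y_axis, cluster.grid
    X, Y = np.meshgrid(x, y)
    baseline0 = float(np.median(Z))

    dx = float(np.median(np.abs(np.diff(np.sort(x))))) if len(x) > 1 else 1.0
    dy = float(np.median(np.abs(np.diff(np.sort(y))))) if len(y) > 1 else 1.0

    seeds = []
    for (sx, sy) in cluster.peak_seeds:
        if not (min(x) <= sx <= max(x) and min(y) <= sy <= max(y)):
            raise InvalidModelError(f"seed ({sx}, {sy}) outside grid")
        j = int(np.argmin(np.abs(x - sx)))
        i = int(np.argmin(np.abs(y - sy)))
        # local maximum over a 3x3 neighbourhood around the seed
        local = Z[max(i - 1, 0): i + 2, max(j - 1, 0): j + 2]
        amp0 = float(np.max(local)) - baseline0
        if amp0 <= 0:
            raise NoPeakError(f"no peak detected at seed ({sx}, {sy})")
        seeds.append((sx, sy, amp0))

    # parameter vector: [baseline, (cx, cy, log sx, log sy, A) per peak]
    theta0 = [baseline0]
    for (sx, sy, amp0) in seeds:
        theta0 += [sx, sy, np.log(2 * dx), np.log(2 * dy), amp0]
    theta0 = np.array(theta0)

    def model(theta):
        out = np.full_like(Z, theta[0])
        for p in range(len(seeds)):
            cx, cy, lsx, lsy, A = theta[1 + 5 * p: 6 + 5 * p]
            sx_, sy_ = np.exp(lsx), np.exp(lsy)
            out = out + A * np.exp(
                -((X - cx) ** 2) / (2 * sx_**2) - ((Y - cy) ** 2) / (2 * sy_**2)
            )
        return out

    sol = least_squares(
        lambda th: (model(th) - Z).ravel(), theta0,
        method="lm", xtol=1e-14, ftol=1e-14, max_nfev=5000,
    )
    fitted = []
    for p in range(len(seeds)):
        cx, cy, lsx, lsy, A = sol.x[1 + 5 * p: 6 + 5 * p]
        sx_, sy_ = float(np.exp(lsx)), float(np.exp(lsy))
        vol = 2.0 * np.pi * float(A) * sx_ * sy_
        fitted.append((float(cx), float(cy), sx_, sy_, float(A), vol))
    return replace(
        cluster, fitted=fitted, baseline=float(sol.x[0]), converged=bool(sol.success)
    )
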