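"""Side-chain rotamer statistics and backbone fluctuations from MD ensembles.

χ1/χ2 dihedrals extracted from trajectory frames are binned into discrete
rotamer states (χ1: g+, g−, t with bins centered at +60°, −60°, 180°;
χ2: −90°/+90°), conformational transitions are counted as combined-state
label changes (with an optional minimum-dwell debounce against angular
chatter), coupling between two residues' transitions is assessed by a
circular-shift permutation test, and backbone RMSF is computed after
least-squares superposition of every frame onto the iterated mean structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidModelError

__all__ = [
    "Trajectory",
    "DihedralSeries",
    "RotamerStateSeries",
    "TransitionCounts",
    "ConcertedResult",
    "RMSFProfile",
    "CHI1_CENTERS",
    "CHI2_CENTERS",
    "compute_dihedral",
    "wrap_angle",
    "assign_rotamer_states",
    "count_label_changes",
    "count_transitions",
    "detect_concerted",
    "extract_dihedrals",
    "compute_rmsf",
    "kabsch",
    "BACKBONE_ATOMS",
    "CHI_ATOM_TABLE",
]

#: χ1 rotamer bin centers (deg); naming convention: g+ ↔ +60°, g− ↔ −60°, t ↔ 180°
CHI1_CENTERS = {"g+": 60.0, "g-": -60.0, "t": 180.0}
#: χ2 bin centers (deg)
CHI2_CENTERS = {"+90": 90.0, "-90": -90.0}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: default atom names defining χ1 (N–CA–CB–γ) and χ2 (CA–CB–γ–δ) per residue type
CHI_ATOM_TABLE = {
    "TRP": {"chi1": ("N", "CA", "CB", "CG"), "chi2": ("CA", "CB", "CG", "CD1")},
    "PHE": {"chi1": ("N", "CA", "CB", "CG"), "chi2": ("CA", "CB", "CG", "CD1")},
    "TYR": {"chi1": ("N", "CA", "CB", "CG"), "chi2": ("CA", "CB", "CG", "CD1")},
    "LEU": {"chi1": ("N", "CA", "CB", "CG"), "chi2": ("CA", "CB", "CG", "CD1")},
    "ILE": {"chi1": ("N", "CA", "CB", "CG1"), "chi2": ("CA", "CB", "CG1", "CD1")},
    "VAL": {"chi1": ("N", "CA", "CB", "CG1")},
    "THR": {"chi1": ("N", "CA", "CB", "OG1")},
    "SER": {"chi1": ("N", "CA", "CB", "OG")},
    "CYS": {"chi1": ("N", "CA", "CB", "SG")},
    "MET": {"chi1": ("N", "CA", "CB", "CG"), "chi2": ("CA", "CB", "CG", "SD")},
}


@dataclass
class Trajectory:
    """A coordinate ensemble: frames × atoms × 3 (Å), with atom metadata."""

    coords: np.ndarray  # (n_frames, n_atoms, 3)
    atom_names: list[str]
    residue_indices: np.ndarray  # per atom
    residue_names: list[str]  # per atom
    frame_interval: float = 1.0  # ns

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InvalidModelError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[0] < 2:
            raise InvalidModelError("need at least 2 frames")
        n = self.coords.shape[1]
        if not (len(self.atom_names) == len(self.residue_indices) == len(self.residue_names) == n):
            raise InvalidModelError("atom metadata not aligned with coordinates")


@dataclass
class DihedralSeries:
    """Per-frame χ1/χ2 angles (deg, wrapped to [−180, 180)) for one residue."""

    residue_label: str
    chi1: np.ndarray
    chi2: np.ndarray
    times: np.ndarray  # ns

    def __post_init__(self):
        self.chi1 = np.asarray(self.chi1, dtype=float)
        self.chi2 = np.asarray(self.chi2, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if not (self.chi1.shape == self.chi2.shape == self.times.shape):
            raise InvalidModelError("chi1/chi2/times must be aligned")


@dataclass
class RotamerStateSeries:
    """Per-frame discrete rotamer labels for one residue."""

    residue_label: str
    chi1_states: np.ndarray  # of {"g+", "g-", "t"}
    chi2_states: np.ndarray  # of {"-90", "+90"}

    def __post_init__(self):
        self.chi1_states = np.asarray(self.chi1_states)
        self.chi2_states = np.asarray(self.chi2_states)
        if self.chi1_states.shape != self.chi2_states.shape:
            raise InvalidModelError("chi1/chi2 state arrays must be aligned")

    @property
    def combined(self) -> np.ndarray:
        return np.char.add(np.char.add(self.chi1_states.astype(str), "/"), self.chi2_states.astype(str))

    def __len__(self):
        return len(self.chi1_states)


@dataclass
class TransitionCounts:
    combined: int  # χ1×χ2 combined-state changes
    chi1_only: int  # changes of the χ1 label alone
    min_dwell: int


@dataclass
class ConcertedResult:
    co_transition_count: int
    window: int
    p_value: float
    n_permutations: int


@dataclass
class RMSFProfile:
    residue_indices: np.ndarray
    rmsf: np.ndarray  # Å, per residue
    selection: tuple = BACKBONE_ATOMS
    burn_in_fraction: float = 1.0 / 3.0


def wrap_angle(deg):
    """Wrap angle(s) in degrees to [−180, 180)."""
    return np.mod(np.asarray(deg, dtype=float) + 180.0, 360.0) - 180.0


def compute_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral (deg in [−180, 180)) defined by four points.

    Standard convention: cis = 0°, trans = ±180° (wrapped to −180°).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.linalg.norm(b1) < 1e-12 or np.linalg.norm(b2) < 1e-12 or np.linalg.norm(b3) < 1e-12:
        raise InvalidModelError("coincident consecutive points")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise InvalidModelError("collinear consecutive points")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return float(wrap_angle(np.degrees(np.arctan2(y, x))))


def assign_rotamer_states(series: DihedralSeries) -> RotamerStateSeries:
    """Bin χ1 into {g+, g−, t} and χ2 into {−90, +90}.

    Half-open bins: χ1 ∈ [0°, 120°) → g+, [−120°, 0°) → g−, else t;
    χ2 ∈ [0°, 180°) → +90, else −90.  Equivalent to nearest-center away from
    the boundaries; input angles are wrapped first, so adding multiples of
    360° never changes the assignment.
    """
    if len(series.chi1) == 0:
        raise InvalidModelError("empty dihedral series")
    c1 = wrap_angle(series.chi1)
    c2 = wrap_angle(series.chi2)
    s1 = np.where(
        (c1 >= 0.0) & (c1 < 120.0), "g+", np.where((c1 >= -120.0) & (c1 < 0.0), "g-", "t")
    )
    s2 = np.where((c2 >= 0.0), "+90", "-90")
    return RotamerStateSeries(series.residue_label, s1, s2)


def count_label_changes(labels, min_dwell: int = 1) -> int:
    """Count label changes where the new label persists ≥ min_dwell frames.

    With min_dwell = 1 this is the raw change count.  A change is accepted
    (and becomes the new reference state) only when its run length reaches
    min_dwell; shorter excursions are ignored.
    """
    if min_dwell < 1:
        raise InvalidModelError("min_dwell must be >= 1")
    labels = np.asarray(labels)
    if len(labels) == 0:
        return 0
    # run-length encode
    change = np.nonzero(labels[1:] != labels[:-1])[0] + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [len(labels)])))
    run_states = labels[starts]
    current = run_states[0]
    count = 0
    for state, length in zip(run_states[1:], lengths[1:]):
        if state != current and length >= min_dwell:
            count += 1
            current = state
    return count


def count_transitions(states: RotamerStateSeries, min_dwell: int = 1) -> TransitionCounts:
    """Count rotamer transitions in the combined χ1×χ2 state and in χ1 alone."""
    return TransitionCounts(
        combined=count_label_changes(states.combined, min_dwell),
        chi1_only=count_label_changes(states.chi1_states, min_dwell),
        min_dwell=min_dwell,
    )


def _transition_indicator(states: RotamerStateSeries) -> np.ndarray:
    comb = states.combined
    return (comb[1:] != comb[:-1]).astype(np.int8)


def detect_concerted(
    states_a: RotamerStateSeries,
    states_b: RotamerStateSeries,
    window: int = 1,
    n_permutations: int = 199,
    seed: int = 0,
) -> ConcertedResult:
    """Permutation test for synchrony of transitions between two residues.

    The statistic is the number of B transitions falling within ± `window`
    frames of any A transition.  The null preserves each series' transition
    count and spacing by circularly shifting B's transition indicator by a
    uniformly random offset; p = (1 + #{null ≥ observed})/(1 + n_permutations).
    """
    if len(states_a) != len(states_b):
        raise InvalidModelError("state series must have equal length")
    if window < 0:
        raise InvalidModelError("window must be nonnegative")
    ta = _transition_indicator(states_a)
    tb = _transition_indicator(states_b)
    if ta.sum() == 0 or tb.sum() == 0:
        return ConcertedResult(0, window, 1.0, n_permutations)
    L = len(ta)
    # dilate A's indicator by the window
    mask = np.zeros(L, dtype=bool)
    idx = np.nonzero(ta)[0]
    for off in range(-window, window + 1):
        j = idx + off
        j = j[(j >= 0) & (j < L)]
        mask[j] = True
    obs = int(np.sum(tb[mask]))
    rng = np.random.default_rng(seed)
    shifts = rng.integers(1, L, size=n_permutations)
    tb_idx = np.nonzero(tb)[0]
    n_ge = 0
    for s in shifts:
        shifted = (tb_idx + s) % L
        if int(np.count_nonzero(mask[shifted])) >= obs:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_permutations)
    return ConcertedResult(obs, window, p, n_permutations)


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimizing |R·P + t − Q|²."""
    Pc = P.mean(axis=0)
    Qc = Q.mean(axis=0)
    H = (P - Pc).T @ (Q - Qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Qc - R @ Pc
    return R, t


def compute_rmsf(
    traj: Trajectory,
    selection=BACKBONE_ATOMS,
    burn_in_fraction: float = 1.0 / 3.0,
    max_passes: int = 20,
    tol: float = 1e-10,
) -> RMSFProfile:
    """Per-residue RMSF after superposition onto the iterated mean structure.

    The initial `burn_in_fraction` of frames is discarded, every remaining
    frame is least-squares superposed (Kabsch) onto the running mean
    structure of the selected atoms, and the mean is recomputed and the
    superposition repeated until the mean stops moving (at most
    `max_passes` iterations, at least 2).  Then

        RMSF_i = √⟨|r_i − ⟨r_i⟩|²⟩

    is averaged over each residue's selected atoms.
    """
    sel = np.array([name in set(selection) for name in traj.atom_names])
    if not np.any(sel):
        raise InvalidModelError("empty atom selection")
    n_frames = traj.coords.shape[0]
    start = int(np.floor(burn_in_fraction * n_frames))
    X = traj.coords[start:, sel, :].copy()
    if X.shape[0] < 2:
        raise InvalidModelError("fewer than 2 frames after burn-in")

    prev = None
    for it in range(max_passes):
        ref = X.mean(axis=0)
        if prev is not None and it >= 2 and np.max(np.abs(ref - prev)) < tol:
            break
        prev = ref
        for f in range(X.shape[0]):
            R, t = kabsch(X[f], ref)
            X[f] = X[f] @ R.T + t

    mean = X.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=0))

    res_idx = traj.residue_indices[sel]
    residues = np.unique(res_idx)
    rmsf = np.array([per_atom[res_idx == r].mean() for r in residues])
    return RMSFProfile(
        residue_indices=residues,
        rmsf=rmsf,
        selection=tuple(selection),
        burn_in_fraction=burn_in_fraction,
    )


def extract_dihedrals(traj: Trajectory, residue_index: int, atom_table=None) -> DihedralSeries:
    """Compute a residue's χ1/χ2 series from trajectory coordinates.

    Residues with no χ2 definition (e.g. Val, Thr) get χ2 = 0 for all frames.
    """
    table = CHI_ATOM_TABLE if atom_table is None else atom_table
    in_res = traj.residue_indices == residue_index
    if not np.any(in_res):
        raise InvalidModelError(f"residue index {residue_index} not in trajectory")
    resname = [n for n, m in zip(traj.residue_names, in_res) if m][0]
    if resname not in table:
        raise InvalidModelError(f"no chi-atom definition for residue type {resname}")

    def atom_pos(name):
        hits = np.nonzero(in_res & (np.asarray(traj.atom_names) == name))[0]
        if len(hits) == 0:
            raise InvalidModelError(f"atom {name} missing in residue {residue_index}")
        return traj.coords[:, hits[0], :]

    defs = table[resname]
    chi1_pts = [atom_pos(a) for a in defs["chi1"]]
    n_frames = traj.coords.shape[0]
    chi1 = np.array([compute_dihedral(*(p[f] for p in chi1_pts)) for f in range(n_frames)])
    if "chi2" in defs:
        chi2_pts = [atom_pos(a) for a in defs["chi2"]]
        chi2 = np.array([compute_dihedral(*(p[f] for p in chi2_pts)) for f in range(n_frames)])
    else:
        chi2 = np.zeros(n_frames)
    times = np.arange(n_frames) * traj.frame_interval
    return DihedralSeries(f"{resname}{residue_index}", chi1, chi2, times)
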