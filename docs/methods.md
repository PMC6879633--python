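# Methods

This note records the models implemented in `confex`, the assumptions they
make, the defaults and why they were chosen, what the synthetic-data layer
does and does not emulate, and the numerical choices that matter.

## Two-site ZZ-exchange kinetics

During the mixing time of a ZZ-exchange experiment, longitudinal
magnetization prepared on one conformational state relaxes (R₁) and
exchanges (k) with the other state.  For two states the four observable
curves (two auto peaks, two cross peaks) follow the linear system
dM/dt = −K·M with

    K = [[R1_1 + k_12, −k_21],
         [−k_12,       R1_2 + k_21]].

`predict_zz` evaluates exp(−K t) through the 2×2 eigenvalue closed form
(spectral projectors); when the eigenvalue gap is below 1e−12 relative to
the trace, it falls back to `scipy.linalg.expm`, so the degenerate case is
exact rather than ill-conditioned.  The closed form is tested against the
matrix-exponential oracle on 1000 random parameter draws at relative 1e−8.

Two structural identities follow from the model and are asserted as
properties: both cross peaks share one scalar kernel
(I_AB/(I0_1·k_12) = I_BA/(I0_2·k_21)), and in the equal-relaxation limit
I_AA + I_AB = I0_1·e^(−R1·t) exactly (magnetization is conserved apart from
uniform relaxation).

`fit_zz` fits all six parameters (k_12, k_21, R1_1, R1_2, I0_1, I0_2)
jointly to the four curves.  Choices:

- **Joint fit**, not per-curve: each individual curve is a sum of two
  exponentials and is badly under-determined on 8 mixing times; the joint
  system shares its eigenvalues across curves.
- **Log-parameterization** of all six parameters enforces positivity
  without active bound constraints, which keeps Levenberg–Marquardt away
  from boundary-stuck fits.  In the no-exchange limit the rates run to
  ~1e−10 s⁻¹ and the optimizer reports non-convergence (the gradient never
  vanishes on an open ray); this is flagged, never silent.
- **Initialization**: with no user initialization, a deterministic
  multi-start runs over k_12, k_21 ∈ {0.1, 1, 10} s⁻¹ with both relaxation
  rates tied to R1 ∈ {0.5, 2} s⁻¹ (18 starts, fixed order) and intensities
  seeded from the observed curve maxima; best residual sum of squares wins,
  ties resolved by start order.
- **Weighting** by per-point σ is available but off by default; whether the
  original experiments weighted their fits is not knowable from the data
  formats, so unweighted is the neutral default.
- Fitting requires ≥ 6 distinct mixing times (6 free parameters).

Peak quantification (`quantify_peaks`) fits a sum of axis-aligned 2-D
Gaussians plus one flat baseline per cluster; the volume of each peak is
the analytic integral 2π·A·σx·σy.  A flat (not planar) baseline is the
smallest model that makes cluster-local volumes well defined.  A seed whose
3×3 neighborhood never rises above the cluster median raises a
"no peak detected" error before any fitting happens.

## Arrhenius and Eyring analysis

Both fits are linear least squares in 1/T: ln k for Arrhenius
(Eₐ = −slope·R, R = 1.987×10⁻³ kcal/(mol·K)) and ln(k/T) for Eyring
(ΔH‡ = −slope·R; ΔS‡ = R·(intercept − ln(k_B/h)), reported in cal/(mol·K);
transmission coefficient fixed at 1).  Temperatures are stored in kelvin;
file readers convert °C on input.  Optional weights are 1/δ(ln k)² with
δ(ln k) = k_stderr/k.  For a temperature-invariant series the slope is
identically zero and Eₐ = 0 exactly; r² is defined as 1 in that case (the
flat line is a perfect fit), keeping r² ∈ [0, 1] total.

Classification: exchange is "Arrhenius" iff the apparent activation energy
is strictly positive in both transition directions, so a zero-slope series
classifies non-Arrhenius (no thermally activated barrier crossing is
resolved).  A negative apparent Eₐ is treated purely as a diagnostic of a
composed process — here, exchange that only the monomer can undergo while
heating shifts the population into the dimer — not as a thermodynamic
quantity; no mechanistic fit of the composed law is attempted on real
data.  When a dimer-interface reporter residue is provided, the probe is
called reporter-consistent when |Eₐ(probe) − Eₐ(reporter)| ≤ 2·√(se² + se²)
in both directions.  The factor 2 is this package's operational reading of
"the same within error"; it is configurable in no way other than editing
the call because a study should pick one criterion and keep it.

The textbook identity Eₐ = ΔH‡ + R·T̄ is asserted to 2% on synthetic series
spanning ≤ 30 K.

## Monomer–dimer equilibrium

Convention: Kd = [M]²/[D], concentrations in monomer equivalents.  Mass
action at total concentration C gives [M] = (−Kd + √(Kd² + 8·Kd·C))/4;
monomer fraction f = [M]/C.  Each dimer carries two copies of the reporter
residue, so the dimer peak volume is modeled as proportional to 2[D] and
the observed monomer fraction is simply V_M/(V_M + V_D); a per-state
response factor is exposed (default 1) for nuclei whose minor-state volume
responds differently.  The fit runs over log₁₀ Kd within [1e−9, 1e−1] M
(positivity and scale invariance), seeded by a coarse 0.25-decade scan.
When the observed fractions never leave the flat extremes (all > 0.98 or
all < 0.02) the titration carries no information about Kd and the fit is
declared unidentifiable rather than returning a boundary value.  No
correction for exchange broadening of peak volumes is applied.

## Chemical-shift displacement

Δδ = √(Δδ_HN² + (Δδ_N/5)²) in ppm; the ¹⁵N scaling factor 5 is the
standard amide weighting and is fixed.  The same formula is applied to the
tryptophan indole Hε1/Nε1 pair as to backbone amides.  The default
classification threshold is 0.6 ppm — the midpoint of the gap between the
dimer-type displacements (≈0.32–0.34 ppm) and the conformational-exchange
displacements (≈0.94–1.32 ppm) seen in this family of Gβ1 variants — and
is configurable because it is an empirical separator, not a constant of
nature.  Variants with no minor-state peaks are classified "no exchange"
before any Δδ is computed.

## Two-state stability fits

Both denaturation fits use one sigmoid between two linear baselines,

    signal(x) = (b_f + s_f·x)·(1 − p_U) + (b_u + s_u·x)·p_U.

Chemical mode (linear extrapolation model): p_U(D) = 1/(1 + exp(m·(Cm −
D)/(R·T))) with T fixed at 298.15 K; ΔG_U = m·Cm.  Thermal mode: the van't
Hoff form p_U(T) = 1/(1 + exp(ΔH_vH/R·(1/T − 1/Tm))); the slope parameter
ΔH_vH is fitted but not reported as an enthalpy (melts of small proteins
rarely justify it).  Degenerate-input handling: a flat response, a fitted
midpoint outside the data range, a negative m-value, or coincident fitted
baselines (gap at the midpoint below 10⁻³ of the data span) all raise a
"no transition" error instead of returning a meaningless midpoint.
Baseline initialization comes from the first/last sixth of the points; the
midpoint initialization is the datum closest to halfway between the end
levels.  Fluorescence spectra are reduced to fraction unfolded by
integrating each spectrum and normalizing between linear baselines fitted
to the lowest/highest two denaturant points; values slightly outside [0, 1]
are kept (clamping would bias the subsequent fit).

ΔΔG = ΔG_U(reference) − ΔG_U(variant), so destabilized variants score
positive.

## MD rotamer and fluctuation analysis

Dihedrals use the standard atan2 construction (cis = 0°, trans = ±180°,
wrapped to [−180, 180)); the implementation is checked against an
independent projection-based construction on random geometries, under
rigid motion (invariant) and mirror reflection (sign flip).

Rotamer bins are half-open: χ1 ∈ [0°, 120°) → g+, [−120°, 0°) → g−, else
t; χ2 ∈ [0°, 180°) → +90, else −90.  This is deterministic and tie-free
and equals nearest-center assignment away from the boundaries.  The χ1
naming convention used throughout (g+ ↔ +60°, g− ↔ −60°, t ↔ 180°) is a
recorded package convention; rotamer nomenclature is not uniform across
literatures.

Transition counting reports both the combined χ1×χ2 state changes and the
χ1-only changes (it is ambiguous whether "χ1 and χ2 changes between bins"
means the product state or either dihedral, so both are available).  The
minimum-dwell filter accepts a state change only when the new state
persists ≥ min_dwell frames; min_dwell defaults to 1 (raw counting).  The
filter exists because angular noise near a bin boundary manufactures
spurious back-and-forth counts: at 40° angular noise raw counting
overcounts several-fold, while a 5-frame dwell recovers the true jump
count within ~15% provided true dwells are long against the filter (the
tests use mean dwells of ~65 frames).  Counting is monotone non-increasing
in min_dwell by construction.

Concerted motion between two residues is scored by the number of B
transitions within ± window frames of any A transition; the null
distribution circularly shifts B's transition indicator by a uniform
random offset, preserving both series' transition counts and internal
clustering, with p = (1 + #{null ≥ obs})/(1 + n_permutations).  This
permutation procedure is this package's own test construction (reported as
such): it is calibrated — on independent chains the false-positive rate at
p < 0.05 sits near 0.045 over 200 simulations — and conservative for small
permutation counts.  The default 199 permutations makes attainable p
values multiples of 1/200.

RMSF discards the first third of frames (burn-in; configurable), then
iterates Kabsch superposition of every frame onto the mean structure until
the mean stops moving (tolerance 1e−10 Å, at most 20 passes — random
global orientations need more than the 2 passes that suffice for
pre-aligned trajectories).  RMSF_i = √⟨|r_i − ⟨r_i⟩|²⟩ is computed per
atom over the backbone selection (N, CA, C, O) and averaged within each
residue.  The result is independent of the input's global reference frame
to ~1e−6 Å.

## Synthetic data: what it emulates, and what it does not

Every generator consumes a `SynthSpec` (seed, noise_sd, sampling grid,
ground-truth parameters) and draws all randomness from one seeded
generator, so fixed seeds give bit-identical output and noise_sd = 0 gives
the exact model prediction.  Noise models: additive Gaussian for
intensities, ellipticity and fraction-scale observables; multiplicative
lognormal for strictly positive observables (peak volumes, rates).  The
magnitudes are configurable placeholders — experimental noise levels are
not derivable from published tables — with defaults (2% intensity noise,
5% volume/rate noise, 0.02 fraction units) at the level a well-set-up
experiment of each kind plausibly achieves.

Defaults tied to the experimental design being emulated: mixing-time grid
of 8 points over 0–0.4 s; temperature grid 278–303 K (the 5–30 °C window
within which such ZZ-exchange series are measurable); reference
temperature 298.15 K for all rate laws; chemical denaturation on 12 evenly
spaced points over 0–5 M; melts every 2 °C.

The dimerization-coupled rate law composes three exact ingredients:
Arrhenius intrinsic kinetics k_int(T), a van't Hoff temperature-dependent
Kd(T) = Kd0·exp(ΔH_assoc/R·(1/T − 1/T0)) (positive ΔH_assoc ⇒ dimer
favored at high temperature), and the mass-action monomer fraction.  With
ΔH_assoc = 30 kcal/mol, Kd0 = 100 µM, C = 1 mM and an intrinsic barrier of
9 kcal/mol, the apparent activation energy of the observed rate is ≈ −2
kcal/mol: heating speeds the intrinsic flip but depletes the
exchange-competent monomer faster.  Setting ΔH_assoc = 0 reduces the law
exactly to Arrhenius scaled by a constant monomer fraction.

Rotamer trajectories are continuous-time Markov chains on the 3×2 product
of χ1 × χ2 bins, started from the stationary distribution, with jumps
changing one dihedral at a time by default (the simplest mechanism
consistent with the binning); emitted angles are state centers plus
wrapped Gaussian noise, and the exact jump log is returned as the oracle
for counting tests.  Backbone ensembles displace each residue's four
backbone atoms by one isotropic Gaussian vector per frame around a
synthetic idealized chain (not a real protein structure), optionally
composed with a random global rotation and translation that
superposition-based analysis must undo; the internal displacements are
drawn before the rigid-body overlay so the two variants of a seed share
identical internal motion.

None of this emulates raw NMR spectra (no FIDs, no spectral processing),
force-field MD, solvent effects, correlated (non-isotropic) backbone
motion, peak overlap beyond what the Gaussian-cluster model expresses, or
baseline drifts beyond linearity.  Passing tests therefore demonstrate
correctness of the estimators under their stated models — recovery,
identities, calibration — not robustness to every pathology of real
spectra or trajectories.

## Problem sizes used by the test suite

The simulation studies run at sizes chosen to make their acceptance bounds
statistically meaningful while keeping the suite quick: 50 replicates for
ZZ and chemical-denaturation noise studies, 100 for Kd, 200 for
permutation-null calibration (3000-frame chains, 199 permutations each),
5000 frames × 50 residues for the RMSF closed-form limit, and CTMC runs of
2000–8000 frames for transition counting.

## Known limitations

- The ZZ fit does not impose the equilibrium tie p₁·k_12 = p₂·k_21 on the
  initial intensities: peak intensities carry instrument factors, so I0
  ratios are not population ratios.  Consequently k_12 and k_21 are
  determined by curve shapes alone.
- No three-site exchange, no oligomers beyond dimer, no three-state
  unfolding, no ΔH/ΔCp analysis of melts.
- The Kd estimate inherits any differential exchange broadening of the
  monomer and dimer peaks; the response-factor option is the only lever.
- Trajectory input is multi-model PDB or per-frame dihedral tables;
  compressed MD formats (DCD/XTC) are out of scope.
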