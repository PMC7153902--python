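# Methods

`hingedyn` implements the analysis methodology for hinge-type dimeric
peptides — virtual-atom descriptors, essential-dynamics PCA, well-tempered
metadynamics and free-energy-surface (FES) reconstruction — together with a
coarse-grained synthetic hinge on which every stage can be validated
against closed-form ground truth. This note records the models, the
numerical choices, and what the validation does and does not demonstrate.

## The synthetic hinge

The generator (`hingedyn.hinge_model`) evolves two internal coordinates:
the opening angle θ (degrees) and the twist coordinate w, defined as the
W–W′ distance (nm). The potential is

    U(θ, w) = B [((θ−θ_m)/δ)² − 1]² + (A/2)(θ−θ_m)/δ
            + (k_w/2)(w−w₀)² + c (θ−θ_m)(w−w₀)

with θ_m the midpoint and δ the half-separation of the two wells. B and A
are calibrated numerically (cubic stationary points + a two-equation
`fsolve`) so that the saddle sits exactly `barrier` above the lower well
and the two minima differ by exactly `asymmetry`. Defaults: wells at 60°
and 110°, barrier 4 kJ/mol, asymmetry 0, k_w = 10 kJ/mol/nm² (sd ≈ 0.5 nm
at 300 K, matching the ~0.3–3 nm spread a hinge dimer's tryptophan
distance explores), w₀ = 1.5 nm, coupling c = 0, T = 300 K. The
double-well/harmonic form reproduces the qualitative landscape of a
disulfide-stapled hinge — two angle basins separated by a thermally
accessible barrier, with an orthogonal twist degree of freedom — while
keeping the Boltzmann density exp(−U/k_BT) analytic.

Sampling is overdamped Langevin with the Euler–Maruyama step

    x ← x − (Δt/γ) ∂U/∂x + sqrt(2 k_B T Δt / γ) ξ,

one friction coefficient γ (default 1 ps⁻¹) per coordinate, and reflecting
boundaries at θ = 0°/180° and w = 0 (a warning is emitted if more than 1%
of steps reflect). The scheme's stationary law is exact only as Δt → 0;
two consequences matter in practice:

* for a harmonic coordinate the stationary variance is inflated by a
  factor 2/(2 − k Δt/γ); the equipartition checks therefore run at
  Δt = 0.003 ps (bias ≈ 1.5%, below the blocked standard error at 10⁶
  steps), while the default Δt is 0.01 ps;
* the per-step displacement sqrt(2 k_B T Δt/γ) must stay well below the
  narrowest feature of the *biased* potential. With 0.05-nm metadynamics
  hills on the twist coordinate this forces Δt = 2×10⁻⁴ ps for
  twist-biased production runs (at Δt = 0.01 the step length is 0.22 nm —
  four hill widths — and the sampled ensemble is visibly distorted). For
  angle-biased runs the step is 0.22° against 2.9°-wide hills, so
  Δt = 0.01 ps is fine.

Every internal state maps deterministically to a 30-bead Cartesian frame
(two 12-bead Cα arms, a tryptophan side-chain bead per arm, four sulfur
beads in a tetrahedron at the pivot) constructed so that the descriptor
module recovers θ and w from coordinates to ~10⁻⁸ exactness: the sulfur
tetrahedron's center is the exact vertex, the C5/C8 beads straddle the arm
axis symmetrically, and the tryptophan beads sit on tethers whose geometry
solves the commanded W–W′ distance exactly. Combinations of (θ, w) outside
the tether's reach raise an error listing the feasible range. The
embedding is rigid-arm and noise-free; it exercises descriptor geometry,
not conformational detail.

## Descriptors

Virtual atoms are unweighted geometric centers. The opening angle is
measured at the disulfide-cluster center between the per-chain C5α/C8α
midpoints (clamped arccos, reported in degrees); the twist is the distance
between the two tryptophan side-chain centers ("side chain" = every atom
outside the backbone set, the default; an indole-only group can be
selected instead); the loop distance is the G7–G7′ Cα distance. The
hydrogen-bond count uses d(D···A) ≤ 0.35 nm and a D–H···A angle within 30°
of linear — conventional MD values, exposed as parameters, since the
count is a monitoring quantity rather than a calibrated observable.

## RMSD, RMSF, PCA

Superposition is Kabsch (via `scipy`'s `Rotation.align_vectors`,
reflections excluded). The RMSD reference defaults to the last frame,
overridable. RMSF superposes all frames onto an iteratively refined mean
structure (Cα fit), averages atoms per residue, and pairs residue i of the
two chains when chain-averaging; backbone is N/CA/C/O, side chain the
remaining heavy atoms.

PCA builds the positional covariance of the pooled Cα selection (both
chains in one matrix) with population (1/M) normalization after
superposing onto the converged mean structure — iteration runs to a fixed
point (tolerance 10⁻¹³ on the mean) so that projections of the fitting
data are centered and their variances equal the eigenvalues to machine
precision. No mass weighting. Eigenvalues are clipped at zero; modes are
sorted descending.

## Well-tempered metadynamics

Gaussian hills of initial height w₀ = 0.2 kJ/mol, width σ = 0.05 (CV
units) and bias factor γ = 10 are deposited every 1 ps; the height decays
as h = w₀ exp(−V/k_BΔT) with ΔT = (γ−1)T, and the FES follows from
F = −γ/(γ−1) V, min-shifted. An `untempered` flag gives the standard
(γ→∞) limit. The angle CV is expressed in radians for biasing (the
convention of standard metadynamics engines; σ = 0.05 rad ≈ 2.9°), the
twist CV in nm; degrees remain the reporting unit everywhere.

Implementation: public bias evaluation (`bias_value`, `bias_force`,
`next_hill_height`) is exact summation over hills. The integrator instead
carries the bias on per-CV uniform grids (spacing σ/5, hills accumulated
to 8σ, linear interpolation); grid nodes agree with exact summation to
≤10⁻⁹, and the interpolation error between nodes is second order in the
spacing (~10⁻² kJ/mol on converged biases). Deposited hill heights are
computed from the same grid — exact per-deposition summation would be
quadratic in hill count and unusable at the 10⁵–10⁶ hills of a
microsecond run. Hill centers and heights are quantized to 9 significant
decimal digits at deposition (the package's text precision), so a HILLS
file round trip is lossless and a run resumed from HILLS (plus the saved
generator state) continues bit-identically.

The integrator kernel is written once in plain Python and compiled with
numba when available; the compiled and interpreted paths execute the same
IEEE-ordered arithmetic and produce bit-identical trajectories (tested),
so the interpreted path doubles as the reference implementation.

## FES estimation

Densities are binned KDE histograms (weighted histogram smoothed by a
Gaussian kernel, renormalized to unit mass; default bandwidth one grid
spacing, the production pipeline uses 3° × 0.15 nm on a 425 × 425 grid).
F = −k_BT ln ρ on visited cells, min-shifted; unvisited cells are masked,
never reported as zero. The production pipeline additionally masks cells
whose smoothed density corresponds to fewer than ~10 raw samples per
kernel footprint — below that the "free energy" is tail noise.

Metadynamics reweighting uses the final-bias estimator
w_i ∝ exp(+V_final(s_i)/k_BT) (weights normalized to mean 1, effective
sample size reported), with the leading 20% of samples discarded as the
pre-convergence transient; a time-dependent-offset estimator is a
documented extension point. For runs with ≳10⁴ hill-sample pairs the
final bias is evaluated by grid replay + linear interpolation (agrees
with exact summation to ~10⁻³ kJ/mol); the exact path remains available.

Convergence is assessed by recomputing the FES on the series truncated at
checkpoint times (default 20/40/80/100% of the run) and reporting the
maximum |ΔF| over cells visited in all checkpoints. Per-basin statistical
errors come from contiguous block averaging of the basin occupancy
(−k_BT ln occupancy per block; standard error over blocks; blocks that
never visit a basin are excluded and counted). Barriers are minimax grid
paths (4-connected; Kruskal/union-find activation in order of increasing
F), deterministic and gauge-invariant.

## Validation studies and their scope

The acceptance studies (`hingedyn.experiments`, mirrored by
`tests/test_acceptance.py` and `scripts/acceptance.py`) run:

* **Angle-biased recovery** — five independent 2-µs runs biasing θ
  (asymmetry 2 kJ/mol). The snapshot-averaged bias over the last 20% of
  hills recovers the well ΔF to ≲0.2 kJ/mol, the minimax barrier to
  ≲0.2 kJ/mol, and the bias shape matches −(1−1/γ)F over [50°, 120°] to
  ≲0.2 kJ/mol. 2 µs is needed because the protocol's convergence error
  decays as 1/√t with the generator's slow angular diffusion.
* **Equipartition** — 10⁶ unbiased steps of the harmonic twist: sample
  variance within three blocked standard errors of k_BT/k_w and the
  histogram FES within 0.3 kJ/mol of the parabola out to 2 sd.
* **End-to-end** — a 400-ns run biasing only the twist (the angle crosses
  its barrier thermally), reweighted to a 2-D FES whose two minima land
  within a fraction of a degree / ~0.02 nm of the true wells, with
  checkpoint deviations shrinking over the run.

What this shows: the engine, estimators and descriptors are internally
consistent and recover a *known* landscape under realistic sampling noise.
What it does not show: anything about force-field accuracy, solvent
effects, or real-peptide kinetics — the synthetic hinge has rigid arms, no
secondary-structure degrees of freedom, and a single harmonic twist, so
passing these studies certifies the methodology, not the biology.

## Known limitations

* Overdamped dynamics only; no inertia, no thermostat emulation.
* The coupling constant between opening and twist defaults to 0; the real
  peptide's coupling is unknown.
* Final-bias reweighting is the only built-in unbiasing estimator.
* 1–2 CVs only; no multiple walkers, adaptive widths or replica exchange.
* The selection mini-grammar covers chain/resid/resname/name with
  and/or/parentheses — not a full selection language.
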