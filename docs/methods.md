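# Methods

`pamscope` packages the analysis machinery used to characterize how a
protein reads a DNA recognition motif — concretely, how the arginine dyad in
a Cas9-family PAM-interacting domain engages PAM nucleobases and backbone
phosphates — together with the enhanced-sampling and free-energy estimators
such a study rests on.  Every method operates on plain data (structures,
coordinate frames, energy tables) and is validated against synthetic inputs
whose ground truth is known in closed form.  This note records the models,
the defaults and why, the numerical choices, and what the synthetic
validation does and does not establish.

## Units

Internal units form the consistent nm / kJ/mol / amu / ps / K system
(kB = 0.0083144621 kJ/mol/K), in which 1 kJ/mol = 1 amu·nm²/ps², so
frequencies derived from energies and mass-weighted covariances are directly
in ps⁻¹.  Angstrom appears at user-facing boundaries where the field reports
distances (hydrogen bonds, RMSD, domain distances), and kcal/mol
(1 kcal = 4.184 kJ) is available for free-energy output.

## Contact fingerprinting

A residue–DNA pair is an *effective contact* in a frame when two criteria
hold simultaneously:

1. the mass-weighted COM distance between the arginine guanidinium group and
   the DNA group is below 0.6 nm (nucleobase pairs) or 0.5 nm (backbone
   phosphate pairs), and
2. the pair interaction energy is attractive with magnitude at least
   100 kJ/mol (bases) or 350 kJ/mol (phosphates), i.e. E ≤ −threshold.

The energy criterion is interpreted as attraction (negative energies)
because contacts are favourable interactions; the dual criterion separates
genuinely interacting pairs from pairs that are merely adjacent.  Candidate
pairs are prefiltered by requiring the distance criterion in at least 5% of
the frames pooled over all replicates (boundary inclusive; the distance
comparison itself is strict `<`).  Pooled prefilter occupancy is exactly the
frame-count-weighted mean of per-replicate occupancies.

Energies are user data: the primary path is a per-frame energy table
exported from whatever engine produced the trajectory (the thresholds apply
to whichever energy definition the table carries — this is deliberately not
reinterpreted).  A point-charge Coulomb evaluator with optional 12-6
Lennard-Jones terms (Lorentz–Berthelot combination, prefactor
138.935458 kJ·mol⁻¹·nm·e⁻²) is provided for synthetic fixtures and
charge-annotated structures; it makes no attempt at Ewald/PME electrostatics.

### Occupancy statistics

Per-frame contact indicators are Bernoulli observations with variance
p̂(1−p̂), but consecutive frames are correlated.  The integrated
autocorrelation time

τ = Δt · (½ + Σₖ ρ(k))

is estimated with an automatic truncation window (smallest W with
W ≥ 6·τ(W)/Δt, Sokal's criterion; FFT-based autocorrelation).  A constant
series has τ ≡ 0; an i.i.d. series converges to Δt/2.  Following the
source workflow, τ is computed from the pair's *energy* series, and when
several replicates are pooled the largest replicate τ is used.  Effective
sample count is n_eff = n·Δt/(2τ), capped at n, and SE = √(p̂(1−p̂)/n_eff).
Replicate-level means are combined as mean ± SD(replicate means)/√R.

Validation: on two-state Markov chains with planted stationary occupancy and
autocorrelation time (flip rates chosen so the second eigenvalue
μ = (τ/Δt − ½)/(τ/Δt + ½) yields the requested integrated τ), the 1.96·SE
intervals cover the true occupancy at ~95% across p ∈ {0.1, 0.3, 0.5} and
τ/Δt ∈ {1, 10, 50}.  Series length for these experiments is 50 000 frames,
chosen so that n_eff ≥ 500 even at the largest correlation time and the
binomial normal approximation underlying the interval is valid; at much
shorter lengths the check would measure small-sample interval distortion
rather than the estimator.

## Hydrogen bonds and specificity

Geometric criteria: donor–acceptor distance ≤ 3.5 Å and
hydrogen–donor–acceptor angle ≤ 30° (small angle = nearly linear bond).
Hydrogens are paired to their covalent donor by same-residue proximity
(≤ 1.25 Å) when no topology is available.  Frequencies are per-triplet
occupancies (presence count / total frames); category frequencies sum the
triplet frequencies within a category (PAM-nucleobase, PAM-backbone,
non-PAM).  Normalization divides a residue's category frequencies by their
sum; an all-zero dataset is returned unchanged with a warning.

The specificity index compares hydrogen bonding to the PAM against the rest
of the DNA.  Its algebraic form is not uniquely fixed by the definition "PAM
frequency relative to non-PAM frequency", so the package implements the
ratio SI = f_PAM/(f_nonPAM + ε) with ε = 10⁻⁶ (default) and the share form
f_PAM/(f_PAM + f_nonPAM) behind a flag; reports should never mix the two.
f_PAM is the sum of the PAM-nucleobase and PAM-backbone frequencies, since
the category scheme splits "PAM nucleotides" into those two classes.  Errors
propagate to first order.

## Superposition, RMSD, RMSF, domain distances

Rigid superposition is the weighted Kabsch algorithm (SVD of the weighted
cross-covariance, smallest-singular-vector sign flip to exclude
reflections); collinear point sets are rejected.  Backbone RMSD pairs atoms
across structures by chain id + author residue number + atom name — author
numbering is kept throughout so residue labels like R1333/R1335 mean what
they mean in the literature — with unmatched atoms dropped and counted.  The
backbone atom set defaults to N, CA, C, O and is a parameter, since
published RMSD values rarely state the convention.

RMSF fits every frame onto the iteratively refined ensemble mean over a fit
selection before measuring √⟨|xᵢ−⟨xᵢ⟩|²⟩, and reports both per-atom values
and the side-chain (heavy-atom) mean, because aggregation conventions vary.

Domain–domain COM distances use all heavy atoms of each domain
(Cα-only is switchable); densities are histograms with Scott-rule bin
widths, reported with their bin edges.  Domain residue ranges are user
configuration; the defaults (REC3 = 497–713, HNH = 775–908) follow the
standard SpCas9 domain architecture.  Two ensembles are compared with
Z = (mean_A − mean_B)/√(SE_A² + SE_B²), two-tailed p = 2(1−Φ(|Z|)), with
each SE corrected by the series' integrated autocorrelation time.

## Quasi-harmonic entropy

The mass-weighted covariance σᵢⱼ = ⟨Δxᵢ√mᵢ · Δxⱼ√mⱼ⟩ is built after
least-squares fitting each frame onto the ensemble mean of the selection
(removing rotation and translation).  Each eigenvalue λ (amu·nm²) defines an
oscillator ω = √(kB·T/λ), and the entropy is the quantum
harmonic-oscillator sum (Andricioaei–Karplus):

S = R · Σ [ x/(eˣ−1) − ln(1−e⁻ˣ) ],  x = ħω/(kB·T),

over retained modes.  This matches the covariance-eigenvalue route of the
`gmx covar`/`gmx anaeig` workflow.  Schlitter's upper bound
S ≤ (R/2)·Σ ln(1 + e²/x²) is available behind a flag.  After rigid-body
removal the six near-zero eigenvalues are excluded by a magnitude floor
(λ < 10⁻⁸ amu·nm²) rather than a fixed count, with a warning when the
dropped count differs from six — a fixed count silently misbehaves on
degenerate selections.  Temperature is a required argument and is never
defaulted: entropies are strongly T-dependent and simulation and analysis
temperatures can legitimately differ.  At least 3N frames are recommended
(warned otherwise).  Validation: ensembles drawn from a planted covariance
reproduce the closed-form entropy of the planted mass-weighted eigenvalues
within 2% at 5·10⁴ frames, and a single mode with x = 1 gives
R·(1/(e−1) − ln(1−e⁻¹)) ≈ 8.65 J/mol/K.

## Well-tempered metadynamics

The bias is a sum of Gaussians deposited every t_G along the CV trajectory;
in the well-tempered variant the height of each new hill is scaled by
exp(−V(s)/kB·ΔT) with ΔT = (γ−1)·T.  The printed form of the tempering
exponent omits kB, as is common shorthand; dimensional consistency with a
unitless bias factor γ fixes the energy scale as kB·ΔT.  The free energy is
recovered as F(s) = −(γ/(γ−1))·V(s), shifted so min F = 0 (the additive
C(T) is absorbed by the shift); γ → ∞ recovers standard metadynamics.

Defaults mirror the production setup they model: per-deposition hill height
ω·t_G (a constructor accepts the deposition rate/stride pair, e.g.
1.0 kJ/mol/ps and 10 ps), bias factor 4 at 300 K, one-sided harmonic walls
with k = 3500 kJ/mol·nm².  Wall *positions* are user data — they bound
whatever CV range is physically meaningful (0.3–1.2 nm for the original
group-distance CVs; ±1.5 for the toy double well whose wells sit at ±1).

Sampling on toy landscapes uses BAOAB Langevin integration with the CVs
equal to the coordinates (no CV Jacobian handling).  Multiple walkers
propagate independently against a shared hill log; deposition rounds are
synchronous and hills are ordered by (time, walker id) so runs are
bit-reproducible given a seed.  Bias forces use analytic Gaussian gradients;
the inner loop reads them from a cached grid (spacing σ/8, linear
interpolation) — correctness is defined by direct summation, which the grid
matches to interpolation error.  Energy blow-up (non-finite or escaping
coordinates) aborts the run.

Convergence diagnostic: the hill log is split into consecutive equal blocks;
each block's own FES is compared to the final block's FES by RMS difference
after mean alignment.  Identical halves give exactly 0; converged runs show
a decreasing trend; short noisy logs show large deviations.

Validation: on V(x) = a(x²−1)² with a = 2.5 kJ/mol at 300 K (barrier
2.5 kJ/mol, 1 CV), a 2 000 ps run with 4 walkers (hill height 1.0 kJ/mol
every 0.5 ps, σ = 0.1) reconstructs the barrier within 1 kJ/mol of the
Boltzmann-integrated reference and the inter-basin ΔF within 0.5 kJ/mol of
its symmetric value 0; a single-hill log reproduces the closed-form FES
exactly.  These problem sizes run in tens of seconds and are the package's
regression conditions.

## Alchemical free energies

MBAR solves f_i = −ln Σₙ exp(−u_i(xₙ)) / Σₖ Nₖ exp(f_k − u_k(xₙ)) with
f₀ ≡ 0.  The solver runs self-consistent iteration (log-sum-exp throughout)
until the update is below 10⁻⁴, then Newton–Raphson on the sampled-state
subspace to a gradient tolerance of 10⁻⁸ (damped when steps exceed 2 reduced
units).  States with zero samples are evaluated by a final self-consistent
pass, which reduces exactly to exponential averaging.  Uncertainties come
from the asymptotic covariance Θ = V S (I − S Vᵀ N V S)⁺ S Vᵀ of the weight
matrix W = U S Vᵀ; the estimated σ of a two-state ΔG tracks the empirical
scatter within a factor of two, and 1.96σ intervals cover the analytic
harmonic-state ΔG ≈ 95% of the time over repeated draws.  Adjacent-state
overlap below 0.03 triggers a warning.

Neighbor swaps accept with min(1, e^(−Δ/kBT)),
Δ = U_i(x_j) + U_j(x_i) − U_i(x_i) − U_j(x_j).  The λ-schedule optimizer
estimates pairwise swap acceptance from pilot samples (common random numbers
within an iteration) and moves interior λ values down the finite-difference
gradient of the summed squared acceptance deficits, inserting a midpoint
window when a gap stalls below target; it terminates when the minimum
acceptance reaches the target (default 0.10) and otherwise returns the best
schedule flagged unconverged.  The contract is the target acceptance, not
any particular optimizer trajectory; the exchange-attempt period is a
parameter because published practice varies (0.5–2 ps).

Thermodynamic-cycle ΔΔG = ΔG_m2 − ΔG_m1 (mutation with DNA bound minus
without), uncertainties in quadrature; negative ΔΔG means the mutation
favours DNA binding.  Per-residue enthalpy decompositions discard the first
10% of frames as equilibration and report the mean with SD(5 block means)/√5.

## Synthetic generators

The generators define the statistical conditions every estimator is tested
under; all are seeded and echo their parameters:

- **Markov binary series** — planted stationary occupancy and integrated
  autocorrelation time (exponential-autocorrelation convention, with the
  μ ↔ τ mapping above).  Emulates correlated contact indicators, not any
  particular physical kinetics.
- **Gaussian ensembles** — i.i.d. frames from a planted (3N×3N) covariance;
  planted entropy in closed form.  Real trajectories are *not* i.i.d. and
  not Gaussian in all modes; passing here shows estimator correctness, not
  sampling adequacy on real data.
- **Probe-site trajectories** — scheduled episodes at nucleobase /
  phosphate / non-PAM sites that jointly satisfy (or, for planted
  near-misses, deliberately half-satisfy) the dual contact criteria, giving
  exact ground-truth occupancies.  Geometry and energy levels are stylized;
  only the decision structure of the classifier is exercised.
- **Double well** — V(x) = a(x²−1)², separable in 2D, with the reference
  FES by Boltzmann integration on a fine grid.
- **Harmonic λ families** — exact Gaussian samples; ΔG analytic
  ((kBT/2)·ln(k_j/k_i); center shifts contribute nothing).

Synthetic trajectories can be written as multi-model PDB plus CSV energy
tables so tests exercise the real I/O path.

## Known limitations

- No force-field engine: pair energies are Coulomb(+LJ) or user tables; no
  PME, no solvent-mediated terms.
- The metadynamics engine targets analytic low-dimensional CVs; it does not
  propagate atomistic systems, handle CV Jacobians, or reweight auxiliary
  observables.
- MBAR assumes all samples can be evaluated in all states; hybrid-topology
  construction for real mutations is out of scope.
- Published system-scale quantities that depend on microsecond all-atom
  trajectories of the solvated complexes (mutation ΔΔG tables, per-residue
  entropies of the real protein, the production free-energy landscapes)
  are beyond desk-scale inputs; the oracle suites above validate the
  estimators, and the same code paths accept deposited trajectories where
  users have them.  Crystal-structure comparisons (backbone RMSD between
  PAM-bound structures, REC3–HNH distances) are implemented and tested but
  require the RCSB files on disk.
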