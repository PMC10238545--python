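# Methods

`exstate` implements the computational workflow used to detect a sparsely
populated ("excited") conformational state of a protein and to solve its
backbone structure: two-site-exchange analysis of CPMG relaxation
dispersion measured at several temperatures, alignment-tensor fitting from
residual dipolar couplings (RDCs) with a sparsity correction of the tensor
magnitude, population-weighted two-state ensemble refinement against
multi-medium RDCs with leave-one-set-out cross-validation, and the
structural-comparison utilities used to characterize the result. A
synthetic-data generator supplies every input with known ground truth, so
the whole pipeline is testable end to end.

## Two-site exchange models

A nucleus exchanging between a major site A and a minor site B
(populations pA, pB = 1 - pA; forward rate k1 = pB·kex, reverse rate
k-1 = pA·kex; chemical-shift difference Δω) relaxes during a constant-time
CPMG spin-echo train with an effective rate R2eff that depends on the
refocusing frequency νCPMG.

`r2eff_exact` evaluates the exact all-timescale solution by closed-form
eigendecomposition of the 2×2 complex Bloch–McConnell propagator: one
(τ–180°–τ)² block is built from the analytic 2×2 matrix exponential, the
n = T_CP·νCPMG block propagator is raised to the n-th power through its
spectrum, and R2eff = −ln|M(T_CP)|/T_CP with the magnetization started at
(pA, pB). No fast- or slow-exchange approximation is involved; the
Carver–Richards expression is the same object written out explicitly.
`r2eff_numeric` is an independent oracle that propagates the same train
echo by echo with scipy's generic `expm`; the two agree to machine
precision and the test suite requires < 0.1 s⁻¹ over a broad random
parameter grid.

Shift differences are stored in ppm and converted with the nucleus Larmor
frequency derived from the ¹H field via fixed gyromagnetic ratios. The
sign of Δω is not identifiable from CPMG data, so fits constrain Δω ≥ 0.
Echo counts are rounded (with a warning) when |n − T_CP·ν| < 0.01.

One caveat discovered while testing: R2eff(ν) is *not* monotone in ν in
the deep slow-exchange regime (kex ≪ Δω in rad/s), where genuine resonance
oscillations appear; the monotonicity property is asserted only for
kex ≳ Δω.

The 1D exchange lineshape I(ω) = Re[1ᵀ(i(ω−Ω) + R2 + K)⁻¹ p] supports any
number of sites with a detailed-balance-checked kinetic matrix; peak areas
of slow-exchange spectra recover populations, and the Arrhenius laws
(k = A·exp(−Ea/RT), parameterized for conditioning as a rate at a
reference temperature plus activation energy) reproduce the
coalescence-on-warming behaviour of the experiment.

## Dispersion fitting

Single-temperature fits share (kex, pB) across residues; each residue has
its own Δω and an intrinsic-R2 baseline. Because equal intrinsic
relaxation factors out of the propagator exactly, baselines are profiled
out analytically (weighted mean of data minus exchange contribution),
which removes one parameter per profile. Fitting begins with a grid search
(kex log-spaced 100–6000 s⁻¹ × pB 0.01–0.5 × Δω 0.1–5 ppm) and finishes
with bounded trust-region least squares; the wrapper guarantees the
monotone-descent contract (the returned solution never has a higher χ²
than its start).

Multi-temperature fits couple the rates through two Arrhenius laws (for k1
and k-1) while Δω stays temperature-independent per residue; populations
pB(T) = k1(T)/kex(T) fall out of the fitted laws. Initialization fits each
temperature separately and regresses ln k against 1/T. Replicated νCPMG
points enter χ² individually; when no error column is provided, point
errors come from the spread of replicated measurements (replicated points
carry their own sample standard deviation, unreplicated points the pooled
value).

Parameter uncertainties follow the multi-start protocol: the standard
deviation among the 10 best of 100 fits launched from random points within
the bounds. With a fully converging monotone optimizer every start that
reaches the global basin lands on the same optimum, so this spread
measures the reproducibility of the optimum and is a *lower* bound on the
statistical error; the test suite verifies it never exceeds three times a
200-replicate parametric bootstrap. Callers who need statistical errors
can run the bootstrap with the same problem objects.

Exchange is reported per residue only when the dispersion amplitude
R2eff(ν_min) − R2eff(ν_max) strictly exceeds twice the median point error
(threshold configurable; ties reject).

## RDC alignment tensors

All couplings are kept on the amide N–H scale: predicted couplings are
D = (Dmax_type/Dmax_NH)·vᵀS̃v with S̃ the Saupe tensor in Hz, so
Da = S̃zz/2 (Hz) and rhombicity R = (2/3)(S̃xx − S̃yy)/S̃zz with the
|S̃zz| ≥ |S̃yy| ≥ |S̃xx| eigenvalue convention. Type constants use fixed
gyromagnetic ratios and effective bond lengths (N–H 1.041 Å, Cα–Hα
1.117 Å, N–C′ 1.329 Å, H^N–C′ 2.085 Å). Amide and alpha protons missing
from crystal structures are rebuilt with ideal geometry (in-plane
bisector construction for H^N, tetrahedral completion for Hα); proline
N–H vectors are skipped.

The tensor is fitted by SVD of the five-column direction-cosine design
matrix, rows weighted by 1/σ after normalization to the N–H scale.
Relative singular values below 5% of the largest are truncated. This
stabilizes ill-conditioned fits but is also the origin of the *sparsity
underestimate*: a single coupling type measured on an orientationally
anisotropic subset (the nearly parallel N–H vectors of one helix) yields a
near-rank-deficient design whose truncated solution shrinks along the
unsampled directions, biasing |Da| low while leaving the rhombicity
essentially intact. The magnitude correction refits the tensor jointly
over *all* coupling types in one alignment medium (a much better
conditioned problem), then grid-searches a common scale factor 1.00–1.20
(step 0.01) applied to the magnitude — orientation and rhombicity fixed —
minimizing the summed R factor over the types, where
R = rmsd/√(2Da²(4+3R²)/5) normalizes the misfit by the RMS expected for
randomly distributed bond vectors. On densely sampled synthetic data the
selected scale is 1.00–1.02 (no correction needed); on sparse anisotropic
subsets the corrected magnitude is systematically closer to the generating
tensor than any single-set SVD magnitude.

During development an alternative generative mechanism for the
underestimate — orientational noise between the vectors generating the
couplings and the fitting structure — was rejected: because the design
rows are pure rank-2 spherical harmonics of the bond vector, isotropic
jitter attenuates single-set and joint fits by exactly the same factor,
and the scale search then overshoots symmetrically. The conditioning
mechanism reproduces the asymmetry actually exploited by the correction.

## Two-state ensemble refinement

The excited-state conformer is refined in Cartesian coordinates against
population-weighted RDCs while the ground-state conformer stays fixed to
the crystal structure:

    E = Σ_sets k_rdc Σ ((D_obs − [(1−w)·D_ground + w·D_minor])/σ)²
      + k_geom Σ_pairs (d_ij − d_ij⁰)²                (bonded, 1-3, 1-4)
      + k_disp Σ_atoms max(0, |r_i − r_i⁰| − 3 Å)²
      + k_dihe Σ (torsion deviations beyond their halfwidth)²

Only heavy atoms are free coordinates. Amide and alpha protons are rebuilt
rigidly from their bonded heavy atoms at every energy evaluation, with
chain-rule gradients through the construction. This mirrors torsion-space
refinement, where protons carry no independent degrees of freedom, and is
essential: with free proton coordinates each N–H vector can tilt
independently by several degrees at negligible restraint cost, absorbing
both data signal and noise and destroying the population dependence of
the fit. Unrestrained peptide-plane (ω) torsions open the same loophole,
so ω restraints accompany the φ/ψ restraints by default.

Dihedral restraints are consumed as generic (residue, angle, target,
halfwidth) tuples; the pipeline centres them on the ground structure's own
φ/ψ/ω (standing in for chemical-shift-derived restraints) with zero
halfwidth, i.e. harmonic wells of weight k_dihe = 500 rad⁻². The weight
was calibrated on synthetic data so that the torsion-change prior matches
the scale of backbone changes the method is designed to detect (a few
degrees per torsion for sub-3-Å segment displacements); it is the analogue
of the force-constant adjustment performed interactively in the original
protocol. Each run starts from the ground coordinates plus 0.5 Å Gaussian
noise, is pre-relaxed under the geometry terms alone, then minimized by
L-BFGS-B (the energy is non-increasing across iterations); runs exceeding
the displacement cap by more than 10% are discarded and redrawn. The
reported ensemble is the n_keep lowest-energy conformers of n_runs.

Cross-validation excludes one RDC set (medium × coupling type) at a time,
refines on the rest, and scores the held-out set with the R-free factor of
the weighted two-state prediction, alongside the R factor of the ground
conformer alone (the N = 1 reference). The population grid search repeats
this over minor fractions 0.15–0.45 and selects the fraction minimizing
the summed cross-validated R-free. "No identifiable optimum" is declared
when the minimum sits at a grid edge or shows no improvement over N = 1 —
the signature of one-state data. Population identification rests on two
real mechanisms: below the true fraction the required displacement scales
as w_true/w and collides with the 3 Å cap and the torsion prior; above it
the data are reproducible with cheaper motion but the prediction inherits
proportionally more overfitted orientation noise. The optimum is
accordingly shallow, and on repeated synthetic draws it scatters by about
one 0.05 grid step around the generating fraction.

## Synthetic data

The generator builds an idealized mixed α/β backbone (~166 residues,
NeRF construction from per-residue φ/ψ) whose excited state tilts two
segments (defaults 105–116 and 127–140) about random axes through their
centroids by 22°, tapered over three residues at each end and then
regularized by the same elastic-geometry minimizer the refiner uses, so
both conformers are chemically regular (bonds within 1% of ideal) and the
maximum displacement stays below 3 Å. Rotations rather than translations
carry the displacement because RDCs sense orientation only.

Defaults mirror the experimental regime: minor weight 0.30; two alignment
media with Da = +10 Hz (R = 0.30) and −8 Hz (R = 0.55) at independent
random orientations; four coupling types with Gaussian noise σ = 0.5 Hz
(N–H), 1.0 Hz (Cα–Hα), 0.2 Hz (N–C′ and H^N–C′); switch-region residues
(30–38, 59–76) dropped to emulate exchange broadening. CPMG data cover
seven methyl probes at 20/25/30 °C with νCPMG ∈ {100, 200, 400, 500, 800,
1000} Hz plus repeats at 100/400/1000 Hz, R2eff noise 0.2 s⁻¹, rates from
Arrhenius laws with k1(25 °C) = 150 s⁻¹ (Ea 30 kJ/mol) and
k-1(25 °C) = 850 s⁻¹ (Ea 60 kJ/mol), i.e. pB = 15% and kex = 1000 s⁻¹ at
25 °C rising to ~30% population on cooling to 3 °C, reconciling the
dispersion-derived and lineshape-derived populations within one model.

What the generator does not emulate: real side chains and packing
(polyalanine backbone, no sterics), internal dynamics of bond vectors
(order parameters are unity), structural noise between the fitting
structure and the solution average, peak overlap in spectra, and
correlated noise. Passing tests therefore demonstrate the estimators'
correctness and calibration under the stated statistical model, not
robustness to every feature of experimental data.

## Numerical choices and degenerate inputs

- Bounded quasi-Newton (`least_squares` trust-region and L-BFGS-B)
  everywhere; descent wrappers enforce monotonicity by returning the
  start whenever a polish fails to improve it.
- 2×2 propagator eigendecompositions guard the degenerate equal-eigenvalue
  branch explicitly; lineshape linewidths have a small positive floor.
- Dispersion detection ties break to "not detectable" (strict inequality).
- Tensor fits require ≥ 5 usable couplings and full design rank; the
  scale grid reports when its optimum is not bracketed (an edge optimum at
  1.00 simply means no correction is needed).
- Superposition raises the chirality-mismatch error only when the
  reflected fit is decisively (2×) better than the proper one.
- All random draws flow through explicit seeds; every generator is a pure
  function of its parameters and seed.

## Problem sizes used in the shipped checks

The acceptance script and test suite run the full-size synthetic system
(166 residues, 8 RDC sets, 3 temperatures) but economize on repetition:
population grids of 5–7 points with the four high-precision holdout sets
(N–H and Cα–Hα in both media), single-start cross-validation fits, and a
20-run/10-kept reporting ensemble. These sizes reproduce the pipeline's
behaviour stably; enlarging them sharpens the same answers.

## Known limitations

- The multi-start error protocol underestimates statistical errors for
  well-conditioned problems (see above); use the bootstrap for those.
- The population optimum from RDC cross-validation alone is shallow;
  in practice it should be read together with the independent population
  estimates from lineshape areas, as the original analysis did.
- The refinement engine is a restrained Cartesian minimizer, not a
  simulated-annealing torsion dynamics engine; energies are not
  comparable to molecular-mechanics force fields, and side chains beyond
  Cβ are out of scope.
- Hydrogens are ideal-geometry constructs; systems where amide-proton
  positions deviate strongly from planarity will carry that bias into
  N–H-based couplings.
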