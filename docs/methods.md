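# Methods

`sbsphase` models a chromatin locus with the Strings-and-Binders (SBS)
picture: a self-avoiding bead chain carries typed binding sites ("colors"),
and diffusing binder particles of matching types bridge cognate sites.
Above a threshold binder concentration the chain undergoes a first-order-like
coil → globule phase-separation transition; the package infers the binding
site arrangement from a bulk contact matrix, simulates equilibrium
single-molecule ensembles across binder concentrations, and provides the
single-molecule statistics used to compare such ensembles with
chromatin-tracing data.  This note records the model, the numerical choices,
and what the synthetic fixtures do and do not establish.

## Polymer model and sampler

**Energy function** (reduced units, lengths in bead diameters σ, energies in
kBT):

* consecutive beads: FENE bonds, U = −½ k R₀² ln(1 − (r/R₀)²),
  k = 30 kBT/σ², R₀ = 1.5 σ (equilibrium bond ≈ 0.97 σ);
* all particle pairs: purely repulsive WCA cores.  Bead–bead cores are
  0.8 σ — a bead is a 30-kb chromatin window, itself a polymer blob that can
  partially interpenetrate a neighbour — binders have 0.5 σ cores (a binder
  stands for a protein-scale complex, much smaller than a bead), and
  binder–bead cores use the arithmetic mean;
* binder–bead attraction: a square well of range 1.5 σ with depth
  `e_specific` when the binder type equals the bead color, `e_unspecific`
  (any bead) otherwise.  Defaults are `e_specific = 8.0`,
  `e_unspecific = 0.5` kBT, inside the weak biochemical ranges the method
  explores (3.1–8.0 and 0–2.7 kBT); the strong end is used because a
  desk-scale chain of ~100 beads offers far fewer cooperative contacts than
  a full locus model.

Binders diffuse in a periodic cubic box.  The default box edge is 2.5× the
SAW gyration radius of the chain: the box must exceed the open coil's
extent, because binder–bead interactions use the minimum-image convention
and a smaller box lets a single binder bridge the chain through its periodic
images (we observed large binding energies with no real-space compaction
when the edge equals the SAW Rg itself).  The binder count is
P = round(c·V·N_A) from the molar concentration and the physical box volume
(via `sigma_nm`).  Binders have no valence cap: one binder may bridge every
bead inside its well, which is the SBS bridging mechanism.

**Sampling** is Metropolis Monte Carlo of the canonical distribution — the
method's claims are equilibrium-thermodynamic, so an equilibrium sampler on
the same energy function replaces molecular dynamics.  A sweep attempts one
local displacement per bead (±0.25 σ) and per binder (±0.5 σ; 30% of binder
moves are box-uniform teleports, a symmetric proposal that accelerates
binder search), plus ~N/10 chain pivot moves.  70% of pivots rotate by small
angles (±0.08 π): full-angle pivots are essentially never accepted in
collapsed states, while small rotations let whole globules approach, merge
and rearrange.  Pivot moves are disabled for time-series runs, where only
local, diffusive dynamics is physical.

**Equilibration.**  The collapse is nucleation-limited: a quench at the
target affinities freezes chains in whatever multi-globule state first
forms, and traces show per-chain Rg unchanged between 6k and 20k sweeps.
Equilibration therefore uses an overshoot-and-relax protocol (first 30% of
the equilibration at 1.5× affinities, then the targets).  Compact-start
control runs show the overshoot globule dissolves within a few thousand
sweeps wherever the coil is the stable phase, so sub-threshold points are
not biased.  Stationarity is checked by split-half means of the
gyration-radius and binding-energy traces (must agree within 5%); failures
are flagged on the ensemble, never silent.

**Two-phase coexistence.**  At desk scale both phases are long-lived:
open-start supra-threshold ensembles retain ~25–35% un-nucleated coil-like
chains.  Ensembles meant to *represent a labeled thermodynamic state* (the
coil/globule reference pools used for RMSD classification and mixture
fitting) are therefore prepared in their own basin — compact initial
configurations for globule ensembles, open ones for coil ensembles — the
standard way to sample coexisting phases.  The unbiased phase *scan* always
uses open starts, and this is why its measured Rg drop (~37–43%) undershoots
the drop a fully equilibrated ensemble would show.

**Ensemble structure.**  By default every molecule is an independent chain
with its own derived seed.  For desk-scale budgets, `samples_per_chain > 1`
draws several decorrelated samples per chain (gap `decorrelation_sweeps`);
the tests use 4–10 samples per chain.

**SAW reference.**  The binder-free chain is sampled with pivot moves and
cached per chain length; it provides the order-parameter normalization
Rg/Rg_SAW and the default box edge.  The effective Flory exponent of this
chain over N = 20–200 is ≈ 0.62 (finite-size corrections push the apparent
exponent above the asymptotic 0.588).

## Inference (regularized simulated annealing)

The cost is a distance-scaled mean squared error over matrix elements,
H₀ = ⟨(pred − target)² / d̄(|i−j|)⟩, with d̄(k) the target's mean at genomic
distance k — without this scaling the strong near-diagonal signal dominates
the fit.  A chemical potential H_λ = λ·(number of colored beads) penalizes
complexity.  Before optimization the target is normalized by its masked
mean (config flag), making λ's scale comparable across count depths, and
the prediction is aligned to the target by the least-squares scalar on the
evaluated mask (counts and probabilities live on different scales).  The
main diagonal is always excluded, and the 70/30 train/test split is over
unique upper-triangle elements.

The forward map is a mean-field template superposition calibrated on the
simulator once per chain-length class: p₀(k) is the colorless-chain contact
decay, φ(k) the excess contact of a fully bound single-color chain in the
globule state, and P(i,j) = clip(p₀ + s·φ, 0, 1) with s(i,j) the
shared-color bead-pair fraction between windows.  This is the module's core
approximation; the test suite validates it against direct simulation of a
half-colored 50-bead chain (pattern correlation ≥ 0.9).

Annealing uses geometric cooling (factor 0.97/sweep, 400 sweeps) from a
temperature set so initial uphill acceptance is ≈ 50% (T₀ = mean|ΔH|/ln 2
over probe moves).  Moves recolor a random bead to a random color including
color 0, so the λ penalty can actually decolor beads.  Each move updates the
masked sums incrementally in O(W); sums are refreshed every 50 sweeps
against float drift.

**Model selection.**  n\* minimizes the held-out cost; at desk scale the
rigid block forward map cannot chase element-level noise, so the test curve
is flat for n ≥ n_true and several n are statistical ties.  Ties (means
within 10% of the minimum, the run-to-run noise scale) break toward smaller
n, larger λ and smaller r — parsimony — and any tie is reported as
ambiguous together with the tie set.  r\* is the smallest r within 5% of
the largest-r plateau.

## Single-molecule statistics

All matrices are at window resolution (bead chains reduce to per-window
centroids, mirroring probe-level imaging data); NaN entries are handled
pairwise-complete everywhere and the main diagonal never enters a
correlation.

**r′ (distance-corrected correlation)** subtracts each matrix's own
per-diagonal mean before the Pearson correlation, removing the generic
decay with genomic separation.  It is exactly invariant under per-diagonal
additive shifts of either matrix.

**Separation score.**  At window i, segments L = [i−su, i) and
R = [i, i+sl); the score is median(intra-L ∪ intra-R) / median(cross L–R)
pairwise distances.  Distances are first decay-normalized (each element
divided by its diagonal's median within the same matrix): on raw distances
a random coil scores ≈ 0.5 simply because intra pairs span shorter genomic
separations than cross pairs, and the genome mean *rises* upon collapse —
the opposite of the behavior the score must capture.  Decay-normalized, a
coil profile is flat at ≈ 1 and segregated globules dip below 1 at their
junctions.  Positions whose segments would be clipped by the locus ends are
undefined (clipped segments score systematically low and fake boundaries).
`decay_correct=False` recovers the raw variant.

**Boundary calling.**  Boundaries are local minima of the separation
profile with at least `valley` bins between calls, `gb` edge bins excluded,
and minimum prominence 0.2 (junction dips in segregated states have
prominence ≳ 1; profile wiggles from overlapping junction tails stay below
≈ 0.1).  Undefined bins are filled by nearest-neighbour padding before peak
finding — a high sentinel would hand dips near the defined-region edge an
artificial cliff of prominence.  Call strength is the mean of the two
flanking profile maxima over the minimum (≥ 1 by construction).  Boundary
probability is the per-window call frequency across molecules, smoothed
with a two-point running average.  The segment-size/valley semantics are
this package's operationalization of the imaging-analysis parameters
(gb/valley/su/sl); the two printed settings (experimental gb=1, valley=1,
su=10, sl=6; model gb=1, valley=4, su=5, sl=5) are shipped as presets.

**Structural matching.**  Kabsch RMSD uses centering, unit-scale
normalization and the SVD rotation constrained to det = +1 (no reflections:
chirality is physical).  Normalization is isotropic (division by the RMS
radius) rather than per-axis: per-axis standardization shears the cloud and
a rigidly rotated copy then cannot reach RMSD 0; per-axis remains available
via `per_axis=True`.  For cross-modality comparison (imaging nm vs model σ)
the scale-free form is the default.  For *state classification* of
same-unit structures the physical size is kept (`scale_normalize=False`):
after scale removal a smooth open coil drapes closer to any structure than
two independent dense globules sit to each other (index-matched deviations
inside a random-packed ball are diameter-scale), which systematically
misassigns globule queries — while size is precisely the order parameter
separating the states.

**Mixture decomposition.**  The coil weight of a two-state mixture is
fitted by resampling w-proportional mixtures of single-molecule distance
matrices (medians do not mix linearly, so no averaging of two state
medians), scoring each mixture median by r′ against the target, and taking
the argmax of the noisy unimodal objective after a 3-point moving average.
Several independent resamples per grid point (default 5 × 600 molecules)
control the noise of the median estimator.  A flat objective (ends and
interior within 0.05 of each other) is flagged as ambiguous.

**Time correlations.**  The persistence curve is the mean r′ between
distance matrices of the same molecule at increasing frame lags; residual
vectors are precomputed per frame (the per-diagonal subtraction factorizes).
Lag 0 is exactly 1.  The decay time is the first lag where 95% of the total
variation range (plateau = mean of the final 10% of lags) has been spanned;
the stretched-exponential fit f(t) = f∞ + (f₀−f∞)exp[−(t/τ_s)^β] is
reported separately and never feeds the decay time.

**Unit mapping.**  σ (nm) is calibrated by equating model and experimental
median gyration radii; the MD time unit is the Brownian time
τ = 6πησ³/(kBT) with the nucleoplasm viscosity η = 0.003 Pa·s and T = 310 K
by default (the temperature only enters this conversion; kBT = 1 in reduced
units).  Molar concentration is c = P/(V·N_A); conversions round-trip to
1e−12 relative.

## Synthetic data

Ground-truth colorings place each color in a successive genomic region with
trapezoidal tails; the tail width is searched so that the realized
between-color window overlap hits a requested target (feasible ranges grow
with beads-per-window r — with r = 1 domains are disjoint by construction
and only 0% is feasible).  The block-copolymer control has contiguous
blocks and exactly zero between-color overlap.  Synthetic contact maps are
element-wise Poisson draws with mean depth × probability (the standard count
noise model), mirrored for exact symmetry.  Imaging emulation scales window
centroids to nm, adds isotropic Gaussian localization noise and drops whole
probes per molecule to NaN — per-probe, as tracing experiments lose probes,
not per-element.  Binding-site bootstraps resample each color's window
positions with replacement, preserving per-color site counts; replicates
are occupancy-count profiles (resampling ignores the per-window capacity)
and feed the overlap and track-correlation controls.

**What the fixtures do not show.**  The synthetic study stands in for bulk
Hi-C and chromatin tracing of real loci: it has no mappability or
normalization artifacts, no microscopy drift, exact Poisson noise, and
chains of 36–100 beads instead of 650–830.  Passing tests establish that
each operation implements its definition and that the method chain recovers
planted structure under those conditions — not that the biological
conclusions transfer, and not at the published loci's scale.

## Problem sizes and known limitations

Desk-scale sizes used by the tests and the acceptance script: 60-window
inference fixtures at Poisson depth 10⁴; a 100-bead two-color chain
(interleaved 25-bead blocks — cognate blocks must bridge across the chain,
keeping the two color globules adjacent yet demixed) scanned over 8
concentrations in 0–0.35 µmol/l with 32 molecules per point; 260-molecule
state pools of a 40-window chain; six 70-frame trajectories per state of a
36-window chain.

Limitations:

* The ensemble-mean Rg drop across the transition is 37–43% depending on
  the seed: the un-nucleated coil fraction of open-start supra-threshold
  ensembles keeps the ensemble floor at rg_norm ≈ 0.60–0.65 even though
  individual collapsed chains reach 0.42–0.55.  Equilibrium-grade sampling
  of the bistable region (e.g. replica exchange over an affinity ladder)
  would sharpen this but is outside the desk budget.
* The mean-field forward map ignores color–color competition and many-body
  saturation; it is validated only at the pattern level (correlation with
  direct simulation), not element-wise.
* MC kinetics are not physical dynamics; time correlations are meaningful
  through the equilibrium-fluctuation route (persistence of structure), and
  the absolute time mapping uses the Brownian-time convention only.
* The effective SAW exponent of short chains sits near the top of the
  plain-fit window (≈ 0.62 ± 0.01); fits including corrections to scaling
  are too unstable with four chain lengths to improve on this.
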