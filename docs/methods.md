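# Methods

This note records the models implemented in `rhpkit`, the defaults and
why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that matter for reproducing results.

## Pseudo-residue alphabet and HLB tables

Sequences are reduced onto four classes: hydrophilic (P), hydrophobic
(H), very hydrophobic (V) and charged (C). The amino-acid assignment
shipped as the `amino-acid` preset is

    C = {D, E, K, R}   V = {F, I, L, V, W, M}
    H = {A, C, G, P, Y}   P = {S, T, N, Q, H}

Charged is defined as the four ionizable residues D/E/K/R; the V/H/P
split follows a standard side-chain hydrophobicity ordering. Both maps
and all HLB tables are plain two-column text configs, so a user with a
different published assignment can substitute it without code changes.
Non-canonical amino-acid codes (B, Z, X, U, O) are rejected rather than
guessed at.

The six methacrylate monomers (`monomer` preset) map as MMA→H, EHMA→V,
OEGMA300/OEGMA500→P, SPMA/DMAEMA→C. Per-monomer HLB defaults follow
Griffin's formula HLB = 20·(hydrophilic-portion mass / molar mass)
with hydrophilic-portion masses estimated from the monomer structures
(ester oxygen content, oligo-ethylene-glycol side chains, ionic
groups): EHMA 4.4, MMA 8.8, OEGMA300 15.3, OEGMA500 17.2, DMAEMA 17.5,
SPMA 19.0. Griffin's formula is not strictly valid for ionic monomers,
so the charged values are effective numbers placed above the nonionic
ones; every pipeline property exercised here needs only that the scale
is monotone in hydrophilicity. Amino-acid HLB defaults are assigned per
class (C 19, P 15, H 9, V 4) on the same 0–20 scale.

## Windowing

Windows are 50 residues wide with a 15-residue step (both
configurable), 0-based and half-open. A sequence shorter than one
window yields nothing (logged); trailing residues not covered by a full
window are dropped, keeping every model input exactly 50-mers. One-hot
encoding uses the fixed column order (P, H, V, C).

## Ensemble simulation

Chains grow under terminal-model kinetics: from a chain ending in
monomer *i*, the next monomer is *j* with probability
(f_j/r_ij)/Σ_k(f_k/r_ik), where f are the instantaneous feed fractions
and r_ij = k_ii/k_ij. All chains share one finite monomer pool of
n_chains·dp/conversion units (integer-apportioned by largest
remainder), decremented after every addition; chains are advanced one
at a time in uniformly random order so all chains sample the same
conversion trajectory — growing chains to completion sequentially would
give early chains a systematically richer feed. The first unit of each
chain is drawn from the current feed. A monomer with less than one
whole unit left is unavailable (probability zero), mirroring monomer
exhaustion in a batch.

Defaults: DP 50, conversion 1.0 (batch to completion), all reactivity
ratios 1 (ideal copolymerization; experimentally determined matrices
can be supplied per monomer pair). Ensembles default to 2,000 chains,
with uniform subsampling when more are generated. One seeded generator
drives a run; the seed is recorded in the ensemble header.

Two statistical subtleties matter when testing the simulator against
the Mayo–Lewis closed form. First, because initiation draws from the
feed rather than the terminal-model stationary composition, full-chain
compositions carry an O((f1−F1)/DP) transient; instantaneous
composition is estimated from positions past a 5-unit burn-in. Second,
at finite conversion the expected batch composition is the
conversion-average of F1 along the drifting feed (Skeist relation), not
F1 at the initial feed; at 2% conversion the difference is below 0.002
but already resolvable at 5,000 chains. The test oracles account for
both effects exactly. Similarly, maximal runs ("blocks") inside
fixed-length chains are size-biased short relative to the
unconstrained geometric distribution — a long draw is likelier to
overrun the chain end — so run-length tests compare against exact
enumeration/renewal-recursion values rather than 1/(1−p).

## Latent model

The model is an autoencoder with a regression side-branch. Encoder:
200 → 256 → 128 → 64 → 16 (ReLU, linear latent). Decoder: mirror image
with per-output sigmoid; outputs are independent per-position,
per-class probabilities (rows are deliberately not normalized), and
reconstruction reads out by per-position argmax. Regressor:
16 → 16 → 16 → 1 (ReLU, linear output) predicting the window's mean
HLB. The loss is element-wise binary cross-entropy summed over the
50×4 outputs plus λ times the squared HLB error, averaged over the
batch; λ defaults to 1 and is exposed everywhere. Training both heads
jointly forces the 16-d latent space to encode the sequential
arrangement (needed for reconstruction) and the segmental
hydrophobicity (needed for regression).

Optimization: Adam at 1e-3, batch 256, 50 epochs by default, with the
learning rate halved when the validation total loss has not improved
for 5 epochs. The split is 90/10, seeded, stratified by source family
when families are given. The network is implemented directly in numpy
with explicit backprop; at these sizes that keeps training
bit-reproducible for a fixed seed on a single CPU, which the
reproducibility guarantees rely on. Desk-scale defaults (hundreds of
sequences, tens of epochs) replace the million-window corpora a
production run would use; the synthetic families below are the training
data for all tests.

## PCA, densities and overlap

PCA is fitted on a reference embedding set only — by design the
(synthetic-)protein windows — and every polymer ensemble is projected
into that fixed basis, so comparisons share one coordinate system. Two
sign conventions make the axes interpretable and deterministic: PC1 is
flipped if needed so its correlation with predicted HLB is ≥ 0 (more
hydrophobic segments at lower PC1), PC2 so its skewness over the
reference scores is ≥ 0.

Densities use Gaussian KDE with Scott's-rule bandwidth per ensemble, on
a shared 256×256 grid covering the union bounding box padded by three
pooled bandwidths; 2D grids and both marginals are renormalized to sum
to one. Ensemble similarity is the Bhattacharyya coefficient
Σ√(p·q)·cell over the shared grid — bounded, symmetric, 1 iff
identical. This coefficient is this package's own quantification of
"overlap"; upstream discussion of ensemble overlap is qualitative.
"Occupied area" is the area of the 95% highest-density region, and the
convergence analysis reports the smallest nested subsample whose area
is within 5% of the largest-n area.

## Biophysical calculators

* **Collision kinetics**: k_on = 4πDr with D in µm²/s, r in nm,
  converted to M⁻¹s⁻¹ via N_A·10⁻¹⁵ l/µm³; dn/dt = k_on·c∞/M.
* **Overlap concentration**: c* = 3M/(4πN_A R_g³), reported in g/cm³
  and wt% at a configurable solution density (default 1 g/cm³). R_g is
  taken exactly as given: the 17 wt% reference value corresponds to
  using the 4.4 nm sphere radius (half the SAXS-fitted 8.8 nm diameter)
  directly, not the sphere-equivalent R_g = R√(3/5).
* **Guinier fit**: linear least squares of ln I on q², slope −R_g²/3,
  with the range iteratively re-trimmed to q·R_g ≤ 1.3 until stable
  (standard practice). A non-negative slope is an error.
* **HLB profile**: centred sliding window (default 5 units), clipped at
  chain ends, so the profile has the chain's length.
* **WLC**: Marko–Siggia interpolation
  F = (k_BT/Lp)[1/(4(1−ξ)²) − 1/4 + ξ] with ξ = x/Lc − F/K, solved by
  damped fixed-point iteration to 1e-6 pN; K = ∞ recovers the
  inextensible form. Unfolding work integrates (F_pull − F_baseline) by
  the trapezoid rule after linear interpolation onto the union grid of
  the shared extension range; 1 kcal/mol = 6.95 pN·nm (3 s.f.). Rip
  detection (force drop > 1 pN within < 5 nm) is descriptive, not a
  calibrated classifier.
* **FRAP**: with r = I_b/I_u, the recovery
  R(t) = (r_after(t) − r_after(0))/(r_before − r_after(0)) starts at 0
  by construction and is fitted to R = A(1 − e^(−t/τ)) by nonlinear
  least squares, A bounded in [0, 1.5], τ > 0. The decaying-exponent
  sign is used throughout (the growing form is not a recovery). When a
  trace shows no recovery the fit is degenerate in τ; A is then the
  meaningful (near-zero) quantity.

## Synthetic data

Families are realizations of a semi-Markov run-length process: a class
is drawn from stationary frequencies, then a geometric run length with
that class's configured mean, with no immediate class repeats. The
run-length structure was chosen over i.i.d. letters so the data contain
a genuine block-arrangement (PC2-type) signal. The benchmark pair:
membrane-like (P/H/V/C frequencies 0.20/0.20/0.50/0.10, mean V-block 8)
versus globular-like (0.35/0.25/0.15/0.25, mean blocks ≈ 2), 400
sequences of 80–300 residues per family by default — sized so the full
train-project-compare pipeline runs in minutes on one CPU. These
families caricature the hydrophobic-block contrast between membrane
and globular proteins; they do not mimic real topology, composition
bias, or evolutionary correlation, so passing tests demonstrate that
the pipeline resolves block statistics and hydrophobicity, not that it
reproduces any real protein map.

Curve generators are exact forward models of their fitters (Guinier
exponential, exponential recovery, WLC with an optional rectangular
force excess) plus stated Gaussian noise, with ground truth returned
alongside — each (generator, fitter) pair is a closed parameter-recovery
loop.

## Known limitations

* Reactivity ratios default to ideal (all 1); quantitative drift for a
  specific chemistry requires the experimentally determined matrix.
* The residue→class map and HLB tables are documented surrogates,
  configurable but not the exact published tables.
* The latent model is desk-scale; embeddings from different training
  runs are not comparable, and the PCA basis must come from the same
  model that embeds the ensembles being compared.
* Penultimate-model kinetics, molecular-weight dispersity, 2- or
  8-class alphabets, and sphere-form-factor SAXS fitting are out of
  scope.
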