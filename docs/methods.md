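# Methods

This note documents the models and numerical procedures implemented in
`writhekit`, the choices made where the design was genuinely open, and what
the synthetic test ensembles do and do not establish about real data.

## Discrete writhe

For a smooth curve r(s), the writhe is the Gauss double integral of the
normalized triple product (T(s₁) × T(s₂)) · (r(s₂) − r(s₁)) / ‖…‖³ over all
point pairs, divided by 4π.  For an open polymer chain traced through one
backbone atom per residue (Cα by default), we approximate the curve by
straight segments connecting atom a to atom a + l; the *segment length* l
controls the smoothing scale of the description (l = 1 is the virtual-bond
chain; larger l suppresses local-structure signal in favour of global
topology).

For two straight segments the double integral has a closed form: the signed
solid angle Ω of the spherical quadrilateral whose vertices are the four
unit view directions between segment endpoints.  Each unordered segment
pair contributes Ω/2π, and the sum over pairs reproduces the quadrature of
the Gauss integral on the discretized curve.  We evaluate the solid angle
with the standard four-arcsine formula, with every arcsine argument clamped
to [−1, 1].

Conventions and guards:

* **Sign.** The crossing sign is sign((Tᵢ × Tⱼ) · (midⱼ − midᵢ)).  Because
  the component of the inter-segment displacement along Tᵢ × Tⱼ is constant
  over the pair, any reference points on the two segments give the same
  sign; we use midpoints.  The quadrature oracle integrates
  (T(s₁) × T(s₂)) · (r(s₂) − r(s₁)), which matches this sign convention.
  Under this convention a right-handed α-helical Cα fragment has negative
  total writhe; the mirror image has the opposite sign, exactly.
* **Exclusions.** Segment pairs sharing an endpoint atom have a singular
  integrand; they are recorded as structural zeros with an exclusion mask
  (|i − j| ∈ {0, l}).  Open chains are never virtually closed.
* **Degeneracy.** Inter-endpoint distances below 1e−8 Å raise a
  degenerate-geometry error naming frame and pair.
* **Precision.** Double precision throughout the core.  Symmetry contracts:
  proper rotations/translations change no entry by more than 1e−10; mirror
  reflection negates every entry to rounding.

Two independent oracles check the implementation: a brute-force midpoint
quadrature of the Gauss integral (self-converging on smooth curves, ≤ 1e−3
agreement with the 400-segment discrete sum on a helix), and the Hopf link,
whose cross-curve pair sum must equal 2 × (linking number) = ±2 to 1e−9 at
any polygon resolution ≥ 16.

## Segment-to-atom writhe map ("writhe-graph Laplacian")

The score network needs writhe features indexed by *atom* pairs.  We map
the segment-pair writhe matrix to atom pairs by incidence averaging:
w_{ij} = Σ_{s∋i, t∋j} wm_{st} / (deg_i · deg_j), where s ∋ i means atom i
lies on the span [s, s+l] of segment s.  The map is linear, hence
parity-preserving and zero-preserving, and a constant matrix maps to that
constant on fully incident atom pairs.  Crossing-normal pseudovectors are
aggregated to atom pairs by the same incidence rule (averaging the
unnormalized cross products, then renormalizing; pairs whose aggregate is
shorter than 1e−8 are flagged undefined).  **This aggregation rule is this
package's own design choice** — it is one natural normalization of the
segment-atom incidence graph, and other choices are possible; all parity
and equivariance contracts hold for any linear incidence weighting.

## Feature families and their parity

* Multiscale writhe descriptors: the non-excluded upper triangle of the
  writhe matrix per segment length, concatenated in ascending l.
  Parity-odd.
* Euclidean Cα–Cα distances, all pairs by default (a minimum sequence
  separation is optional and recorded in the labels).  Parity-even: a
  structure and its mirror image have identical distance features, which is
  the reason distance-based models cannot see chirality.
* Backbone dihedral sin/cos (φ, ψ) for interior residues, full N/CA/C
  input required, IUPAC sign convention (cross-checked against mdtraj).
  Sines parity-odd, cosines parity-even.

Per-feature integrated autocorrelation times use the FFT autocorrelation
with initial-positive-sequence truncation (sum acf(k) until the first
negative value): parameter-free and standard.  Constant features are
flagged NaN rather than raised.

## Time-lagged CCA, kinetic variance, tICA

tCCA whitens the instantaneous and lagged covariances (separate means, as
the covariance definitions require) and takes the SVD of
C_X^{−1/2} C_XY C_Y^{−1/2}.  Singular values are autocorrelations of the
canonical coordinates; the kinetic variance Σσᵢ² (the squared Frobenius
norm of the whitened correlation matrix) is the VAMP-2 score used to rank
feature sets.  Numerical policy: relative diagonal shrinkage
ε · trace/d (default ε = 1e−10) before inversion; whitener spectrum
truncated at 1e−8 of its largest eigenvalue; zero-variance features removed
with a warning and re-embedded as zero rows so labels stay aligned.  Lagged
pairs never straddle trajectory boundaries.  tICA solves the generalized
symmetric eigenproblem ½(C_XY + C_YX)V = CVΛ against the full-data
covariance; for reversible data its eigenvalues coincide with the tCCA
singular values, and symmetrization discards irreversible correlation
(eigenvalues ≤ singular values), both asserted in tests.

## Markov state models

* **Discretization**: scikit-learn K-means (k-means++, 10 restarts, fixed
  seed); silhouette scans subsample to 10,000 frames (seeded) to bound the
  O(n²) cost.
* **Estimation**: sliding-window counts at lag τ, restriction to the
  largest strongly connected component (by total counts), reversible
  maximum-likelihood transition matrix via the self-consistent fixed-point
  iteration on symmetric edge weights, converged to 1e−10.  The stationary
  distribution is the normalized row sum of the converged weights.
* **Validation**: implied timescales t_i = −τ/ln λ_i with a convergence
  flag (relative change < 10% over the last three lags — the plateau
  criterion is this package's quantification of "converged"); the
  Chapman-Kolmogorov test compares T(τ)^k with T(kτ) aggregated over
  metastable sets with stationary weighting; 5-fold cross-validated VAMP-2
  scores use contiguous time blocks (never frame-shuffled, to respect
  autocorrelation), with the trained discretization's indicator functions
  scored on held-out pairs.
* **Coarse-graining**: PCCA-style spectral simplex transformation of the
  leading m right eigenvectors (π-weighted symmetrization for numerics),
  vertices by farthest-point search, memberships clipped nonnegative and
  renormalized.  Degenerate eigenvalues at the cut raise an error advising
  a different m.
* **TPT**: forward/backward committors by linear solves (backward via the
  time-reversed chain), gross flux f_ij = π_i q⁻_i T_ij q⁺_j, net flux
  max(0, f − fᵀ), MFPT by the first-step linear system, π-weighted over the
  source set, reported in lag units and physical time.
* **Uncertainty**: percentile bootstrap over trajectories, or over
  contiguous blocks of a single trajectory (default 10 blocks; coverage
  improves with more blocks and the tests use 50).  This replaces a
  Bayesian transition-matrix posterior; it is simpler, and its coverage is
  verified by simulation in the test suite.

## Equivariant score network and diffusion model

The generative model is a denoising diffusion model over one-bead-per-
residue coordinates with a polarizable message-passing score network.
Nodes carry invariant scalars s_i (initialized from a learned per-residue
embedding plus a diffusion-time embedding) and equivariant vector channels
v_i (initialized to zero).  Edges (fully connected for the small chains
used here; a distance cutoff is available for longer chains) carry the
displacement direction r̂_ij, the distance embedded with sin+cos sinusoids
φ±, and — in the writhe-augmented variant — the atom-level writhe w_ij
embedded with *sine-only* sinusoids φ− (odd functions, so the embedding
preserves the feature's odd parity) together with the crossing-normal
pseudovector ŵ_ij.  Message residuals are continuous-filter convolutions:
Δs_i sums φ_s(s_j) ∘ φ_s′(z_ij) over neighbours; Δv_i sums three gated
terms (v_j, r̂_ij, ŵ_ij), each gate a Hadamard product of an MLP of s_j
and an MLP of z_ij.  Update blocks mix scalar and vector channels through
norm gating and contain no writhe terms.  Ablating the writhe channels
yields a strictly parity-symmetric (E(3)) network: its score, and hence its
sampled distribution, is exactly mirror-symmetric.  With writhe channels
the network is equivariant under proper rotations/translations only, which
is the symmetry class a chiral ensemble requires.  In the comparison
protocol the ablated baseline keeps the same total edge-embedding width
(its distance embedding is widened by the number of channels the writhe
embedding would occupy), so the contrast isolates parity information
rather than raw capacity.

Choices that were open and how they were fixed:

* **Noise schedule**: variance-preserving SDE with linear β ramp,
  β ∈ [0.1, 20], horizon 1; prior = isotropic Gaussian on mean-centered
  coordinates.  Coordinates are globally centered and scaled to unit
  standard deviation for training.
* **Parametrization**: the head predicts the denoised structure as a
  residual on the noised input (x̂₀ = x_t + net(x_t, t)); this is much
  better conditioned near t → 0 for sharply peaked ensembles than noise
  prediction, which is also available.  The training loss is the x₀
  residual error weighted by the truncated signal-to-noise ratio
  min(α²/σ², 5)/5 — the un-truncated weight recovers the noise-prediction
  objective exactly.
* **Time conditioning**: the network conditions on the normalized log-SNR
  of the schedule rather than raw t, which resolves the low-noise regime
  where distributional detail forms.
* **Encoding length scales**: distances use L = 40 Å (spanning the extent
  of the chains modelled here); writhe uses L = 1 (writhe per pair is
  bounded below 1 by construction); log-SNR uses L = 1 after scaling.
* **Edge recomputation**: writhe and crossing-normal features are functions
  of the *current* (noised) coordinates and are recomputed at every
  diffusion step, exactly like distances.
* **Optimization**: Adam with cosine learning-rate decay and an exponential
  moving average of the weights (decay 0.98–0.99) used for sampling;
  training and sampling are deterministic given seeds.
* **Sampling**: probability-flow ODE (Heun, quadratically spaced steps
  concentrated near t = 0) or reverse-SDE Euler–Maruyama, optionally with
  annealed-Langevin corrector steps applied at low noise levels (where the
  learned score is most accurate; step size set by a target
  signal-to-noise ratio of 0.15) and a final denoising jump to the
  predicted clean structure.  In our experiments the stochastic sampler
  with correctors gives the best distributional coverage for sharply
  peaked targets; all variants are exposed.
* **Precision**: the autodiff engine runs in single precision (equivariance
  tolerances 1e−4); the writhe features feeding it are computed in double.

The network runs on a small tape-based reverse-mode autodiff engine written
for this package (numpy arrays; gather/scatter and channel-mixing ops for
graph message passing).  Gradients are exact to finite-difference checks;
rotation equivariance of the assembled network holds to single-precision
rounding.

## Synthetic ensembles

* **Chiral helical ensemble**: each frame is an α-helix-like Cα fragment
  (3.8 Å virtual bonds, 100° turn, 1.5 Å rise, radius solved for exact
  bond length) in one of its two mirror forms, the negative-writhe form
  drawn with probability p (default 0.8), plus isotropic Gaussian jitter
  (σ = 0.3 Å) and a random global rotation.  This emulates an ensemble
  with asymmetric populations of positive and negative chain crossings.
* **Two-state switching polymer**: a hairpin-like loop with a single
  crossing and its exact mirror image, switching by a hidden two-state
  Markov chain with per-frame rates k₁₂, k₂₁ (slow relaxation time
  −1/ln(1 − k₁₂ − k₂₁) frames).  Because the states are mirror images,
  every Euclidean distance is statistically identical between them: the
  transition is invisible to parity-even features and fully visible to
  writhe.  This is the desk-scale analogue of comparing writhe-based and
  distance-based kinetic models.
* **Canonical curves**: helices (writhe known by quadrature), circles and
  planar zig-zags (writhe 0), and a polygonal Hopf link (cross-curve sum
  ±2 exactly).

What these fixtures do *not* establish: the ensembles are rigid templates
with Gaussian jitter and memoryless switching — they have none of the
continuous conformational heterogeneity, multi-scale barriers, or
solvent-mediated dynamics of real disordered-protein trajectories.
Passing the tests demonstrates the correctness of the machinery and the
parity argument (distances blind to mirror transitions, writhe not), not
the field performance of the method on molecular simulations.

## Problem sizes

Test and reproduction runs are sized for a single CPU: chiral ensembles of
1,200 frames of 10 beads for generative training (networks of 3
message-passing layers and 32 hidden channels, with the writhe-augmented
model and its ablated baseline given identical training budgets — the
architecture scales to the 8-layer/64-channel configuration appropriate
for real-data work), switching polymers of eight independent 4,000-frame
trajectories for kinetic recovery (independent realizations let the
trajectory bootstrap capture between-realization variance of the realized
kinetics around the analytic relaxation time), and AR(1) series of 10⁵
steps for tCCA calibration.  Bootstrap uncertainty uses 200–1,000
replicates depending on context.
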