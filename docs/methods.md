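# Methods

## Model

A sample is a point of the Grassmann manifold 𝒢(p, D): a p-dimensional
subspace of ℝ^D, represented by any D×p matrix X with orthonormal
columns.  Two bases related by a right p×p orthogonal factor are the
same point, and every operation in the package is invariant to that
choice.  The geometry used throughout is the projection embedding
Π(X) = XXᵀ and the projection metric δ_P(X₁, X₂) = ½‖Π(X₁) − Π(X₂)‖²_F,
a squared chordal distance that approximates the geodesic arc-length
distance and, unlike it, admits a closed-form mean.  Internally δ_P is
evaluated as p − ‖X₁ᵀX₂‖²_F (an exact algebraic identity, O(Dp²) instead
of O(D²p)); a test asserts the identity against the dense form.  The
factor ½ is kept as part of the metric's definition; it cancels from
every ratio and ranking the package computes.

The Fréchet mean of {Xᵢ} under δ_P — the minimizer of Σᵢ δ_P(Xᵢ, M) —
is spanned by the top-p eigenvectors of Σᵢ XᵢXᵢᵀ.  It is computed from
the SVD of the horizontally stacked bases when np ≤ D and from a D×D
eigendecomposition otherwise.  When eigenvalues p and p+1 tie (relative
gap ≤ 1e-8) the mean is only defined up to the tied directions; a
RuntimeWarning is emitted and the solver's eigenvector order breaks the
tie — ties are a measure-zero event and the mean is genuinely non-unique
there.

## The FMGDA learner

Given labeled points, FMGDA learns A ∈ ℝ^{D×d}, p ≤ d < D, mapping X to
f(X, A) = the orthonormalized columns of AᵀX.  AᵀX itself is generally
not orthonormal; following the QR route, AᵀX = Q_x R_x gives the valid
representative Q_x = AᵀX′ with X′ = X R_x⁻¹.  With class Fréchet means
M⁽ᵏ⁾ and global mean M, the objective is the ratio of between- to
within-class spread in the reduced manifold,

    d_b(A) = Σ_k n_k δ_P(f(M⁽ᵏ⁾,A), f(M,A)),
    d_w(A) = Σ_k Σ_i w_k δ_P(f(Xᵢ⁽ᵏ⁾,A), f(M⁽ᵏ⁾,A)).

The default within-class weight is w_k = n_k inside the double sum
(`within_weighting="classwise"`); `"uniform"` switches to w_k = 1, the
classical LDA convention.  The class-weighted form is the method's
stated definition and stays the default; the flag is the documented
escape hatch, and both conventions share all code paths and tests.

Optimization alternates two steps:

1. **Surrogate construction.**  With all QR normalizations frozen at the
   current A, d_b and d_w become quadratics tr(AᵀB̃A), tr(AᵀQ̃A) with
   B̃ = Σ_k n_k B⁽ᵏ⁾AAᵀB⁽ᵏ⁾, B⁽ᵏ⁾ = M′⁽ᵏ⁾M′⁽ᵏ⁾ᵀ − M′M′ᵀ, and
   Q̃ = Σ_k Σ_i w_k Q_ik AAᵀQ_ik, Q_ik = Xᵢ′⁽ᵏ⁾Xᵢ′⁽ᵏ⁾ᵀ − M′⁽ᵏ⁾M′⁽ᵏ⁾ᵀ.
   Each summand is (SA)(SA)ᵀ for symmetric S, so both matrices are
   assembled from stacked low-rank factors (one GEMM) rather than dense
   D×D products per point, then symmetrized ((S+Sᵀ)/2) for numerical
   hygiene.  At A = A_prev the surrogate ratio equals the exact d_b/d_w
   to machine precision (asserted at 1e-8 relative).

2. **Trace-ratio solve.**  max_A tr(AᵀB̃A)/tr(AᵀQ̃A) over orthonormal A
   by the standard iteration λ ← ratio(A); A ← top-d eigenvectors of
   B̃ − λQ̃, which produces a non-decreasing λ sequence.  Inner stopping:
   |Δλ| < 1e-8 (relative), at most 50 iterations.

The outer loop re-evaluates the *exact* objective after each solve and
stops on relative change < 1e-6, after 20 iterations, or when d_w → 0.
These stopping rules are standard for trace-ratio solvers; nothing in
the method prescribes specific values.  Diagnostics (objective per outer
iteration, λ per inner iteration) are kept on the model and exportable
as CSV.

Numerical guards, all in the code and exercised by tests:

* **d_w → 0** (perfectly collapsed classes): if tr(AᵀQ̃A) < 1e-12 the
  ridge εI is added to Q̃ with ε = 1e-10·tr(Q̃)/D (ε = 1e-10 when Q̃ = 0);
  an infinite exact objective stops the outer loop.
* **Rank-deficient reduced bases**: on (near-)separable data the solver
  can drift to a mapping annihilating part of a class subspace, making
  some AᵀX rank-deficient.  The fit then stops with a warning and keeps
  the last evaluable mapping.  `transform` itself raises on
  rank-deficient AᵀX, as a mapped point would be ill-defined.
* **Initialization**: first d coordinate axes by default (deterministic,
  reproducible); a seeded random orthonormal start is available.  The
  trace-ratio solver happens to return orthonormal A, but the QR
  normalization is applied to every product AᵀX regardless, so the code
  is correct for any full-rank A.
* QR sign convention: diag(R) ≥ 0 everywhere, making every orthonormal
  factor a deterministic function of its input; SVD bases get an
  analogous largest-entry-positive convention.  Orthonormality is
  validated at 1e-8 Frobenius (double-precision QR/eig noise is ~1e-14).

The exact objective is *not* guaranteed monotone across outer iterations
— the surrogate majorizes nothing once the frozen normalizations go
stale — and at near-zero noise it can dip below its initial value while
classification stays perfect.  At moderate noise the ascent property
holds empirically and is asserted on generated data.

A small classical-LDA solver (`euclidean_lda_reference`, generalized
eigenproblem S_b a = λ S_t a with pseudo-inverse fallback) is included
purely as a Euclidean sanity oracle for the trace-ratio machinery.

## EEG front-end

The reader consumes the Bonn archive layout: folders Z/O/N/F/S (groups
A–E), ASCII files of one integer sample per line, 173.61 Hz.  Per
recording: sub-epochs of 512 samples with hop 512 (M = 8 windows from a
4097-sample segment; the method's source never states the epoching, and
eight frames per "clip" mirrors typical image-set sizes); per sub-epoch
a Hann STFT with window 128, overlap 64, FFT 128, no boundary padding
(m = 7 frames × n = 65 bins), magnitude-squared and log-compressed with
floor ε = 1e-12.  The M spectrograms are vectorized column-major
(fixed and documented — any fixed order works, mixing orders breaks
comparability), stacked as columns of Y, and the top-p left singular
vectors of Y give the recording's point in 𝒢(p, m·n).  Default p = 5;
optional block-average resizing reduces m·n when the STFT geometry would
make D unwieldy.  With the defaults D = 455.

Note p must not exceed the smallest target dimension of an experiment
grid; `run_grid` refuses p > min(dims) before any fitting, so grids that
include d = 4 need p ≤ 4 features.

## Classification and experiment grids

1-NN (k configurable) under δ_P; ties broken by majority, then smallest
summed distance among the k neighbours, then lowest label id.  Splits
are stratified per class — round-half-up of ratio·n_k training items,
sampled without replacement, deterministic per seed.  A grid runs
ratios × dims × repeats; splits are shared across dims within one
(ratio, repeat) so dimensions are compared on identical data, and one
round per ratio with 10 repeats each is the default protocol.  The mean
table (rows = ratio, columns = dim) and raw per-repeat records export to
CSV; a no-reduction 1-NN baseline per split is recorded alongside.

## Synthetic generators

**Grassmann class clouds.**  K prototype subspaces drawn as QR factors
of Gaussian matrices, redrawn (≤ 200 attempts) until pairwise δ_P meets
`prototype_separation`; members are orthonormalize(prototype + σ·G) for
standard normal G — a simple perturbation that spans the manifold
locally without exact tangent-space sampling, which fixtures do not
need.  Maximal separation (= p) cannot be hit by rejection, so when
requested (and K·p ≤ D) prototypes are built as disjoint column blocks
of one random orthonormal matrix.  Defaults K=3, 30/class, D=40, p=5,
σ=0.05 — the recovery study's conditions.

**Synthetic EEG.**  Five Bonn-analogue classes with disjoint dominant
bands — A: 8–13 Hz, B: 14–20 Hz, C: 2–6 Hz, D: 25–35 Hz, E: 40–55 Hz at
1.5× power plus a 6 /s Poisson train of high-amplitude biphasic pulses
(the broadband ictal signature) and 1.5× noise.  Band components are
built in the frequency domain (unit magnitude, random phase on the
band's bins), so they are exactly band-limited; white Gaussian noise
(default SD 0.2 against unit-RMS bands) is added and everything scaled
to ADC-like integer amplitudes.  Segments default to 4097 samples at
173.61 Hz, 100 per class — the archive's shape.

What the generator does *not* emulate: 1/f background spectra,
non-stationarity within a segment, inter-subject variability,
artifacts, or any physiological waveform realism.  Bands were chosen
disjoint, so synthetic classes are far more spectrally separable than
the real groups; passing end-to-end tests demonstrates the pipeline's
correctness and its ability to recover *separable* class structure, not
the accuracy level attainable on real recordings, which overlap heavily
in spectrum and are far harder to separate.

## Problem sizes in tests and the acceptance script

Oracle and invariance checks run at D ≤ 9 with 10⁴-point grid /
10⁵-candidate Monte-Carlo oracles.  The recovery study uses the default
generator conditions (K=3, D=40, p=5, d=10, 30/class, 10 repeats, 50/50
splits).  The end-to-end EEG experiment uses 16–20 segments per group,
p = 4, spectrograms block-averaged to 7×13 (D = 91), and one repeat per
grid cell over the full 5-ratio × 14-dimension table — sizes chosen so
the whole study re-runs in well under a minute while every pipeline
stage is exercised at full structural fidelity.

## Known limitations

* The alternating optimization has no global convergence guarantee; the
  exact objective can decrease when classes are (near-)separable.
* The within-weighting ambiguity (n_k in the double sum) is resolved by
  a flag, not by evidence.
* Serialization is plain JSON — convenient and portable, not compact;
  very large feature sets are better regenerated than stored.
* Only the projection metric is implemented; arc-length, Binet–Cauchy
  and kernelized variants are out of scope, as are geodesics and
  exp/log maps.
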