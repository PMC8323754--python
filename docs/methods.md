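# Methods

## Model

The package works in the linear regime of neural field theory.  Activity
perturbations `Q(r, t)` about a steady state obey an integral equation
with a direct effective-connectivity (EC) kernel `Λ(r, r′, ω)`; in
discretized form on K surface points,

    Q(ω) = Λ̂(ω) Q(ω) + N(ω),       Λ̂[j, k] = Λ[j, k] · ΔS_k,

where `ΔS_k` is the surface area represented by point k.  Carrying the
area weights inside the matrices makes every matrix product a discrete
surface integral and every matrix dimensionless.  The transfer function
(total EC, Green function, evoked response) and white-drive cross-spectrum
follow as

    T̂ = (I − Λ̂)⁻¹,        Ĉ = T̂ T̂†.

Assumptions: linearity (valid for perturbations about the steady state),
time-invariant structure on the analysis timescale, symmetric connectivity
for all spectral decompositions (the asymmetric case needs spectral
factorization and is out of scope), and spatially uncorrelated white
background drive with normalization `N0` for the Ĉ = T̂T̂† identity.

For symmetric systems the three operators commute; eigenvalues satisfy
`θ_j = 1/(1 − λ_j)` and `κ_j = |θ_j|²`, and the shared eigenmodes `u_j`
are the basis for everything else: spectral reconstruction
`Ĉ = Σ_j κ_j u_j u_jᵀ diag(ΔS)`, the FC-similarity operator `Ŝ = Ĉ²`
(eigenvalues κ_j²), input inference `N = T̂⁻¹Q`, and EC-from-FC inversion
through `θ_j = +√κ_j` (the positive branch — correct for real symmetric
stable systems where all θ_j > 0; systems with λ_j > 1 are rejected as
unstable).

## Area-weighted inner product

Modes are orthonormal under `⟨f, g⟩ = Σ_k f_k g_k ΔS_k`, the discrete
surface integral, so `Uᵀ diag(ΔS) U = I`.  On a uniform grid this reduces
to plain orthonormality.  One consequence documented here because it is
easy to trip over: on a *nonuniform* grid the weighted matrix
`Ĉ = C_raw diag(ΔS)` of a symmetric kernel is not plainly symmetric.  The
covariance container therefore validates Hermitian-ness of the similarity
transform `W^{1/2} C_raw W^{1/2}` (plain Hermitian-ness on uniform grids),
and the eigendecomposition diagonalizes that symmetric matrix, giving
vectors that satisfy both `Ĉ u = κ u` and the weighted orthonormality.

Reproducibility conventions: eigenvalues sorted by descending |κ|
(ascending k² for geometric modes); each eigenvector's largest-magnitude
component is made positive; eigenvalue groups with relative gap below
1e-8 are flagged degenerate, and comparisons inside such groups must use
subspace projectors, not individual vectors.  Linear solves raise above
condition number 1e12 ("marginally stable") and warn above 1e8.

## Geometric eigenmodes

* **String** (pedagogical 1-D cortex): fixed ends give
  `u_j = √(2/L) sin(jπx/L)`, `ω_j = k_j v`; periodic boundaries give
  `k_j = 2πj/L` with sine/cosine pairs.  Standing waves equal half-sums of
  counter-propagating travelling waves, term by term.
* **Sphere**: a cortical hemisphere is topologically a sphere, so
  spherical harmonics `Y_lm` are the zeroth-order modes, with eigenvalues
  `k² = l(l+1)/R_s²` (m-degenerate) and `(l_max+1)²` modes through degree
  `l_max`.  The Condon–Shortley phase is included (scipy's convention);
  real modes are the standard cosine/sine combinations with the (−1)^m
  factors.  Quadrature is Gauss–Legendre in cos ϑ crossed with a uniform
  trapezoid in φ, with node counts chosen from a declared exact degree —
  2·l_max for orthonormality tests, 3·l_max for triple-product (Gaunt)
  oracles — so orthonormality holds to machine precision, not just to
  discretization error.
* **Triangle meshes** (convoluted-cortex stand-in): cotangent stiffness
  matrix with lumped (per-vertex area) mass matrix; generalized
  eigenproblem solved in shift-invert mode about zero.  On closed meshes
  the first mode is constant with eigenvalue ~0; on icospheres the
  spectrum converges to `l(l+1)/R²` with multiplicities 2l+1 (0.6% at
  subdivision 3, used by the tests as the 2% criterion with margin).
  Icospheres are generated by midpoint subdivision (10·4ⁿ+2 vertices,
  capped at n = 7 to bound memory); deformed spheres apply a radial field
  that is either a single harmonic band l′ (for selection-rule
  experiments; the reported band spectrum is computed by vertex-area
  quadrature) or a sum of localized Gaussian bumps.

## Temporal structure

Dispersion: `T(k, ω) = A(ω)/(v²(k² + q²(ω)))`.  The default local
dynamics is the damped-wave closure `q² = (γ_d − iω)²/v²`, chosen because
it is the minimal form that reduces to the undamped wave equation as
γ_d → 0; arbitrary polynomial or callable `q²` are accepted (polynomials
are solved exactly via companion matrices, callables by complex Newton
from a seed grid over a declared window).  Resonances solve
`k² + q²(ω) = 0`; for the default model, `ω = ±kv − iγ_d`.

Pole models represent a mode's response as `T(k_j, ω) = Σ_p r_jp/(ω −
ω_jp)`, `ω_jp = Ω_jp − iγ_jp`, γ > 0.  The Fourier convention is
physics-style (forward `e^{+iωt}`), making decaying responses
lower-half-plane poles with impulse response `h(τ) = −i Σ_p r_p
e^{−iω_pτ}` for τ ≥ 0.  Reality of `h` requires the partner pole at −Ω to
carry weight **−conj(r)** (and zero-frequency poles purely imaginary
weight); this follows from the closed-form transforms of the damped sine
and cosine oscillators and is cross-checked against an FFT inverse
transform in the tests.  Statements elsewhere that the partner weight is
the plain conjugate correspond to a different residue convention.

## Simulators (what the synthetic data emulate)

* `simulate_linear` realizes `Q(ω) = T̂(ω)N(ω)` exactly in the frequency
  domain with Gaussian white drive — no time-stepping error.  Twice the
  requested duration is synthesized and the first half discarded to
  remove FFT wrap-around.  Sample covariance converges to `T̂T̂†` as
  N^(−1/2).
* `impulse_response` synthesizes the Green function mode by mode,
  `T(r, r₀, τ) = Σ_j u_j(r) u_j(r₀) θ_j(τ)`, with θ_j from pole models.
* Two-mode beating: the lowest two nonuniform periodic-string modes with
  pole pairs at alpha-band frequencies (defaults ~10 Hz centers, ≤0.5 Hz
  half-splits, matching corticothalamic values).  The instantaneous and
  fast-averaged covariance kernels follow the unit-pole-amplitude
  normalization (the kernel of the full signal is 4× these values; the
  signal's coefficients are 2 sin Ωt cos Δωt).  The fast-averaged kernel
  `½u_j u_j′ cos²(Δω_j t)` additionally assumes distinct mode center
  frequencies so the cross term averages out — with equal centers the
  cross term is sin² and survives averaging; the oracle tests therefore
  use 10/15 Hz centers.
* Band-limited noise: white Gaussian spectra shaped by `|H(f)| =
  (1 + (f/f_c)⁸)^(−1/2)` (4th-order low-pass), with BOLD-like f_c =
  0.07 Hz and EEG-like f_c = 15 Hz presets.  The nominal correlation time
  is *derived from the declared spectrum* (first 1/e crossing of its
  cosine transform, ≈4.7 s for the BOLD preset) rather than asserted, and
  Monte-Carlo autocorrelations are checked against it within a factor of
  two.

What these generators do **not** emulate: hemodynamic forward modelling,
1/f backgrounds, nonstationary EC, motion/physiological artifacts, or
subject variability.  Passing tests therefore demonstrate correctness of
the algebra and estimators under the stated statistical model, not
robustness to real-data pathologies.

## Dynamic FC tracking

Mode coefficients are purely spatial projections, `c_j(t) = Σ_k u_j(r_k)
Q(r_k, t) ΔS_k`, with no temporal smoothing; with J modes ≪ K vertices
this suppresses fine-scale spatial noise (var c_j ≈ σ² Σ_k (u_j ΔS_k)²
for independent vertex noise) without blurring time.  Instantaneous
kernels `κ_j(τ, t) = c_j(t+τ)c_j(t)` (and the symmetric variant with
±τ/2) reconstruct rank-J instantaneous FC; explicit unit-integral windows
(boxcar default, Gaussian available) perform any desired averaging, with
truncating edge handling and reported effective sample counts.
Conventional sliding-window covariance (within-window mean subtraction by
default, the field convention) is provided for comparison, and window
lengths are classified into three regimes against a mode's fast period
2π/Ω and beat period 2π/|Δω|: (i) t_L ≥ F·beat (long-term mean
recovered), (iii) t_L ≤ fast (oscillation-resolved), (ii) in between
(beat/window interactions masquerade as FC dynamics).  The "much greater
than" of regime (i) is operationalized as F = 10, configurable, since no
universal factor exists.

Short-time Fourier kernels over the symmetric κ′_j use a configurable
taper (Hann default) — the trade-off between spectral and temporal
resolution is intrinsic (uncertainty principle), not an implementation
artifact.

## Sparse transfer recovery

Sampling the evoked response at M points gives `a_k(τ) = Σ_j b_kj θ_j(τ)`
with design `b_kj = u_j(r_k)u_j(r₀)`.  The solver is independent per-lag
least squares (optional ridge for noisy data, default 0 — plain per-lag inversion
is the intended estimator).  Retained modes default to min(M, J); the
factor-2 margin sometimes quoted for Fourier-like sampling is exposed as
a user choice, not enforced.  Stimuli within 1e-3 of a modal zero
(relative to the mode's max amplitude) are rejected with the standard
remedy (add or substitute measurement points); 1e-2 warns.  Exactness on
noiseless data with full-rank designs, divergence of the condition number
on approach paths to modal zeros, and the end-to-end EC round trip
(recovered θ → T̂ → Λ̂ = I − T̂⁻¹) are all verified in the tests.

## Problem sizes and numerical choices

Test and acceptance workloads are sized for a single CPU: 998 × 998
eigendecompositions for the compression demonstration, 2×10⁵-sample
simulations for covariance convergence, subdivision-3 icospheres (642
vertices) for mesh spectra, l ≤ 6 Gaunt scans with quadrature exact to
degree 18, and 7200-s records for windowing sweeps.  Gaunt coefficients
are evaluated symbolically (Wigner-3j route) and cached, so
selection-rule zeros are exact zeros, with spherical quadrature as the
independent oracle.  Perturbation theory diagonalizes each degenerate
l-block of the perturbation first, then computes cross-block mixing from
matrix elements over unperturbed eigenvalue gaps; perturbation fields are
scalar multipliers of the Helmholtz operator (the operator-valued general
case is out of scope).

## Known limitations

* Symmetric connectivity only; no spectral factorization for directed EC.
* Scalar (potential-like) perturbations; no operator-valued coefficients.
* The EC-from-FC inversion takes the positive θ branch and requires a
  positive-definite FC.
* Mesh eigenmodes assume closed, consistently oriented, non-degenerate
  triangulations; no boundary handling.
* The covariance-vs-zero-frequency-cross-spectrum distinction: both the
  τ = 0 lagged covariance (frequency-integrated) and the ω = 0
  cross-spectrum estimators are provided (`sample_correlation` and
  `covariance_from_transfer` respectively); for white-driven
  frequency-flat transfer models they coincide up to normalization, but
  they are distinct estimators in general and are not conflated.
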