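# Methods

## The model

`neurofield` simulates and numerically verifies properties of the stochastic
neural field equation

    dY(t, x) = [ -Y(t, x) + ∫_{R^N} w(x, y) G(Y(t, y)) dy ] dt
               + σ(Y(t, x)) dW^φ(t, x),        x ∈ R^N, t ≥ 0,

for the mean activity Y of a cortical sheet.  Here w is the connectivity
(neural field) kernel, G a bounded globally Lipschitz gain, σ a Lipschitz
diffusion coefficient of linear growth, and W^φ a space-time white noise
smoothed in space by a correlation function φ ∈ L².  The equation has no
spatial differential operator, so the solution is exactly as rough as the
driving noise; the solution concept used throughout is the mild
(variation-of-constants) form

    Y(t, x) = e^{-t} Y₀(x) + ∫₀ᵗ e^{-(t-s)} F(Y(s))(x) ds
              + ∫₀ᵗ ∫ e^{-(t-s)} σ(Y(s, x)) φ(x - y) W(ds dy),

with F(h)(x) = ∫ w(x, y) G(h(y)) dy.  Two well-posedness frameworks exist —
a Hilbert-space-valued formulation in a weighted space L²(R^N, ρ_w), and a
random-field (Walsh) formulation — and they agree under the admissibility
conditions below.  The package treats both as discrete update rules and
verifies their agreement numerically rather than proving anything.

## Discretization

All fields live on a node-centred uniform lattice covering [-L, L)^N
(N = 1 or 2) with M nodes per axis, spacing h = 2L/M, periodic wrap-around.
Convolutions (the drift of homogeneous kernels, the noise smoothing, the
weight constructions) are circular FFT convolutions weighted by the cell
volume h^N; the periodic torus stands in for R^N, so every kernel must decay
well inside L (the smoothing kernel reports the fraction of its squared mass
outside L/4 as a wrap-around hazard).  The dense-matrix path for
non-homogeneous kernels evaluates w on node pairs; for homogeneous kernels
the dense matrix uses periodically wrapped displacements so that the FFT and
matrix paths are identical to round-off.

White noise is represented by its increments over cells and time steps:
i.i.d. centred Gaussians of variance dt·h^N, matching the set-indexed
covariance E[Ẇ(A)Ẇ(B)] = |A ∩ B| for unions of cells.  The smoothed
increment ΔW^φ(x) = Σ_cells φ(x - y_cell) ΔW(cell) is a Riemann-sum
approximation of the Walsh integral; its error is O(h) in φ's modulus of
continuity.  Reproducibility uses a counter-based Philox generator keyed by
the run seed with the step index in the counter block, so any step's draws
can be recomputed independently and shared across solver code paths.

## Time stepping

The **exponential Euler** step treats the linear decay exactly:

    Y_{n+1} = e^{-dt} Y_n + (1 - e^{-dt}) F(Y_n) + e^{-dt} σ(Y_n) ΔW^φ_n.

The drift weight 1 - e^{-dt} is the exact integral of the mild kernel over a
step, so constant-drift problems are solved exactly (the σ ≡ 0, G ≡ c case
reproduces y' = -y + cW₁ to round-off, and pure decay is exact for any dt).
The stochastic term uses left-point (Itô) evaluation with the damping factor
e^{-dt}, the mild kernel at the step start; e^{-dt} and 1 are both
O(dt)-consistent, and the damped choice keeps the noise-free cases exact.
The scheme's strong order on stochastic runs is 1/2, which the tests observe
through refinement against the Picard reference below.

The **Picard reference** iterates the fully discretized mild map on the
whole path with frozen noise:

    (ΦY)(t_n) = e^{-t_n} Y₀ + Σ_{k<n} e^{-(t_n - t_k)} [ F(Y_k) dt
                + σ(Y_k) ΔW^φ_k ],

using left-point Riemann weights.  Its fixed point is a discretization of
the same mild equation but differs from the exponential-Euler path at O(dt)
in the drift weights, which makes the shared-noise comparison between the
two a meaningful consistency check (their sup-difference shrinks under
dyadic dt-refinement).  The iteration contracts with a factorial-type tail —
the sweep-to-sweep sup-squared differences H_n fall far below any geometric
envelope — mirroring the t^n/n! bound that drives existence proofs for such
fixed points.

## Admissibility conditions and verdicts

The well-posedness theory needs integrability conditions on w:

* C1: ∫∫ |w(x,y)|² dx dy < ∞,
* C2: x ↦ ||w(x,·)||_{L¹} ∈ L²,
* C2': sup_x ||w(x,·)||_{L¹} ≤ C_w,
* C1': ∫ |w(x,y)| ρ(x) dx ≤ Λ ρ(y) for a positive integrable weight ρ,
* C3': ||w(x,·) - w(x̃,·)||_{L¹} ≤ L_w |x - x̃|^α.

Conditions over R^N can only be checked by truncated quadrature, so C1, C2
and C2' return three-way verdicts from the estimates I(R) at dyadic radii
R ∈ {4, 8, 16, 32} × (kernel length scale), with quadrature spacing a
quarter length scale.  The classifier looks at the ratio of successive
increments under radius doubling: an immediate pass when the relative change
falls below the tolerance (default 1e-4); otherwise ratio ≤ 0.75 means a
geometrically shrinking tail (pass), ratio ≥ 0.95 means persistent or
growing increments (fail), and anything between is inconclusive.  The ratio
rule, rather than a plain relative-change threshold, is needed because
physically relevant cases sit at both extremes: the separable kernel
(1+|x|)⁻¹(1+|y|)⁻¹ has a C1 integral converging only algebraically (tail
~ 1/R, ratio ≈ 0.5) and a C2 integral diverging only logarithmically in part
(ratio ≥ 1); both are classified correctly, as are the homogeneous kernels
(C1/C2 fail, C2' pass).  The sup in C2' is taken over nodes and midpoints
and is reported as a lower bound of the true sup.  C1' certifies a supplied
(ρ, Λ) pair only — for kernels outside the two construction routes below the
existence of a weight is a genuine eigenvalue problem that the checker does
not attempt to solve.  C3' regresses the truncated L¹ shift modulus on
dyadic separations in log-log coordinates and reports the slope α̂ and the
constant L_w; a constant kernel yields zero modulus and passes with L_w = 0.

## Weight constructions

For homogeneous kernels the weight ρ_w of C1' is built by **Fourier
deconvolution**: with v = |w|, z(x) = e^{-|x|²/2} and Λ = ||v||_{L¹} + 1,

    ρ̂(ξ) = F z(ξ) / (Λ - F v(ξ)),     F f(ξ) = ∫ e^{-2πi x·ξ} f(x) dx,

and ρ = F⁻¹ρ̂ computed by DFT on the grid.  Because |Fv| ≤ ||v||_{L¹}, the
denominator is bounded below by 1; on the lattice we take Λ from the *grid*
quadrature of v, which makes the discrete bound Λ - Fv(ξ) ≥ 1 exact by
construction (Fv(0) = Λ - 1) instead of holding only up to the O(h²)
quadrature error of a kinked integrand such as the Mexican hat modulus.  The
resulting ρ satisfies the residual identity Λρ(y) - (v ⋆ ρ)(y) = e^{-|y|²/2}
*exactly as a DFT identity* — the only error against the continuum target is
the periodization of z, controlled by L (below 1e-6 for L ≥ 6, machine
precision at L = 20); refining M does not change it.  Positivity follows
from the equivalent Neumann series ρ = Λ⁻¹ Σ_k (v⋆/Λ)^k z with nonnegative
terms, which is also implemented (`rho_neumann`) and agrees with the FFT
route to better than 1e-8; far tails that decay below machine epsilon are
floored at round-off level.  The width of z is exposed as a parameter
(default 1), since the construction tolerates any Schwartz bump.

For kernels with sufficient decay but no homogeneity, **power iteration**
on J h(y) = ∫ |w(x,y)| h(x) dx in the norm ‖h‖_X = max(‖h‖_{L¹}, ‖h‖_∞)
(cell-volume-weighted L¹ part) yields the spectral radius r(J) and a
positive eigenfunction, giving the pair (ρ, Λ = r(J)).  On a rank-one
separable kernel f(x)f(y) the computed radius matches the closed form
⟨f, f⟩ to 1e-10, and r(J) dominates the quadrature lower bound
inf_{y∈Ω} ∫_Ω |w| dx for any test box Ω.

## Noise diagnostics

* **Itô isometry** (the p = 2 Burkhölder constant c₂ = 1): the sample second
  moment of the discrete Walsh integral Σ f·ΔW of a deterministic integrand,
  divided by Σ f² dt h^N, is 1 up to a Monte-Carlo standard error of
  √(2/n_replicates) (the integral is Gaussian, so its squared ratio is χ²₁).
* **Covariance**: W^φ(t,·) has spatial covariance t(φ⋆φ̃)(x-y); the
  empirical covariance over replicates (averaged over base points by FFT
  autocorrelation — valid by stationarity on the torus) is compared to the
  circular theoretical curve with a family-wise 5-standard-error band.  The
  band is diagnostic, not a calibrated multiple-testing procedure.
* **Q-Wiener processes**: truncated Karhunen–Loève sums Σ √λ_k ξ_k e_k over
  an orthonormal basis (a complete real sin/cos basis on the 1D lattice is
  provided, making the "identity" surrogate exact); the covariance identity
  E⟨ΔW,g⟩⟨ΔW,h⟩ = dt⟨Qg,h⟩ and mode independence are checked by Monte
  Carlo, and the colored spatial covariance c = Q^{1/2}φ ⋆ Q^{1/2}φ̃ reduces
  to φ⋆φ̃ when all retained eigenvalues are 1.
* **Hölder exponents** are estimated by second-order structure functions:
  the OLS slope of log RMS increment against log lag, with a standard error
  from replicate groups (≥ 4 lags spanning ≥ 2 dyadic octaves).  In time the
  population slope for W^φ is exactly 1/2 at every lag (independent
  increments).  In space the population slope equals the log-log slope of
  φ's *discrete* shift modulus at the probed lags, which approaches the
  modulus exponent α only for lags well inside φ's length scale — estimates
  therefore compare against the analytically computed modulus slope, and
  lags must stay inside the linear regime (inside the support for an
  indicator φ, a fraction of β for a Gaussian φ).  The indicator kernel's
  modulus obeys ‖φ - τ_zφ‖² = 2|z| exactly on the lattice, so its slope is
  1/2 to machine precision; a Gaussian φ lies in W^{1,2} and has exponent 1
  with constant ‖φ'‖_{L²}.

## Solution-concept equivalence

The random-field update multiplies σ(Y(x)) by the smoothed increment
pointwise; the Hilbert-space update applies the noise operator
B(Y)(u) = σ(Y)·(φ⋆u) to the raw white-noise vector and otherwise uses the
same drift and decay weights.  The two discrete updates are algebraically
identical, so on shared noise draws their weighted-L²(ρ) discrepancy is FFT
round-off (< 1e-10); mismatched seeds produce O(1) discrepancy and serve as
the negative control.  This is the discrete counterpart of the equivalence
of the two solution concepts, not a proof of it.

## Moment diagnostics

Over an ensemble (≥ 100 replicates) the package tracks t ↦ max_x Ê|Y(t,x)|^p
and t ↦ Ê‖Y(t)‖^p_{L²(ρ)}.  The boundedness verdict fits a log-log growth
exponent to the post-transient (second half) sup-second-moment curve and
declares "bounded" when the exponent is at most 0.25 — a quarter-power
allowance that separates the plateau of bounded-G, bounded-σ dynamics from
genuine super-linear growth while tolerating Monte-Carlo wiggle.  With
σ ≡ 0, G ≡ 0 the second moment decays exactly as e^{-2t}E|Y₀|².

## Synthetic orientation maps

The anisotropic long-range kernel needs a preferred-orientation map
θ: R² → [0, π).  No concrete map is prescribed by the theory, so the package
synthesizes one as the half-argument of a random superposition of complex
plane waves with box-commensurate wavevectors (a standard construction for
cortical orientation maps): smooth away from the zeros of the complex field,
with pinwheels located by the ±2π winding of the phase around lattice
plaquettes, deterministic given the seed.  With zero pinwheels requested a
single plane wave is used and θ is linear modulo π.  This map is a
reproducible stand-in; it is not fitted to any anatomical data.

## Default parameters and problem sizes

| quantity | default | rationale |
| --- | --- | --- |
| grid | N = 1, L = 10, M = 64–256 | ≥ 10 kernel length scales of padding for FFT wrap-around |
| weight-construction grid | L = 20, M = 1024 | ρ's tail decays like x^{-2N}; periodization error < 1e-12 |
| dt | 1e-2 | strong order 1/2; closed-form cases are exact anyway |
| condition radii | {4, 8, 16, 32} length scales | dyadic doubling for the increment-ratio classifier |
| quadrature spacing | length scale / 4 | resolves the kernel's variation |
| Hölder estimation | 2000 replicates, lags {2,4,8,16}·dt or {1,2,4,8}·h | slope SE ~ 1e-3; lags span 3 octaves |
| isometry check | 10⁴ replicates | ratio SE = √2/100 ≈ 0.014 |
| moment ensembles | 100–2000 replicates | χ² error bars small against the plateau |

Simulation sizes in the test-suite and scenarios (64–256 nodes, 10²–10⁴
replicates, horizons of a few time units) were chosen so that every
diagnostic has Monte-Carlo error comfortably below the effect it measures
while a full verification run stays in the minutes range on one core.

## What the generators do and do not emulate

The synthetic configurations exercise exactly the hypotheses of the
underlying theory: bounded Lipschitz gains, Lipschitz linear-growth
diffusions, kernels with uniform L¹ bounds, square-integrable smoothing
kernels with known shift moduli, and initial conditions (constant, bump,
i.i.d. Gaussian field) with finite moments.  Passing tests show that the
discretized operators reproduce the covariance, moment, contraction and
regularity structure of the model on a periodic lattice.  They do not show
anything about real cortical tissue: kernels are not fitted to anatomy, the
torus suppresses boundary phenomena, the noise is exactly Gaussian and white
in time, and traveling-wave or pattern-formation dynamics are out of scope.

## Known limitations

* C1/C2 double-integral checks are implemented for N = 1 (the 2N-dimensional
  quadrature grids grow too fast otherwise); C2' and C3' likewise.
* Q-Wiener covariance operators must be supplied spectrally; only the 1D
  Fourier eigenbasis ships as a built-in, and the pure (unsmoothed)
  space-time white-noise limit — where the solution is distribution-valued —
  is deliberately not represented.
* The Hölder estimators report point slopes with replicate-group standard
  errors, not joint space-time moduli.
* No adaptive time stepping; the scheme is strong order 1/2 and the Picard
  reference shares the same spatial discretization, so spatial quadrature
  error is not probed by their agreement.
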