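# Methods

## Model and procedure

The measurement model is the standard emission-tomography Poisson model:
ray sums `p_j ~ Poisson(q̄_j)` with mean `q̄_j` the line integral of the
activity along ray `j`. Reconstruction uses the multiplicative
alpha-weighted EM iteration

    x_i <- x_i * [Σ_j a_ij p_j / q_j^α] / [Σ_j a_ij q_j / q_j^α],   q = A x,

which contains classical ML-EM as the α = 1 member. Its additive
rewriting,

    x_i <- x_i + [x_i / Σ_j a_ij q_j^(1-α)] * Σ_j a_ij (p_j − q_j) / q_j^α,

identifies the iteration as gradient descent on the weighted
least-squares objective `F = Σ_j W_j (q_j − p_j)²` with iteration-varying
weights `W_j = 1/q_j^α` and a per-pixel step size `x_i / Σ_j a_ij
q_j^(1-α)`. The package implements the multiplicative form as the
primary path (it is nonnegativity-preserving without any step-size
control) and the additive form purely as a cross-checking oracle; the
test suite asserts their agreement to 1e-10 relative on random systems.

Key exact properties, all enforced by tests:

- α = 1 reduces to ML-EM *bitwise* (IEEE `pow(x, 1.0) = x`, and
  `Aᵀ(q/q) = Aᵀ1` equals the precomputed sensitivity image).
- ML-EM preserves total counts: `Σ_j q_j^(n)` equals `Σ_j p_j` after
  every iteration (a consequence of the Poisson weighting; it fails for
  α ≠ 1, which a test demonstrates rather than asserts away).
- ML-EM never decreases the Poisson log-likelihood
  `Σ_j (p_j ln q_j − q_j)`.
- Any x with `A x = p` is a fixed point for every α.

## Simulation apparatus

**Phantom.** An additive analytic scene: background ellipse centered at
(63.5, 63.5) with semi-axes (54, 40) and activity 1; five hot discs
(radius 5, activity 2) on a ring of radius 25 at polar angles 0°, 72°,
144°, 216°, 288°; one cold disc (radius 5, activity 0.5) at the center.
Only the region *ratios* (1 : 2 : 0.5) and the scene inventory are fixed
by the study design; the concrete sizes and positions are this package's
choice, frozen so every downstream number is reproducible. Consequently
absolute MSE/stdev magnitudes are specific to this phantom and are not
comparable across implementations with different geometry — the package's
claims are the *relative* ones (which α wins, in which direction the
optimum moves with count level).

**Projections.** Ray sums are exact chord lengths through the components
(quadratic-root formula for ellipses; the rotation-invariant
perpendicular-distance formula for discs, which makes centered-disc
sinograms bitwise identical across views). The phantom is never
pixelized on the data side.

**Geometry.** Parallel beam, 120 views over 360° (3° steps), 128 bins of
width 1 pixel, offsets symmetric about the rotation axis. Pixel centers
sit at integer coordinates 0..127; the rotation center is (63.5, 63.5).

**Calibration.** The phantom amplitude is rescaled once so the analytic
sinogram sums to exactly 1e7 at scaling factor 1; the factors
{0.1, 1, 10, 100, 1000} then give expected totals 1e6..1e10. The
reconstruction operates directly on raw counts; the scaling factor
enters only the evaluation normalizers.

**System matrix.** Siddon ray tracing: one central line per detector
bin, weights equal to exact line-pixel intersection lengths (~2.3M
nonzeros at 128²), stored sparse and cached in-process because the grid
experiment reuses it across hundreds of reconstructions. Backprojection
is the literal matrix transpose, so the projector pair is an exact
adjoint (tested to 1e-12). Forward-projecting the rasterized phantom
reproduces the analytic sinogram to ~0.6% relative L2 — deliberately
nonzero: the data model is not the reconstruction model (no inverse
crime). One consequence worth knowing: the *noiseless* analytic sinogram
behaves like an extremely-low-noise measurement, so even without Poisson
noise the MSE curve has an interior minimum (≈ iteration 41 at scale 1)
instead of decreasing forever; only data generated *through* the
discrete projector give a monotone MSE curve.

**Noise.** Independent Poisson draws from `scale × q̄`, one generator
per (master seed, realization, scale) triple via `numpy.SeedSequence`,
so every stream is reproducible and streams never collide across the
5 × 5 study grid.

**Truth and metrics.** The MSE reference is the phantom rasterized with
4× supersampling (each pixel the mean of 16 interior sample points)
times the scaling factor. MSE sums over the support — pixels whose
center lies inside the background ellipse, the natural reading that
excludes the trivially zero exterior — and divides by
`N = 16384 × scale`. Noise alone is measured as the sample standard
deviation (ddof = 1) in the background rectangle x ∈ [98, 112],
y ∈ [58, 70], chosen ≥ 4 px clear of every disc, divided by the scaling
factor. Data discrepancy is `Σ_j (q_j − p_j)²`. Central profiles average
image rows 63 and 64.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| α | 1.0 | — | ML-EM baseline; study grid 0.1–3.0 in 0.1 steps (grid runs to 3.0 because the low-count optimum sits that high; a sanity cap rejects α > 5) |
| iteration budget | {30, 60, 80, 120, 200} for scales {0.1, 1, 10, 100, 1000} | iterations | ≥ 2× the observed MSE optima, so the argmin is interior |
| init_value | auto | counts/pixel | uniform on the FOV, scaled so the initial forward projection carries the measured total counts (scale-free start) |
| epsilon | 1e-12 × mean(q) | counts | floor for q in ratios/logs; the update is otherwise undefined at q_j = 0 |
| supersampling | 4 | — | sub-percent mean boundary-pixel error at negligible cost |
| target_total | 1e7 | counts | pins scale 1 to the 1e7-count regime |

Stopping: the driver records the full MSE curve and takes the global
argmin within the budget rather than halting at the first uptick —
equivalent for U-shaped curves and robust to jitter. The per-level best
α aggregates per-realization best MSEs by their median across the five
realizations (ties break toward smaller α).

## What the synthetic data do and do not show

The generator reproduces the idealized study conditions: pure Poisson
noise on exact parallel-beam line integrals of a piecewise-constant 2-D
phantom. It omits attenuation, scatter, randoms, detector blur, depth-
dependent resolution, and 3-D effects. Passing tests therefore establish
the mathematical behavior of the weighting family — the count-level
dependence of the optimal α and stopping point — not clinical image
quality; on real data the optimal α would additionally absorb whatever
model mismatch those omitted effects introduce.

## Numerical choices and degenerate inputs

- Zero-sensitivity pixels (none inside the FOV circle at the default
  geometry) are frozen at 0 and excluded from the EM division.
- Rays with q_j below the epsilon floor use the floor in every ratio;
  rays with p_j = q_j = 0 contribute nothing.
- The initial image must be strictly positive on the FOV (a
  multiplicative algorithm can never leave 0); max_iterations = 0
  returns the initial image with its diagnostics.
- Chord formulas clip tiny negative discriminants/radicands to 0, so
  grazing rays return 0 rather than NaN.
- Toy fixtures give each pixel one dominant ray; without that, EM on
  small dense random systems needs ~1000 iterations to push the
  fidelity below 1e-10 of its initial value, which is pointlessly slow
  for unit tests.

## Problem sizes used by the shipped runs

The experiment driver exposes the full 5 × 5 × 30-cell study; the test
suite and the acceptance script exercise a reduced grid chosen as the
smallest one that still exhibits the study's qualitative result —
α ∈ {0.5, 1, 1.5, 2, 3}, two realizations, the lowest and highest count
levels, with budgets 30 and 200 iterations — plus 100-iteration
monotonicity runs at scale 1, all on the full 128 × 128 / 120 × 128
problem.

## Known limitations

- Absolute MSE values depend on the phantom geometry, projector
  discretization, initialization, and support definition, all of which
  have no canonical choice; only ordering/trend statements transfer.
- The projector uses a single central ray per bin; strip-integral or
  rotation-based projectors would shift absolute numbers mildly.
- No attenuation/scatter modelling, no ordered subsets, no
  post-filtering, no automatic data-driven α selection — the count-level
  heuristic (larger α at lower counts) is the guidance the study
  supports.
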