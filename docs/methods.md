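# Methods

This note records the model, the numerical choices, and their rationale, at
the level of detail a maintainer needs to modify the package safely.

## Model and assumptions

The denoising flow is the Perona–Malik equation on the unit square,

    ∂u/∂t = div( c(h·|∇u|) ∇u ),

for a grayscale image rescaled to `[0, 1]`, with `|∇u| = (u_x² + u_y²)^{1/2}`
and `h` the fine-grid spacing. Composing the diffusivity with `h` makes its
argument the intensity change per pixel, so the edge threshold `k` is a
resolution-independent fraction of the intensity range: with the default
`k = 0.1`, a 10% jump between neighbouring pixels marks an edge. Without
this convention a fixed `k` is meaningless across resolutions — the raw
unit-square gradient of pixel noise scales like `σ√2/h` (≈ 9 at 129², far
above any intensity-scale `k`), which would switch the diffusion off
entirely.

The divergence is expanded by the chain rule into the collocation form

    F = c·(u_xx + u_yy) + h²·q·(u_x²·u_xx + 2·u_x·u_y·u_xy + u_y²·u_yy),

with `q(s) = c'(s)/s`, which is finite and smooth through zero gradient for
both diffusivity families (rational: `q = −(2/k²)·c²`; exponential:
`q = −(2/k²)·c`). No gradient regularization is applied; the well-known mild
ill-posedness of the model (backward diffusion across strong edges) is
accepted and shows up, as expected, as slight edge sharpening and an
occasional ~1% overshoot of the input intensity range near very sharp
contours.

Boundary conditions: none are imposed strongly. The interval wavelet
extrapolates boundary data outward, which behaves like a homogeneous Neumann
condition for the diffusion flux; the conservative finite-difference baseline
uses mirror boundaries, making its gray-level sum exactly conserved.

## Basis functions

Three interpolating (cardinal) scaling functions are available. Shannon
(`sin πx / πx`) and Shannon–Gabor (sinc × Gaussian, width `σ`) are evaluated
in closed form, with series expansions near `x = 0` and an explicit
truncation radius (default 40 grid units) beyond which they are treated as
zero — a documented approximation knob, since the sinc decays only like
`1/x`.

The default basis is the autocorrelation of the Daubechies scaling function
with `M` vanishing moments (default `M = 3`) — the Deslauriers–Dubuc
fundamental function of 2M-point iterative interpolation: symmetric,
supported on `[−(2M−1), 2M−1]`, interpolating, and exact on polynomials up to
degree `2M−1`. It has no closed form. Evaluation:

* The refinement mask is the autocorrelation of the Daubechies filter
  (coefficients from PyWavelets); exact zeros at even offsets and the unit
  centre tap are enforced.
* Values of φ at dyadic points are generated by subdivision from the cardinal
  data at the integers; values of φ′ likewise, starting from the eigenvector
  of the refinement transition matrix at eigenvalue 1 (normalized by
  Σ k·φ′(k) = −1). Both tables are exact up to roundoff at resolution
  `2^−r` (default `r = 10`).
* Off-dyadic values, and the second derivative everywhere, come from the C¹
  cubic Hermite interpolant of the (φ, φ′) tables. This choice is deliberate:
  φ″ of the Deslauriers–Dubuc function is barely continuous (`M = 3`) or
  fails to exist (`M = 2`), so *any* pointwise φ″ is an approximation. The
  Hermite interpolant keeps the three derivative orders mutually consistent
  (finite differences of one order reproduce the next to ~10⁻⁶ relative) and,
  because cubic Hermite interpolation of data lying on a polynomial of degree
  ≤ 3 is exact, the collocation identities Σ p(k)·w^{(d)}(x−k) = p^{(d)}(x)
  hold to machine precision for constants, linears and quadratics — the
  property the diffusion operator actually relies on. Accuracy limit: the
  pointwise second derivative of a generic field carries an `O(2^{−0.19 r})`
  error inherited from the basis roughness; reproduction-type errors are at
  machine precision.

## Interval extension

On a level-`j` grid the basis needs data at external nodes. Two knobs are
distinguished (they coincide in the classical construction):

* the **extrapolation order** `L`: external values are predicted by the
  degree-(L−1) polynomial through the `L` interior nodes nearest the
  boundary (Lagrange weights for the static form; Newton divided differences
  for the dynamic form — adding a point costs one extra term, O(L) work,
  instead of an O(L²) weight rebuild);
* the **extension width** `W`: how many external nodes are filled. For the
  compactly supported basis `W = max(L, 2M−2)`, so the extension always
  covers the basis support. With `W = L` (the literal classical form) the
  missing support tail breaks even constant reproduction of the *derivative*
  operators at boundary-adjacent nodes (measured: a constant image drifted by
  1% per 3 steps at L = 1); with the support-covering width, constants extend
  exactly for every `L ≥ 1` and a constant image is a machine-precision fixed
  point of the solver. For the truncated Shannon families the width stays
  `L`: their 40-unit "support" would demand far-field extrapolation, which is
  exactly the boundary pathology this basis is known for.

### Dynamic choice of L

Per block side and per step, divided differences of the boundary-normal node
lines (aggregated by maximum magnitude over the lines) drive the order:

1. the smallest `L` with `|f[x₀..x_L]| < T_a` (default `T_a = 10⁻³` on
   `[0,1]` intensities) or with `|f[x₀..x_L]| < |f[x₀..x_{L−1}]|` is taken;
2. if the sequence never falls below tolerance and never decays — rough,
   noise-dominated boundary data — the order with the smallest difference
   magnitude is taken (`L = 1` for monotone growth). Falling back to `L_max`
   here would maximize exactly the noise amplification the dynamic scheme
   exists to avoid; measured on the microgroove phantom, that fallback makes
   dynamic seams *worse* than static `L = 3`, while the smallest-difference
   fallback makes them better.
3. an increase from `L` to `L+1` is refused whenever the 1-norm condition
   estimate of the linearized update grows by a factor ≥ 10.

The ε of the divided-difference criterion and `T_a` are exposed separately
(`DynamicLConfig.eps`, defaulting to `T_a`). `L_max` defaults to 6 and is
additionally capped at `2M−1` for the compact basis (external shifts beyond
that never reach the domain).

### Conditioning probe

The monitored matrix is `A = I + τ·D`, where `D` is the diffusion RHS
linearized by freezing its scalar fields (`c`, `h²q`, `u_x`, `u_y`) at the
current state and discretizing with the interval basis on a small probe grid
(level 4, 17×17, per block). `‖A‖₁` is exact; `‖A⁻¹‖₁` uses a deterministic
Hager estimate on an LU factorization (exact for diagonal matrices, within a
factor ~3 of the dense value on the probe operators). Measured behaviour on
noisy phantoms: the condition number is mildly U-shaped in `L` (dip at
`L = 2–3`, growth from `L = 4`), with successive-`L` ratios far below the
factor-10 cap at the default `τ` — the cap only binds in stiffer regimes.

## Multilevel sparse grid

Standard interpolatory (hierarchical-surplus) decomposition between levels
`j₀` (default 4) and `J`, with the three new-node families per level indexed
(odd, even), (even, odd), (odd, odd) in (x, y). The boundary lines of each
family are kept — full table shapes `(2^j+1)×2^j` etc.; truncating both
indices at `2^j − 1` silently drops the last even line and destroys
losslessness. With threshold 0 the round-trip decompose→reconstruct is exact
to ~10⁻¹² for both bases.

Compression masks coefficients with `|α| < threshold` (absolute, on `[0,1]`
intensities; default `10⁻³`); coarse-level values are never masked.
Derivatives of the sparse interpolant sum active coefficients only; the
deactivation error is measured empirically (sup-norm reconstruction error
below `10⁻²` at threshold `10⁻³` on smooth fields), not bounded analytically.

The decomposition's operation counter counts coefficients computed (each is
O(1) work for a compactly supported basis), growing as `O(4^J)`; the explicit
extension-operator assembly implements the same algebra as matrices over the
fine grid at `O(4^{2J})` cost and is used only as an independent small-grid
oracle.

## Time stepping

Each step runs: (1) decompose + threshold the current field; (2) evaluate
`F_n`; (3) predictor `φ₀ = φ_n + τ·F_n` (the zeroth-order homotopy term);
(4) decompose + threshold the predictor and evaluate `F(φ₀)`; (5) corrector
`φ_{n+1} = φ_n + (τ/2)(F_n + F(φ₀))`. The coefficients entering the second
stage necessarily come from the predictor — the corrected state does not
exist yet — which is also what keeps the per-step coefficient cost `O(4^J)`.
No corrector iteration is performed. Against a scalar surrogate the step
reproduces `1 + z + z²/2` exactly; against a fine-step reference on the heat
limit the measured temporal order is ≈ 2.05.

Stability: the stepper is explicit; the collocation Laplacian's spectral
radius is ≈ `2.3·10⁵` per dimension at level 7 versus ≈ `5.7·10⁴` at level 6,
so the default `τ = 10⁻⁵` is stable for per-block grids up to 65×65 (the
block sizes the method is designed around) and unstable on a monolithic
129×129 grid. This is intrinsic to the partitioned design: blocks both cap
the `O(4^J)`-per-step cost and keep the explicit step inside its stability
envelope. The solver raises on divergence rather than returning garbage.

## Partitioning

Even tiling only (content-adaptive partitioning is out of scope); block size
must divide the image. Blocks are solved independently with no halo
exchange — boundary data are extrapolated from inside the block — so
processing order is irrelevant and the scheme is embarrassingly parallel
(scheduling itself is out of scope). Blocks whose pixel side `b` is not
`2^J+1` are solved on the `(2^J+1)²` node grid with `J = ceil(log2(b−1))`
and resampled bilinearly (the pixel↔node map is `x = col/(b−1)`,
`y = row/(b−1)`). The seam metric is the largest intensity jump across
interior block boundaries, minus the same quantity on the input, so 0 means
no added seam.

## Synthetic phantoms

The seeded generator emulates the two image classes the method targets:
`disks` (sharp closed contours on a flat background — Gibbs-phenomenon bait)
and `microgrooves` (fine parallel low-contrast ridges — block-seam bait),
plus `step_edge` and `sine` for calibration. Clean intensities stay inside
`[0.15, 0.85]` so additive Gaussian noise at the default `σ = 0.05` is
essentially never clipped and the measured noise level equals the nominal
one. What the phantoms do **not** emulate: correlated acquisition noise,
intensity-dependent (Poisson) noise, anatomy-scale texture spectra, and
partial-volume soft edges. Tests passing on phantoms therefore certify the
numerics (exactness, stability, adaptivity, seam behaviour), not clinical
denoising quality.

## Problem sizes and defaults

Defaults: rational diffusivity, `k = 0.1`, `τ = 10⁻⁵`, `t_end = 5·10⁻⁵`
(five steps), `j₀ = 4`, threshold `10⁻³`, Daubechies-autocorrelation basis
with `M = 3`, dynamic `L` with `T_a = 10⁻³`, `L_max = 6`, condition-ratio cap
10. The test suite and the acceptance script run on 17²–129² grids and
120²–128² images in 60–64-pixel blocks — the block size the partitioned
method is built around — which keeps the full suite around ten seconds while
exercising every code path at the operating point of the defaults.

## Known limitations

* Explicit time integration: `τ` must respect the level-dependent stability
  bound; no semi-implicit variant is provided.
* The pointwise second derivative of the `M = 2` autocorrelation basis does
  not exist; the Hermite surrogate is well-defined but `M ≥ 3` is recommended
  for diffusion.
* Shannon families reproduce polynomials only approximately (truncation), so
  boundary behaviour is visibly worse than the compact basis — consistent
  with their role as the artifact-prone comparison case.
* PSNR gains depend on `k` matching the noise level; `k` far below the
  per-pixel noise amplitude switches diffusion off, `k` far above it smooths
  edges.
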