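# pmwave

Edge-preserving denoising of grayscale images by a **dynamic sparse-grid
wavelet collocation** solver for the Perona–Malik anisotropic diffusion
equation. The intended use is biological/medical imagery — sharply contoured
structures (brain-like contours) and fine low-contrast texture (tissue
microgrooves) — where plain smoothing destroys exactly the features of
interest.

## The model

The image `u(x, y, t)` evolves on the unit square by

    ∂u/∂t = div( c(h·|∇u|) ∇u ),      u(x, y, 0) = f(x, y),

with diffusivity `c(g) = 1/(1 + (g/k)²)` (rational) or `c(g) = exp(−(g/k)²)`
(exponential). The diffusivity senses the intensity jump per pixel (`h` is
the grid spacing), so the edge threshold `k` lives on the `[0, 1]` intensity
scale: gradients below `k` are treated as noise and diffused away, gradients
above `k` are treated as edges and preserved.

The discretization is what distinguishes the package from a stock
finite-difference loop:

* **Interpolating wavelet collocation.** Spatial derivatives come from a
  multilevel interpolant built from cardinal scaling functions — Shannon
  (sinc), Shannon–Gabor, or the autocorrelation of the Daubechies-M scaling
  function (the Deslauriers–Dubuc fundamental function; the default, since
  compact support suppresses Gibbs artifacts at sharp contours).
* **Sparse (adaptive) grids.** A field on the `(2^J+1)²` dyadic grid is a
  coarse level-`j₀` interpolant plus hierarchical surpluses `α¹, α², α³` at
  each level's new nodes. Surpluses below a threshold deactivate their
  collocation points, so the active set tracks image detail and shrinks as
  the image smooths. Coefficient updates cost `O(4^J)` per step via the
  recursive residual route (the explicit operator assembly, kept only as a
  small-grid cross-check, costs `O(4^{2J})`).
* **Interval boundary treatment with dynamic order.** Blocks are processed
  independently; boundary data are extrapolated to external collocation
  points by Newton's divided-difference form. The extrapolation order `L`
  adapts per block side and per step to the decay of the divided differences
  (smooth boundary → higher order pays off; rough boundary → low order avoids
  amplifying noise), and an increase of `L` is refused if it would inflate
  the 1-norm condition estimate of the linearized update by a factor ≥ 10.
* **Homotopy predictor–corrector time stepping.** Each step embeds the
  right-hand side in a homotopy between `t_n` and `t_{n+1}`; truncating the
  perturbation series at first order gives an explicit Euler predictor whose
  wavelet coefficients are refreshed before a trapezoidal corrector
  (second-order accurate in `Δt`).

## Worked example

```
$ pmwave phantom brain_like.png --scene disks --size 128 --noise-sigma 0.05 \
      --seed 42 --clean-output brain_clean.png
wrote disks phantom (128x128, sigma=0.05, seed=42)

$ pmwave denoise brain_like.png denoised.png --block 64 \
      --clean brain_clean.png --report report.json
PSNR in  : 25.99 dB
PSNR out : 32.87 dB
blocks=4 steps=5 active 16561 -> 15977
```

The phantom is a seeded disk scene (sharp contours on a flat background)
with Gaussian noise of standard deviation 0.05 — hence the input PSNR of
about `10·log10(1/0.05²) ≈ 26` dB. Five diffusion steps (`τ = 10⁻⁵` to
`t = 5·10⁻⁵`, rational diffusivity, `k = 0.1`) raise the PSNR by ~7 dB while
the disk contours stay sharp. The image is processed as four independent
64×64 blocks with dynamically chosen boundary extrapolation orders; the
active collocation count drops from 16561 to 15977 as the noise (the only
fine-scale content) is removed — the adaptive grid discarding points it no
longer needs. `report.json` records, per block and step, the chosen `L` on
each side, the condition estimate of the linearized update, and the active
point count.

The same pipeline is available as a library:

```python
from pmwave import DiffusionConfig, PhantomSpec, generate_phantom, psnr, solve_blocks

clean, noisy = generate_phantom(PhantomSpec(size=(128, 128), scene="disks",
                                            noise_sigma=0.05, seed=42))
cfg = DiffusionConfig(k=0.1, tau=1e-5, t_end=5e-5, L_mode="dynamic")
out, report = solve_blocks(noisy, cfg, b=64)
print(psnr(clean, noisy), psnr(clean, out))
```

## Layout

| module                 | contents                                                        |
|------------------------|-----------------------------------------------------------------|
| `pmwave.bases`         | Shannon / Shannon–Gabor / Daubechies-autocorrelation evaluation |
| `pmwave.interval`      | Lagrange extension, divided differences, dynamic-L selection    |
| `pmwave.sparse_grid`   | multilevel decomposition, compression, reconstruction           |
| `pmwave.solver`        | Perona–Malik RHS, predictor–corrector stepper, FD baseline      |
| `pmwave.conditioning`  | linearized update matrix, 1-norm condition estimation           |
| `pmwave.blocks`        | even partitioning, per-block solves, seam metrics               |
| `pmwave.imaging`       | phantoms, PNG/TIFF/PGM I/O, PSNR                                |
| `pmwave.cli`           | the `pmwave` command                                            |

See `docs/methods.md` for the numerical choices and their rationale.
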