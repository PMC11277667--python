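# rpcalign

Batch enhancement of correlated, degraded images — retinal fundus
photographs being the motivating case — by robust principal component
analysis with a weighted nuclear norm, an L2,1 column-sparse error term,
and jointly estimated per-image affine alignment.

## The problem and the model

Repeated photographs of the same scene class (e.g. a set of fundus images
of one eye, or a batch of same-protocol acquisitions) are highly
correlated: stacked as columns of a matrix
`N = [vec(R₁) | … | vec(Rₙ)] ∈ ℝ^{m×n}` they are approximately low rank.
Degradations — light disturbance, blur, artifacts, outlier frames — break
that structure. The decomposition model is

```
min_{L,E,Δτ}  ‖L‖_{w,*} + α‖E‖_{2,1}
subject to    N∘τ + Σᵢ Jᵢ Δτ ωᵢωᵢᵀ = L + E
```

* `‖L‖_{w,*} = Σᵢ wᵢ σᵢ(L)` is the **weighted nuclear norm** with
  `wᵢ = b√n / (σᵢ(L) + ε)`: large singular values (the shared anatomy)
  are penalised less, small ones (noise and artifacts) more. Its proximal
  map has the closed form `σ̂ = max((σ−ε) + √((σ+ε)² − 4C), 0)/2` with
  `C = b√n`, the stationary point of thresholding at `C/(σ+ε)`.
* `‖E‖_{2,1} = Σⱼ ‖Eⱼ‖₂` promotes **column sparsity**: whole corrupted
  images (outlier frames) are explained by E rather than contaminating L.
* `τ` holds one 6-parameter **affine transform per image**; the warp is
  linearised through per-image Jacobians `Jᵢ = ∂vec(Rᵢ∘τᵢ)/∂τᵢ`, giving a
  closed-form least-squares alignment update each pass.

The constraint is enforced by an augmented Lagrangian and solved by ADMM:
weighted singular-value thresholding for L, column shrinkage at `α/μ` for
E, `Δτᵢ = Jᵢ⁺ rᵢ` for the warps, then multiplier and penalty updates with
`μ ← min(μ_max, ρμ)`. A convex baseline mode (uniform nuclear norm +
elementwise L1) reproduces classical robust PCA and is used for
exact-recovery checks. Enhanced images are the columns of L.

The package also ships the full-reference quality metrics used to score
enhancement (PSNR, windowed and global SSIM, Pearson correlation,
block-variance VIF) and a synthetic degradation generator that produces
stacks with exact ground truth (low-rank structure, sparse corruption,
sub-pixel misalignment, blur/illumination/artifact degradations).

## Worked example

```
python examples/enhance_degraded_stack.py
```

```
degraded stack: 12 images of 64x64
solver: converged=True after 41 iterations, residual 8.89e-08
mean PSNR: 22.52 dB -> 31.05 dB
mean SSIM: 0.552 -> 0.842
```

Twelve synthetic 64×64 images sharing rank-2 structure are degraded with
blur, illumination gradients, spot artifacts, ≤1 px misalignment and
sparse corruption. The decomposition raises mean PSNR against the clean
ground truth by ~8.5 dB and SSIM from 0.55 to 0.84 — the degradations were
routed into E and the alignment corrections instead of the enhanced L.

Other examples: `convex_recovery.py` (exact recovery in the convex
regime, relative error 3.9e-4), `alignment_recovery.py` (0.05 px RMS
translation recovery after removing the undetermined common frame
offset), `quality_metrics.py` (metric behaviour on a noise ladder).

## Command line

```
rpcalign simulate full_degraded -o fixture --seed 0
rpcalign enhance fixture/degraded -o run --reference fixture/clean --align
rpcalign evaluate run/enhanced fixture/clean --report run/metrics
```

`enhance` writes the enhanced images, the recovered transforms (CSV), a
run manifest (JSON, full resolved configuration + iteration histories)
and, when a reference is given, a metrics report. Exit codes: 0 success,
2 usage error, 3 numerical failure.

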