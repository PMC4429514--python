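# spfseg

Region-based level-set segmentation of grayscale images whose intensities
drift smoothly within tissue classes — the *intensity inhomogeneity* (bias
field) typical of MR acquisitions. Purely global region models (Chan–Vese
style) fail on such images because a single pair of region means cannot
describe a class whose brightness varies across the field of view; purely
local models (local-binary-fitting style) handle the drift but are
notoriously sensitive to where the initial contour is drawn. `spfseg`
implements a geodesic-active-contour evolution driven by a **signed
pressure force (SPF)** that adaptively blends both sources of evidence,
in a two-phase form (object/background) and a four-phase form (two coupled
level-set fields encoding four tissue classes, e.g. WM/GM/CSF/background).

It is aimed at researchers who want a small, dependency-light, fully
deterministic implementation with built-in synthetic phantoms and
Dice-based evaluation.

## The model

A contour is the zero level of a field φ evolved by

```
φ ← φ + Δt · α · S(I, φ) · |∇φ|,
```

followed each iteration by binarization (φ ← ±1 by sign) and smoothing with
a small Gaussian — the selective-binary regularization that replaces both
the curvature term and signed-distance re-initialization. The force S is
built from:

- **global SPF** — `s_g(x) = (I(x) − (c₁+c₂)/2) / max|·|`, where c₁, c₂ are
  the regularized-Heaviside-weighted mean intensities inside/outside the
  contour (H_ε(z) = ½(1 + (2/π) arctan(z/ε)), ε = 0.3);
- **local SPF** — the same construction with c₁, c₂ replaced by local
  fitting functions `fᵢ = K_σ∗(H·I) / K_σ∗(H)` (Gaussian window, σ = 5 px);
- **adaptive weight** — `ω(x) = exp(−β·C_R(x)/mean C_R)` with C_R the 5×5
  Michelson local contrast; ω ≈ 1 in smooth regions (trust the global
  force, sweep fast) and ω → 0 near edges (trust the local force, stop
  accurately):

```
S = ω · s_g + (1 − ω) · s_l            ∈ [−1, 1].
```

The four-phase form evolves two fields whose sign pairs encode four
regions with memberships M₁ = H(φ₁)H(φ₂), …, summing to one everywhere;
each field is driven by a pairwise region-competition SPF (assign each
pixel to the nearer of the two region references competing across that
field's interface, conditioned on the other field) and updated with a
regularized-Dirac localization δ_ε(φ) = ε/(π(ε² + z²)).

Accuracy is reported as the Dice similarity coefficient
DSC = 2|S₁∩S₂| / (|S₁|+|S₂|).

## Worked example

Generate an inhomogeneous disk phantom (multiplicative Gaussian-blob bias
of strength 0.5, noise σ = 0.02), segment it with the combined model and
with the global-only ablation, and score both against the known truth:

```
$ spfseg phantom --geometry disk --shape 128 128 --bias gaussian_blob \
      --bias-strength 0.5 --noise 0.02 --seed 1 --out phantom
$ spfseg segment2 phantom/image.png --mode proposed --init 30 60 30 60 --out seg_proposed
$ spfseg segment2 phantom/image.png --mode gcv      --init 30 60 30 60 --out seg_gcv
$ spfseg evaluate seg_proposed/mask.png phantom/truth.png --best-permutation
{"mean": 1.0, "per_label": {"0": 1.0, "1": 1.0}}
$ spfseg evaluate seg_gcv/mask.png phantom/truth.png --best-permutation
{"mean": 0.7640921978430377, "per_label": {"0": 0.904752800825909, "1": 0.6234315948601663}}
```

The combined force recovers the disk exactly (Dice 1.0 for both labels)
while the global-only force misses the dim side of the object and leaks
into the brightened background near the bias apex (object Dice 0.62). Each
run writes an iteration log (`log.jsonl`: changed-pixel count and region
means per iteration) and its fully resolved configuration (`config.json`);
re-running with `--config` reproduces the outputs byte-for-byte. Four-phase
segmentation (`spfseg segment4`) emits an integer label map plus a legend
mapping labels to sign pairs; NIfTI volumes are processed slice-wise.

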