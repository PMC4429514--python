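# Methods

## Model

`spfseg` segments a grayscale image I : Ω → [0, 1] by evolving one (two-phase)
or two (four-phase) level-set fields under a signed pressure force (SPF)
instead of a gradient-based edge-stopping function. The SPF is a per-pixel
value in [−1, 1] whose sign tells the contour to expand (inside the object)
or shrink (outside); its construction is the substance of the package.

**Regularized step and impulse.** All region statistics use the smooth
Heaviside H_ε(z) = ½(1 + (2/π) arctan(z/ε)) and its exact derivative, the
Lorentzian δ_ε(z) = ε/(π(ε²+z²)). Two widths are carried: `eps_h` for region
weighting and `eps_d` for update localization, both defaulting to 0.3. The
classical global-fitting literature uses ε = 1.0; 0.3 is the compromise
this model is built around (see the sensitivity experiment below). Note
that with ε = 0.3 a binarized field gives H(±1) ≈ 0.90/0.10, so "region
means" are always mildly blended with the opposite region — a property
that matters for the four-phase dynamics (below).

**Two-phase force.** With c₁, c₂ the H-weighted means inside/outside the
contour and f₁, f₂ the Gaussian-window local fits
fᵢ = K_σ∗(w·I)/K_σ∗(w) (w = H or 1−H, σ_fit = 5 px):

- s_g = (I − (c₁+c₂)/2) / max|·| (global),
- s_l = (I − (f₁+f₂)/2) / max|·| (local),
- S = ω s_g + (1−ω) s_l, clipped to [−1, 1] (the convex combination can
  exceed the bound by one ulp in floating point; the contract is hard).

A constant image produces a (numerically) zero deviation field and hence a
zero SPF — no evidence, no force. All normalization denominators are
floored at 1e−12.

**Adaptive weight.** ω(x) = exp(−β·C_R(x)/mean(C_R)), β = 1, with C_R the
Michelson contrast (max−min)/(max+min+1e−8) over a 5×5 replicate-padded
window. ω is computed once from the input image (C_R depends only on I),
lies in (0, 1], is scale-invariant under positive intensity rescaling, and
decays where contrast is far above the image average. Semantics: smooth
regions → ω near 1 → the global force sweeps the contour quickly and keeps
it from stalling in flat areas; near edges → ω near 0 → the local force
places the boundary accurately even under a strong bias field. In noisy
images the mean contrast is set by the noise floor, so "smooth" regions
sit near ω ≈ e^{−1} rather than 1; the qualitative division of labor is
unchanged.

**Evolution.** One iteration: build S from the current field; advect
φ ← φ + Δt·α·S·|∇φ| (central differences, replicate boundary); binarize
(φ > 0 → +1, else −1 — zero is outside); smooth with a Gaussian of
σ_reg = 1. The binarize-then-smooth step is the selective-binary
regularization: it keeps φ in [−1, 1], confines |∇φ| to a band around the
interface, and removes both the curvature term and signed-distance
re-initialization. With σ_reg = 1 the implied threshold dynamics pin at the
grid scale, so flat interfaces and thin structures are not eroded while
single-pixel roughness is. The balloon force α sets speed and orientation:
α > 0 makes the positive phase capture the brighter side. The CLI picks
the sign automatically from which side of (c₁+c₂)/2 the initialization's
mean intensity falls; its magnitude defaults to 20 but is a per-image
choice (the experiments here use 20 for two-phase, 30 for the four-quadrant
phantom and 50 for the brain-like phantom).

Initialization is binary: +ρ strictly inside a rectangle or mask, 0 on its
inner boundary, −ρ outside (ρ = 2; any positive value gives the same
trajectory after the first binarization). Convergence is declared when the
thresholded mask changes by ≤ `tol` pixels (default 0) for 3 consecutive
iterations, capped at `max_iters` = 200. The solver contains no randomness.

Modes: `proposed` (adaptive blend), `gcv` (ω ≡ 1, global-only) and `local`
(ω ≡ 0, local-only) — the last two double as ablation baselines.

## Four-phase extension

Two fields encode four regions by sign pairs; memberships
M₁ = H(φ₁)H(φ₂), M₂ = H(φ₁)(1−H(φ₂)), M₃ = (1−H(φ₁))H(φ₂),
M₄ = (1−H(φ₁))(1−H(φ₂)) sum to 1 algebraically (observed float deviation
≤ 2e−16). Region means cᵢ and local fits fᵢ generalize the two-phase
statistics with M-weights.

The force on φ₁ is a pairwise **region competition** conditioned on φ₂:

D₁ = H(φ₂)(|I−r₃| − |I−r₁|) + (1−H(φ₂))(|I−r₄| − |I−r₂|),

with rᵢ = cᵢ (global) or fᵢ(x) (local), each normalized by its max and
blended with the same ω; symmetric for φ₂ with pairs (1,2)/(3,4). For an
ordered pair this equals the sign of I minus the conditional midpoint of
the competing references — the direct generalization of the two-phase
force — saturating at the pair separation. Two properties drove this
choice over a fixed conditional-midpoint field: (i) it points the right
way even when a transient inverts the brightness ordering of a pair (a
fixed midpoint form then drives a phase into irrecoverable collapse), and
(ii) its saturated dynamic range keeps normalized competition forces deep
inside regions strong enough to reassign mislabeled territory. A quadratic
(energy-gradient) competition satisfies (i) but not (ii): its extremes
dominate the max-normalization and interior forces drop below the
reassignment threshold.

Updates are Dirac-localized, φᵢ ← φᵢ + Δt·α·Dᵢ·δ_ε(φᵢ), then binarized and
smoothed as in two-phase. On a binarized field δ_ε(±1) ≈ 0.088 (ε = 0.3),
so a far-from-interface pixel flips only when α·δ_ε(1)·|S| > 1. This is
the mechanism behind the Dirac-width trade-off: ε = 0.1 nearly forbids
far-field reassignment (the flow strands in local minima), ε = 0.8
reassigns freely but mislocates boundaries even from a perfect start;
ε = 0.3 does both acceptably, and the brain-phantom experiment reproduces
exactly this ordering.

**Initialization matters more in four-phase.** Because H is soft, a phase
whose hard region vanishes gets a mean blurred toward the global image
mean, which typically repels exactly the pixels it should claim — an
absorbing three-class state. Generic overlapping rectangles reach the
correct four-class equilibrium on the four-quadrant phantom (crossed
rectangles; the equilibrium itself is strongly attracting: started from
the true configuration the flow stays there), but on three-tissue images
they reliably strand one tissue. `quantile_initializations(image)` (φ₁
positive above the median intensity, φ₂ above the 0.8 quantile) starts
every sign class near a coherent intensity band and is the recommended
default for multi-tissue images. Labels are read off the final sign pairs;
for T1-like images tissue names are assigned post hoc by brightness
ranking (brightest = WM).

## Synthetic phantoms

`make_phantom` renders piecewise-constant geometries (disk, rectangle,
hand-like polygon, two vessels, four quadrants, brain-like nested rings)
and corrupts them as `clip(v[truth]·(1+bias) + N(0, σ), 0, 1)`:
multiplicative bias (MR inhomogeneity scales tissue intensity; additive
would not), then Gaussian noise, then clipping (which slightly truncates
the noise at the range ends). Bias fields are a zero-mean linear ramp
(endpoints ±strength) or a centered Gaussian blob rescaled to +strength at
the apex and −strength at the far corners (width 0.25·min(shape)).

The disk is deliberately placed off the blob apex (center 0.35·shape,
radius 0.2·min(shape)): a bias concentric with the object rescales both
classes identically at every radius and leaves them globally separable,
whereas the misaligned bias makes the object's dim side darker than the
brightened background — the failure regime of global-only models that the
package exists to handle. Default two-region intensities are 0.4/0.6
(low-contrast, soft-tissue-like); the brain rings use 0.05/0.35/0.6/0.85
(background < CSF < GM < WM, T1-like ordering).

The generator draws all randomness from `default_rng(seed)`; identical
specs are bit-identical. The solver itself is RNG-free, so end-to-end runs
are reproducible byte-for-byte.

What the phantoms do **not** emulate: Rician noise statistics, partial
volume mixing at tissue interfaces, anatomical shape variability, and
slice-dependent bias. Passing phantom experiments therefore demonstrates
correct mechanics under controlled inhomogeneity and noise, not clinical
segmentation accuracy.

## Study conditions used by the tests and acceptance script

Problem sizes are chosen so the full experiment battery runs in seconds on
one core while keeping every structure several kernel widths across:

- Biased disk (128², blob strength 0.5, noise 0.02): combined model vs
  global-only ablation, rectangle init overlapping the disk.
- Two-vessel robustness (128², intensities 0.3/0.7, ramp 0.2, noise 0.01):
  four large init rectangles, each straddling both vessels; minimum
  pairwise Dice across inits and against truth, combined vs local-only.
  The raised contrast keeps the biased background on one side of the
  evolving global midline — the regime the robustness claim belongs to; a
  stronger overlap makes every global-weighted model leak by design.
- Brain rings (96², blob 0.2, noise 0.01): quantile inits, α = 50,
  50 iterations, ε_d ∈ {0.1, 0.3, 0.8}.
- Four-quadrant (96², noise-free): crossed rectangle inits, α = 30.

## Numerical choices and edge cases

- Gaussian kernels: truncated at ⌈3σ⌉, renormalized to sum 1; all
  convolutions and min/max filters use replicate padding, so constant
  fields are fixed points and the image border exerts no spurious force.
- Degenerate region (total weight < 1e−12) in the two-phase means: that
  side falls back to the global image mean with a warning (with the arctan
  Heaviside this cannot occur for finite fields; it guards pathological
  input).
- Empty-vs-empty Dice is defined as 1 (agreement of empties), logged.
- Best-permutation label matching searches all bijections between label
  sets (≤ 4! here) and reports per-reference-label Dice.
- Binarize maps exactly 0 to −1 (strict positivity defines the object).
- Images are min–max rescaled to [0, 1] on load; constant images map to
  0.5 with a warning. All parameter defaults are calibrated to this scale.

## Known limitations

- Two-phase evolution moves a front; with |∇φ| localization it cannot
  claim bright components disconnected from the initialization (the
  four-phase Dirac localization can). Initialize across all objects of
  interest.
- The adaptive weight trusts the global force in smooth regions; if a
  bias field pushes a smooth background region across the global midline,
  the combined model follows the global force there and mislabels it.
  That regime needs either stronger class contrast or bias correction.
- Four-phase segmentation from arbitrary blob initializations can strand
  a tissue class (see above); use quantile initializations.
- α is a per-image choice (sign and magnitude); the automatic sign helper
  covers the common bright-object case only.
- Volumes are segmented independently slice-wise; no 3-D regularization.
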