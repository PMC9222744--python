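# Methods

## Model and pipeline

`nedsem` segments the banded edge of melanoma dermoscopy images in six
stages: RGB channel split → neutrosophic (T, I, F) conversion → single-valued
neutrosophic entropy → R−B feature augmentation → dilation → MRF-regularized
hierarchical Gaussian mixture (HGMM) clustering. The stages are pure
functions over `(H, W)` float arrays; nothing resamples, so every
intermediate aligns pixel-for-pixel with the input.

### Morphology

All operators are flat grayscale morphology (min/max filters under a binary
footprint) with reflect padding, so constants are fixed points and the frame
introduces no artificial edges. Closing is dilation followed by erosion —
the composition that fills dark holes and removes thin dark artifacts, which
is its role here (hair suppression before brightness is read off).
Structuring elements are configurable (`disk`, `square`, `cross`; default a
5×5 disk, i.e. radius 2). The disk radius trades artifact suppression
against boundary detail: radius 2 removes 1–3 px hairs while shifting region
boundaries by at most 2 px.

### Neutrosophic conversion and entropy

T is the min-max normalized closing of the channel; F = 1 − T; I is the
min-max normalized absolute morphological gradient. Degenerate inputs are
defined explicitly: a constant channel has T = 0.5 (maximal ambiguity
between membership and non-membership) and I = 0 (no edges). Both T and I
are invariant to positive-affine rescaling of the channel, a property the
test suite checks and the feature construction relies on.

The entropy of a neutrosophic point is E = 1 − (2/√3)·d with d the Euclidean
distance from (t, f, i) to the axis {t = f, i = ½}. The normalization 2/√3
makes E span exactly [0, 1] over the unit cube (the farthest corners, e.g.
(1, 0, 0), sit at d = √3/2). E is applied per pixel so the entropy *map*
preserves spatial structure; the aggregate (mean) entropy is exposed as
`EntropyMatrix.scalar`. The reference indeterminacy is fixed at ½, which is
what makes the |1 − 2i|/2 term the intuitiveness distance.

### Feature

R_b = E_R − E_B. Melanin makes the core dark in red while the blue-gray veil
keeps its blue component relatively high; the pigmented rim is red-brown
(blue-dark). Consequently E_R peaks on and inside the band, E_B peaks on the
outer rim and the veil, and the difference is positive on the band, negative
on the core and ≈0 on background — a univariate feature separating the three
regions. The default pipeline dilates R_b *after* subtraction
(`rb_then_dilate`); the alternatives (`dilate_then_rb`, `none`) are kept as
ablation options and score measurably worse on the noisy phantom (band Dice
0.84 vs 0.75 vs 0.70 at seed 1), because subtracting first cancels artifact
energy common to both channels before it can be spread by the dilation.

### HGMM with MRF prior

Each of K categories carries a density Σ_r η_jr G(x | μ_jr, Σ_jr); the
default R = 1 reduces to a plain Gaussian per category, and R > 1 is
supported through nested responsibilities (z_ijr = z_ij η_jr G_jr / D_ij)
driving per-sub-component moments and η updates. Features are univariate
(the DI matrix); variances are scalars floored at 1e-8, and a category whose
responsibility mass vanishes is re-seeded at the least-explained data point.

The MRF enters through g_ij = exp[β/(2|N_i|) Σ_{m∈N_i}(z_mj + π_mj)] over
the 8-connected neighborhood (truncated at borders — the average divides by
the actual neighbor count) and the self-normalizing prior update
π_ij = (z_ij + g_ij)/Σ_j(z_ij + g_ij), which absorbs the MRF partition
function. The prior's posterior influence is therefore *bounded* (odds
roughly (1+e^β)/2 at saturation): it flips pixels whose likelihood is mildly
wrong but cannot override decisive likelihoods. β defaults to 2.0 — enough
to remove isolated single-pixel islands in overlapping-cluster regimes
without erasing genuine thin structure; β = 0 switches the prior off.

Iteration order is E-step → neighborhood weights → M-step; the objective
Σ z(log π + log D) + Σ g log π is recorded per iteration and iteration stops
when its gain drops below `conv_tol` (default 0.1). Only the β = 0,
shared-prior reduction is guaranteed monotone (it is exactly textbook
GMM-EM, and its incomplete-data log-likelihood trace is asserted
non-decreasing in the tests); the MRF-augmented objective carries no such
guarantee and none is claimed.

**Initialization.** Category means start at the sorted centers of a seeded
k-means run (sklearn, `n_init=4`), sub-means at within-category quantiles
with a tiny symmetry-breaking jitter; variances at the global variance;
priors uniform. Quantiles of the raw data were tried first and rejected:
with a dominant background mode (~60 % of pixels near feature 0) all K
quantiles land near zero and EM converges to a degenerate solution in which
one wide component absorbs both core and band. k-means initialization is the
standard remedy and everything remains deterministic given `seed`.

**Label semantics.** Cluster indices are arbitrary, so the mask is relabeled
by region statistics: the cluster with the highest mean feature value is the
banded edge (the feature is constructed to peak there); among the remaining
clusters the one with the lowest mean red intensity is the core (melanin
absorbs red); the rest are background. With K = 2 the split is lesion vs
background and no core label is assigned.

## Synthetic phantom

The generator emulates the dermoscopic appearance that gives the method its
signal: a dark core with *relatively elevated blue* (blue-gray veil, default
RGB (70, 60, 95)), a red-brown banded edge (default (150, 75, 60)), and
light skin (default (195, 150, 130)), blended radially core → band → skin by
two smoothstep ramps across a wobbled annulus (default inner radius 25 px,
outer 40 px on 128×128, wobble amplitude 2 px over 4 harmonics, additive
Gaussian noise σ = 4). A distinct band color is essential, not cosmetic: if
each channel merely interpolated core → skin, all channels would be
positive-affine images of one another, the affine-invariant NS conversion
would make E_R ≡ E_B, and the R_b feature would vanish identically. The
harder fixture used for the ablations adds σ = 8 noise, 8 hair strokes and
4 bubbles. Hair strokes are quadratic Bézier curves 1–3 px wide; where
strokes overlap they exceed the default disk and closing removes only part
of their edge energy (roughly half on the default phantom), which is the
realistic regime the R−B cancellation is meant to mop up.

What the phantom does *not* emulate: pigment-network texture, multi-focal
lesions, ruler markings, vignetting, and the full color diversity of
clinical dermoscopy. Passing tests therefore demonstrate that the
implementation realizes the model faithfully and behaves as designed on
images with the assumed three-region radial structure — not clinical-grade
accuracy on real data.

## Problem sizes and numerical choices

Tests and the acceptance script use 128×128 phantoms (16 384 pixels), a
64×64 three-level image for parameter recovery (true means 0.2/0.5/0.8,
σ = 0.05; recovered within ±0.02 after Hungarian matching), a 64×64
two-region image with σ = 0.15 noise plus 5 % uniform-valued impulse speckle
for the MRF-smoothing comparison, and 2 000 samples for the textbook-EM
reduction check (agreement to 1e-6 per iteration). These sizes were chosen
so the whole suite runs in seconds while every estimate is far from its
small-sample regime. Probabilities are floored at the machine-tiny value
inside logs; responsibilities are computed in log space with logsumexp, so
underflow never raises.

## Known limitations

- K must be chosen by the user (default 3); no model selection is provided.
- The banded-edge identification heuristic assumes the feature peaks on the
  band; on images without a band (e.g. fully crisp lesions) the highest
  cluster is still called "banded edge".
- The MRF prior cannot repair errors backed by decisive likelihoods; heavy
  compact artifacts (overlapping hairs, large bubbles) survive it.
- The fuzzy c-means baseline is a minimal standard implementation (fuzzifier
  m = 2) included for comparison only.
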