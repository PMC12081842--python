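# Methods

## Problem and approach

Manual gating of flow-cytometry data draws boundaries (gates) on 1-D or
2-D plots to select cell subpopulations, with each gate conditioning on
its parent population.  Because instrument drift and biological
variability shift populations between samples, a fixed template gating
strategy placed on one sample rarely fits the next.  `elastigate` treats
this as an image-registration problem: each plot of a manually gated
*training* sample is rendered as a grayscale density image, elastically
registered onto the corresponding plot of an ungated *target* sample, and
the recovered deformation is applied to the training gate vertices.  The
hierarchy is walked top-down so that every plot is built from the events
of its (already adapted) parent population.

The pipeline for each plot is:

1. **Density imaging.**  Events (in normalized plot units, see below) are
   binned onto the plot's pixel grid; counts are converted to `L` gray
   levels by `gray = round((L-1) · log(1+max(c-d,0)) / log(1+max))`,
   where `d` is the *density level*.  `d = 0` keeps maximum sensitivity
   to sparse regions; larger `d` filters sparse areas out before
   normalization.  The log law is this package's concrete choice of the
   "flattening" normalization; it is tested against its qualitative
   contract (monotone in counts, anti-monotone in `d`, full-range).
2. **Training-plot selection.**  With several training samples, the one
   whose density image has minimum L2 error (summed squared gray
   difference) against the target image is chosen, per plot; ties break
   to the lowest index.  Different plots of one target may therefore use
   different training samples.
3. **Elastic registration** (below), producing a training→target map.
4. **Gate transfer.**  Gate vertices map through the deformation field
   (bin-centre pixel convention `p = v·W − 0.5`), with optional vertex
   densification before and Douglas–Peucker simplification after, then
   clamp to the plot.  Rectangles and quads can be preserved
   (axis-aligned; a rectangle keeps the min/max of its two mapped
   defining corners, a quad maps only its crosshair centre) or split into
   polygons for full freedom.
5. **Classification.**  Events are assigned by point-in-gate tests
   (even-odd rule with boundary points inside for polygons; closed
   intervals for rectangles/ranges; half-open quadrant splits so a quad
   group partitions the plane) intersected with the parent mask.

## Normalized plot units

All event values and gate vertices are stored in [0, 1] per parameter
after a per-parameter display transform (linear, log10, or a scaled-asinh
biexponential `f(d) = (asinh(d/w) − asinh(−10^A)) / (asinh(10^M) −
asinh(−10^A))` with `w = |width_basis|`, `A` negative and `M` positive
decades).  The same transform configuration applies to every sample of a
run, so plots share an identical scale range and registration only has to
explain genuine data movement.  Each transform is strictly monotone with
a closed-form inverse (round-trip exact to 1e-9 over its stated range).
Pixel bins are half-open `[i/W, (i+1)/W)` with the last bin closed, origin
bottom-left.

## Deformation model and energy

The displacement is a tensor-product cubic B-spline on a uniform control
grid over the plot: `T(x) = x + Σ_ij c_ij β₃(x/s − i) β₃(y/s − j)`.  An
axis with `n` control intervals carries `n+3` coefficients (one margin
control point past each end), so the basis is a partition of unity on the
whole plot and zero coefficients give the identity exactly.

Two fields are estimated jointly: the backward field (target→training)
that resamples the source image for the similarity measure, and the
forward field (training→target) that is applied to gate vertices.  The
energy, minimized deterministically by L-BFGS from the identity with
analytic gradients, is

```
E = w_sim · [ Σ (S(T_bwd(x)) − T(x))² + Σ (T(T_fwd(x)) − S(x))² ]
  + w_reg · Σ (div u)² + (curl u)²          (both fields)
  + w_cons · Σ ‖T_fwd(T_bwd(p)) − p‖² + ‖T_bwd(T_fwd(p)) − p‖²
```

with images lifted to [0, 1] (`gray/(L−1)`) and sampled by cubic spline
interpolation; the consistency sum runs over a fixed probe grid (17 per
axis).  Estimating the forward map directly, tied by the inverse
consistency penalty, avoids numerically inverting a spline field for
vertex transfer.

Defaults: `w_sim = 1`, `w_reg = 0.1`, `w_cons = 1`; control grid refined
from 4×4 to 16×16 intervals over `log2(16/4)+1 = 3` pyramid levels, with
a Gaussian image pyramid synchronized to the control grid (level images
never below 16 px).  Between levels the coarse solution is carried
forward by a separable least-squares refit of the coefficients onto the
finer basis.  Each level's energy is normalized by its starting value and
optimization stops at a relative decrease below `rel_tol = 1e-4` or 200
iterations; non-convergence is reported in the result, not raised.  The
1-D histogram path uses the same energy with 1-D splines (regularizer
`Σ (du/dx)²`).

Numerical notes: sampling positions are clipped to the image and the
similarity gradient is masked where clipped; the optimizer records a
per-level energy trace (non-increasing across accepted iterates); all
steps are deterministic — no random initialization anywhere.

## Sparse-plot up-sampling

A plot whose grid has fewer than 0.5 % of bins occupied or fewer than
2000 binned events is replaced by a Gaussian-smoothed copy (σ = 1.5 px)
whose integer counts preserve the total mass exactly via
largest-remainder apportionment.  The thresholds are heuristic and
config-exposed; smoothing the *image* is this package's stand-in for the
qualitative "automatic up-sampling of sparse plots" behaviour, which
could equally be implemented by resampling events.

## Evaluation

Automated and ground-truth populations are compared event-wise over the
identical event set: `F1 = 2TP/(2TP+FP+FN)`.  When both masks are empty
the score is defined as 1.0 and flagged; summaries instead exclude gates
whose truth population is below a `min_cells` threshold (default 0,
surfaced on the CLI; 40 is a sensible choice for small panels).  Per-gate
summaries report median, mean and SEM (sample standard deviation, ddof 1;
a single retained row has SEM 0) across samples, plus the overall median
across all retained (gate, sample) pairs.

## Synthetic panels

The generator draws samples from Gaussian mixtures whose components
stand in for cell populations; per-sample perturbations are a translation
of the means (shared across populations by default, emulating
instrument-level drift), a covariance scale factor, and an abundance
multiplier.  Oracle gates are the perturbed components' Mahalanobis
3.5-σ ellipses polygonized at 16 vertices (an inscribed 16-gon at 3.5 σ
still covers > 99.7 % of a 2-D Gaussian; at 3 σ coverage would fall just
below 99 %).  Oracle membership is the component label, not geometry, so
scoring punishes both misplaced gates and events genuinely outside any
gate.

Preset conditions (all config-exposed; sizes chosen as a realistic desk
scale for a three-to-five population assay):

| preset  | populations | events/sample | drift (translation) | image |
|---------|-------------|---------------|---------------------|-------|
| scatter | 3 (lymph/mono/gran analogue on FSC/SSC) | 5000 | up to ±0.08 | 128² |
| beads   | 5 equal 1-D peaks, σ 0.018 | 5000 | up to ±0.04 | 256 bins |
| hier    | debris + 3 T-cell subsets; scatter gate then CD4/CD8 quad | 6000 | up to ±0.05 | 128² |

Scale drifts span [0.95, 1.05] and abundance multipliers [0.7, 1.3].

What the generator does **not** emulate: spillover spreading error,
autofluorescence, acquisition-time drift within a sample, doublets, and
heavy non-Gaussian tails.  Passing the synthetic suite therefore shows
that the algorithm recovers known geometric drift under realistic
density structure — not that it matches expert gating on any particular
biological dataset.

## Design choices made where the design was open

- **Bidirectional estimation** instead of registering once and inverting:
  vertex transfer needs the forward map while SSD needs backward
  sampling; joint estimation with a consistency penalty gives both
  without numerical inversion.
- **Compensation convention**: with spillover matrix `S` (row `i` =
  detector, column `j` = dye), compensated events solve `S·x = observed`
  per event.  Compensation runs only when a matrix is supplied or present
  in the file's `$SPILLOVER` keyword.
- **FCS I/O** is a minimal built-in FCS 3.0/3.1 list-mode reader/writer
  (float/double/integer data, uniform bit width, `$SPILLOVER` honoured);
  ANALYSIS segments and keyword escaping are not supported.
- **Degenerate gates**: a rectangle or range that collapses under the
  deformation, or a polygon that degenerates, is kept at its original
  geometry with a warning rather than dropped; gates with > 5 % of
  vertices clamped at the plot border are flagged for review.
- **Quad groups** share one transformed crosshair by construction
  (preserve on), so the four quadrants always partition the plot.

## Known limitations

- SSD similarity assumes comparable density rendering between training
  and target; strongly different event counts are only partly absorbed by
  the per-plot gray normalization.
- Deformations larger than roughly the coarsest control spacing
  (~1/4 of the plot) are outside the capture range of the multiresolution
  scheme.
- Boolean gates, FMO-linked workflows, ellipse gates, and >2-D gating are
  out of scope; GatingML import is an extension point, not implemented.
- The F1 comparison assumes identical event sets (same file, same
  pre-processing) for prediction and truth.
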