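# Methods

## Data model and reduction

A dataset is a complete N x M x R grid of scans: N tissue samples, each
scanned R times on each of M multispectral microscopes. A scan is a set of
HPF tiles, each an H x W x K stack of uint16 counts (one multi-page TIFF
page per narrowband layer; page order defines the 0-based layer index k).
Layers are grouped by the broadband filter cube they were acquired through;
exposure times are stored per (scan, broadband group), because acquisition
auto-exposes per broadband filter, and are broadcast to member layers when
converting counts to flux (counts/ms).

Per tile, a single 2-D binary mask removes background and saturated pixels:

* Background: Otsu's threshold (scikit-image) on a projection image — by
  default the per-pixel mean over all exposure-normalized layers,
  configurable to a named layer subset. The threshold is computed per HPF.
  Saturated pixels are excluded from the Otsu histogram; their off-scale
  values would otherwise dominate the between-class variance and collapse
  the background/tissue split. For integer projections the histogram uses
  one bin per integer level, making the threshold an exact minimizer of the
  intra-class variance; float projections use 256 bins. A constant
  projection leaves Otsu undefined: the mask keeps all non-saturated pixels
  and a warning is emitted.
* Saturation: a pixel above its per-layer threshold (default 65500 counts,
  configurable per layer) in any layer is removed from all layers, matching
  the single-mask accumulation below.

No morphological cleanup is applied.

Each scan reduces to one spectrum: the masked mean image
M = sum_h(B_h I_h) / sum_h(B_h) (double-precision streaming sums; pixels
with zero coverage are set to 0 and a warning fires above 50% zero
coverage), averaged over all H x W pixels per layer — zero-coverage pixels
deliberately stay in the divisor, so a scan's spectrum scales with its
tissue area on the tile frame. Spectra are then weighted by each scan's
share of all HPFs in the dataset and divided by the grand mean, giving the
stage-X tensor with grand mean exactly 1. The HPF count per scan includes
all acquired tiles, masked-empty or not.

## Correction model

Stage X is modelled as (sample amplitude B_n) x (microscope amplitude C_m)
x (sample spectral profile b_nk) x (microscope spectral profile w_mk) x
noise. Fitting is sequential — amplitudes, then tissue profile, then
microscope profile — with each factor a ratio of unweighted arithmetic
means over the complete grid (incomplete grids are an error, never silently
reweighted; every formula assumes the full N x M x R design). Each
correction is applied exactly once; there is no joint refit or iteration.
On exact product data the sequence is idempotent: refitting on corrected
spectra returns factors of 1 to machine precision. Factors are identified
only up to mean-one gauge conventions, so comparisons against simulator
ground truth always go through gauge fixing (below).

The microscope profile decomposes as w_mk = w_ill,m x w_BB,mk x w_NB,mk:
the overall illumination scale (mean over layers), the broadband part
(within-group mean of w/w_ill, constant within each filter group), and the
narrowband remainder (mean one within each group). The reconstruction is
exact by construction.

## Diagnostics

The headline statistic is the per-layer standard deviation of the N*M*R
values at each layer, averaged over a designated layer set, reported as
percent of the (about-one) normalized flux. The per-layer std uses the
sample convention (divisor NMR-1); the choice is immaterial at the design
sizes used but is recorded in every report. For unmixed spectra the
autofluorescence component is excluded from the layer average on request.

The layer-projected covariance centers each observation on its own
microscope's per-layer mean over (n, r) and pools over all (n, m, r) with
divisor NMR (population convention, following the defining formula). This
centering makes the matrix blind to static between-microscope offsets and
sensitive to correlated within-microscope structure; on data with
group-level fluctuations it shows the block pattern of the broadband
filter groups.

## Bootstrap generalization

Tissue effects are first homogenized on the full dataset: chi = X / B_n,
beta_nk (the sample-profile analogue, per-layer sample mean one) fit from
chi, psi = chi / beta_nk. Each iteration takes a fit subset of N' samples
(default: all C(N, N') subsets exhaustively, in lexicographic order, making
the whole procedure deterministic; seeded random subsets are available for
large N), computes C_ms as the mean amplitude over fit samples and scans,
and fits omega_mks from the amplitude-corrected psi / C_ms — the same
amplitude-then-profile order as the main model. Computing omega from raw
psi instead would leave the microscope amplitude in omega and divide it out
twice in z = psi / (C_ms omega_mks), retaining a 1/C_m residual; the
sequential form is the self-consistent convention this package uses.
Residual layer-averaged stds are computed separately for fit and held-out
samples; the summary reports their means and stds across iterations plus
the elementwise factor means.

For standardization the per-(m, k) scale is the product of the separate
across-iteration means of C_ms and omega_mks (mean-of-products is available
as an option; the two differ only at second order in the across-iteration
spread). Dividing by the reference microscope's own scale gives factors
that leave reference data bitwise unaltered. Because the factor is a
per-layer scalar it applies equivalently to count or flux stacks; output
stays floating point by default, with opt-in half-to-even requantization to
uint16.

## Spectral unmixing

Per pixel, non-negative least squares against a K x K' library (K'
components: markers plus autofluorescence) — the standard linear unmixing
formulation, used here as a documented surrogate for proprietary vendor
unmixers whose algorithms are not public. Implementation: one vectorized
unconstrained least-squares solve for all pixels, with per-pixel active-set
NNLS (scipy) only where the unconstrained optimum leaves the non-negative
quadrant; deterministic for fixed input. Rank-deficient libraries yield a
warning and one valid optimum; the minimum-norm tie-break over the optimal
face is not implemented. Unmixing operates on flux (exposure-normalized)
input.

The scenario harness reduces unmixed stacks exactly like raw ones (masked
mean image, layer means, HPF weighting, grand normalization at K' layers),
removes sample effects via the amplitude and sample-profile analogues, and
compares residual stds across three routes: (A) raw images with the
reference microscope's library, (B) raw images with each microscope's own
library, (C) standardized images with the reference library. On simulated
data with planted microscope differences the ordering std(C) < std(B) <
std(A) holds: per-microscope libraries compensate spectral shape but not
overall amplitude, while standardization compensates both.

## Synthetic data generator

Expected tile flux is background + tissue(i,j) x A_n g_m t_nk omega_mk x
scene(i,j,k) x signal scale, realizing exactly the multiplicative structure
the corrections assume, with omega built as illumination x broadband-group
offsets x smooth narrowband ripple. Counts are exposure-scaled, perturbed
by multiplicative Gaussian noise and per-scan amplitude jitter, salted with
saturated pixels, rounded, and clipped to uint16.

Scenes (tissue region from a thresholded smooth field; log-normal texture;
in marker mode, smooth non-negative abundance maps times a well-conditioned
synthetic reference library) are drawn once per sample and shared across
microscopes and scans — the same physical slide is what gets re-scanned.
The scene and acquisition-noise random streams are separate, so the same
slides can be "re-scanned" with fresh noise (used for Monte-Carlo standard
errors of the fitted factors). Per-microscope libraries are the reference
library seen through each instrument's amplitude and spectral profile, then
column-normalized: pure-spectrum libraries carry shape, not absolute
brightness, which is what makes scenario B intermediate between A and C.

Defaults are the study design at desk scale: N=8, M=3, R=2, K=12 in 3
groups, 64x64 tiles, 4 HPFs/scan; sample amplitude spread ~15%, microscope
amplitude ~10%, tissue spectral ripple ~8%, broadband offsets uniform up to
+/-20% (the scale at which broadband filter cubes have been observed to
differ), narrowband ripple ~3%, counting noise CV 1%, scan jitter 0.5%,
saturation fraction 0.2%, exposures 10-40 ms per (microscope, group) with
+/-5% per-scan variation. The scenario experiments use 32x32 tiles with 5
components (4 markers + autofluorescence).

`gauge_fix_truth` expresses planted factors in the estimators' gauge by
pushing the noiseless expected dataset (true-region masks, no rounding)
through the exact reduction and fit equations — the only gauge in which
fitted and true factors are directly comparable, since masked spatial
averaging and the mean-one conventions both enter the mapping from
generative to fitted parameters.

What the simulator does not emulate: real fluorophore emission chemistry
and bleed-through, optical point-spread functions, tile overlap and
stitching, spatial flat-field structure within a tile, staining-batch
effects, and the model-mismatch couplings of real tissue beyond a
multiplicative sample-profile term. Passing tests therefore demonstrate
correctness of the estimators under the model's assumptions and robustness
to realistic noise — not that real instruments satisfy the model.

## Numerical conventions and limitations

* All accumulation in float64; factors persisted at full precision.
* Mean-one gauges enforced to 1e-9..1e-12 in tests; decomposition and
  round-trip identities to 1e-12.
* Zero denominators (empty layers, zero factors) raise errors rather than
  propagate NaNs; degenerate Otsu input falls back with a warning.
* Exhaustive bootstrap + fixed seeds make full runs byte-reproducible;
  every output CSV carries a hash of the run configuration.
* Residual stds below ~0.5% on synthetic data are dominated by scan jitter
  and count quantization, not by the correction model.
* Whole-slide stitching, per-pixel flat-fielding, cross-institution
  transfer, and staining-batch standardization are out of scope.

## Problem sizes

Tests and the acceptance script run the full design at 64x64 (calibration,
bootstrap) and 32x32 (unmixing scenarios) tile sizes with K=12 layers —
small enough for interactive iteration while keeping every structural
property of the full-scale design (complete N x M x R grid, 56-subset
exhaustive bootstrap, 7-group default layout at K=43 for layout-level
checks). Full-size generation (1872 x 1404, K=43) is available through the
same configuration object.
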