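# Methods

This note documents the models, parameter choices and numerical decisions
behind `semsharp`, and what the synthetic test conditions do and do not
show about real micrographs.

## Scope and assumptions

The package scores *blurriness* (defocus-type distortion) of single-channel
micrographs. It assumes the image content is edge-dominated: strong region
boundaries (grain edges, sample/tape boundaries) carry the structural
information, while texture and noise are perceptually redundant. All
scoring happens on the cartoon component; images whose salient content is
pure texture with no strong boundaries are outside the method's design
regime. Other distortions (astigmatism, charging, drift) are not modeled
and will be conflated with blur insofar as they suppress high-frequency
content.

Pixels are internally rescaled to a canonical [0, 255] floating-point range
regardless of source bit depth, so every constant below applies verbatim to
8- and 16-bit inputs. Images smaller than 64×64 are rejected (one 32×32
analysis block plus margin).

## Cartoon-texture decomposition

The nonlinear filter pair computes, at scale `σ` (default 3 px):

- `LTV_σ(f) = L_σ * |∇f|`, with `|∇f|` from central differences under
  replicate padding and `L_σ` a normalized Gaussian truncated at radius
  `⌈4σ⌉`;
- the relative reduction rate
  `λ_σ = (LTV_σ(f) − LTV_σ(L_σ*f)) / LTV_σ(f)`, defined as 0 where
  `LTV_σ(f) = 0` (flat regions are cartoon by definition) and clamped to
  [0, 1] before thresholding, since numerical overshoot would otherwise
  leak through the weight;
- the soft threshold `w(λ)` with knees `a1 = 0.25`, `a2 = 0.5`;
- `u = w·(L_σ*f) + (1−w)·f` and `v = f − u` (reconstruction is exact by
  construction).

`σ` trades texture removal against edge fidelity: smaller values leave
texture in the cartoon, larger values misclassify edges as texture and
introduce zigzag artifacts. The default 3 is the conventional choice for
this filter and is kept fixed throughout.

## Spectral sharpness S1

Per 32×32 block (stride 16) the block mean is removed, a Hanning window
applied, and the DFT magnitude collapsed onto radial bins of width `2/m`
in normalized frequency (nearest-bin assignment, DC excluded). The summed
orientation spectrum `z(f)` is computed as the per-bin *mean* magnitude
scaled by a fixed orientation count (360): summing over a uniform set of
orientations per radius rather than over the raw ring population, whose
size grows with `f` and would otherwise bias the slope by one. The
absolute log-log slope `α` comes from ordinary least squares of `log z`
against `log f` over all bins with positive magnitude (at least three
required; flatter blocks score `S1 = 0`, as flat regions carry no
sharpness evidence), and

    S1 = 1 − 1/(1 + exp(τ1 (α − τ2))),   τ1 = −3, τ2 = 2.

`S1` is strictly decreasing in `α`; a block with `α = 2` scores 0.5.

The mean-S1-decreases-with-blur property saturates: once blur pushes a
noise-free spectrum several decades down, `S1` underflows to the sigmoid
tail and comparisons there are vacuous. The pooled score is protected by
the fusion with S2 and the top-fraction pooling.

## Spatial sharpness S2, fusion and pooling

For a 2×2 neighborhood `ξ`, `v_ξ` is the sum of absolute differences over
its 6 unordered pixel pairs divided by 255 (the 8-neighbor total-variation
formula restricted to 2×2 support; the full 8-neighbor block TV with
replicate padding is also provided as `total_variation`). Per block,
`S2 = max_ξ v_ξ / 4`. The maps fuse as `S3 = S1^μ S2^(1−μ)` with
`μ = 0.5` and the convention `0^0 = 0`; `S` is the mean of the top
`⌈0.01·n_blocks⌉` values of S3 (pooling counts blocks, not pixels), which
suppresses flat and noisy regions. Pooled values are clipped at 1 (extreme
checkerboard contrast can push `S2` slightly above 1).

## MLV edge sparsity d

The MLV map `ψ(I)` is the per-pixel maximum absolute difference to the 8
neighbors (replicate padding). Edge pixels are detected per direction with
a 3×3 Sobel derivative across the edge orientation ("vertical" edges are
transitions along a row), non-maximum suppression along the scan
direction, and a threshold at 10 % of the global maximum response. The
threshold is relative so the detector still fires on low-contrast blurred
maps. Non-maximum suppression admits two-pixel response plateaus on both
pixels; this keeps the rule invariant under scan reversal, which is what
makes scores exactly symmetric under rotation and transposition.

Two readings of edge-pixel sparsity are implemented:

- **width** — the mean Marziliano width over detected edge pixels: for
  each one, the distance between the local extrema of the MLV scan-line
  profile bracketing it. The extremum search runs while the profile is
  strictly monotone, passes a plateau only if the trend resumes beyond it,
  and otherwise stops at the last strictly-changed index; searches that
  hit the line boundary are truncated there and flagged.
- **spacing** (default) — the average distance between edge pixels along
  scan lines, computed as the mean segment length when each line is cut at
  its edge pixels: `n_lines · line_length / (n_edges + n_lines)`, the
  inverse linear density of edge pixels.

The direction of the two readings under blur is genuinely opposite: blur
widens individual edges (width grows) but also multiplies detected edge
pixels (density grows, spacing falls). On the graded-blur calibration
suite the width reading is not even monotone — widths first grow with the
spreading ridge, then shrink again as retained noise truncates the
extremum searches — while the spacing reading decreases strictly in every
series in each direction, matching the documented behavior of the metric
(lower sparsity for more blurred micrographs). The shipped default is
therefore `spacing`; the mode is recorded in every score record and
switchable in config. Finally `d = sqrt(d_v² + d_h²)`, and `d = 0` iff no
edges are detected in either direction.

## Fusion into Q

Over a batch, `Q_i = η·S_i/max_j S_j + (1−η)·d_i/max_j d_j` with
`η = 0.3` (the edge term dominates, consistent with edge-weighted human
sensitivity). Normalizers default to batch maxima; fixed reference
normalizers can be configured for reproducible single-image scoring. A
batch with all-zero `S` or `d` (e.g. flat frames) raises a degenerate-batch
error instead of dividing by zero.

## Evaluation

PLCC uses the standard product-moment form (the sample-standard-deviation
normalization). SROCC uses the rank-difference formula
`1 − 6Σ(r_x − r_y)²/(n(n²−1))` with average ranks for ties; the formula is
exact only for tie-free data, and with ties it is the conventional
approximation (a documented deviation from the textbook tie-corrected
estimator). PLCC and RMSE are reported both raw and after mapping the
objective scores through the monotone 4-parameter logistic
`x̂ = β1(1/2 − 1/(1+exp(β2(y−β3)))) + β4`, fitted by least squares from
five deterministic initializations (fallback: identity mapping with a
logged warning). SROCC is always computed on raw scores.

## Synthetic study conditions

`render_scene` emulates a polished-sample micrograph: 6 discs/rectangles
with well-separated gray levels on a uniform background, sinusoidal
texture on a random subset of regions, and additive Gaussian noise
(σ = 2). Texture defaults are peak-to-peak 24 at 0.125 cycles/px: local
texture gradients (~9 gray/px) stay below the σ=3-smoothed gradient
response of strong boundaries (~13 gray/px per 100 gray of step height),
while the 8 px period is still well inside the filter's texture regime
(low-pass attenuation ≈ 0.25, so λ ≈ 0.75 in texture interiors). This is a
design constraint, not a free knob: texture whose gradients rival the
boundaries makes the LTV filter classify the boundaries themselves as
texture, and the cartoon of a *sharp* frame then loses its edges — the
regime the method explicitly does not serve.

`make_blur_series` blurs the clean scene at σ_b ∈ {0, 1, 2, 3} and adds
the same noise field afterwards, so the series varies only focus, like a
defocus series at fixed detector settings. Pseudo-MOS is ordinal (reversed
blur rank), not simulated human scores. The standard suite is 5 scene
parameterizations × 3 seeds × 4 levels = 60 images at 256×256, generated
in a few seconds.

What passing on this suite shows: the pipeline responds monotonically to
pure defocus on edge-dominated content and ranks frames correctly within a
scene. What it does not show: performance on broadband natural texture,
correlated noise, charging artifacts, astigmatism, or the absolute scale
of human opinion scores. On randomly re-seeded scenes the strict
monotonicity of `d` occasionally (roughly one series in fifteen) shows a
near-tie inversion at the first blur step; `S` and `Q` have been strictly
monotone in every observed realization.

## Numerical choices

- Gaussian kernels truncated at radius `⌈4σ⌉` (negligible-tail cutoff).
- Replicate (edge) padding everywhere a border rule is needed: gradients,
  MLV neighborhoods, block TV, Sobel.
- Degenerate spectra (fewer than 3 usable radial bins) map to `S1 = 0`.
- Extremum-search ties break toward the nearer index; terminal plateaus
  stop at their entry.
- The low-contrast block exclusion used by some spectral-spatial
  implementations is not applied before slope fitting; flat blocks are
  handled by the degenerate-spectrum rule instead.
- All randomness flows through `numpy.random.default_rng` seeds carried in
  the scene specs; identical specs render bit-identical images.

## Known limitations

- `d`'s absolute scale depends on image size and content density through
  the inverse-density definition; only comparisons within a batch are
  meaningful (Q max-normalizes them away).
- Batch max-normalization makes `Q` depend on the batch composition;
  pin `max_s_ref`/`max_d_ref` for cross-batch comparability.
- The spectral stage assumes approximate 1/f-law content; heavily
  processed or binary images violate it.
- The decomposition assumes texture gradients below structural-edge
  gradients (see above); violating content degrades the cartoon and with
  it both metrics.
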