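# Methods

This note records the models, parameter choices, numerical decisions and
known limitations behind `forestchange`. Everything quantitative stated here
is computed by the test suite or by `scripts/acceptance.py`.

## The change-detection model

The method treats forest disturbance mapping as a supervised classification
whose training data are harvested from the image pair itself. Its core
assumptions:

- **Spectral contrast.** Closed-canopy forest is dark in the red and SWIR
  bands; freshly cleared land is bright in SWIR. The SWIR difference
  *d* = SWIR(early) − SWIR(late) is therefore strongly negative over
  disturbance and strongly positive over regrowth, while the bulk of the
  scene forms an approximately Gaussian no-change mode near zero. Any offset
  of that mode from zero (atmosphere, phenology, calibration) is absorbed by
  using the *window mean* μ as the reference point, which is why no
  radiometric or atmospheric correction is required.
- **Local thresholds, global multiplier.** Thresholds μ ± kσ are computed
  per local window (default 400 px) because a single scene-wide threshold is
  distorted by regional differences; the multiplier k = 1.5 is fixed across
  all windows and scenes. A window contributes training only when at least
  25 % of it is valid and both tails hold at least `min_tail_count` (25)
  pixels — the published rule requires "sufficient proportions" of change
  and no-change without quantifying them, so the count is an explicit,
  documented proxy.
- **Label noise is expected.** Automatically extracted labels inherit every
  mask and threshold error, so the training set is passed through a
  consensus filter before classification (below).

## Pipeline parameters (defaults and why)

| parameter | default | rationale |
|---|---|---|
| `threshold_multiplier` | 1.5 | published value, fixed across windows |
| `window_size` | 400 px | published "usually 400 by 400 pixels" |
| `no_change_band` | 0.5 σ | unambiguous core of the no-change mode |
| `min_tail_count` | 25 | proxy for the unquantified sufficiency rule |
| `water_swir_max` | 0.25 | published water rule ("less than 25 %") |
| `water_ndvi_max` | 0.3 | published water rule |
| `mmu` | 6 px | published minimum mapping unit (~0.5 ha) |
| `n_folds` | 10 | published cross-validation depth |
| `filter_train_frac` | 0.70 | published 70 % training share |
| `svm_c_exp`, `svm_gamma_exp` | 2⁻⁵…2¹⁵, 2⁻¹⁵…2³ (step 2²) | standard log₂ grid for RBF-SVM search |
| `grid_cv_folds` | 5 | standard for grid search; the source is silent |
| `merge_threshold` | 0.05 | reflectance-unit distance at which adjacent stands stop merging; ~3–5× the within-stand noise scale |
| `morph_radius` | 1 (3 × 3) | smallest opening that deletes isolated pixels without eroding real patches |
| `n_samples_per_stratum` | 100 | published validation design |
| `max_training_samples` | 6000 | stratified cap keeping filter + SVM tractable on large scenes; accuracy is insensitive above a few thousand samples |

Forest-peak detection constants (`forest_hist_bin_width` 0.005,
`forest_hist_smooth_bins` 3, `forest_peak_prominence_frac` 0.05,
`forest_peak_margin_bins` 2, `forest_peak_max_red` 0.10) operationalize the
published idea — "the location of the dark peak is used as a threshold" —
which is under-specified on its own: a threshold *at* the peak would cut the
forest mode in half, and a bright unimodal window must yield no forest. The
threshold is therefore peak location + max(full width at half prominence,
2 bins), and only peaks darker than 0.10 red reflectance qualify.

The water trend clause ("decreasing from visible to infrared") is read
strictly: red > nir > swir1; equalities fail. The 25 % SWIR rule is applied
to the ~1.6 µm band (`swir1`), the conventional choice, and is configurable
to `swir2`.

One global `rng_seed` drives every stochastic stage (no-change subsampling,
fold assignment, subsampling inside the filter, grid-search subsampling,
validation sampling), so a run is bit-reproducible from (inputs, config).

## Consensus filter

The published description mixes two samplings ("subsets … 70 percent …
with replacement" vs "10-fold cross-validation"). They are reconciled as:
stratified 10-fold CV for held-out prediction, with each of the four
classifier families trained on a stratified 70 % subsample (without
replacement) of the training folds, the class distribution forced to match
the full set. A sample is removed only when **all four** families mispredict
it. The families (RBF SVM with default C, depth-10 tree, 5-NN, one hidden
layer of 16 units) are deliberately plain: the filter's power comes from the
consensus, not from any single model, and all four operate in the same
6-feature space as the final classifier — the filter must judge
separability where classification happens. A class smaller than `n_folds`
is exempted from removal (logged), and a majority-vote mode exists as a
config option but is off by default.

What consensus filtering can and cannot do: it removes samples that are
*inconsistent* with any learnable structure (random flips, isolated mask
glitches) — on the 3 000-sample blob benchmark with 10 % flipped labels it
removes ≥ 80 % of the flips and ≤ 5 % of clean samples — but it correctly
*keeps* coherent blocks of systematically mislabeled samples (e.g. an entire
agricultural area leaking through the forest mask), because those are
indistinguishable from signal inside the feature space. On the synthetic
scenes, whose labels are nearly feature-consistent by construction, removal
is accordingly near zero; this is the "near-perfect training set" regime,
not the noisy real-imagery regime where published removal averaged ~20 %.
Passing filter tests here demonstrate the mechanism, not real-data removal
rates.

## Classification

Features are standardized per plane with training statistics (stored in the
model): tasseled-cap indices have very different ranges and RBF kernels are
scale-sensitive. Grid search maximizes stratified CV accuracy; ties break
toward smaller C then smaller γ, making the search deterministic. On
training sets above `grid_search_max_samples` the search scores a stratified
subsample and the winning parameters are refit on the full set. Training
keeps all three classes (disturbed / regrowth / no-change); regrowth is
folded into stable forest only when the map is composed, since the final map
carries no regrowth class.

## Segmentation and map composition

The original polygon step used a proprietary segmenter; this package
substitutes a contract-compatible region merger on the six-band
(red/NIR/SWIR × two dates) stack. Implementation: every valid pixel starts
as a segment; in each round every segment nominates its spectrally nearest
8-connected neighbour, candidate pairs are scanned in increasing-distance
order, and a keeper may absorb several partners per round (the absorbed side
is consumed once). The globally closest pair always merges first, so the
rounds approximate strict best-merge while keeping the per-round work
vectorized; merging stops at `merge_threshold`. Strictly sequential
best-merge was implemented first and gave the same contracted behaviour but
was two orders of magnitude slower at 512², which is why the round-based
order is the package's choice. Afterwards every segment below the minimum
mapping unit is absorbed into its spectrally nearest neighbour. Connected
components of the valid region that are themselves smaller than the MMU can
never form a legal polygon; they are left unsegmented and composed as stable
forest (they passed the early-date forest gate). Ties everywhere break
toward smaller ids, so segmentation is deterministic.

Plurality labelling assigns each segment its most frequent pixel label; any
tie goes to no-change, a conservative choice because commission in the
disturbance class is the dominant error mode. Composition precedence is
cloud > shadow > water > stable non-forest > classified labels, and
polygons are vectorized with 8-connectivity to match the segmenter.

## Synthetic scenes: what they emulate, what they do not

The generator paints patches (rectangles and dilated random walks, sizes
log-uniform 6–48 px) of seven surface conditions over a bright non-forest
background, with documented archetype reflectances chosen to satisfy the
qualitative orderings the method relies on — they are synthetic stand-ins,
not sensor measurements. Realism features: per-patch spectral jitter
(SD 0.008, emulating stand-to-stand variability), a Gaussian point-spread
(σ 0.7 px) mixing boundary pixels, i.i.d. band noise (SD 0.01), clouds that
are bright, flat and cold, and shadows displaced from their clouds by
h·tan(zenith) along the anti-solar azimuth at a known height.

Two deliberate design points:

- **Regrowth at date 1** is a young regrowing stand — dark in red (0.045)
  but still elevated in SWIR — so the *estimated* early-date forest mask
  picks most of it up (realistic mask commission) while the *truth* masks
  record it as non-forest. Without this, the early-forest gate would empty
  the regrowth tail of every window and the extraction sufficiency rule
  could never be satisfied on scenes containing regrowth.
- **Agriculture** flips brightness between dates (green crop → bare field),
  the classic confuser for disturbance mapping. With default jitter its red
  reflectance stays above the forest-peak threshold, making the default pair
  a *clean* scene; larger jitter lets whole fields leak through the forest
  mask, which is the degraded regime used by the corrupted-mask experiments.

Not emulated: radiative transfer, topographic illumination, phenology,
sensor saturation, geometric misregistration, SLC-off gaps. Consequently,
passing tests show the algorithmic machinery is correct and calibrated to
its stated constants — they do not certify accuracy on real imagery.

## Scale of the shipped experiments

Default end-to-end runs use 512 × 512 scenes (~0.26 Mpx; a full Landsat
footprint is ~35 Mpx) and the paired-filter replicates use 128 × 128 scenes
with windows sized to the scene — sizes chosen so the whole suite runs in
minutes on one CPU while every stage still operates far from degenerate
regimes. All stages are linear or near-linear in pixel count.

## Known limitations

- Regrowth is detected as a training class but not mapped as a product
  class (folded into stable forest), matching the published product.
- The cloud screen is a simplified spectral-thermal test plus geometric
  shadow projection, not a full object-based cloud algorithm; thin cirrus
  and warm low cloud will be missed, and without a thermal band the screen
  degrades to spectral-only with a warning.
- The consensus filter cannot remove coherent, systematic label errors
  (see above) — the same limitation the published discussion attributes to
  agricultural confusion that filtering "does not improve".
- Disturbance type is not attributed (harvest vs natural loss), and
  multi-date gap filling is out of scope: the method is strictly pair-wise.
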