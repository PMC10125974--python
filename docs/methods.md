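# Methods

This note documents the models and procedures implemented in `igem`, the
assumptions behind the synthetic-data generators, the tunable parameters
with their defaults, and the numerical choices made where the underlying
assay software leaves the operator undefined.

## 1. Imaging model and quantification

### What the simulator renders

Each well consists of `n_fields_per_well` (default 9, as in a 96-well
high-content acquisition) two-channel fields of `image_size` (default
256×256) pixels:

* **Nuclei channel** — disks at rejection-sampled centers (minimum
  separation 2.4× the mean radius, so most nuclei are separate and a few
  touch), radius ~ N(11, 1.2²) px, amplitude 120, Gaussian-blurred (σ = 2)
  with additive Gaussian noise (σ = 2).
* **MBD channel** — a diffuse nuclear signal (amplitude 8) plus punctate
  foci rendered as 2-D Gaussians. Focus count per nucleus is Poisson
  (mean 3); centers are placed by best-candidate sampling inside 0.65 of
  the nucleus radius with a soft minimum separation of 5 px (MBD puncta
  concentrate in the nuclear interior; the separation keeps most foci
  optically resolvable). Placements that cannot satisfy the separation are
  still made and the nucleus is flagged *crowded* — recovery guarantees
  apply to the uncrowded stratum.

**Effect multipliers are well-level semantics.** A chemical's multiplier
tuple (intensity, area, count, nuclei) scales the four *per-well*
parameters the pipeline reports. Per focus this means a flux factor of
`m_int / m_count` and an area (σ²) factor of `m_area / m_count`, so focus
amplitude stays near the control level and the per-nucleus totals scale
exactly as requested. The built-in reference agents are an
etoposide-like hypermethylation profile (1.37, 1.35, 1.34, 0.90) and a
5-aza-2′-deoxycytidine-like hypomethylation profile (0.56, 0.56, 0.63,
1.10).

### Quantification pipeline

* **Nuclear segmentation** — Gaussian smoothing (σ = 2 px) → Otsu
  threshold → hole filling → distance-transform watershed (marker minimum
  distance 8 px) → border-touching regions discarded → area gate
  [120, 2000] px. Otsu always yields a threshold, so the split is accepted
  only when foreground exceeds background by `min_contrast` (default 20
  intensity units); a structure-free noise image therefore yields zero
  labels. Cell segmentation is deliberately collapsed into nuclear
  segmentation: every reported parameter is nuclear.
* **Foci detection** — difference of Gaussians at `spot_sigma_px`
  (default 1.5; wide σ = 1.6×). Per nucleus the candidate mask is
  `enhanced > median(enhanced) + k · σ_noise` with k = 5. The robust noise
  scale σ_noise is estimated from the field background outside all nuclei
  (1.4826 × MAD); inside a focus-dense nucleus the local spread is
  dominated by spot skirts, not noise, so a within-nucleus estimate would
  inflate the threshold and miss real spots. Spot markers are **h-maxima**
  with prominence equal to the threshold height, which stops noise ripples
  on the skirts of bright spots from being counted as extra foci; a
  watershed on the enhanced image splits touching spots. Finally a spot
  must stand above the nucleus background by k robust noise SDs in the
  *raw* channel (field-median of per-nucleus lower-side MADs) — this
  rejects the band-pass ridge that the rim of the diffuse nuclear signal
  produces.
* **Per-focus measures** — the background level of a nucleus is the median
  of its pixels *outside* the candidate spot mask (spot skirts would bias
  a whole-nucleus median upward by an amount proportional to total focus
  flux, which differs between conditions). `integrated_intensity` is the
  background-subtracted sum over the focus segment: under a pure gain
  change of the channel by c it scales by exactly c. `area_px` counts
  pixels above half the focus's own peak (an FWHM-style area): it is
  invariant to amplitude and tracks σ², so the area and intensity
  parameters respond independently to their respective effects. Both
  definitions are available; per-nucleus totals use the integrated
  intensity.
* **Well measure** — nuclei count summed over fields; each foci parameter
  is the total over all foci divided by the nuclei count (focus-free
  nuclei count in the denominator). Zero nuclei ⇒ parameters undefined
  (NaN, flagged).

Verified recovery: with 20 wells per condition the measured
ratio-to-control of all four parameters matches the simulated multipliers
within ±10% (typically ±4%); focus counts on the resolvable stratum are
exact, and well-level counts are within 5%.

## 2. Screen profiling

Ratios to the vehicle control are means over replicate wells with
delta-method standard errors. The viability gate keeps rows with nuclei
ratio ≥ 0.70 (the "more than 70%" rule is implemented inclusively at the
boundary; configurable); gated rows are flagged, not dropped.

Chemicals are clustered on **1 − Pearson r** between their 4-ratio
profiles with **average linkage**, and the tree is cut at k = 3. Pearson
distance is scale-free: only the *shape* of a profile matters. For that
reason the simulator gives the intermediate class C a weak but correlated
shape — intensity/area tick up ~4%, count dips ~8%, nuclei flat —
orthogonal to the hypo/hyper axis. A class whose profiles were pure noise
around (1,1,1,1) would have no defined correlation direction and no
clustering method based on profile shape could group it; the chosen shape
stays inside the "little or no effect" band (mean foci ratio 1.00) while
giving the class a recoverable identity. Constant profiles make Pearson r
undefined and raise a hard error naming the offending rows.

Category labels: with exactly three clusters the labels are forced
distinct by ranking cluster means of the three foci ratios (lowest → A,
highest → B, middle → C); otherwise a ±δ band around 1 (δ = 0.05 default)
separates B/A/C. With the default generator (noise σ = 0.02, effect sizes
≥ 0.15 from 1) category recovery is 100%.

### Test statistics

* Dose–response: one-way ANOVA followed by Tukey HSD per dose-vs-control
  pair (two-sided, studentized-range reference). Identical groups are
  reported as F = 0, p = 1.
* **Steel–Dwass all-pairs comparison**: for each pair, joint ranking, rank
  sum standardized with the tie-corrected variance, and √2·|t| referred to
  the studentized range distribution with k groups (∞ df). With k = 2 this
  is exactly the tie-corrected normal-approximation Wilcoxon test. Because
  the asymptotic reference is inaccurate for very small samples, a
  **permutation mode** refers each pairwise statistic to the permutation
  distribution of the maximum standardized pairwise statistic over all
  pairs — the exact analogue of the family adjustment — enumerated
  exhaustively up to 250 000 assignments and otherwise sampled with a
  seeded Monte Carlo (default 100 000 resamples). `method="auto"` selects
  the permutation reference when total n ≤ 24 and k ≥ 3.

## 3. Activity harmonization

Records are joined across databases by the chemical identifier column
only (no fuzzy name matching; reproducibility over recall). The rules:

* **Genotoxicity**: any positive experiment → active; all negative →
  inactive; no records → missing.
* **Carcinogenicity**: IARC group 1/2A → active. Group 2B/3: any positive
  CCRIS animal experiment → active, otherwise inconclusive — including
  the zero-record case, where "negative for all experiments" would hold
  only vacuously. Group 4 or no IARC data: any positive → active, all
  negative → inactive, no records → missing.
* **Tox21 parent/hydrochloride merge** (symmetric): equal values stand;
  {active, inconclusive} → active; **{active, inactive} → inconclusive**;
  {inactive, inconclusive} → inactive; one side absent defers to the
  other; both absent → missing. The {active, inactive} rule is applied as
  documented even though it reads oddly; `merge_tox21(...,
  active_inactive=...)` switches the resolution.

Chemicals missing in every column are excluded; the labeled subset of the
default synthetic snapshot has exactly 114 of 135 chemicals.

## 4. Association

Activity labels are encoded ordinally (active = 1, inconclusive = 0.5,
inactive = 0) with missing cells imputed to the column median — this
preserves the full chemical sample instead of case deletion; one-hot
encoding is available. A regression random forest (default 500 trees,
⌈p/3⌉ features per split, bootstrap sampling, fixed seed) is fitted with
one MBD parameter ratio as the response. Importance is the total
node-variance decrease summed over trees (unnormalized, scaled by the
sample count → response-variance units, matching the classic
"increase in node purity"); ties are broken alphabetically so rankings
are deterministic. The synthetic snapshot plants a strong enrichment of
active "CAR antagonist" and "H2AX phosphorylation" outcomes among
hypermethylation-category chemicals (odds ratio ≥ 5); in ≥ 90% of seeds
"CAR antagonist" ranks in the top 3 for foci intensity.

## 5. Methylome analytics

* **log2 summaries**: β floored at ε = 1e-3 before ratios (prevents −∞ at
  fully unmethylated sites; configurable).
* **DiffScore** = sgn(β_t − β_c) · (−10 log10 p). With one array per
  condition there is no replicate variance, so p comes from a Gaussian
  measurement-error model on β: p = 2Φ(−|Δβ| / (√2 σ_β)), σ_β = 0.03
  default. This model is declared, testable, and not claimed identical to
  any scanner software's proprietary score. |13.0103| ⇔ p = 0.05; the
  hypermethylation call requires p strictly below 0.05 (score > 13.0103,
  printed as "> 13").
* **Region distributions**: counts/proportions of called sites per RefGene
  group and per CpG context; proportions sum to 1 per axis; an empty call
  set is flagged rather than divided.
* **Gene panels**: a probe belongs to a gene when the symbol appears in
  its (possibly `;`-separated) gene annotation; per-gene output is the
  site count and mean log2 ratio. "Hypermethylated" defaults to mean
  log2 ratio > 0 (`min_meth_effect` exposes a stricter cutoff).
* **High-fold common-hyper genes**: called sites with β ratio strictly
  > 10 in both named treatments; the β ratio (floored) is the fold
  measure — the DiffScore saturates under the noise model and the
  intensity ratio is not observable from β alone.
* **RRBS**: filters drop sites with coverage < 10 (strict) and above the
  per-sample 99.9th coverage percentile (strict, computed before
  filtering). Coverage normalization rescales each sample to the median
  of per-sample median coverages; methylated counts are re-derived from
  the scaled coverage and the original fraction, so per-site fraction
  drift is bounded by 0.5/coverage exactly. Tiling sums counts over
  1-based, 1000-base non-overlapping windows per chromosome with strands
  merged (non-directional protocol). Gene-level RRBS calls use mean log2
  ratio > 0.30 — the binomial counting noise of ~80 sites at ~30×
  coverage gives the gene mean a standard deviation near 0.07, so 0.30
  separates planted gains (≈ +0.6 to +0.8 log2) from noise by several σ
  in both directions.
* **t-SNE**: perplexity = min(5, n − 1) because targeted studies embed
  ≤ 6 samples; PCA initialization and a fixed seed make the embedding
  deterministic.
* **Expression**: fold change = RPKM_treated / RPKM_control per gene;
  genes with zero control RPKM are excluded and reported; treatments are
  clustered on Euclidean distance with average linkage; the common-down
  set is genes with fold change < 1 under both named hypermethylation
  agents.

## 6. What the generators emulate — and what they do not

The simulators reproduce the *structure* of the study: the 63/36/36
category split (largest-remainder apportionment of the configured
proportions), exactly 114 chemicals with at least one database record,
the planted association between hypermethylation and CAR-antagonist/H2AX
activity, the U-shaped EPIC β distribution (mixture of Beta(0.5, 8) and
Beta(8, 0.5) with island probes biased to the unmethylated component),
island-concentrated hypermethylation effects (restricted to probes with
control β ≥ 0.05, so a global effect can never masquerade as a > 10-fold
change), negative-binomial RRBS coverage with a heavy right tail, and a
100-gene panel whose leading entries carry the planted funnel: 28 genes
commonly down-regulated under both hypermethylation agents, 16 of them
hypermethylated under at least one, 9 under both, and 4 of those
re-confirmed in RRBS.

They do **not** emulate: optics point-spread functions, illumination
gradients or plate-position effects, raw bisulfite reads or alignment
artifacts, array probe cross-hybridization, β measurement noise (β noise
defaults to 0 so that a zero-effect configuration is exactly null; the
DiffScore noise model supplies significance), or biological replicate
variation in expression. Passing tests therefore demonstrate that the
analysis chain is correct and internally consistent — not that it is
robust to every artifact of real microscopes, arrays, or sequencers.

## 7. Problem sizes and determinism

Default test and acceptance runs use the study-scale synthetic
configuration: 135 chemicals, 114 labeled, 30 000 array probes, 50 000
RRBS sites (80 per tracked gene), 100 panel genes, 9 fields per well, and
20 wells per condition for imaging recovery; unit tests use a down-scaled
copy. Every stochastic component draws from
`numpy.random.default_rng((seed, generator_offset, …))` with a stable
per-generator offset, so outputs are bit-identical across runs and adding
one generator never perturbs the draws of another. Pipeline artifacts
(CSV/TSV/JSON/Newick/BED) are byte-identical on rerun under an unchanged
configuration; log files append and carry no timestamps.

## 8. Known limitations

* The foci detector's spot model is isotropic; elongated or ring-shaped
  heterochromatin structures would be segmented as multiple spots.
* The per-nucleus background median assumes spots cover well under half
  of the nucleus; beyond that the estimator falls back to the
  whole-region median and integrated intensities shrink toward zero.
* The Gaussian β-noise model behind the DiffScore treats all probes as
  equally noisy; real array noise is intensity-dependent.
* Steel–Dwass permutation mode is exact only up to Monte-Carlo error when
  the assignment count exceeds the exhaustive limit.
* IARC group 4 with no CCRIS records is labelled *missing* (no source
  determines an outcome); group 2B/3 with no records is *inconclusive*.
  Both conventions are configurable at the snapshot level and documented
  here because the harmonization rules do not address the zero-record
  cases explicitly.
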