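# Methods

This document describes the statistical models, algorithms and parameter
defaults implemented in `mitochrom`, the assumptions behind the synthetic
data generators, and the deliberate numerical choices that affect results.

## 1. LFQ enrichment (`mitochrom.lfq`)

### Input model

The reader (`read_protein_group_table`) consumes a tab-separated
protein-group table in the MaxQuant `proteinGroups.txt` dialect:

- intensity columns named `LFQ intensity <sample>` are mapped to
  `(condition, biological replicate, technical replicate)` triples by an
  explicit column map;
- intensity `0` means "not quantified" and is converted to NaN;
- quality flags (`Reverse`, `Potential contaminant`, `Only identified by
  site`) use the `"+"` convention;
- `Razor + unique peptides` carries the peptide support count.

`filter_protein_groups` removes flagged rows and rows with fewer than
`min_peptides` (default 2) razor + unique peptides.
`average_technical_replicates` averages technical duplicates on the raw
intensity scale (a mean of linear intensities, before the log transform,
matching how technical injections of the same sample are normally
combined; one valid value suffices). `log2_transform_table` then moves to
log2 intensities, the scale on which all statistics operate.

### Moderated statistic

For each protein, with per-group means, pooled standard deviation
`s_pooled` over `n₁ + n₂ − 2` degrees of freedom, the statistic is

```
d = (mean_a − mean_b) / (s_pooled · sqrt(1/n₁ + 1/n₂) + S0)
```

`S0` (default **0.1**) is a variance-moderation constant added to the
standard error: it suppresses proteins whose nominal t is huge only
because their replicate variance is accidentally tiny, while leaving
proteins with substantial fold changes nearly untouched. At `S0 = 0` the
statistic reduces exactly to the pooled-variance Student t (this identity
is asserted against an independent textbook implementation in the test
suite). Rows with fewer than `min_valid_per_group` (default 2) valid
values in either group are not tested. A zero denominator yields ±inf for
a nonzero difference and 0 for a zero difference.

### Permutation FDR

Null statistics come from balanced relabelings of the (technical-averaged)
replicate columns: every split of the `2B` columns into two groups of `B`.
Two choices matter:

- **The observed labelling (and its complement) is excluded from the
  null.** Including it would add every observed |d| to the null pool, so
  the estimated FDR at any cutoff could never fall below roughly
  `1 / (number of splits)`; at `B = 3` (10 balanced splits) that floor is
  ~0.1, which would make an FDR target of 0.01 unreachable regardless of
  effect size. With the identity excluded, the null is built only from
  label assignments that actually break the group structure.
- **Cutoff rule.** For a sweep of candidate cutoffs `c` (the observed |d|
  values), the estimated FDR is the mean number of null |d| ≥ c across
  randomisations divided by the observed count of |d| ≥ c. The
  significance cutoff is the **smallest `c` whose raw estimated FDR is at
  or below the target**. No running minimum is applied across cutoffs:
  monotonising the estimate from the stringent end propagates the ~0 FDR
  of the extreme tail to every weaker cutoff and collapses the procedure
  into calling everything significant. The raw-estimate rule is
  conservative where the estimate is noisy and is the variant validated by
  the all-null false-discovery benchmark (see §6).

Defaults: `fdr = 0.01`, `n_randomizations = 250`, `side = "both"`.
`exhaustive=True` enumerates all balanced splits (identity excluded,
complement pairs counted once) instead of sampling; for `B = 3` that is 9
splits, and sampled and exhaustive modes produce identical calls (asserted
in the acceptance tests). Calls are partitioned into
`enriched` / `depleted` / `ns` / `not_tested`.

### Clustering of significant rows

`cluster_significant_rows` reproduces a standard heat-map pipeline:
prefilter rows (at least `min_valid_per_group` valid values in one group
and significant at a permissive setting, default FDR 0.05 with `S0 = 0`),
z-score each row using the **population** standard deviation
(`ddof = 0`, the convention of mainstream proteomics GUIs, so that heat
maps are comparable with those tools), optionally reduce rows by k-means
(default 300 clusters; `kmeans_k=None` disables), then average-linkage
hierarchical clustering with Euclidean distance on rows and columns.
Missing values are zero-filled after z-scoring for distance computation
only.

## 2. Synthetic LFQ tables (`mitochrom.simulate`)

`simulate_lfq_table` draws per-protein base abundances on the log2 scale
from Normal(`base_log2_mean = 25`, `base_log2_sd = 2`) — the magnitude
range of real LFQ intensities. Each biological replicate adds
Normal(0, `within_sd_log2 = 0.3`) noise; technical replicates add
Normal(0, `within_sd_log2 / 2`) around their biological replicate. A
fraction `frac_enriched` / `frac_depleted` of proteins receives
±`effect_log2` (default 2, i.e. 4-fold) on the sorted condition.
Missingness is `none`, `mcar` (uniformly random) or `mnar`
(missing-not-at-random: only values below the per-column
`threshold_quantile = 0.2` intensity quantile can be dropped, emulating
the detection-limit censoring typical of LFQ data). Missing entries are
written as `0`, matching the input convention. The generator emits the
full MaxQuant-dialect table (flag columns, peptide counts) so tests
exercise the parser, not just the statistics.

What it does **not** emulate: peptide-level quantification and protein
inference, correlated protein abundances, batch effects, or
normalisation artefacts between samples.

## 3. Chromosome morphometry (`mitochrom.morphometry`)

### Segmentation

`segment_chromosomes` thresholds the DAPI channel (`otsu` default, or
`fixed` / `quantile`), optionally removes border-touching objects
(`exclude_border = True`; partial objects bias area down), labels
8-connected components, and discards objects below `min_object_px`
(default 25 px, ~0.25 µm² at 0.1 µm pixels — smaller than any plausible
chromosome).

**Otsu is computed on `log1p` intensities and back-transformed with
`expm1`.** Chromosome images are effectively trimodal: background, body,
and a bright pericentric/centromeric domain that can be several-fold
brighter than the body. Plain Otsu on such images can place the threshold
*inside* the foreground, segmenting only the bright domain. The log
transform compresses the bright tail so the optimal split falls between
background and body; for a truly bimodal image the choice is essentially
equivalent to plain Otsu.

### Measurements

- chromosome area: foreground pixel count × `pixel_size_um²` (µm²);
- pericentric (DAPI-high) area: pixels above the per-object
  `centromere_quantile` (default 0.8) intensity quantile, largest
  8-connected component;
- Cenpa overlap: fraction of Otsu-thresholded Cenpa-positive pixels that
  fall inside the DAPI-high mask (None when no Cenpa channel present).

### Group comparison

`compare_groups` is the unpaired two-tailed Student's t-test with pooled
variance (`scipy.stats.ttest_ind`, `equal_var=True`), reporting n,
mean, and sample SD (`ddof = 1`) per group. At least 2 measurements per
group are required.

## 4. Synthetic chromosome images (`mitochrom.simulate`)

`simulate_chromosome_image_set` places one rotated super-ellipse
(exponent `shape_exponent = 2`, axis ratio `elongation = 2.5`) per image,
with target areas drawn from Normal(`area_mean_um2`, `area_sd_um2`)
(redrawn if non-positive) and the axes solved analytically from the
super-ellipse area formula `4ab·Γ(1+1/n)²/Γ(1+2/n)`. A zero-mean Fourier
perturbation of the boundary radius (`boundary_jitter = 0.02`) roughens
the outline; because the perturbation is zero-mean in radius, the expected
area inflation is of order `jitter²` (~0.04% at the default) and is
ignored in the recorded ground truth. One end of the long axis
(`centromere_area_frac = 0.2` of the area) is brightened by
`centromere_brightness_ratio` (default 2) to model the DAPI-dense
pericentric domain, and a Gaussian Cenpa spot (σ = 0.3 of the short
semi-axis) is centred in it. Photon noise is Poisson on the clean image
plus Gaussian read noise (`noise_sd = 20`) over a uniform background
(`background_level = 100`, foreground `foreground_level = 3000`), clipped
to uint16. Pixel size defaults to 0.1 µm.

Not emulated: overlapping/touching chromosomes, sister-chromatid
substructure, optical blur (PSF), uneven illumination, or multi-object
crowding.

## 5. ATAC accessibility (`mitochrom.atac`)

### Insertion sites

Tn5 inserts as a dimer and the two cut sites are 9 bp apart, so aligned
read 5′ ends are shifted to the insertion centre with the standard
offsets: **+4 on the plus strand, −5 on the minus strand**. In 0-based
half-open BED coordinates the plus-strand 5′ end is `start` (site =
`start + 4`) and the minus-strand 5′ end is `end − 1` (site =
`end − 1 − 5`). Reads with unknown strand or out-of-bounds sites are
dropped and counted; the retained/dropped partition is exact and asserted
in the run report.

### Windowed enrichment

The genome is tiled in non-overlapping windows (`window_size = 25000` bp;
final window truncated at the chromosome end). The expected count per
window is `total_sites × window_length / genome_length`, i.e. a uniform
background, and the score is `log2(observed / expected)`. Zero-count
windows substitute a pseudocount of **0.5** (half the minimum observable
count) for the observed value, keeping scores finite while clearly
flagging depletion.

### Summit trend profiles

For each peak class, ±25 bp around every insertion site is accumulated
into 10 bp bins over ±1000 bp around the summit (difference-array
coverage, clipped to the span), averaged over summits, then **normalised
to mean 1** across bins so that classes with different site densities are
comparable; a flat profile reads 1 everywhere and a summit-centred
enrichment reads as a fold over the local average. Empty classes are
omitted with a warning.

### Synthetic reads

`simulate_atac_reads` draws Poisson background insertions at
`background_rate` (default 0.004 sites/bp) plus, per peak, extra
insertions at `background_rate × (fold − 1)` over the peak span with
positions Normal(summit, half_width/2). Read intervals are constructed to
invert the offset arithmetic exactly (+ strand: `start = site − 4`; −
strand: `end = site + 6`), read length 50 bp, strands assigned at
`frac_minus_strand = 0.5`. Not emulated: sequence bias, duplicates,
fragment-length mixtures (nucleosomal ladders), or mappability gaps.

## 6. Pipeline and CLI (`mitochrom.pipeline`, `mitochrom.cli`)

A YAML config is validated up front with **all** violations reported at
once (value ranges, stage/input requirements, input-path existence);
nothing runs on an invalid config. Stages: `simulate` (write generator
outputs only), `enrich`, `measure`, `atac`. Every stage seeds
`numpy.random.default_rng` from the config seed, so a repeated run is
byte-identical (asserted in tests). The run report asserts its own
consistency: enrichment calls partition the tested rows, and ATAC
retained + dropped reads equal the input.

## 7. Validation and benchmark sizes

`scripts/acceptance.py` and `tests/test_acceptance.py` validate the chain
end to end at sizes chosen to make Monte-Carlo error small relative to the
tolerances: 20 all-null tables × 5000 proteins for the false-discovery
benchmark (200 000 protein-level decisions overall), 100 objects per
image-set for area recovery (standard error of the mean ≈ SD/10), 50
random tables for sampled-versus-exhaustive permutation equivalence, and
12-significant-digit agreement with textbook oracles for the t statistics.

## 8. Limitations

- The permutation null at `B = 3` rests on only 9 distinct balanced
  non-identity splits; FDR estimates at very small targets are coarse and
  the procedure leans on the pooled-statistic sweep across proteins.
- Technical-replicate averaging assumes duplicates are exchangeable
  injections; it is not a mixed model and does not propagate
  technical-variance uncertainty.
- Segmentation assumes isolated chromosomes on a uniform background;
  touching objects are merged, and no deblending is attempted.
- Windowed ATAC enrichment uses a global uniform expectation; it does not
  model local mappability or GC bias, so scores on real data reflect those
  biases as well as accessibility.
- The generators are intentionally minimal mechanistic sketches (see the
  "not emulated" notes above); they validate the analysis arithmetic, not
  biological realism.
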