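# Methods

This note documents the models, default parameters, numerical choices and
known limitations of the package. It is the design record: nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Moderated differential expression (`diffexpr`)

The model is the standard gene-wise linear model with empirical-Bayes
variance moderation for two-group designs. Residual variances are pooled
within groups (df `n1+n2-2`); the scaled-inverse-chi-square prior `(d0,
s0^2)` is estimated by method of moments on `log s_g^2` (digamma/trigamma
matching, with a Newton trigamma inverse). The posterior variance is the
df-weighted average of prior and gene variance, and the moderated t gains
the prior df. An independent test cross-checks the full statistic chain
(t, p, prior df) against the Bioconductor reference implementation on a
heterogeneous-variance toy; agreement is at machine precision.

Choices worth noting:

- `prior_df` is exposed: `0` disables moderation (ordinary pooled t,
  useful as an oracle), `inf` forces one common variance (then |t| orders
  exactly like |log2FC|, since all genes share a standard error).
- Two-sided p values throughout; up/down calls imply no preferred side.
- Genes with exactly zero residual variance are *kept* with `p = 1` and a
  `zero_variance` flag, so gene universes stay aligned across datasets
  for the consensus stage. A fully constant matrix raises a warning.
- DEG thresholds are strict inequalities: adjusted `P < .05` and
  `|log2FC| > 0.5` (so a gene exactly at 0.5 is not called). The stricter
  `|log2FC| > 1` cut is used only by the pathway-analysis export.
- BH adjustment is delegated to `statsmodels` behind `adjust_bh`, which
  validates `p ∈ (0, 1]`; a hand-computed step-up vector pins the
  behaviour in the tests.

## Consensus and common markers (`marker_consensus`)

"Consistent deregulation" is read conservatively: a consensus marker must
be a same-direction DEG in at least `min_datasets` (default 3) datasets
*and* an opposite-direction DEG in none. A switch
(`require_exclusive=False`) relaxes this to a majority rule; with the
relaxed rule a gene qualifying in both directions goes with the majority
and is dropped on ties, so the up/down sets are disjoint for any input.

"Most upregulated/downregulated" rankings use the unweighted mean log2FC
across datasets; the ranking statistic is otherwise arbitrary, and mean
was chosen as the simplest symmetric option. The linear fold-change cuts
of the common panel (FC > 1.7 in ≥ 4 datasets for up; FC < 0.5 in all
datasets for down) are applied on `2^log2fc`. Note that the all-datasets
down rule can be unsatisfiable when planted effects are present in only a
subset of datasets — the function then returns an empty list with a
warning rather than failing.

The region panel takes all consensus-up genes plus the `n_region_down`
(default 133) most-downregulated consensus-down genes.

Gene-identifier harmonization (probe-to-symbol collapse) is the caller's
responsibility; every table is assumed to have one row per gene symbol.

## Single-cell caller (`sc_senescence`)

The combined call is the conjunction of five boolean criteria (the first
two jointly form the "common marker" requirement): up-marker sum strictly
above `up_sum_min`, down-marker sum at or below `down_tolerance`, SASP and
ECM totals in the top `top_quantile` of cells, and at least
`min_cdki_expressed` CDKi genes non-zero.

- `up_sum_min = 1000` is kept in the units of the input matrix because the
  appropriate value depends on the normalization; the call table carries
  `c1_up_sum` per cell so users can inspect the distribution and
  recalibrate.
- `down_tolerance = 0` encodes strict absence. Dropout in sparse data
  argues for a small tolerance; the default follows the strict reading
  and the knob exists.
- The top-quantile cut is the `1 - top_quantile` quantile with `higher`
  interpolation, membership inclusive (`>=`), so ties at the cut all pass
  and slightly more than the nominal fraction may qualify.
- Which up-marker list feeds criterion 1 is configurable
  (`up_gene_set`): the short common panel (default) or the full
  consensus-up set.
- Escape detection: base set = CDKN1A-positive cells with top-quantile
  SASP (the same quantile rule as the caller, for internal consistency —
  an interpretation, since "expressing p21 and SASP" is not otherwise
  quantified); escape = base cells with MKI67 > 0. MCM co-expression
  defaults to "any subunit > 0" (`mcm_rule="all"` available).
- Group-wise expression comparisons use the Mann-Whitney U test with tie
  correction (scipy), two-sided.

## Region score (`region_score`)

Scaling is per gene across regions — forced by the "region with the
highest sum" reading — and a gene constant across regions contributes 0
(its 0/0 scaling is undefined; 0 is the neutral choice). Scores are
therefore bounded by the panel size and exactly antisymmetric under
swapping the up and down sets. Multi-sample atlases are collapsed to one
row per region upstream by `aggregate_region_samples` (mean by default,
median available; the aggregation used by the original atlases is not
documented, mean is assumed).

## Cluster communication (`ligrec`)

The reported interaction strength follows the scaled-mean convention:
per-gene cluster means, min-max scaled across clusters, averaged over the
ligand (sender) and receptor (receiver) sides; receptor complexes take
the minimum over components, and a side whose raw mean is 0 zeroes the
score.

The permutation test shuffles the cluster assignment globally across
cells (preserving cluster sizes) and recomputes the statistic each round,
with `p = (r+1)/(n_perm+1)` — never exactly zero. The *ranked* statistic
is the unscaled cluster-mean combination rather than the scaled score:
min-max scaling is invariant to expression magnitude, so under label
shuffles the scaled score of a given (sender, receiver) cell attains its
maximum whenever that sender happens to hold the max ligand mean
(probability ≈ 1/k² for k clusters), which bounds attainable p values
away from useful significance levels for small k. Ranking raw means
(the convention of the established cell-communication tools) preserves
null uniformity — verified by a KS calibration test — and restores power
on planted signal. Clusters with fewer than `min_cells = 3` cells are
excluded, not imputed.

## Concordance (`concordance`)

Per-gene Spearman correlations are computed on pairwise-complete samples
with a minimum of 4 pairs (genes below the minimum are skipped and
counted in a warning). "Significant correlation" uses raw `P < .05`, not
adjusted. Phosphosite prevalence counts non-missing normalized
intensities among tumor samples, with no imputation; the tumor-vs-normal
shift uses Welch's unequal-variance t when both classes have ≥ 2 detected
values. Overlap reports emit both denominators — up/down/unchanged/missing
over all panel members (summing to 1) and up/down/unchanged re-based on
detected members — so either convention of a summary pie chart can be
reproduced.

## Synthetic data (`synthetic_data`)

The generators emulate the statistical structure the pipeline reads, not
tumor biology (no pathway co-regulation, no copy-number structure).

- **Bulk panels**: Gaussian log2 intensities (microarray-like), per-gene
  baseline ~ N(8, 1.5) shared across datasets, noise sd 0.5 by default.
  Defaults mirror the study conditions: 6 datasets, planted log2FC 2
  carried in exactly 4 of the 6 datasets per marker, 4 replicates per
  group (the source datasets ranged 2–5; `n_replicates_per_group` accepts
  a per-dataset tuple, `STUDY_REPLICATES = (2, 2, 3, 3, 4, 5)`), 800
  genes with 40 + 40 planted markers where a size is needed but not
  dictated by the conditions.
- **Single cell**: negative-binomial counts (dispersion 2) around
  per-gene means normalized to a mean library size (default 5 000 counts,
  raw-count regime; the caller's 1000-count threshold is calibrated to
  this scale), thinned by Bernoulli dropout (rate 0.3). Planted senescent
  cells (default 2.5%, as in the study's single-cell compartment) carry
  boosted up-marker/SASP/ECM means, hard-zero down markers and
  proliferation genes, and guaranteed CDKi expression; planted escaped
  cells (default 1%) are CDKN1A+/high-SASP/MKI67+/PCNA+/MCM+ and keep
  down-marker expression so the strict caller rejects them. After
  sampling, the planted guarantees are enforced deterministically (top-up
  of the first panel gene where dropout broke a bound), so every planted
  senescent cell passes all four criteria at the default thresholds by
  construction — provided `frac_senescent + frac_escaped ≤ top_quantile`,
  since both planted groups occupy the top of the SASP distribution.
  "Absence of expression" is planted as hard zeros, matching the caller's
  zero-tolerance default.
- **Regions**: lognormal FPKM baselines with multiplicative noise; one
  random region gets up-genes × 4 and down-genes × 0.25.
- **Paired omics**: per-gene bivariate Gaussian with Pearson coefficient
  `2 sin(πρ/6)` so the population Spearman correlation equals the set's
  target ρ.

Everything is driven by explicit seeds (never global RNG state) and is
bit-reproducible; determinism is asserted in the tests. What passing
tests show is that the pipeline's decision rules recover exactly the
structure they are defined on; they do not show robustness to the
features real data add (batch effects, probe-level noise, ambient RNA,
cell-type-correlated expression), which the generators deliberately do
not model.

## Problem sizes

The default validation studies use 800-gene bulk panels (20 seeds),
5 000-cell × 1 000-gene single-cell matrices (20 seeds), 5-region FPKM
matrices (100 seeds), 300-cell × 400-gene communication matrices with
200 pairs at 1 000 permutations, and 99-sample paired-omics tables —
sizes at which every planted recovery and calibration property is
measurable with comfortable statistical margins while the whole suite
runs in well under a minute per stage.

## Known limitations

- No covariate adjustment or multi-factor designs in the DE model; no
  count-based (voom-style) weighting, so RNA-seq counts should be
  transformed upstream.
- The caller takes cluster labels as given; it performs no clustering or
  cell-type annotation.
- No curated ligand-receptor database ships with the package; users
  supply pair lists.
- Pathway enrichment/impact analyses themselves are out of scope; only
  their input export (significant genes at |log2FC| > 1) is provided.
- Mass-spectrometry preprocessing (peptide rollup, normalization) is
  assumed done; the concordance stage consumes normalized tables.
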