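# Methods

`stresstrata` implements a stratification pipeline for postmortem
brain-cohort bulk RNA-seq: cases are split into high and low
stress-response subgroups from the expression of a stress-responsive gene
panel, controls are classified by a quartile-weighted index over a subset
of those genes, subgroup contrasts feed a differential-expression →
gene-set overrepresentation chain, and DNA-damage histology (TUNEL with a
methyl-green counterstain) is quantified from RGB brightfield fields.
Because cohorts of this kind are not freely distributable, the package
ships a synthetic-data module whose defaults encode the study conditions
the analysis assumes, so every stage is testable end to end.

## Stratification model

Samples are clustered on the z-scores of the panel genes (per-gene mean 0,
sample sd with the n−1 denominator; a zero-variance gene is an error, not a
silent drop). Clustering is Ward's minimum-variance agglomeration computed
by the Lance–Williams recurrence on initial pairwise values ‖x_i − x_j‖²/2,
so every merge height is the Ward objective increment

    ΔSSE = (n_i·n_j / (n_i + n_j)) · ‖c_i − c_j‖²,

the increase in total within-cluster sum of squares caused by the merge.
Heights are therefore monotone. Ties between candidate merges break on the
lexicographically smallest (minimum-leaf-index) pair, which makes the merge
order deterministic across platforms. The implementation is verified
against a brute-force oracle that recomputes ΔSSE from the raw points at
every step (and, independently, against scipy's Ward linkage, whose
reported distance d satisfies ΔSSE = d²/2).

The dendrogram is cut on the SPSS-style axis in which merge heights are
linearly rescaled to 0–25 ("rescaled distance cluster combine"); the
default cut is 20. Merges at rescaled height ≤ threshold are applied; the
cut is closed so that a threshold of 25 always yields one cluster and a
threshold below the first merge yields singletons. Whether the plotted
heights derive from incremental ΔSSE or the cumulative agglomeration
schedule is ambiguous in SPSS output, so both are available behind the
`schedule` flag; the default is incremental.

The two clusters are labeled by directional concordance: mean z over
stress-up genes minus mean z over stress-down genes, per cluster;
variable-direction genes participate in clustering but not in labeling.
The higher-concordance cluster is the high stress-response (HSR) stratum.
An exact tie is an error rather than an arbitrary choice.

## Stress-response index

For each index-panel gene, subjects are split into quartiles with
interpolated (median-unbiased) cut points and closed-right intervals
(v ≤ Q1 → quartile 1), so values equal to a cut point are handled
deterministically and the rule depends only on values, not tie order.
Quartiles 1–4 score −3/−1/+1/+3 for genes that run high in the HSR stratum
and +3/+1/−1/−3 for genes that run high in the LSR stratum; the per-gene
scores sum to the index. Positive → HSR, negative → LSR. A score of
exactly 0 is reported as INDETERMINATE with a warning: the scoring rule
defines only the strict inequalities, and we refuse to bin the undefined
case silently. With the default ten-gene panel the score is an even integer
in [−30, 30]. The panel is configuration, not code, because the gene list
is chosen post hoc from the case-stratum contrasts.

## Statistics

* **Mann–Whitney U** — midrank U; exact two-sided p by full enumeration of
  the U null distribution when n_x + n_y ≤ 12 with no ties, otherwise a
  normal approximation with tie correction and 0.5 continuity correction.
  The effect size r = |Z|/√N derives from the corrected normal deviate on
  both paths, matching the convention of packages that report Z (and r)
  alongside exact p-values; `method` records which p path was used.
* **Fisher exact, 2×2 and R×C** — two-sided by the minimum-likelihood rule
  (sum of probabilities of all fixed-margin tables no more probable than
  the observed one). The R×C form enumerates the full fixed-margin polytope
  and refuses totals above 60 by default. Both are validated against
  independent brute-force enumerations.
* **Student t** — pooled-variance two-sample form. Zero pooled variance
  with equal means gives p = 1 by convention; with unequal means p = 0 with
  a warning.
* **Benjamini–Hochberg** — statsmodels' step-up implementation, checked
  against a hand-rolled cummin oracle.

Type-I error of the MWU (approximate path) and pooled t is checked by
simulation: 10,000 null replicates at n = 15 + 15, empirical rejection at
α = 0.05 required to fall in [0.03, 0.07].

## Differential expression and overrepresentation

Genes are ranked by the pooled t on log2(CPM + 1); the log transform is a
deliberate choice (the upstream tooling is ambiguous between raw counts,
CPM and log-CPM) and stabilises the mean–variance coupling of CPM values.
Genes with zero within-group variance in both groups are excluded with a
logged count. The top-N list (ascending p; ties by |t| then gene id) enters
a right-tailed hypergeometric overrepresentation test per gene set, with
the universe defined as all genes surviving the variance filter and BH
adjustment across sets. This is a transparent surrogate for commercial
canonical-pathway software, which reduces to the same computation for set
overlap; proprietary causal analytics are out of scope. Per-overlap-gene
direction (sign of log2fc) is attached when DEG records are supplied.

## Histology quantification

Colour deconvolution follows the Beer–Lambert model: per pixel,
OD_c = −log10(max(I_c, 1)/255); concentrations are the OD vector through
the inverse of the stain basis (rows: DAB, methyl green, and a residual
normalized cross product), negatives clipped to 0. The DAB vector is the
widely published brightfield OD triplet; methyl green has no canonical
published vector, so the default was fixed once from a pure-stain synthetic
calibration field and both vectors are user-overridable.

Each concentration channel is binarized at the iterative intermeans
(isodata) fixed point t = (mean(v ≤ t) + mean(v > t))/2 (ImageJ's "Default"
threshold is a modified isodata variant; the plain fixed point is a
documented possible minor divergence). Particles are 8-connected
components; the perimeter is the Moore boundary-walk chain length with
diagonal steps weighted √2 and circularity is min(1, 4π·area/perimeter²).
Under this rule a rasterized disk of radius ≥ 15 px has circularity ≈ 0.91
(comfortably above the 0.1 filter floor) and a 50 × 50 square scores ≈
0.82. Default filters: area ≥ 2000 px², circularity 0.1–1, which rejects a
radius-20 disk (≈ 1257 px²) and keeps a radius-30 disk (≈ 2821 px²). The
case-level positivity rate pools counts across fields (robust to sparse
fields) with denominator TUNEL-positive + methyl-green-positive particles;
alternative denominators are an open reading and configurable. No
declumping/watershed is attempted, matching the upstream particle-counting
workflow.

## Synthetic-data generator

**Cohorts.** Counts are negative binomial per gene and sample
(var = m + α·m²), scaled to CPM by a simulated library size drawn uniform
in 30–50 million reads. The stress panel's latent subgroup means are the
reported case-stratum values (e.g. IL6 0.77 vs 0.38 CPM, SOD2 84.7 vs
46.1, SYP 350.1 vs 556.3); where group SEMs are reported, the per-gene
within-group sd (SEM·√n) fixes the dispersion of that entry, floored at
the Poisson counting noise. Three panel genes reported only as trends
(NR3C1, APOA1, SLC6A4) get a full-size up ratio (1.8×) with a large
coefficient of variation (0.45) so the contrast stays sub-significant at
n = 7/18, mirroring the reported BDNF trend. The remaining direction-class
genes co-move with the strata at half the mean reported log-effect of
their class (ratio √2 up, √0.62 down) — genes enter this panel precisely
because they respond to stress, so zero co-movement would be an
unrealistic null. APOA2 and S100B (inconsistent reported direction, no
reported trend) are neutral. Controls carry latent high/low labels in a
14/7 split; their means are the reported control-stratum values where
stated and an 0.85-attenuated case effect otherwise. Background genes get
log-normal baselines (median 10 CPM); a planted set (named after the
homologous-recombination DSB-repair genes) is shifted by `planted_log2fc`
(default 1.0) in the latent high-stress cases, and decoy gene sets are
sampled from the unshifted background.

Default cohort sizes are the study conditions: 25 cases split 7/18 and 21
controls split 14/7; 1000 background genes keep the DEG → ORA chain fast
at desk scale (the top-N fraction used in recovery checks is 17% of the
universe, the same ratio as 8000 of a ~47k-gene transcriptome).

**What the generator does not emulate:** read-level data, RIN- or
agonal-state-dependent degradation, gene–gene correlation beyond the
latent-group mean structure, batch effects, or compositional coupling
between genes. Passing recovery tests therefore show the pipeline is
correct and well-calibrated under its own model assumptions, not that the
biological findings replicate on new cohorts.

**Histology fields.** Cells are filled disks (default radius 28–34 px, so
every nucleus clears the 2000 px² filter) placed without overlap by
rejection sampling; per-pixel transmitted intensity is
I_c = 255·10^(−amplitude·stain_vector_c), plus Gaussian read noise
(default sd 2 on the 8-bit scale) and clipping. Non-overlap is deliberate:
the counting workflow has no declumping step, so fixtures must not require
one. Renderer truth (counts, centers, radii) drives exact-recovery tests.

All randomness flows from explicit per-spec seeds; no global RNG state is
touched, and identical seeds give byte-identical outputs.

## Pipeline arms and determinism

`run_sz_arm`: standardize → Ward → rescaled cut → concordance labels →
per-panel-gene MWU contrasts, Fisher tests on cause-of-death (R×C) and
family history (2×2) where known → DEG → top-N → ORA. `run_control_arm`:
stress index → classes → the same contrast/DEG/ORA chain, plus a
four-group contrast table (case/control × high/low) for the top enriched
set's genes. Outputs are TSV/JSON with a manifest recording config hash,
seed, package version and per-stage row counts — and no timestamps — so a
rerun with identical inputs is byte-identical.

## Numerical choices and edge cases

* Quartile cut points: numpy's median-unbiased quantile estimator;
  closed-right membership.
* Ward tie-break: smallest (min-leaf, min-leaf) pair; heights compared
  exactly (ties only arise from exactly duplicated distances).
* Degenerate dendrogram (all heights 0): single cluster with a warning.
* Exact-p comparisons inside the Fisher tests use a 1 + 1e−9 relative
  slack when testing "no more probable than observed", guarding against
  floating-point noise in pmf evaluation.
* Isodata on a constant channel is an error; in `quantify_case` such
  fields are skipped with a warning, and only if all fields fail does the
  case error out.
* Boundary perimeter of a single-pixel component is 0; its circularity is
  defined as 1 and the area filter removes it in practice.

## Known limitations

* The exact R×C Fisher enumeration is exponential in table size; the
  default total bound is 60 and there is no Monte-Carlo fallback yet.
* The MWU exact path requires untied data; tied small samples fall back to
  the corrected normal approximation.
* Colour deconvolution assumes exactly two stains plus residual; no
  automatic stain-vector estimation from the image is provided.
* The stress-index INDETERMINATE class (score 0) is reported but the
  downstream control arm simply excludes those subjects from contrasts.
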