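# Methods

This note documents the statistical models behind each pipeline stage, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely
open.

## Differential stage ("DE-lite")

The two-group comparison emulates the role a DESeq2 fit plays in this kind
of analysis, with every component simple enough to verify directly:

* **Normalization** — median-of-ratios size factors: for sample *j*,
  `s_j = median_g(K_gj / geomean_g)` over genes expressed in every sample,
  with the median taken on the ratio scale.
* **Fold change** — `log2((m_alt + 0.5)/(m_ref + 0.5))` on group means of
  normalized counts; the 0.5 pseudocount keeps zero-mean genes finite and
  preserves antisymmetry under group exchange.
* **Dispersion** — per-group method-of-moments estimates
  `(var − mean)/mean²`, averaged, then shrunk 50/50 toward a trend
  `α(μ) = a0 + a1/μ` fitted across genes, and floored at the trend. The
  floor matters: at 3 replicates the gene-wise moment estimator scatters
  far below the truth and underestimated dispersions are precisely what
  breaks type-I control (null rejection at p < 0.05 measured at 0.037–0.049
  with the floor versus 0.056–0.071 without).
* **Test** — delta-method standard error of the log2 FC
  (`Var(m) = (μ·mean(1/s) + αμ²)/n` per group), Wald statistic against a
  standard normal. Genes whose mean normalized count falls below
  `mean_count_floor` (default 1) receive an NA adjusted p and are
  `NOT_ASSESSED` downstream; BH adjustment runs across the remaining genes.

The module is explicitly an emulation: an externally produced results table
with columns (gene_id, log2fc, pvalue, padj) can be ingested via
`read_table(..., schema="differential")` and slotted into the classifier,
so a real DESeq2 fit can replace the internal stage without touching
anything downstream.

Contrasts are two-group only (TPk vs TP1); there is no GLM with covariates.

## Regulatory classification

Classification is a deterministic function of the four statistics
(mrna_lfc, mrna_padj, ribo_lfc, ribo_padj) and two thresholds
(`fc_threshold` = 1 in log2 units, `alpha` = 0.05). Every gene receives
exactly one label. Two labels are implementation additions for totality:
`DISCORDANT` (both assays significant with opposite signs — biologically
odd and surfaced rather than silently binned) and `NOT_ASSESSED` (NA
adjusted p in either assay).

## Translational efficiency

TE is the log2 ratio of footprint TPM over transcript TPM, computed per
gene at one time point after pooling replicate TPMs (median by default,
`replicate_average="mean"` available). TE is defined only where both
abundances are positive; zero-footprint genes are reported NA and excluded
from the fit. The headline regression is OLS of TE on log10(TPM + 1) at the
reference time point (per-time-point fits rather than pooled; the contrast
time point is used for the residual-by-group comparison because that is
where transcriptional regulation is defined).

**Known bias.** mRNA noise enters the predictor and, with opposite sign,
the response (TE contains −log2 mRNA), so the OLS slope estimand is more
negative than the data-generating slope by roughly
`(log2(10) − |β|)·σ_u²/σ_x²`, where σ_u² is the variance of the measured
log10 abundance around its truth. At NB dispersion 0.05 with three
replicates this is ≈ 0.02–0.04 on a slope of −1.10 (2–4%), and it is a
property of the published regression itself, not of this implementation:
confidence-interval coverage of the planted slope is nominal when the
predictor is noise-free and drops to ≈ 88–92/100 with the noisy predictor.
The corresponding acceptance check is left failing rather than papering
over the effect; the regression is reported exactly as specified.

Group comparisons of TE residuals use a two-sided Mann–Whitney U — exact
enumeration for untied samples with n1+n2 ≤ 8, normal approximation with
tie correction otherwise — within abundance bins (10, 100], (100, 1000],
(1000, 10000] TPM; groups with fewer than 3 genes are reported untestable.
The "transcriptionally up/down" groups condition on the mRNA contrast only;
"non-DET" is mRNA padj ≥ α regardless of footprints.

Gene-set abundance tests draw `n_perm` uniform same-size sets without
replacement (vectorized via per-row key argpartition, chunked to bound
memory), with plus-one correction `p = (#{null ≤ obs} + 1)/(n_perm + 1)`
for the lower tail. Tie comparison uses a 1e-9 relative tolerance because
resampled means differ from the observed one only by float summation
order. The default tail is `lower` (the scientific claim is "less abundant
than expected"); `upper` and `two` are available.

Prediction-interval outlier flagging is ordinary OLS with per-point 95%
prediction intervals (statsmodels `get_prediction`); a point is flagged
when its response lies strictly outside.

## Ribosome stoichiometry

Protein log2 FC uses replicate medians of raw intensities; zeros and
missing values propagate as NA (data-independent-acquisition dropouts are
informative; nothing is imputed). SR subtracts the per-time-point median
over detected RPs (mean-centering available), which forces median(SR) = 0
per time point and makes SR invariant to any per-time-point loading
constant.

The 95% interval for deviation events is, by default, the robust Gaussian
interval `median ± z₀.₉₇₅ · 1.4826 · MAD` of the cross-RP SR distribution.
The empirical percentile interval is available
(`flag_deviant_rps(..., method="percentile")`, plus a bootstrap-of-median
variant) but is not the default for a structural reason: with ~10% of RPs
genuinely deviating, the 2.5th-percentile edge of the contaminated
empirical distribution lands on the smaller deviants themselves, so a
protein deviating by |SR| ≈ 0.3–0.35 can never be detected reliably —
while a bulk-calibrated interval detects |SR| ≥ 0.35 in > 90% of
simulations at replicate sd 0.1 and keeps the null flag rate near the
nominal ~2% (P(≥2 events among 3 time points at 5% each) ≈ 0.7%, plus
scale-estimation noise). The |SR| ≈ 0.30 case remains borderline
(detected ~60%), as expected this close to the interval edge.

## Corem classes

The gene × gene distance is the binary mismatch/union metric (`pdist`
jaccard on boolean membership rows) after excluding genes present in no
corem; clustering is UPGMA (scipy average linkage; scipy's deterministic
order-dependent tie resolution is documented rather than replaced).
Bootstrap support of a clade is the fraction of `n_bootstrap` (default
10,000) corem-column resamples whose UPGMA tree contains the identical
leaf set — plain bootstrap probability, not a multiscale "approximately
unbiased" correction; the 0.95 support threshold is interpreted on BP.
Classes are maximal supported clades, excluding the root, singletons, and
clades merged at the metric's maximum height 1.0: such a merge joins
groups sharing no corem at all, and at low noise those unions reproduce
perfectly without being clusters in any meaningful sense. Genes outside
every supported clade are `unassigned` — on block-structured data with a
few outlier genes this reproduces the "small residual class by exclusion"
pattern.

Corem signatures are per-condition medians (with IQR) over member genes.
Pair similarity follows the SRCC > 0.4 ∧ P < 0.05 ∧ KS P > 0.05 rule;
constant signatures are flagged degenerate and never similar. Class
similarity per condition category is the proportion of similar pairs over
unordered within-class pairs (self-pairs excluded) or all cross-class
pairs; categories with fewer than 3 conditions are reported untestable.
A corem's class is the majority class among its classified member genes.

## Interaction modules

Community detection runs on the undirected simple projection of the
deduplicated directed graph (self-loops removed for clustering, kept and
reported otherwise), using igraph's C implementation of the Newman–Girvan
edge-betweenness dendrogram cut at maximal modularity. The result is
deterministic for a fixed input graph; betweenness ties are resolved by
igraph's internal order. Note that the algorithm optimizes only over
partitions generated by its own removal sequence — on small dense graphs
the global maximum-modularity partition is frequently not reachable by any
valid removal order, which is a property of the algorithm, not a defect of
an implementation; the test suite therefore validates against an
independent oracle that enumerates all tie-break executions of the removal
sequence. RP subunit summaries read the leading S/L of the RP name.

## Synthetic data

The generators define the study conditions: 4 time points × 3 replicates;
negative-binomial counts with gene-shared dispersion 0.05 and library size
2×10⁷ (the per-library depth implied by two high-output flow cells across
24 libraries); log10 base abundance ~ N(2.0, 0.8) TPM; planted significant
|log2 FC| uniform on (1.5, 3), null |log2 FC| < 0.4, class proportions
matching the observed 875/110/79/15/24/304 mixture (transcription-only
split evenly between up and down); a TE line with slope −1.10 per
log10(TPM+1) decade, intercept 2.5 and gene-level scatter sd 1.5 — chosen
so the *observed* TE–abundance correlation lands at R ≈ −0.5, matching
the real-data magnitude; translation-only upregulated genes are drawn 0.8
log10 units lower in abundance. TP2/TP3 effects interpolate the TP1→TP4
log2 effects linearly. TE couples to the *reference-time-point* abundance
so that the planted footprint log2 FC is exactly `true_lfc_ribo`; coupling
to instantaneous abundance would leak `−slope·Δlog10(mRNA)` into every DE
gene's footprint change and make the planted classes internally
inconsistent.

The proteomics generator plants a global trend (0, −0.3, −0.7, −1.04 log2)
with five deviants at the observed SR magnitudes (+0.94, +0.39, −0.94,
−0.35, −0.30) at the two latest time points, log-normal replicate noise
sd 0.1. The corem generator plants block-diagonal membership (class sizes
38/7/6/3 over 72 corems by default) with independent bit flips and a
compendium where classes respond coherently across conditions
(class-effect sd 1.5, gene noise sd 0.5). The interaction generator is a
planted-partition graph (p_in = 0.8, p_out = 0.05, 7 modules) with each
edge oriented from a uniformly chosen endpoint.

What the generators do **not** emulate: overdispersion heterogeneity
across genes (a per-gene dispersion option exists but the default is
shared), operon-level correlation between neighboring genes, partial
footprint coverage/periodicity artifacts, peptide-level proteomics error
(intensities are drawn at the protein level), corem size heterogeneity
beyond the block structure, and degree heterogeneity within network
modules. Passing tests therefore demonstrate correctness of the statistics
under a clean version of the assumed data-generating process, not
robustness to every real-data pathology.

## Reproducibility and scale choices

Every stochastic operation takes an explicit seed; the pipeline fans a
single config seed out to stages by CRC32 of the stage name, so stage
results do not depend on execution order. Identical seeds give
bit-identical outputs.

The test suite and acceptance script run recovery simulations at sizes
chosen to finish in minutes on one CPU: 100-seed slope-coverage and
deviant-detection loops, 200-set permutation calibration at n_perm = 10⁴,
corem bootstrap at n_boot = 1,000 in tests (10,000 in the acceptance
script and pipeline default), 20-seed module-recovery at the full
126-node size. The `tiny` fixture scale (300 genes) exists for smoke
tests; `paper_like` mirrors the printed dimensions (2,663 genes, 72
corems, 128 network nodes).

## Known limitations

* The DE-lite stage is a deliberately simple NB Wald test; it does not
  reproduce DESeq2's MAP shrinkage or outlier handling, and its fold
  changes are unshrunken.
* The TE–abundance OLS slope inherits the correlated-measurement-error
  bias discussed above.
* Bootstrap clade support is BP, which is known to be conservative for
  deep clades relative to multiscale corrections.
* The Newman–Girvan cut cannot exceed the modularity attainable along its
  own removal sequence.
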