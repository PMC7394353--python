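# ribointerplay

Analysis pipeline for the interplay of transcriptional and translational
regulation across growth-phase transitions in *Halobacterium salinarum*
(and prokaryotes generally), built around paired RNA-seq / Ribo-seq
experiments, quantitative proteomics of the assembled-ribosome fraction,
conditionally coregulated gene modules (corems), and bait→prey
protein-interaction data.

It is written for systems-biology practitioners who have count/TPM tables
in hand (the pipeline starts *after* read processing and quantification)
and want a tested, reproducible implementation of the downstream
statistics, together with a synthetic-data generator that plants ground
truth for every stage so the whole analysis is testable without any
external download.

## What it computes

**Regulatory classification.** For a contrast (stationary TP4 vs early
exponential TP1 by default), each gene's transcript and footprint responses
are tested separately (a self-contained "DE-lite" negative-binomial Wald
test standing in for DESeq2; external results tables can be ingested
instead). With sig(x) ≡ |log2 FC| > 1 ∧ BH-adjusted P < 0.05, genes are
classified as

| class | transcript | footprints | reading |
|---|---|---|---|
| TC± | sig | sig, same sign | transcription-driven |
| COMP− | sig up | flat | translation buffers an mRNA increase |
| COMP+ | sig down | flat | ribosome loading maintained |
| TL± | flat | sig | translation-only regulation |
| NR | flat | flat | not regulated |

plus `DISCORDANT` (both significant, opposite signs) and `NOT_ASSESSED`
(filtered low-expression genes).

**Translational efficiency.** TE = log2(footprint TPM / mRNA TPM) per gene;
OLS of TE on log10(TPM + 1) quantifies preferential ribosome loading of
low-abundance transcripts (slope *a*, correlation *R*); residuals ("TE
deviation given expression") are compared between transcriptionally up-,
down- and non-regulated genes per abundance bin (Mann–Whitney U), and gene
sets are tested for abundance bias against 10⁴–10⁶ random same-size sets
(plus-one-corrected empirical p).

**Ribosome stoichiometry.** Per ribosomal protein (RP) and time point, the
log2 fold change of replicate-median intensity versus TP1; the
stoichiometry ratio SR subtracts the per-time-point median over RPs
(deviation from the collective trend). Deviation events are SRs outside the
95% interval of the cross-RP distribution; RPs with ≥ 2 events are flagged
as candidate composition changes.

**Corem classes.** Genes are clustered on binary corem membership
(mismatch/union distance, UPGMA), clades are bootstrapped by resampling
corems 10,000 times, and maximal clades with support ≥ 0.95 become classes.
Two corems are "similar" when their per-condition median expression
signatures have Spearman ρ > 0.4 with P < 0.05 and a non-significant
two-sample KS test; class-level similarity per condition category is the
proportion of similar corem pairs.

**Interaction modules.** The deduplicated directed bait→prey network is cut
into modules by the Newman–Girvan edge-betweenness algorithm at maximal
modularity, and physical interactions between general transcription factors
(TBP/TFB/Bat) and RPs are extracted with per-subunit summaries.

## Worked example

```python
from ribointerplay.config import PipelineConfig
from ribointerplay.differential import test_differential
from ribointerplay.interplay import (classify_regulation, compute_te,
                                     regress_te_on_abundance)
from ribointerplay.synthetic import (SimulationParams, make_design,
                                     make_truth, simulate_paired_counts)

design = make_design()                      # 4 time points x 3 replicates
params = SimulationParams(n_genes=2663, seed=1)
truth = make_truth(params)
mrna, ribo, mrna_tpm, ribo_tpm = simulate_paired_counts(params, truth, design)

de = {assay: test_differential(cm.data[design.samples_for("TP1", assay)],
                               cm.data[design.samples_for("TP4", assay)],
                               assay=assay)
      for assay, cm in (("rna", mrna), ("ribo", ribo))}
classes = classify_regulation(de["rna"], de["ribo"], PipelineConfig())
print(classes["class"].value_counts().to_string())

te = compute_te(mrna_tpm, ribo_tpm, design, "TP1")
fit = regress_te_on_abundance(te)
print(f"TE ~ log10(TPM+1): slope={fit.slope:.2f}  R={fit.r:.2f}  p={fit.pvalue:.2e}")
```

prints

```
class
TC+           816
TC-           814
NR            572
COMP-         207
COMP+         156
TL-            58
TL+            38
DISCORDANT      2
TE ~ log10(TPM+1): slope=-1.21  R=-0.52  p=8.53e-183
```

The class counts recover the planted mixture (>97% per-gene label
agreement at NB dispersion 0.05 with three replicates), and the TE fit
recovers the planted negative coupling: TE falls by roughly one log2 unit
per decade of transcript abundance, i.e. low-abundance transcripts carry
disproportionately many ribosomes. The OLS slope is slightly steeper than
the planted −1.10 because transcript noise enters both axes of the
regression with opposite signs (see `docs/methods.md`).

A complete synthetic input directory plus an end-to-end run:

```sh
ribointerplay fixture --seed 1 --scale paper_like fixture/
ribointerplay run-all fixture/ results/
```

`results/report.txt` then contains one section per stage (class counts, TE
fit, flagged RPs, corem classes, network modules) with machine-readable
TSVs alongside and a `manifest.json` recording config, input checksums and
stage status.

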