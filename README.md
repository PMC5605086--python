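# rdnacn

Ribosomal DNA copy number from whole-genome sequencing depth: estimation
with aneuploidy and sequencing-plate correction, plus the downstream
association analyses that link rDNA changes in tumors to somatic context and
proliferation.

## The problem

Human ribosomal RNA is encoded by two unlinked multicopy arrays: the 45S
rDNA (18S, 5.8S, 28S components; five acrocentric chromosomes, Pol I) and
the 5S rDNA (chromosome 1q42, Pol III). Both arrays vary ~10-fold in copy
number between individuals, show concerted copy number variation (cCNV) in
some tissues, and change somatically in cancer — recurrently toward **5S
expansion and 45S loss**. Because the arrays collapse to single reference
copies, standard CNV callers cannot measure them; the practical estimator is
a depth ratio:

```
CN_component = mean depth over the component (or selected window)
               ---------------------------------------------------
               BRD  =  mean over background bases b of depth(b) / R(gene(b))
```

where the background is a curated set of single-copy exons/introns on the
rDNA-bearing chromosomes (chr1 exons+introns for 5S; chr13/14/15/21/22
exons for 45S) and `R = (2 + C) / 2` corrects each gene's depth for tumor
aneuploidy using GISTIC gene-level copy number values `C` (C = 0 is
diploid). Adjacent-normal samples skip the correction. The returned CN is
the depth ratio: a cell with `k` copies at diploid background gives `k / 2`.

For the heterogeneous 18S and 28S sequences, CN is measured over a 150 bp
window chosen to minimise the across-sample coefficient of variation of
depth ("lowest mean CV"); 5.8S and 5S are depth-homogeneous and use
full-length means. Plate effects are removed per cancer type by
residualizing `log CN ~ tissue + plate` and exponentiating back.

Downstream, the package provides: pairwise component correlations (cCNV),
one-sided paired tumor-vs-adjacent change tests, SCNA and recurrent-mutation
association tests, exact binomial direction-of-effect aggregation,
pan-cancer covariate models, 1q42 segmental-gain analyses, and
proliferation-index (PRI) / nucleolar-activity analyses on TMM-normalized
RNA-seq counts.

Everything is exercised end-to-end on a synthetic cohort generator
(`rdnacn.simulate`) that produces depth tables, GISTIC-style ploidy tables,
MAF-like mutations, metadata and expression counts with known ground truth,
so the whole pipeline is testable without any sequencing data.

## Worked example

```bash
rdnacn run-all --outdir out --seed 7
cat out/report.txt
```

prints (40 simulated patients under the default generative model, which
injects a median 1.3× tumor 5S gain and 0.8× 45S loss):

```
Per-cancer-type rDNA change calls (p < 0.01):
         CT1    CN_5S:    gain (n=18, median FC=1.361, p=3.81e-06)
         CT2    CN_5S:    gain (n=16, median FC=1.362, p=0.00134)
         CT1   CN_45S:    loss (n=18, median FC=0.743, p=1.14e-05)
         CT2   CN_45S:    loss (n=16, median FC=0.793, p=1.53e-05)
...
Synthetic-truth recovery diagnostics (ploidy-corrected stage):
  5S : Spearman 0.9999, median |rel err| 0.172%
  45S: Spearman 0.9999, median |rel err| 0.091%
```

Each "gain"/"loss" line is a one-sided exact Wilcoxon signed-rank test on
tumor–adjacent pairs sequenced on the same plate; `median FC` is the median
tumor/adjacent CN fold change; the recovery block compares estimates against
the generator's truth (Spearman rank correlation and median absolute
relative error). The run directory also contains the per-stage TSVs
(`cn_estimates.tsv` with raw / ploidy-corrected / batch-corrected stages,
`associations.tsv`, `direction_tests.tsv`, `pri.tsv`, ...) and a
machine-readable `summary.json`; for this run it records the selected CV
windows 18S 1145–1294 and 28S 1522–1671 and a PRI-fold-change vs
5S/45S-ratio-fold-change Spearman ρ = 0.46 (p = 0.0028, 40 patients).

Library use mirrors the CLI:

```python
from rdnacn import SimulationConfig, simulate_cohort, estimate_cn_table

cohort = simulate_cohort(SimulationConfig(n_patients=40, seed=7))
cn = estimate_cn_table(cohort.depth_by_sample, cohort.regions,
                       cohort.ploidy, cohort.metadata)
```

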