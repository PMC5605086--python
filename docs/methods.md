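# Methods

This note documents the statistical model behind `rdnacn`, the defaults and
why they were chosen, what the synthetic cohort generator does and does not
emulate, and the numerical conventions used throughout.

## Copy number estimator

Depth-ratio estimation assumes read depth at a locus is proportional to the
number of DNA copies of that locus in the sequenced cells. For an rDNA
component with `k` copies per cell and a diploid background, the expected
ratio of component depth to background depth is `k / 2`; the package reports
that ratio as "CN" (copies per diploid equivalent divided by two). All
estimates are invariant to per-sample depth scale: multiplying every depth
of a sample by a constant changes nothing.

**Background read depth (BRD).** BRD is the pooled mean of per-base depths
over the kept background regions — pooled over bases, not a mean of
per-region means, so long regions carry proportionally more weight, which is
the lower-variance choice for a mean-depth denominator. For tumors each
base's depth is divided by its gene's ploidy ratio `R = (2 + C)/2` before
pooling; genes with `R = 0` (homozygous deletion) are excluded with a
warning rather than poisoning the mean. The 5S denominator uses chromosome 1
exons and introns; the 45S denominator uses exons only from the acrocentric
chromosomes. Adjacent/normal samples are assumed diploid everywhere and skip
the correction.

**Window selection.** 18S and 28S depth profiles are heterogeneous across
sites (sequence polymorphism between individuals, truncated repeat units),
so their CN is read from a 150 bp window with minimal across-sample
coefficient of variation. Two CV readings exist: (a) the CV across samples
of per-sample window mean depths, and (b) the mean over the window's sites
of per-site across-sample CVs. The selection helper defaults to reading (b),
which matches the "lowest **mean CV**" phrasing of the procedure and is far
more reliable: under reading (a) the realized covariance between individual
copy numbers and window heterogeneity is the same order as the contrast
being sought, and selection fails in a double-digit fraction of replicate
cohorts even at 20 samples; reading (b) averages ~150 nearly independent
per-site estimates and finds the designed window in essentially every
replicate. Reading (a) remains available (`per_site=False`), and
`window_cv_profile` itself computes it.

Before scoring, each sample's component depth vector is divided by its own
mean (`normalize=True`). Inter-individual array copy number — up to 10-fold
— is a common multiplier on every window of a sample; it inflates every
window's CV equally in expectation but, in cohorts with heavy-tailed copy
spread, its sampling noise swamps the heterogeneity contrast. Dividing it
out leaves exactly the quantity selection is after: relative depth
heterogeneity along the sequence.

The conventional windows 18S 1145–1294 and 28S 1522–1671 (component-local,
1-based) ship as defaults usable without recomputation; a fallback mode uses
18S 901–1871 (the first ~600 bp of 18S cross-map to chromosome 21 and are
under-recovered by BAM slicing) with full-length 28S. 5.8S and 5S use
full-length means; their observed depth is nearly constant across sites.

**45S array CN** pools bases across the three component intervals (windows
applied to 18S/28S, full 5.8S), i.e. the depth-weighted average of the
component estimates, and always lies between the component extremes.

## Plate (batch) correction

Detection uses samples sequenced on two plates: for each plate pair sharing
at least 6 samples (matched by patient and tissue), a two-sided exact
Wilcoxon signed-rank test compares duplicate measurements per component.
Removal fits, per cancer type and component, ordinary least squares of
`log CN ~ intercept + tissue + plate` (natural log; any base is equivalent
after back-transform) with the most populous plate as reference, and returns
`exp(log CN − fitted plate contribution)` — back on the CN scale because all
downstream tests operate on CN values. Tissue and intercept terms are kept,
so tumor–adjacent contrasts survive. A plate whose indicator is linearly
dependent on the tissue term (e.g. a plate holding all and only tumors)
cannot be estimated; it is flagged and left uncorrected with a warning.
Correction is a monotone (multiplicative) transform within each plate, so
within-plate sample orderings never change. The 5S/45S ratio is recomputed
from corrected components rather than residualized itself.

A uniform per-sample plate multiplier on *all* loci cancels exactly in the
depth ratio, so such a multiplier (the generator's `batch_sd`) never reaches
the CN scale; real plate effects on CN arise from locus-differential biases.
The generator exposes `batch_cn_bias_sd` (default 0) to put a plate
multiplier on rDNA loci only when a CN-scale batch effect is wanted
end-to-end; batch-correction tests otherwise inject effects directly into
CN tables.

## Association tests

All exact tests enumerate their null when sizes permit (n ≤ 25 per
signed-rank / per rank-sum group) and fall back to normal approximations
with continuity correction above that; the choice is logged per call. Zero
paired differences are dropped before ranking (Pratt handling available).
Test direction ("gain"/"loss", one-tailed alternatives) is always an
explicit argument, never inferred from data.

* **cCNV**: pairwise Pearson correlations among component CNs per cancer
  type and tissue; undefined (zero-variance) pairs reported missing.
* **Paired change**: one-sided exact signed-rank on tumor vs adjacent CN,
  restricted by default to pairs sequenced on the same plate.
* **SCNA**: presence = |ploidy − 2| > 0.1 from GISTIC gene values (the
  ">2.1 / <1.9" phrasing is the same rule on the ploidy scale); OLS of CN on
  the 0/1 indicator, whose coefficient is exactly the group mean
  difference. Tumor CN is the default response; the tumor-minus-adjacent
  difference can be supplied instead by the caller.
* **Mutations**: genes with non-silent somatic mutations in ≥ 10 patients;
  two-sided rank-sum between mutated and wild-type tumors, direction from
  the median difference.
* **Direction aggregation**: exact binomial test of k same-direction
  results among n significant ones against 0.5, two-sided by the
  point-probability rule (equals twice the smaller tail at 0.5).
* **Pan-cancer models**: OLS of the trait on presence plus treatment-coded
  cancer-type dummies; the presence indicator is checked for perfect
  confounding with cancer type and flagged. Per-mutation variants require
  ≥ 5 recurrences.
* **1q42 analyses**: Spearman correlation of mean proxy-gene (RNF187/RHOU)
  ploidy with 5S CN; and a paired one-tailed 5S gain test restricted to
  patients with 1q42 ploidy in [1.98, 2.02] — "paired Wilcoxon" here and
  throughout means the signed-rank test.

Per-feature significance is nominal p < 0.05, matching the source
procedure, which applies no multiplicity correction; Benjamini–Hochberg is
available (`adjust_bh`) but off by default.

## Expression and proliferation index

Counts are filtered to genes with ≥ 10 reads in strictly more than half of
samples ("more than half" is read as a strict majority). TMM normalization
is implemented from its published definition — per-gene log2 ratios (M) and
mean abundances (A) against a reference sample, doubly trimmed by ranks
(30% of M, 5% of A from each side), combined by inverse-delta-method
weights, factors rescaled to geometric mean 1 — because no installed Python
package provides it; a test cross-checks the implementation against
Bioconductor edgeR's `calcNormFactors` on a shared reference column. The
default reference is the sample whose upper-quartile count is closest to
the mean upper quartile.

PRI, nucleolar activity and cRPG expression are per-sample medians of a
gene set's normalized expression, computed on TMM-scaled log2 CPM with
pseudo-count 1 (the scale is unstated in the source; RPKM mode exists via
`rpkm`). Paired tumor/adjacent fold changes per patient feed per-cancer
change tests (≥ 5 pairs; signed-rank default, rank-sum behind a flag) and
Spearman correlations with CN or CN fold changes.

## Synthetic cohort generator

The generator draws, per patient: bivariate-lognormal adjacent 5S/45S
copies (defaults: medians 150 and 400, log-sd 0.6 ≈ 10-fold range across
±2 sd, correlation `ccnv_rho` = 0.6); lognormal tumor fold changes with
medians `tumor_5s_gain_mean` = 1.3 and `tumor_45s_loss_mean` = 0.8 and
log-sd 0.2, shifted ±`driver_effect` (0.2) on the log scale when the
simulated driver mutation (present in ~50% of tumors, maximising association
power) is carried; a 1q42 segmental gain (30% of tumors, C ∈ {0.5, 1}) that
multiplies true 5S copies by its ploidy ratio and surfaces in the ploidy
table through the two proxy genes; and block-constant GISTIC C values on
background genes (blocks of 4 genes, per-block probability
`aneuploidy_rate` = 0.3, C ∈ {−1, −0.5, 0.5, 1, 2}, spanning the R
correction's range) for tumors only.

Depth at each base of a locus with `k` copies is Poisson(`per_copy_depth`
× k × site_rate × batch multiplier); `per_copy_depth` = 15 reads/base is a
30× diploid genome. The Poisson choice is an assumption — no dispersion
model is stated for depth in the source. Site rates are i.i.d.
lognormal(0, `site_het_sd` = 0.3) per (site, sample) on 18S and 28S only,
emulating between-individual polymorphism; each carries one designated
150 bp homogeneous window (rate ≡ 1, at the conventional window
coordinates), which is the target CV selection should find. 5.8S and 5S are
homogeneous, as observed. Per-sample rates (rather than a shared site
profile) are essential: a shared profile is a common multiplier on window
means and cancels in the across-sample CV.

The expression simulator draws negative binomial counts (dispersion 0.05)
around lognormal gene baselines with a deterministic 2.5-fold library-size
spread; the designated PRI set scales with the per-tumor proliferation
factor, nucleolar and cRPG sets with softened powers of it. The
proliferation factor is lognormal with its log correlated
(`proliferation_coupling` = 0.5) with the realised tumor log(5S/45S)
change, so PRI fold changes and ratio fold changes correlate by
construction.

Not emulated: read-level artifacts (mapping, GC bias, duplicates), clonal
heterogeneity and purity, sequence content, pseudo-rRNA contamination, and
plate effects that differ across background loci. Passing tests therefore
demonstrate correctness of the estimator and statistics under the stated
generative model, not robustness to alignment-level artifacts in real BAMs.

## Problem sizes and numerics

Verification runs use cohorts of 20–40 patients at 30× (recovery: 40
patients; window selection: 50 replicates of 20 patients, a scale-down of
the 74-sample adjacent cohort the published windows were selected on;
directional calls: 20 replicates of 30 pairs; plate null calibration: 100
replicates), sizes chosen to keep the full suite and the acceptance script
in the tens of seconds while leaving all statistical margins wide.
Deterministic seeding: identical config (including seed) reproduces every
table and array bit for bit. Ties in window CVs resolve to the leftmost
start; "largest exon" ties resolve to the leftmost; region coordinates are
1-based inclusive at every interface. Degenerate inputs (all-zero paired
differences, constant regressors, zero-variance correlations, empty
region/feature sets) return p = 1, `None`, or missing values as documented
on each function rather than raising, except where the input contract
itself is violated.

## Known limitations

* The estimator inherits any bias shared by the background and rDNA loci
  only when it differs between them (e.g. GC-content differences between
  rDNA and background are not modeled or corrected).
* Plate residualization estimates batch coefficients from between-sample
  contrasts; with few samples per plate the corrected values absorb some
  true biological variation (visible as a recovery penalty on the
  batch-corrected stage relative to the ploidy-corrected stage).
* GISTIC values are taken as exact; noise or segmentation error in the
  ploidy table propagates directly into the BRD correction.
* The near-diploid 1q42 subset analysis conditions on an estimated
  quantity (proxy ploidy) and is only as good as that proxy.
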