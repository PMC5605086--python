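"""Associations between rDNA copy number and somatic / genomic context.

Covers the downstream statistics of the pipeline:

* concerted CNV: pairwise Pearson correlations among component CNs, per
  tissue and cancer type;
* paired tumor-vs-adjacent change tests (one-sided exact signed-rank,
  restricted by default to patients whose two samples share a plate);
* SCNA associations (OLS of CN on a 0/1 presence indicator derived from
  GISTIC ploidy thresholds; the coefficient is the group mean difference);
* somatic mutation associations (two-sided rank-sum, genes with non-silent
  mutations in at least 10 patients);
* direction-of-effect aggregation (exact binomial test against 0.5);
* pan-cancer covariate models (trait ~ presence + cancer type) and
  per-mutation variants of them;
* 1q42 locus analyses: proxy-gene ploidy vs 5S CN (Spearman), and the
  near-diploid-subset amplification test.

Direction ("one-sided") is always an explicit argument, never inferred from
the data.  Significance defaults to nominal p < 0.05 per feature;
Benjamini-Hochberg adjustment is available via :func:`adjust_bh`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import NONSILENT_CLASSES
from .stats import (
    TestResult,
    binomial_direction_test,
    pearson,
    rank_sum_test,
    signed_rank_test,
    spearman,
)

logger = logging.getLogger(__name__)

TRAITS = ("CN_5S", "CN_45S", "ratio_5S_45S")


@dataclass
class AssociationResult:
    """One context feature against one CN trait."""

    feature: str
    trait: str
    test: str
    statistic: float  # coefficient for regression tests, U/W otherwise
    pvalue: float
    direction: int  # sign of the coefficient or median difference
    n_with: int
    n_without: int
    cancer_type: str = "pan-cancer"
    conf_int: tuple | None = None
    flag: str = ""

    def to_dict(self) -> dict:
        d = dict(
            feature=self.feature, trait=self.trait, test=self.test,
            statistic=self.statistic, pvalue=self.pvalue,
            direction=self.direction, n_with=self.n_with,
            n_without=self.n_without, cancer_type=self.cancer_type,
            flag=self.flag,
        )
        if self.conf_int is not None:
            d["ci_low"], d["ci_high"] = self.conf_int
        return d


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; off by default)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# concerted CNV
# ---------------------------------------------------------------------------

def ccnv_correlations(
    cn_table: pd.DataFrame,
    components=("CN_18S", "CN_5_8S", "CN_28S", "CN_5S"),
    min_n: int = 3,
) -> pd.DataFrame:
    """Pairwise Pearson r and p among component CNs per (cancer type, tissue)."""
    rows = []
    for (ct, tissue), sub in cn_table.groupby(["cancer_type", "tissue"]):
        if len(sub) < min_n:
            continue
        for i, a in enumerate(components):
            for b in components[i + 1 :]:
                res = pearson(sub[a], sub[b])
                rows.append(
                    dict(cancer_type=ct, tissue=tissue, component_a=a,
                         component_b=b, r=res.statistic, pvalue=res.pvalue,
                         n=res.n)
                )
    return pd.DataFrame(
        rows, columns=["cancer_type", "tissue", "component_a", "component_b",
                       "r", "pvalue", "n"],
    )


# ---------------------------------------------------------------------------
# paired tumor-adjacent change
# ---------------------------------------------------------------------------

def paired_samples(
    cn_table: pd.DataFrame, same_plate_only: bool = True
) -> pd.DataFrame:
    """Wide per-patient table of tumor and adjacent rows, optionally
    restricted to pairs sequenced on the same plate."""
    t = cn_table[cn_table["tissue"] == "tumor"].set_index("patient_id")
    a = cn_table[cn_table["tissue"] == "adjacent"].set_index("patient_id")
    shared = t.index.intersection(a.index)
    t, a = t.loc[shared], a.loc[shared]
    if same_plate_only:
        keep = t["plate_id"].astype(str) == a["plate_id"].astype(str)
        t, a = t[keep], a[keep.reindex(a.index, fill_value=False)]
    out = t.add_suffix("_tumor").join(a.add_suffix("_adjacent"))
    out.index.name = "patient_id"
    return out


def paired_change_test(
    cn_table: pd.DataFrame,
    component: str,
    direction: str,
    same_plate_only: bool = True,
    min_pairs: int = 1,
) -> pd.DataFrame:
    """One-sided paired test of rDNA gain or loss in tumors, per cancer type.

    ``direction`` is "gain" (tumor > adjacent) or "loss" (tumor < adjacent).
    Returns one row per cancer type with the exact one-sided signed-rank p,
    the number of informative pairs and the median tumor/adjacent fold
    change.  Zero differences are dropped before ranking.
    """
    if direction not in ("gain", "loss"):
        raise ValueError("direction must be 'gain' or 'loss'")
    alternative = "greater" if direction == "gain" else "less"
    pairs = paired_samples(cn_table, same_plate_only=same_plate_only)
    rows = []
    for ct, sub in pairs.groupby("cancer_type_tumor"):
        x = sub[f"{component}_tumor"].to_numpy(dtype=float)
        y = sub[f"{component}_adjacent"].to_numpy(dtype=float)
        if len(x) < min_pairs:
            continue
        res = signed_rank_test(x, y, alternative=alternative)
        fc = x / y
        rows.append(
            dict(cancer_type=ct, component=component, direction=direction,
                 n_pairs=len(x), median_fc=float(np.median(fc)),
                 pvalue=res.pvalue, method=res.method)
        )
    return pd.DataFrame(
        rows, columns=["cancer_type", "component", "direction", "n_pairs",
                       "median_fc", "pvalue", "method"],
    )


# ---------------------------------------------------------------------------
# SCNA context
# ---------------------------------------------------------------------------

def scna_calls(
    ploidy_values: pd.DataFrame, threshold: float = 0.1
) -> pd.DataFrame:
    """SCNA presence and extent from GISTIC gene values C (ploidy = 2 + C).

    A tumor contains the amplification when ploidy - 2 > ``threshold`` and
    the deletion when 2 - ploidy > ``threshold``.  Returns a long table:
    gene_id, sample_id, kind (amp|del), extent (>= 0 when present).
    """
    c = ploidy_values
    rows = []
    for kind, extent in (("amp", c), ("del", -c)):
        mask = extent > threshold
        for gene in c.index:
            hit = mask.loc[gene]
            for sid in c.columns[hit]:
                rows.append(
                    dict(gene_id=gene, sample_id=sid, kind=kind,
                         extent=float(extent.at[gene, sid]))
                )
    return pd.DataFrame(rows, columns=["gene_id", "sample_id", "kind", "extent"])


def scna_association(
    cn: np.ndarray, presence: np.ndarray, feature: str = "", trait: str = "",
    cancer_type: str = "",
) -> AssociationResult | None:
    """OLS of CN on a 0/1 SCNA presence indicator.

    The coefficient equals mean(CN | present) - mean(CN | absent); the
    two-sided p comes from the t statistic.  Returns None when the indicator
    is constant.
    """
    cn = np.asarray(cn, dtype=float)
    presence = np.asarray(presence, dtype=float)
    if presence.min() == presence.max():
        return None
    res = sps.linregress(presence, cn)
    coef, p = float(res.slope), float(res.pvalue)
    if np.isnan(p):  # zero residual variance (constant CN): no evidence
        p = 1.0 if coef == 0.0 else 0.0
    return AssociationResult(
        feature=feature, trait=trait, test="ols_presence",
        statistic=coef, pvalue=p, direction=int(np.sign(coef)) or 0,
        n_with=int(presence.sum()), n_without=int((1 - presence).sum()),
        cancer_type=cancer_type or "pan-cancer",
    )


# ---------------------------------------------------------------------------
# somatic mutations
# ---------------------------------------------------------------------------

def nonsilent_presence(
    mutations: pd.DataFrame, samples, gene: str | None = None
) -> pd.Series | pd.DataFrame:
    """Per-sample 0/1 presence of non-silent mutations, per gene."""
    ns = mutations[mutations["Variant_Classification"].isin(NONSILENT_CLASSES)]
    if gene is not None:
        hit = set(ns.loc[ns["Hugo_Symbol"] == gene, "Tumor_Sample_Barcode"])
        return pd.Series([s in hit for s in samples], index=samples, dtype=int)
    out = {}
    for g, sub in ns.groupby("Hugo_Symbol"):
        hit = set(sub["Tumor_Sample_Barcode"])
        out[g] = pd.Series([s in hit for s in samples], index=samples, dtype=int)
    return pd.DataFrame(out)


def mutation_association(
    cn: np.ndarray,
    presence: np.ndarray,
    feature: str = "",
    trait: str = "",
    cancer_type: str = "",
    min_patients: int = 10,
) -> AssociationResult | None:
    """Rank-sum comparison of CN between mutated and wild-type tumors.

    Genes mutated in fewer than ``min_patients`` patients are skipped
    (returns None); direction is the sign of the median difference.
    """
    cn = np.asarray(cn, dtype=float)
    presence = np.asarray(presence, dtype=int)
    n_mut = int(presence.sum())
    if n_mut < min_patients or n_mut == presence.size:
        logger.debug("feature %s skipped: %d mutated patients", feature, n_mut)
        return None
    mut, wt = cn[presence == 1], cn[presence == 0]
    res = rank_sum_test(mut, wt, alternative="two-sided")
    diff = float(np.median(mut) - np.median(wt))
    return AssociationResult(
        feature=feature, trait=trait, test="rank_sum",
        statistic=res.statistic, pvalue=res.pvalue,
        direction=int(np.sign(diff)) or 0,
        n_with=n_mut, n_without=int(presence.size - n_mut),
        cancer_type=cancer_type or "pan-cancer",
    )


def direction_binomial(k_same_direction: int, n_significant: int) -> TestResult:
    """Exact two-sided binomial test of directional consistency against 0.5."""
    return binomial_direction_test(k_same_direction, n_significant)


# ---------------------------------------------------------------------------
# pan-cancer covariate models
# ---------------------------------------------------------------------------

def pancancer_model(
    trait: np.ndarray,
    presence: np.ndarray,
    cancer_labels,
    feature: str = "",
    trait_name: str = "",
) -> AssociationResult:
    """OLS of trait on mutation presence with cancer type as covariate.

    Treatment-coded cancer-type dummies absorb the per-type baselines; the
    reported coefficient, two-sided p and 95% CI belong to the presence
    term.  A presence indicator confounded with cancer type is flagged and
    the result marked unreliable.
    """
    import statsmodels.api as sm

    labels = pd.Series(list(cancer_labels), dtype=str)
    if labels.nunique() < 2:
        raise ValueError("pan-cancer model needs >= 2 cancer types")
    presence = np.asarray(presence, dtype=float)
    X = pd.DataFrame({"presence": presence})
    dummies = pd.get_dummies(labels, prefix="ct", drop_first=True, dtype=float)
    X = pd.concat([X, dummies.reset_index(drop=True)], axis=1)
    X = sm.add_constant(X)
    flag = ""
    base = X.drop(columns="presence").to_numpy()
    if np.linalg.matrix_rank(np.column_stack([base, presence])) == \
            np.linalg.matrix_rank(base):
        flag = "confounded_with_cancer_type"
    fit = sm.OLS(np.asarray(trait, dtype=float), X.to_numpy()).fit()
    i = list(X.columns).index("presence")
    coef = float(fit.params[i])
    ci = tuple(float(v) for v in fit.conf_int()[i])
    return AssociationResult(
        feature=feature, trait=trait_name, test="ols_cancer_covariate",
        statistic=coef, pvalue=float(fit.pvalues[i]),
        direction=int(np.sign(coef)) or 0,
        n_with=int(presence.sum()), n_without=int((1 - presence).sum()),
        cancer_type="pan-cancer", conf_int=ci, flag=flag,
    )


def per_mutation_model(
    trait: np.ndarray,
    mutation_presence: np.ndarray,
    cancer_labels,
    mutation_id: str,
    min_recurrence: int = 5,
    trait_name: str = "",
) -> AssociationResult | None:
    """Pan-cancer model for one specific recurrent mutation.

    Mutations observed in fewer than ``min_recurrence`` patients are skipped.
    """
    presence = np.asarray(mutation_presence, dtype=int)
    if presence.sum() < min_recurrence:
        return None
    res = pancancer_model(
        trait, presence, cancer_labels, feature=mutation_id,
        trait_name=trait_name,
    )
    res.test = "ols_per_mutation"
    return res


# ---------------------------------------------------------------------------
# 1q42 locus analyses
# ---------------------------------------------------------------------------

def locus_ploidy_vs_cn(proxy_ploidy, cn_5s, min_n: int = 5) -> TestResult:
    """Spearman correlation of mean proxy-gene ploidy at 1q42 with 5S CN."""
    proxy_ploidy = np.asarray(proxy_ploidy, dtype=float)
    cn_5s = np.asarray(cn_5s, dtype=float)
    if proxy_ploidy.size < min_n:
        raise ValueError(f"need >= {min_n} tumors")
    return spearman(proxy_ploidy, cn_5s)


def diploid_subset_test(
    cn_table: pd.DataFrame,
    proxy_ploidy: pd.Series,
    component: str = "CN_5S",
    direction: str = "gain",
    window: tuple[float, float] = (1.98, 2.02),
    same_plate_only: bool = True,
) -> dict | None:
    """Paired one-tailed test of 5S change among near-diploid-1q42 patients.

    ``proxy_ploidy`` maps patient_id to the tumor's mean proxy-gene ploidy
    at 1q42.13.  Only patients with both tumor and adjacent CN and ploidy
    inside ``window`` (inclusive) enter the test.  Returns None when the
    subset is empty.
    """
    pairs = paired_samples(cn_table, same_plate_only=same_plate_only)
    ploidy = proxy_ploidy.reindex(pairs.index)
    keep = (ploidy >= window[0]) & (ploidy <= window[1])
    sub = pairs[keep.fillna(False)]
    if sub.empty:
        return None
    alternative = "greater" if direction == "gain" else "less"
    res = signed_rank_test(
        sub[f"{component}_tumor"].to_numpy(dtype=float),
        sub[f"{component}_adjacent"].to_numpy(dtype=float),
        alternative=alternative,
    )
    return dict(
        component=component, direction=direction, n_patients=int(len(sub)),
        pvalue=res.pvalue, method=res.method,
    )


# ---------------------------------------------------------------------------
# scans (feature tables -> result tables)
# ---------------------------------------------------------------------------

def scna_scan(
    cn_table: pd.DataFrame,
    ploidy_values: pd.DataFrame,
    traits=TRAITS,
    threshold: float = 0.1,
    per_cancer_type: bool = True,
) -> pd.DataFrame:
    """All gene-level SCNA x trait associations on tumor samples."""
    tumors = cn_table[cn_table["tissue"] == "tumor"]
    calls = scna_calls(ploidy_values, threshold=threshold)
    rows = []
    groups = tumors.groupby("cancer_type") if per_cancer_type else [("pan-cancer", tumors)]
    for ct, sub in groups:
        sids = list(sub["sample_id"])
        for (gene, kind), hits in calls.groupby(["gene_id", "kind"]):
            hit_set = set(hits["sample_id"])
            presence = np.array([s in hit_set for s in sids], dtype=float)
            for trait in traits:
                res = scna_association(
                    sub[trait].to_numpy(dtype=float), presence,
                    feature=f"{gene}:{kind}", trait=trait, cancer_type=ct,
                )
                if res is not None:
                    rows.append(res.to_dict())
    return pd.DataFrame(rows)


def mutation_scan(
    cn_table: pd.DataFrame,
    mutations: pd.DataFrame,
    traits=TRAITS,
    min_patients: int = 10,
    per_cancer_type: bool = True,
) -> pd.DataFrame:
    """All non-silent mutated-gene x trait rank-sum associations on tumors."""
    tumors = cn_table[cn_table["tissue"] == "tumor"]
    rows = []
    groups = tumors.groupby("cancer_type") if per_cancer_type else [("pan-cancer", tumors)]
    for ct, sub in groups:
        sids = list(sub["sample_id"])
        pres = nonsilent_presence(mutations, sids)
        for gene in pres.columns:
            for trait in traits:
                res = mutation_association(
                    sub[trait].to_numpy(dtype=float),
                    pres[gene].to_numpy(), feature=gene, trait=trait,
                    cancer_type=ct, min_patients=min_patients,
                )
                if res is not None:
                    rows.append(res.to_dict())
    return pd.DataFrame(rows)
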