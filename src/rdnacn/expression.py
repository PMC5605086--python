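"""Bulk RNA-seq normalization and proliferation-index (PRI) analyses.

Counts are filtered to genes with at least 10 reads in strictly more than
half of the samples, normalized between samples by TMM (trimmed mean of
M-values, implemented from its published definition: a doubly trimmed,
precision-weighted mean of per-gene log2 ratios against a reference sample),
and summarized per sample as the median expression of a gene set:

* PRI (proliferation index): median over a proliferation-associated set
  (the "YW" 793-gene and "RS" 350-gene sets in the source study; synthetic
  sets in tests);
* nucleolar activity: median over nucleolus cellular-component genes;
* cRPG expression: median over cytoplasmic ribosomal protein genes.

PRI is computed on TMM-scaled counts per million, log2 with pseudo-count 1;
an RPKM mode is available.  Per-patient tumor/adjacent fold changes of these
summaries feed the paired change tests and the correlations with rDNA CN.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stats import TestResult, rank_sum_test, signed_rank_test, spearman

logger = logging.getLogger(__name__)


def filter_expressed(counts: pd.DataFrame, min_reads: int = 10) -> list:
    """Genes with >= ``min_reads`` in strictly more than half of the samples."""
    if counts.empty:
        return []
    n = counts.shape[1]
    keep = (counts >= min_reads).sum(axis=1) > n / 2
    return list(counts.index[keep])


def _reference_sample(counts: pd.DataFrame) -> str:
    """Sample whose upper-quartile count is closest to the mean upper quartile."""
    uq = counts.quantile(0.75, axis=0)
    return str((uq - uq.mean()).abs().idxmin())


def tmm_normalize(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: str | None = None,
) -> pd.Series:
    """TMM scaling factors, one per sample, geometric mean 1.

    For sample k against the reference r, with library sizes N and relative
    abundances y/N, each shared expressed gene g contributes

        M_g = log2((y_gk / N_k) / (y_gr / N_r)),
        A_g = 0.5 log2((y_gk / N_k)(y_gr / N_r)),
        w_g = (N_k - y_gk)/(N_k y_gk) + (N_r - y_gr)/(N_r y_gr),

    the most extreme ``trim_m`` of M-values and ``trim_a`` of A-values are
    trimmed from each side (by ranks), and the factor is
    2 ** (sum w M / sum w) over the surviving genes.  Factors are rescaled so
    their geometric mean is 1; multiply by the library size to get the
    effective library size.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs >= 2 samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise ValueError("a sample has zero total counts")
    ref = reference if reference is not None else _reference_sample(counts)
    yr = counts[ref].to_numpy(dtype=float)
    nr = float(lib[ref])
    factors = {}
    for s in counts.columns:
        if s == ref:
            factors[s] = 1.0
            continue
        yk = counts[s].to_numpy(dtype=float)
        nk = float(lib[s])
        ok = (yk > 0) & (yr > 0)
        if not ok.any():
            factors[s] = 1.0
            continue
        pk, pr = yk[ok] / nk, yr[ok] / nr
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        w = (nk - yk[ok]) / (nk * yk[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        n = m.size
        # double trim by ranks, mirroring the published procedure
        rm = pd.Series(m).rank().to_numpy()
        ra = pd.Series(a).rank().to_numpy()
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not keep.any() or w[keep].sum() == 0:
            factors[s] = 1.0
            continue
        factors[s] = float(2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep])))
    f = pd.Series(factors).reindex(counts.columns)
    return f / np.exp(np.log(f).mean())


def effective_library_sizes(counts: pd.DataFrame, factors: pd.Series) -> pd.Series:
    return counts.sum(axis=0).astype(float) * factors


def cpm(counts: pd.DataFrame, eff_lib: pd.Series, log2: bool = True) -> pd.DataFrame:
    """(log2) counts per million on effective library sizes."""
    x = counts.div(eff_lib, axis=1) * 1e6
    return np.log2(x + 1.0) if log2 else x


def rpkm(
    counts: pd.DataFrame, gene_lengths: pd.Series, eff_lib: pd.Series
) -> pd.DataFrame:
    """Reads per kilobase per million: 1e9 * count / (length * library size)."""
    lengths = gene_lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("gene lengths must be positive for all genes")
    return counts.div(eff_lib, axis=1).div(lengths, axis=0) * 1e9


def pri(normalized: pd.DataFrame, gene_set, set_name: str = "") -> pd.Series:
    """Per-sample median normalized expression over a gene set.

    Genes outside the matrix (filtered out) are ignored; an empty
    intersection raises.
    """
    genes = [g for g in dict.fromkeys(gene_set) if g in normalized.index]
    if not genes:
        raise ValueError(f"gene set {set_name or '<unnamed>'} has no retained genes")
    out = normalized.loc[genes].median(axis=0)
    out.name = set_name or "PRI"
    return out


def paired_fold_change(
    values: pd.Series, metadata: pd.DataFrame, same_plate_only: bool = False
) -> pd.DataFrame:
    """Per-patient tumor/adjacent fold change of a per-sample summary."""
    meta = metadata.set_index("sample_id")
    df = pd.DataFrame({"value": values}).join(meta)
    t = df[df["tissue"] == "tumor"].set_index("patient_id")
    a = df[df["tissue"] == "adjacent"].set_index("patient_id")
    shared = t.index.intersection(a.index)
    t, a = t.loc[shared], a.loc[shared]
    if same_plate_only:
        keep = t["plate_id"].astype(str) == a["plate_id"].astype(str)
        t, a = t[keep], a[keep]
    return pd.DataFrame(
        {
            "cancer_type": t["cancer_type"],
            "tumor": t["value"],
            "adjacent": a["value"],
            "fc": t["value"] / a["value"],
        }
    )


def paired_expression_change(
    values: pd.Series,
    metadata: pd.DataFrame,
    min_pairs: int = 5,
    test: str = "signed_rank",
) -> pd.DataFrame:
    """Median tumor/adjacent FC and paired test p per cancer type.

    Cancer types with fewer than ``min_pairs`` tumor-adjacent pairs are
    skipped.  The paired Wilcoxon (signed-rank) test is the default; a
    rank-sum variant on the paired values is available via
    ``test="rank_sum"``.
    """
    fc = paired_fold_change(values, metadata)
    rows = []
    for ct, sub in fc.groupby("cancer_type"):
        if len(sub) < min_pairs:
            continue
        x = sub["tumor"].to_numpy(dtype=float)
        y = sub["adjacent"].to_numpy(dtype=float)
        if test == "signed_rank":
            res = signed_rank_test(x, y, alternative="two-sided")
        elif test == "rank_sum":
            res = rank_sum_test(x, y, alternative="two-sided")
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append(
            dict(cancer_type=ct, n_pairs=len(sub),
                 median_fc=float(sub["fc"].median()), pvalue=res.pvalue,
                 method=res.method)
        )
    return pd.DataFrame(
        rows, columns=["cancer_type", "n_pairs", "median_fc", "pvalue", "method"],
    )


def pri_cn_correlation(x, y, method: str = "spearman") -> TestResult:
    """Correlation between a PRI-style summary (or its FC) and CN (or its FC)."""
    if method != "spearman":
        raise ValueError("only the Spearman rank correlation is supported")
    return spearman(x, y)


def multivariate_ratio_model(
    ratio,
    tp53_presence,
    pri_values,
    cancer_labels=None,
    collinearity_r: float = 0.99,
) -> pd.DataFrame:
    """OLS of the 5S/45S ratio on mutation presence and PRI jointly.

    Cancer-type dummies are added when labels with >= 2 levels are given.
    Reports coefficient, two-sided p and 95% CI per regressor; the pair
    (presence, PRI) is flagged when |r| exceeds ``collinearity_r``.
    """
    import statsmodels.api as sm

    y = np.asarray(ratio, dtype=float)
    pres = np.asarray(tp53_presence, dtype=float)
    priv = np.asarray(pri_values, dtype=float)
    X = pd.DataFrame({"tp53": pres, "pri": priv})
    if cancer_labels is not None:
        labels = pd.Series(list(cancer_labels), dtype=str)
        if labels.nunique() >= 2:
            X = pd.concat(
                [X, pd.get_dummies(labels, prefix="ct", drop_first=True,
                                   dtype=float).reset_index(drop=True)],
                axis=1,
            )
    X = sm.add_constant(X)
    flag = ""
    if np.std(pres) > 0 and np.std(priv) > 0:
        r = float(np.corrcoef(pres, priv)[0, 1])
        if abs(r) > collinearity_r:
            flag = f"collinear(|r|={abs(r):.3f})"
    fit = sm.OLS(y, X.to_numpy()).fit()
    ci = fit.conf_int()
    return pd.DataFrame(
        dict(
            term=list(X.columns),
            coefficient=fit.params,
            pvalue=fit.pvalues,
            ci_low=ci[:, 0],
            ci_high=ci[:, 1],
            flag=flag,
        )
    )
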