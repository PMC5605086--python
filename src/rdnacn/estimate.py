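"""Copy number estimation for the 5S and 45S ribosomal DNA arrays.

The estimator is a depth ratio: the mean per-base sequencing depth over an
rDNA component (or a selected low-variability window of it) divided by the
background read depth (BRD), the mean aneuploidy-corrected per-base depth
over single-copy exons/introns.  The 5S denominator uses chromosome 1 exons
and introns (the 5S array sits on 1q42); the 45S denominator uses exons from
the acrocentric chromosomes 13/14/15/21/22 that carry the 45S arrays.

Tumor genomes are rampantly aneuploid, so background bases are rescaled by
R = (2 + C) / 2 where C is the GISTIC gene-level copy number value of the
gene the base belongs to (C = 0 is diploid).  Adjacent-normal samples are
assumed diploid and skip the correction.

Because 18S and, especially, 28S show depth heterogeneity across sites
(sequence polymorphism, truncated units), their CN is measured over a 150 bp
window chosen to minimise the across-sample coefficient of variation of the
window mean depth; 5.8S and 5S are near-homogeneous and use full-length
means.  The published windows (18S 1145-1294, 28S 1522-1671, component-local
1-based) ship as defaults; a fallback mode uses 18S 901-1871 and full-length
28S.

The returned CN is the depth ratio itself, i.e. copies per diploid
equivalent divided by two: a cell carrying k copies at background diploidy
yields CN = k / 2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import CHROM_GROUP_5S, CHROM_GROUP_45S, RegionSet

logger = logging.getLogger(__name__)

RDNA_COMPONENTS = ("18S", "5.8S", "28S", "5S")

#: published component-local 150 bp windows selected by minimum CV
DEFAULT_WINDOWS = {"18S": (1145, 1294), "28S": (1522, 1671)}

#: fallback mode: last 971 bp of 18S (the first ~600 bp share homology with
#: chr21 and are under-recovered by slicing), full-length 28S
FALLBACK_18S_WINDOW = (901, 1871)

CN_COLUMNS = {
    "18S": "CN_18S",
    "5.8S": "CN_5_8S",
    "28S": "CN_28S",
    "5S": "CN_5S",
}


@dataclass(frozen=True)
class DepthProfile:
    """Per-base depth over one named reference for one sample."""

    reference: str
    depths: np.ndarray
    sample_id: str = ""

    def __post_init__(self):
        d = np.asarray(self.depths, dtype=float)
        if (d < 0).any():
            raise ValueError("negative depths")
        object.__setattr__(self, "depths", d)


class PloidyTable:
    """Gene-level GISTIC copy number values C per tumor sample.

    C = 0 means normal diploid and 2 + C is the actual ploidy of the gene;
    R = (2 + C)/2 is the depth correction divisor.  Samples absent from the
    table (adjacent normal tissue, blood) are implicitly diploid.
    """

    def __init__(self, values: pd.DataFrame, gene_info: pd.DataFrame | None = None):
        # values: index gene_id, columns sample_id, entries C
        if (2 + values.to_numpy(dtype=float) < 0).any():
            raise ValueError("C < -2 implies negative ploidy")
        self.values = values
        self.gene_info = gene_info

    def c_value(self, gene_id: str, sample_id: str) -> float:
        if sample_id not in self.values.columns or gene_id not in self.values.index:
            return 0.0
        return float(self.values.at[gene_id, sample_id])

    def ploidy(self, gene_id: str, sample_id: str) -> float:
        return 2.0 + self.c_value(gene_id, sample_id)

    @property
    def genes(self):
        return list(self.values.index)

    @property
    def samples(self):
        return list(self.values.columns)


def ploidy_ratio(c: float) -> float:
    """R = (2 + C) / 2, the fold change of a gene's copy relative to diploid."""
    if 2 + c < 0:
        raise ValueError(f"C = {c} implies negative ploidy")
    return (2.0 + c) / 2.0


def _slice(depth, start: int, end: int) -> np.ndarray:
    """Per-base depths over a 1-based inclusive interval."""
    if isinstance(depth, pd.Series):
        return depth.loc[start:end].to_numpy(dtype=float)
    arr = np.asarray(depth, dtype=float)
    return arr[start - 1 : end]


def corrected_background_depth(
    depth_by_chrom: dict,
    regions: RegionSet | pd.DataFrame,
    ploidy: PloidyTable | None,
    sample_id: str,
    chrom_group: str,
    correct_ploidy: bool = True,
) -> float:
    """Background read depth: pooled mean of ploidy-corrected base depths.

    Parameters
    ----------
    depth_by_chrom
        Mapping chromosome name -> per-base depth (array over the chromosome,
        or a Series indexed by 1-based position) for one sample.
    regions
        Background region set; only the kept intervals are used.
    ploidy
        GISTIC table; ``None`` (or ``correct_ploidy=False``) treats every
        gene as diploid, as done for adjacent/normal samples.
    chrom_group
        ``"chr1"`` (5S denominator: exons and introns of chromosome 1) or
        ``"chr13_14_15_21_22"`` (45S denominator: exons only).
    """
    if chrom_group == "chr1":
        chroms, features = set(CHROM_GROUP_5S), {"exon", "intron"}
    elif chrom_group == "chr13_14_15_21_22":
        chroms, features = set(CHROM_GROUP_45S), {"exon"}
    else:
        raise ValueError(f"unknown chromosome group {chrom_group!r}")

    kept = regions.kept if isinstance(regions, RegionSet) else [
        r for r in RegionSet.from_frame(regions).kept
    ]
    pieces = []
    for iv in kept:
        if iv.chrom not in chroms or iv.feature_class not in features:
            continue
        if iv.chrom not in depth_by_chrom:
            continue
        d = _slice(depth_by_chrom[iv.chrom], iv.start, iv.end)
        if d.size == 0:
            continue
        r = 1.0
        if correct_ploidy and ploidy is not None:
            r = ploidy_ratio(ploidy.c_value(iv.gene_id, sample_id))
        if r == 0.0:
            warnings.warn(
                f"gene {iv.gene_id} has R=0 in {sample_id}; bases excluded"
            )
            continue
        pieces.append(d / r)
    if not pieces:
        raise ValueError(f"no background bases for {sample_id} in {chrom_group}")
    return float(np.mean(np.concatenate(pieces)))


def window_cv_profile(
    depth_matrix: np.ndarray,
    window_len: int = 150,
    step: int = 1,
    per_site: bool = False,
) -> np.ndarray:
    """Coefficient of variation of window mean depth across samples.

    ``depth_matrix`` is samples x positions.  For each window starting
    position (1 bp steps by default) the per-sample mean depth over the
    window is computed; the CV is the across-sample standard deviation
    (n - 1 denominator) divided by the across-sample mean.  Windows with
    zero mean get NaN.

    ``per_site=True`` switches to the alternative reading: the window value
    is the mean over the window of per-site across-sample CVs.
    """
    mat = np.asarray(depth_matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 samples")
    n_samples, length = mat.shape
    if length < window_len:
        raise ValueError("component shorter than the window")
    if per_site:
        mu = mat.mean(axis=0)
        sd = mat.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            site_cv = np.where(mu > 0, sd / mu, np.nan)
        kernel = np.ones(window_len) / window_len
        prof = np.convolve(site_cv, kernel, mode="valid")
        return prof[::step]
    # window means per sample via cumulative sums
    cs = np.cumsum(np.concatenate([np.zeros((n_samples, 1)), mat], axis=1), axis=1)
    means = (cs[:, window_len:] - cs[:, :-window_len]) / window_len
    mu = means.mean(axis=0)
    sd = means.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mu > 0, sd / mu, np.nan)
    return cv[::step]


def select_component_window(
    cv_profile: np.ndarray, window_len: int = 150, step: int = 1
) -> tuple[int, int]:
    """Window (1-based inclusive) minimising the CV; ties broken leftmost."""
    cv = np.asarray(cv_profile, dtype=float)
    if np.all(np.isnan(cv)):
        raise ValueError("all window CVs are undefined")
    idx = int(np.nanargmin(cv))  # first occurrence = leftmost tie
    start = idx * step + 1
    return (start, start + window_len - 1)


def select_windows_from_cohort(
    depth_by_sample: dict,
    sample_ids,
    components=("18S", "28S"),
    window_len: int = 150,
    per_site: bool = True,
    normalize: bool = True,
) -> dict:
    """Select per-component windows from a cohort of depth profiles.

    The convention is to select on adjacent-normal samples of the largest
    cohort and reuse the windows everywhere; pass the appropriate
    ``sample_ids``.

    ``normalize=True`` (default) divides each sample's depth vector by its
    mean over the component first.  Inter-individual array copy number (up
    to 10-fold) is a common multiplier on every window of a sample and only
    obscures the quantity of interest — relative depth heterogeneity along
    the sequence — so it is removed before scoring.  ``per_site=True``
    (default) scores each window by the mean over its sites of per-site
    across-sample CVs ("lowest mean CV"); ``per_site=False`` scores by the
    CV of per-sample window means.
    """
    windows = {}
    for comp in components:
        mat = np.vstack(
            [np.asarray(depth_by_sample[s][comp], dtype=float) for s in sample_ids]
        )
        if normalize:
            means = mat.mean(axis=1, keepdims=True)
            means[means == 0] = 1.0
            mat = mat / means
        cv = window_cv_profile(mat, window_len=window_len, per_site=per_site)
        windows[comp] = select_component_window(cv, window_len=window_len)
    return windows


def component_cn(depth, brd: float, window: tuple[int, int] | None = None) -> float:
    """Mean per-base depth over the designated interval divided by BRD."""
    if not brd > 0:
        raise ValueError("BRD must be positive")
    arr = (
        _slice(depth, window[0], window[1])
        if window is not None
        else np.asarray(depth, dtype=float)
    )
    return float(np.mean(arr)) / brd


def estimate_45s(
    depth_18s, depth_58s, depth_28s, brd: float, windows: dict | None = None
) -> float:
    """45S array CN: depth pooled across 18S, 5.8S and 28S intervals over BRD.

    The configured windows are applied to 18S and 28S; 5.8S is always
    full-length.  Pooling the bases makes this the depth-weighted average of
    the component estimates, so it always lies between their min and max.
    """
    if not brd > 0:
        raise ValueError("BRD must be positive")
    windows = DEFAULT_WINDOWS if windows is None else windows
    parts = []
    for depth, comp in ((depth_18s, "18S"), (depth_58s, "5.8S"), (depth_28s, "28S")):
        w = windows.get(comp)
        parts.append(
            _slice(depth, w[0], w[1]) if w is not None
            else np.asarray(depth, dtype=float)
        )
    return float(np.mean(np.concatenate(parts))) / brd


def component_discordance(cn_18s: float, cn_58s: float, cn_28s: float) -> float:
    """Mean absolute pairwise difference among the three 45S component CNs."""
    a, b, c = float(cn_18s), float(cn_58s), float(cn_28s)
    return (abs(a - b) + abs(a - c) + abs(b - c)) / 3.0


def estimate_cn_table(
    depth_by_sample: dict,
    regions: RegionSet,
    ploidy: PloidyTable | None,
    metadata: pd.DataFrame,
    windows: dict | None = None,
    mode: str = "selected",
    correct_ploidy: bool = True,
) -> pd.DataFrame:
    """Per-sample CN estimates for all components, the 45S array and 5S/45S.

    Parameters
    ----------
    depth_by_sample
        sample_id -> {reference -> per-base depth}; references must include
        the rDNA components ("18S", "5.8S", "28S", "5S") and the background
        chromosomes.
    metadata
        One row per sample with at least ``sample_id``, ``patient_id``,
        ``tissue`` (tumor|adjacent), ``cancer_type``, ``plate_id``.
    mode
        "selected" uses the configured (or default) windows;
        "full_length" uses whole components for 18S and 28S;
        "fallback" uses 18S 901-1871 and full-length 28S.
    correct_ploidy
        Apply the R = (2+C)/2 correction to tumor background depth.
    """
    if mode == "selected":
        win = dict(DEFAULT_WINDOWS if windows is None else windows)
    elif mode == "full_length":
        win = {}
    elif mode == "fallback":
        win = {"18S": FALLBACK_18S_WINDOW}
    else:
        raise ValueError(f"unknown mode {mode!r}")

    stage = "ploidy_corrected" if correct_ploidy else "raw"
    rows = []
    for meta in metadata.itertuples(index=False):
        sid = meta.sample_id
        depth = depth_by_sample[sid]
        is_tumor = meta.tissue == "tumor"
        do_correct = correct_ploidy and is_tumor
        brd_chr1 = corrected_background_depth(
            depth, regions, ploidy, sid, "chr1", correct_ploidy=do_correct
        )
        brd_other = corrected_background_depth(
            depth, regions, ploidy, sid, "chr13_14_15_21_22",
            correct_ploidy=do_correct,
        )
        cn = {
            "CN_18S": component_cn(depth["18S"], brd_other, win.get("18S")),
            "CN_5_8S": component_cn(depth["5.8S"], brd_other),
            "CN_28S": component_cn(depth["28S"], brd_other, win.get("28S")),
            "CN_5S": component_cn(depth["5S"], brd_chr1),
        }
        cn["CN_45S"] = estimate_45s(
            depth["18S"], depth["5.8S"], depth["28S"], brd_other, windows=win
        )
        cn["ratio_5S_45S"] = cn["CN_5S"] / cn["CN_45S"]
        rows.append(
            dict(
                sample_id=sid,
                patient_id=meta.patient_id,
                tissue=meta.tissue,
                cancer_type=meta.cancer_type,
                plate_id=meta.plate_id,
                **cn,
                BRD_chr1=brd_chr1,
                BRD_other=brd_other,
                stage=stage,
            )
        )
    out = pd.DataFrame(rows)
    logger.info("estimated CN for %d samples (stage=%s, mode=%s)", len(out), stage, mode)
    return out
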