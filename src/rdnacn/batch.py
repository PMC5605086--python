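"""Plate (sequencing batch) effect detection and removal.

Depth-derived copy number estimates can carry systematic plate effects.
Detection exploits samples that were sequenced on more than one plate: for
every pair of plates sharing at least ``min_shared`` samples (identified by
patient and tissue), a paired two-sided Wilcoxon signed-rank test compares
the duplicate measurements.

Removal fits, separately for each cancer type, an ordinary least squares
model

    log CN ~ intercept + tissue + plate

with treatment coding (reference plate = the most populous one) and returns
CN with the fitted plate contribution removed, back-transformed to the
original CN scale.  Tissue and intercept effects are retained, so the
tumor/adjacent contrast survives correction.  A plate whose indicator is
perfectly confounded with tissue cannot be estimated; it is flagged and left
uncorrected with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import signed_rank_test

logger = logging.getLogger(__name__)

CN_COMPONENT_COLUMNS = ("CN_18S", "CN_5_8S", "CN_28S", "CN_45S", "CN_5S")


@dataclass
class BatchModelFit:
    """Per-cancer-type log-linear fit used for plate residualization."""

    cancer_type: str
    component: str
    reference_batch: str
    tissue_levels: list
    batch_levels: list
    coefficients: dict = field(default_factory=dict)
    confounded_batches: list = field(default_factory=list)


def detect_batch_effect(
    cn_table: pd.DataFrame,
    min_shared: int = 6,
    components=CN_COMPONENT_COLUMNS,
) -> pd.DataFrame:
    """Paired tests on samples measured on two plates.

    ``cn_table`` needs columns ``patient_id``, ``tissue``, ``plate_id`` and
    the CN component columns; a sample re-sequenced on two plates appears as
    two rows sharing (patient_id, tissue).  Returns one row per qualifying
    plate pair per component with the two-sided signed-rank p-value; pairs
    sharing fewer than ``min_shared`` samples are skipped.  No qualifying
    pair yields an empty table.
    """
    rows = []
    key = ["patient_id", "tissue"]
    plates = sorted(cn_table["plate_id"].unique())
    for i, a in enumerate(plates):
        for b in plates[i + 1 :]:
            ta = cn_table[cn_table["plate_id"] == a].set_index(key)
            tb = cn_table[cn_table["plate_id"] == b].set_index(key)
            shared = ta.index.intersection(tb.index)
            if len(shared) < min_shared:
                continue
            for comp in components:
                x = ta.loc[shared, comp].to_numpy(dtype=float)
                y = tb.loc[shared, comp].to_numpy(dtype=float)
                res = signed_rank_test(x, y, alternative="two-sided")
                rows.append(
                    dict(batch_a=a, batch_b=b, component=comp,
                         n_shared=len(shared), pvalue=res.pvalue,
                         method=res.method)
                )
    return pd.DataFrame(
        rows, columns=["batch_a", "batch_b", "component", "n_shared",
                       "pvalue", "method"],
    )


def _fit_one(
    log_cn: np.ndarray,
    tissue: pd.Series,
    plate: pd.Series,
) -> tuple[np.ndarray, dict, list, str, list, list]:
    """OLS of log CN on tissue + plate; returns the fitted plate contribution."""
    tissue_levels = sorted(tissue.unique())
    # reference plate: most populous, ties broken by name for determinism
    counts = plate.value_counts()
    ref = sorted(counts[counts == counts.max()].index)[0]
    batch_levels = [ref] + sorted(b for b in plate.unique() if b != ref)

    n = len(log_cn)
    cols = [np.ones(n)]
    names = ["intercept"]
    for t in tissue_levels[1:]:
        cols.append((tissue == t).to_numpy(dtype=float))
        names.append(f"tissue[{t}]")
    base_rank = np.linalg.matrix_rank(np.column_stack(cols))
    confounded = []
    batch_cols, batch_names = [], []
    for b in batch_levels[1:]:
        col = (plate == b).to_numpy(dtype=float)
        test = np.column_stack(cols + batch_cols + [col])
        if np.linalg.matrix_rank(test) == base_rank + len(batch_cols):
            confounded.append(b)
            warnings.warn(
                f"plate {b} is confounded with tissue; correction skipped for it"
            )
            continue
        batch_cols.append(col)
        batch_names.append(b)
    X = np.column_stack(cols + batch_cols)
    beta, *_ = np.linalg.lstsq(X, log_cn, rcond=None)
    coef = dict(zip(names + [f"plate[{b}]" for b in batch_names], beta))
    n_base = len(cols)
    batch_contrib = (
        np.column_stack(batch_cols) @ beta[n_base:] if batch_cols else np.zeros(n)
    )
    return batch_contrib, coef, confounded, ref, tissue_levels, batch_levels


def residualize_batch(
    cn_table: pd.DataFrame,
    components=CN_COMPONENT_COLUMNS + ("ratio_5S_45S",),
) -> tuple[pd.DataFrame, list]:
    """Remove plate effects from CN estimates, per cancer type and component.

    Returns the corrected table (``stage`` set to ``batch_corrected``; the
    5S/45S ratio is recomputed from the corrected components rather than
    residualized itself) and the list of :class:`BatchModelFit`.
    """
    out = cn_table.copy()
    fits: list[BatchModelFit] = []
    resid_components = [c for c in components if c != "ratio_5S_45S"]
    for ct, sub in cn_table.groupby("cancer_type"):
        idx = sub.index
        plates = sub["plate_id"].astype(str)
        if plates.nunique() <= 1:
            continue  # no batch term estimable; values pass through
        tissue = sub["tissue"].astype(str)
        for comp in resid_components:
            vals = sub[comp].to_numpy(dtype=float)
            if (vals <= 0).any():
                raise ValueError(f"non-positive CN in {comp}; cannot take logs")
            contrib, coef, confounded, ref, t_lvls, b_lvls = _fit_one(
                np.log(vals), tissue, plates
            )
            out.loc[idx, comp] = np.exp(np.log(vals) - contrib)
            fits.append(
                BatchModelFit(
                    cancer_type=ct, component=comp, reference_batch=ref,
                    tissue_levels=t_lvls, batch_levels=b_lvls,
                    coefficients=coef, confounded_batches=confounded,
                )
            )
    if "CN_5S" in out.columns and "CN_45S" in out.columns and \
            "ratio_5S_45S" in out.columns:
        out["ratio_5S_45S"] = out["CN_5S"] / out["CN_45S"]
    if "stage" in out.columns:
        out["stage"] = "batch_corrected"
    logger.info("batch-residualized %d cancer-type x component fits", len(fits))
    return out, fits
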