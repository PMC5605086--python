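"""Readers and writers for the pipeline's tabular interchange formats.

Dialects:

* depth tables: the ``samtools depth`` dialect — headerless TSV of
  reference name, 1-based position, depth;
* ploidy tables: the GISTIC ``all_data_by_genes.txt`` dialect — header
  ``Gene Symbol``, ``Locus ID``, ``Cytoband``, then one column per tumor
  sample holding the gene value C (ploidy = 2 + C);
* mutations: minimal MAF-like TSV (Hugo_Symbol, Variant_Classification,
  Change, Tumor_Sample_Barcode);
* sample metadata, CN estimate tables, region sets, truth tables and count
  matrices: plain TSV with headers; all coordinates 1-based inclusive.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .estimate import PloidyTable
from .regions import RegionSet
from .simulate import CohortTruth, SyntheticCohort

FLOAT_FMT = "%.10g"


# --- depth (samtools dialect) ----------------------------------------------

def write_depth_tsv(depth_by_ref: dict, path) -> None:
    """Write one sample's per-base depths, headerless ref/pos/depth."""
    frames = []
    for ref, depth in depth_by_ref.items():
        if isinstance(depth, pd.Series):
            pos = depth.index.to_numpy()
            vals = depth.to_numpy()
        else:
            vals = np.asarray(depth)
            pos = np.arange(1, len(vals) + 1)
        frames.append(pd.DataFrame({"ref": ref, "pos": pos, "depth": vals}))
    out = pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=["ref", "pos", "depth"])
    out["depth"] = out["depth"].astype(np.int64)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_depth_tsv(path) -> dict:
    """Read a samtools-depth TSV into {reference -> Series indexed by position}."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["ref", "pos", "depth"],
                     dtype={"ref": str, "pos": np.int64, "depth": float})
    return {
        ref: sub.set_index("pos")["depth"].sort_index()
        for ref, sub in df.groupby("ref")
    }


# --- GISTIC ploidy dialect --------------------------------------------------

def write_gistic(ploidy: PloidyTable, path) -> None:
    vals = ploidy.values
    info = ploidy.gene_info
    out = pd.DataFrame({"Gene Symbol": vals.index})
    if info is not None:
        out["Locus ID"] = info["Locus ID"].to_numpy()
        out["Cytoband"] = info["Cytoband"].to_numpy()
    else:
        out["Locus ID"] = np.arange(len(vals.index)) + 1
        out["Cytoband"] = ""
    for s in vals.columns:
        out[s] = vals[s].to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_gistic(path) -> PloidyTable:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["Gene Symbol", "Locus ID", "Cytoband"]
    for c in meta_cols:
        if c not in df.columns:
            raise ValueError(f"not a GISTIC all_data_by_genes table: missing {c!r}")
    df = df.set_index("Gene Symbol")
    df.index.name = "gene_id"
    info = df[["Locus ID", "Cytoband"]]
    values = df.drop(columns=["Locus ID", "Cytoband"]).astype(float)
    return PloidyTable(values, gene_info=info)


# --- simple tables ----------------------------------------------------------

def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_regions(regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based inclusive\n")
        regions.to_frame().to_csv(fh, sep="\t", index=False)


def read_regions(path) -> RegionSet:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"removed_reason": str}, keep_default_na=False)
    return RegionSet.from_frame(df)


def write_counts(counts: pd.DataFrame, gene_lengths: pd.Series, path) -> None:
    out = counts.copy()
    out.insert(0, "gene_length", gene_lengths.reindex(counts.index).astype(int))
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_counts(path) -> tuple[pd.DataFrame, pd.Series]:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    lengths = df.pop("gene_length")
    return df.astype(np.int64), lengths


def write_gene_set(name: str, genes, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{name}\n")
        for g in genes:
            fh.write(f"{g}\n")


def read_gene_set(path) -> tuple[str, list]:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return lines[0], lines[1:]


# --- cohort bundles ---------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write a simulated cohort as the file formats the pipeline consumes.

    Per-site rate truth matrices are not serialized (they are large and only
    consumed in-memory by recovery tests); the sample-level truth table is.
    """
    outdir = Path(outdir)
    (outdir / "depth").mkdir(parents=True, exist_ok=True)
    for sid, depth in cohort.depth_by_sample.items():
        write_depth_tsv(depth, outdir / "depth" / f"{sid}.depth.tsv")
    write_gistic(cohort.ploidy, outdir / "ploidy.tsv")
    write_table(cohort.metadata, outdir / "metadata.tsv")
    write_table(cohort.mutations, outdir / "mutations.maf.tsv")
    write_regions(cohort.regions, outdir / "regions.tsv")
    write_table(cohort.truth.samples, outdir / "truth.tsv")


def read_cohort_inputs(indir) -> dict:
    """Read back the pipeline inputs written by :func:`write_cohort`."""
    indir = Path(indir)
    metadata = read_table(indir / "metadata.tsv")
    depth_by_sample = {
        sid: read_depth_tsv(indir / "depth" / f"{sid}.depth.tsv")
        for sid in metadata["sample_id"]
    }
    out = dict(
        metadata=metadata,
        depth_by_sample=depth_by_sample,
        ploidy=read_gistic(indir / "ploidy.tsv"),
        mutations=read_table(indir / "mutations.maf.tsv"),
        regions=read_regions(indir / "regions.tsv"),
    )
    truth_path = indir / "truth.tsv"
    if truth_path.exists():
        out["truth"] = CohortTruth(samples=read_table(truth_path), site_rates={})
    return out


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
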