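"""End-to-end orchestration: simulate -> estimate -> correct -> associate -> PRI.

Every threshold a stage uses is carried in :class:`RunConfig`, so a run is
fully described by one configuration object (serializable to YAML) and a
seed.  Identical configurations produce byte-identical outputs.

Outputs written to the run directory:

* the simulated input bundle (depth tables, ploidy, metadata, MAF, regions,
  truth);
* ``cn_estimates.tsv`` with one row per sample per stage
  (raw / ploidy_corrected / batch_corrected);
* ``batch_checks.tsv`` (plate-pair paired tests before and after correction);
* ``associations.tsv``, ``paired_changes.tsv``, ``direction_tests.tsv``;
* ``pri.tsv`` and ``expression_changes.tsv``;
* ``summary.json`` (machine-readable) and ``report.txt`` (human-readable);
* ``run.log`` with versions, seed and per-test method choices.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import associate, batch, expression, io
from .estimate import PloidyTable, estimate_cn_table, select_windows_from_cohort
from .simulate import (
    DRIVER_GENE,
    PROXY_GENES_1Q42,
    ConfigurationError,
    SimulationConfig,
    simulate_cohort,
    simulate_expression,
)

logger = logging.getLogger(__name__)

EXIT_OK, EXIT_CONFIG, EXIT_DATA = 0, 2, 3


@dataclass
class RunConfig:
    """One place for every input path, threshold and mode of a run."""

    outdir: str = "rdnacn_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    simulate_inputs: bool = True
    input_dir: str | None = None  # used when simulate_inputs is False

    window_mode: str = "selected"  # selected | fallback | full_length
    window_len: int = 150
    select_windows_on: str = "adjacent"  # tissue used for CV selection

    scna_threshold: float = 0.1
    mutation_min_patients: int = 10
    recurrence_min: int = 5
    batch_min_shared: int = 6
    expression_min_reads: int = 10
    expression_min_pairs: int = 5
    significance: float = 0.05
    paired_significance: float = 0.01
    diploid_window: tuple = (1.98, 2.02)

    def __post_init__(self):
        for name in ("scna_threshold", "mutation_min_patients", "recurrence_min",
                     "batch_min_shared", "expression_min_reads",
                     "expression_min_pairs", "significance",
                     "paired_significance", "window_len"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.window_mode not in ("selected", "fallback", "full_length"):
            raise ConfigurationError(f"unknown window mode {self.window_mode!r}")
        if not self.simulate_inputs and not self.input_dir:
            raise ConfigurationError(
                "input_dir is required when simulate_inputs is false"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        if "diploid_window" in raw:
            raw["diploid_window"] = tuple(raw["diploid_window"])
        return cls(simulation=sim, **raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["diploid_window"] = list(d["diploid_window"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _setup_logging(outdir: Path) -> None:
    root = logging.getLogger("rdnacn")
    root.setLevel(logging.INFO)
    root.handlers = [h for h in root.handlers
                     if not isinstance(h, logging.FileHandler)]
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler) and h.stream is sys.stderr
               for h in root.handlers):
        sh = logging.StreamHandler(sys.stderr)
        sh.setLevel(logging.WARNING)
        root.addHandler(sh)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the machine-readable summary dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    logger.info("rdnacn %s, numpy %s, seed %d", __version__,
                np.__version__, config.simulation.seed)
    config.to_yaml(outdir / "config.yaml")
    summary: dict = {"version": __version__, "seed": config.simulation.seed,
                     "stages": {}}

    # --- stage: inputs ----------------------------------------------------
    try:
        if config.simulate_inputs:
            cohort = simulate_cohort(config.simulation)
            io.write_cohort(cohort, outdir)
            inputs = dict(
                depth_by_sample=cohort.depth_by_sample,
                ploidy=cohort.ploidy, metadata=cohort.metadata,
                mutations=cohort.mutations, regions=cohort.regions,
                truth=cohort.truth,
            )
        else:
            inputs = io.read_cohort_inputs(config.input_dir)
            cohort = None
    except FileNotFoundError as e:
        raise StageError("inputs", str(e)) from e
    metadata = inputs["metadata"]
    if metadata.empty:
        raise StageError("inputs", "cohort is empty (no samples)")
    summary["stages"]["inputs"] = dict(
        n_samples=int(len(metadata)),
        n_patients=int(metadata["patient_id"].nunique()),
    )

    # --- stage: estimate-cn -----------------------------------------------
    ploidy: PloidyTable = inputs["ploidy"]
    if metadata["tissue"].eq("tumor").any() and not ploidy.samples \
            and config.window_mode != "full_length":
        raise StageError("estimate-cn", "missing ploidy table for tumor samples")
    windows = None
    if config.window_mode == "selected":
        sel_samples = metadata.loc[
            metadata["tissue"] == config.select_windows_on, "sample_id"
        ]
        windows = select_windows_from_cohort(
            inputs["depth_by_sample"], sel_samples,
            window_len=config.window_len,
        )
        summary["stages"]["windows"] = {k: list(v) for k, v in windows.items()}
    cn_corrected = estimate_cn_table(
        inputs["depth_by_sample"], inputs["regions"], ploidy, metadata,
        windows=windows, mode=config.window_mode, correct_ploidy=True,
    )
    cn_raw = estimate_cn_table(
        inputs["depth_by_sample"], inputs["regions"], ploidy, metadata,
        windows=windows, mode=config.window_mode, correct_ploidy=False,
    )

    # --- stage: correct-batch ----------------------------------------------
    checks_before = batch.detect_batch_effect(
        cn_corrected, min_shared=config.batch_min_shared
    )
    cn_final, fits = batch.residualize_batch(cn_corrected)
    checks_after = batch.detect_batch_effect(
        cn_final, min_shared=config.batch_min_shared
    )
    checks_before["stage"] = "ploidy_corrected"
    checks_after["stage"] = "batch_corrected"
    io.write_table(pd.concat([checks_before, checks_after], ignore_index=True),
                   outdir / "batch_checks.tsv")
    cn_all = pd.concat([cn_raw, cn_corrected, cn_final], ignore_index=True)
    io.write_table(cn_all, outdir / "cn_estimates.tsv")
    summary["stages"]["estimate_cn"] = dict(
        n_rows=int(len(cn_all)),
        n_batch_fits=len(fits),
        confounded_batches=sorted(
            {b for f in fits for b in f.confounded_batches}
        ),
    )

    # --- stage: associate ---------------------------------------------------
    paired = pd.concat(
        [
            associate.paired_change_test(cn_final, "CN_5S", "gain"),
            associate.paired_change_test(cn_final, "CN_45S", "loss"),
        ],
        ignore_index=True,
    )
    io.write_table(paired, outdir / "paired_changes.tsv")

    assoc_frames = []
    scna = associate.scna_scan(
        cn_final, ploidy.values, threshold=config.scna_threshold
    )
    if not scna.empty:
        assoc_frames.append(scna.assign(feature_type="scna"))
    muts = associate.mutation_scan(
        cn_final, inputs["mutations"],
        min_patients=config.mutation_min_patients,
    )
    if not muts.empty:
        assoc_frames.append(muts.assign(feature_type="mutation"))
    assoc = (pd.concat(assoc_frames, ignore_index=True)
             if assoc_frames else pd.DataFrame())
    io.write_table(assoc, outdir / "associations.tsv")

    direction_rows = []
    if not assoc.empty:
        sig = assoc[assoc["pvalue"] < config.significance]
        for (ftype, trait), sub in sig.groupby(["feature_type", "trait"]):
            n = len(sub)
            if n == 0:
                continue
            expected = 1 if trait in ("CN_5S", "ratio_5S_45S") else -1
            k = int((sub["direction"] == expected).sum())
            res = associate.direction_binomial(k, n)
            direction_rows.append(
                dict(feature_type=ftype, trait=trait, k_same_direction=k,
                     n_significant=n, pvalue=res.pvalue)
            )
    direction = pd.DataFrame(
        direction_rows, columns=["feature_type", "trait", "k_same_direction",
                                 "n_significant", "pvalue"],
    )
    io.write_table(direction, outdir / "direction_tests.tsv")

    tumors = cn_final[cn_final["tissue"] == "tumor"]
    extra: dict = {}
    if tumors["cancer_type"].nunique() >= 2 and not inputs["mutations"].empty:
        pres = associate.nonsilent_presence(
            inputs["mutations"], list(tumors["sample_id"]), gene=DRIVER_GENE
        )
        if 0 < pres.sum() < len(pres):
            res = associate.pancancer_model(
                np.log(tumors["ratio_5S_45S"].to_numpy()),
                pres.to_numpy(), tumors["cancer_type"],
                feature=DRIVER_GENE, trait_name="log_ratio_5S_45S",
            )
            extra["pancancer_driver"] = res.to_dict()
    proxies = [g for g in PROXY_GENES_1Q42 if g in ploidy.values.index]
    if proxies and len(tumors) >= 5:
        proxy_ploidy = (
            2.0 + ploidy.values.loc[proxies].mean(axis=0)
        ).reindex(tumors["sample_id"]).fillna(2.0)
        rho = associate.locus_ploidy_vs_cn(
            proxy_ploidy.to_numpy(), tumors["CN_5S"].to_numpy()
        )
        extra["locus_1q42"] = dict(rho=rho.statistic, pvalue=rho.pvalue, n=rho.n)
        by_patient = pd.Series(
            proxy_ploidy.to_numpy(), index=tumors["patient_id"].to_numpy()
        )
        dip = associate.diploid_subset_test(
            cn_final, by_patient, window=tuple(config.diploid_window)
        )
        if dip is not None:
            extra["diploid_subset"] = dip
    summary["stages"]["associate"] = dict(
        n_associations=int(len(assoc)), n_direction_tests=int(len(direction)),
        **extra,
    )

    # --- stage: pri ---------------------------------------------------------
    if cohort is not None:
        counts, lengths, gene_sets = simulate_expression(
            config.simulation, cohort.truth
        )
        io.write_counts(counts, lengths, outdir / "expression_counts.tsv")
        kept = expression.filter_expressed(
            counts, min_reads=config.expression_min_reads
        )
        counts_f = counts.loc[kept]
        factors = expression.tmm_normalize(counts_f)
        eff = expression.effective_library_sizes(counts_f, factors)
        logcpm = expression.cpm(counts_f, eff)
        pri_table = pd.DataFrame(
            {name: expression.pri(logcpm, genes, set_name=name)
             for name, genes in gene_sets.items()}
        )
        pri_table.index.name = "sample_id"
        io.write_table(pri_table.reset_index(), outdir / "pri.tsv")
        changes = pd.concat(
            [
                expression.paired_expression_change(
                    pri_table[name], metadata,
                    min_pairs=config.expression_min_pairs,
                ).assign(gene_set=name)
                for name in gene_sets
            ],
            ignore_index=True,
        )
        io.write_table(changes, outdir / "expression_changes.tsv")
        pri_fc = expression.paired_fold_change(pri_table["YW_PRI"], metadata)
        ratio_fc = expression.paired_fold_change(
            cn_final.set_index("sample_id")["ratio_5S_45S"], metadata
        )
        shared = pri_fc.index.intersection(ratio_fc.index)
        rho = expression.pri_cn_correlation(
            pri_fc.loc[shared, "fc"], ratio_fc.loc[shared, "fc"]
        )
        summary["stages"]["pri"] = dict(
            n_genes_retained=len(kept),
            pri_ratio_fc_spearman=rho.statistic,
            pri_ratio_fc_pvalue=rho.pvalue,
            n_fc_patients=rho.n,
        )

    # --- report -------------------------------------------------------------
    report = write_report(
        paired, direction, assoc,
        cn_final=cn_corrected,  # estimator accuracy, before plate residualization
        truth=inputs.get("truth"),
        significance=config.paired_significance,
    )
    (outdir / "report.txt").write_text(report)
    io.write_json(summary, outdir / "summary.json")
    logger.info("pipeline complete: %s", outdir)
    return summary


class StageError(RuntimeError):
    """A stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def write_report(
    paired: pd.DataFrame,
    direction: pd.DataFrame,
    assoc: pd.DataFrame,
    cn_final: pd.DataFrame | None = None,
    truth=None,
    significance: float = 0.01,
) -> str:
    """Human-readable run summary: calls, direction tests, truth recovery."""
    lines = ["rDNA copy number pipeline report", "=" * 34, ""]
    lines.append(f"Per-cancer-type rDNA change calls (p < {significance:g}):")
    if paired.empty:
        lines.append("  no informative tumor-adjacent pairs")
    else:
        for row in paired.itertuples(index=False):
            call = row.direction if row.pvalue < significance else "no call"
            lines.append(
                f"  {row.cancer_type:>10} {row.component:>8}: {call:>7} "
                f"(n={row.n_pairs}, median FC={row.median_fc:.3f}, "
                f"p={row.pvalue:.3g})"
            )
    lines.append("")
    lines.append("Direction-of-effect tests on significant associations:")
    if direction.empty:
        lines.append("  no features tested")
    else:
        for row in direction.itertuples(index=False):
            lines.append(
                f"  {row.feature_type:>9} x {row.trait:<14}: "
                f"{row.k_same_direction}/{row.n_significant} expected direction "
                f"(binomial p={row.pvalue:.3g})"
            )
    lines.append("")
    if assoc is not None and assoc.empty:
        lines.append("Associations: no features tested")
        lines.append("")
    if truth is not None and cn_final is not None and \
            not getattr(truth, "samples", pd.DataFrame()).empty:
        merged = cn_final.merge(
            truth.samples[["sample_id", "true_cn_5s", "true_cn_45s"]],
            on="sample_id",
        )
        from scipy.stats import spearmanr

        rho5 = spearmanr(merged["CN_5S"], merged["true_cn_5s"]).statistic
        rho45 = spearmanr(merged["CN_45S"], merged["true_cn_45s"]).statistic
        err5 = np.median(
            np.abs(merged["CN_5S"] / merged["true_cn_5s"] - 1)
        )
        err45 = np.median(
            np.abs(merged["CN_45S"] / merged["true_cn_45s"] - 1)
        )
        lines.append("Synthetic-truth recovery diagnostics (ploidy-corrected stage):")
        lines.append(f"  5S : Spearman {rho5:.4f}, median |rel err| {err5:.3%}")
        lines.append(f"  45S: Spearman {rho45:.4f}, median |rel err| {err45:.3%}")
        lines.append("")
    return "\n".join(lines) + "\n"
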