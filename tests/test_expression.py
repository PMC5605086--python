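"""Expression filtering, TMM normalization, RPKM, PRI and its correlations."""

import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from rdnacn import (
    SimulationConfig,
    filter_expressed,
    multivariate_ratio_model,
    paired_expression_change,
    pri,
    pri_cn_correlation,
    rpkm,
    simulate_cohort,
    simulate_expression,
    tmm_normalize,
)
from rdnacn.expression import cpm, effective_library_sizes, paired_fold_change


def _counts(arr, samples=None):
    arr = np.asarray(arr)
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(
        arr, index=pd.Index([f"g{i}" for i in range(arr.shape[0])],
                            name="gene_id"),
        columns=samples,
    )


class TestFilterExpressed:
    def test_strict_majority_kept(self):
        counts = _counts([[12, 11, 10, 0, 0]])  # 3 of 5 samples >= 10
        assert filter_expressed(counts) == ["g0"]

    def test_exact_half_dropped(self):
        counts = _counts([[12, 11, 0, 0]])  # 2 of 4 is not a strict majority
        assert filter_expressed(counts) == []

    def test_all_zero_gene_dropped(self):
        counts = _counts([[0, 0, 0], [50, 60, 70]])
        assert filter_expressed(counts) == ["g1"]


class TestTMM:
    def test_identical_libraries_give_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(100, 50)
        counts = _counts(np.column_stack([col, col, col]))
        np.testing.assert_allclose(tmm_normalize(counts), 1.0)

    def test_uniform_scaling_cancels_in_m_values(self):
        """A 2x library has all M-values 0 after library-size division."""
        rng = np.random.default_rng(1)
        col = rng.poisson(200, 80)
        counts = _counts(np.column_stack([col, 2 * col]))
        np.testing.assert_allclose(tmm_normalize(counts), 1.0, rtol=1e-12)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(2)
        counts = _counts(rng.poisson(100, size=(200, 6)))
        f = tmm_normalize(counts)
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0)

    def test_hand_computed_trimmed_mean(self):
        """With trimming disabled, the factor is the precision-weighted mean
        of per-gene log2 ratios, computable by hand on a tiny matrix."""
        counts = _counts(np.array([[100, 200], [100, 100], [100, 80],
                                   [100, 120], [100, 90]]))
        f = tmm_normalize(counts, trim_m=0.0, trim_a=0.0, reference="s0")
        yk = counts["s1"].to_numpy(float)
        yr = counts["s0"].to_numpy(float)
        nk, nr = yk.sum(), yr.sum()
        m = np.log2((yk / nk) / (yr / nr))
        w = (nk - yk) / (nk * yk) + (nr - yr) / (nr * yr)
        raw = 2 ** (np.sum(w * m) / np.sum(w))
        expected = pd.Series({"s0": 1.0, "s1": raw})
        expected /= np.exp(np.log(expected).mean())
        np.testing.assert_allclose(f, expected.reindex(f.index), rtol=1e-12)

    def test_zero_total_library_rejected(self):
        counts = _counts([[0, 5], [0, 5]])
        with pytest.raises(ValueError):
            tmm_normalize(counts)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript unavailable")
    def test_agrees_with_edger(self):
        """Cross-check against edgeR::calcNormFactors on a small matrix."""
        rng = np.random.default_rng(3)
        base = rng.lognormal(4, 1, 150)
        mats = []
        for j in range(4):
            lib = [1.0, 0.6, 1.4, 1.0][j]
            comp = np.ones(150)
            if j == 3:
                comp[:10] = 8.0  # composition outliers that trimming handles
            mats.append(rng.poisson(base * lib * comp))
        counts = _counts(np.column_stack(mats))
        # pin the same reference column on both sides; reference choice is a
        # convention and TMM factors are only comparable for a shared one
        ours = tmm_normalize(counts, reference="s0")
        with tempfile.TemporaryDirectory() as td:
            cpath = Path(td) / "counts.tsv"
            counts.to_csv(cpath, sep="\t")
            script = Path(td) / "tmm.R"
            script.write_text(
                'x <- read.delim("%s", row.names=1)\n'
                "suppressMessages(library(edgeR))\n"
                "f <- calcNormFactors(as.matrix(x), method='TMM', refColumn=1)\n"
                "cat(f, sep='\\n')\n" % cpath
            )
            out = subprocess.run(["Rscript", str(script)],
                                 capture_output=True, text=True, check=True)
        theirs = np.array([float(v) for v in out.stdout.split()])
        np.testing.assert_allclose(ours.to_numpy(), theirs, rtol=0.02)


class TestRpkm:
    def test_formula(self):
        counts = _counts([[100]])
        lengths = pd.Series({"g0": 1000})
        lib = pd.Series({"s0": 1e6})
        assert rpkm(counts, lengths, lib).iloc[0, 0] == pytest.approx(100.0)

    def test_library_size_proportionality(self):
        counts = _counts([[100, 100]])
        lengths = pd.Series({"g0": 1000})
        lib = pd.Series({"s0": 1e6, "s1": 2e6})
        vals = rpkm(counts, lengths, lib)
        assert vals.iloc[0, 0] == pytest.approx(2 * vals.iloc[0, 1])

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            rpkm(_counts([[1]]), pd.Series({"g0": 0}), pd.Series({"s0": 1.0}))


class TestPri:
    def test_median_of_set(self):
        mat = _counts([[1.0], [5.0], [100.0]])
        assert pri(mat, ["g0", "g1", "g2"]).iloc[0] == 5.0

    def test_invariant_to_non_set_genes(self):
        mat = _counts([[1.0], [5.0], [100.0], [7.0]])
        a = pri(mat, ["g0", "g1", "g2"])
        b = pri(mat.drop(index="g3"), ["g0", "g1", "g2"])
        assert a.equals(b)

    def test_monotone_transform_of_set_genes_moves_median(self):
        mat = _counts([[1.0], [5.0], [100.0]])
        doubled = mat * 2
        assert pri(doubled, ["g0", "g1", "g2"]).iloc[0] == 10.0

    def test_empty_intersection_errors(self):
        with pytest.raises(ValueError):
            pri(_counts([[1.0]]), ["missing"])


class TestPairedExpressionChange:
    def _metadata(self, n):
        rows = []
        for i in range(n):
            for tissue, suffix in (("tumor", "T"), ("adjacent", "A")):
                rows.append(dict(sample_id=f"p{i}-{suffix}",
                                 patient_id=f"p{i}", tissue=tissue,
                                 cancer_type="CT1", plate_id="A"))
        return pd.DataFrame(rows)

    def test_below_min_pairs_skipped(self):
        meta = self._metadata(4)
        values = pd.Series(1.0, index=meta["sample_id"])
        assert paired_expression_change(values, meta, min_pairs=5).empty

    def test_no_change_gives_p_one(self):
        meta = self._metadata(6)
        values = pd.Series(1.0, index=meta["sample_id"])
        res = paired_expression_change(values, meta, min_pairs=5)
        assert res["pvalue"].iloc[0] == 1.0
        assert res["median_fc"].iloc[0] == 1.0

    def test_upregulation_power(self):
        """1.5x tumor up-regulation with 10 pairs and low noise is caught at
        p < 0.01 in >= 90% of replicates."""
        meta = self._metadata(10)
        hits = 0
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(800 + rep)
            vals = {}
            for i in range(10):
                base = rng.lognormal(2, 0.3)
                vals[f"p{i}-A"] = base * rng.lognormal(0, 0.05)
                vals[f"p{i}-T"] = base * 1.5 * rng.lognormal(0, 0.05)
            res = paired_expression_change(pd.Series(vals), meta, min_pairs=5)
            if (res["pvalue"] < 0.01).all():
                hits += 1
        assert hits / reps >= 0.9


class TestPriCnIntegration:
    def test_monotone_toy_rho_one(self):
        res = pri_cn_correlation(np.arange(10.0), np.arange(10.0) ** 2)
        assert res.statistic == pytest.approx(1.0)

    def test_coupling_increases_fc_correlation(self):
        """Spearman(PRI FC, 5S/45S ratio FC) grows with the generative
        proliferation coupling."""
        means = []
        for coupling in (0.0, 0.3, 0.6):
            rhos = []
            for rep in range(4):
                cfg = SimulationConfig(
                    n_patients=40, proliferation_coupling=coupling,
                    seed=900 + rep, site_het_sd=0.0,
                )
                c = simulate_cohort(cfg)
                counts, _, sets = simulate_expression(cfg, c.truth)
                kept = filter_expressed(counts)
                counts = counts.loc[kept]
                f = tmm_normalize(counts)
                mat = cpm(counts, effective_library_sizes(counts, f))
                p = pri(mat, sets["YW_PRI"], "YW_PRI")
                pri_fc = paired_fold_change(p, c.metadata)
                truth = c.truth.samples.set_index("sample_id")
                ratio = truth["true_cn_5s"] / truth["true_cn_45s"]
                ratio_fc = paired_fold_change(ratio, c.metadata)
                shared = pri_fc.index.intersection(ratio_fc.index)
                rhos.append(
                    pri_cn_correlation(pri_fc.loc[shared, "fc"],
                                       ratio_fc.loc[shared, "fc"]).statistic
                )
            means.append(np.mean(rhos))
        assert means[0] < means[1] < means[2]
        assert abs(means[0]) < 0.25

    def test_pri_tracks_tumor_signal_when_coupled(self):
        cfg = SimulationConfig(n_patients=50, proliferation_coupling=0.6,
                               seed=911, site_het_sd=0.0)
        c = simulate_cohort(cfg)
        counts, _, sets = simulate_expression(cfg, c.truth)
        mat = cpm(counts, counts.sum(axis=0).astype(float))
        p = pri(mat, sets["YW_PRI"], "YW_PRI")
        truth = c.truth.samples.set_index("sample_id")
        ratio = truth["true_cn_5s"] / truth["true_cn_45s"]
        p_fc = paired_fold_change(p, c.metadata)
        r_fc = paired_fold_change(ratio, c.metadata)
        shared = p_fc.index.intersection(r_fc.index)
        res = pri_cn_correlation(p_fc.loc[shared, "fc"], r_fc.loc[shared, "fc"])
        assert res.statistic > 0 and res.pvalue < 0.05


class TestMultivariate:
    def test_noise_free_exact_recovery(self):
        rng = np.random.default_rng(5)
        n = 60
        tp53 = rng.integers(0, 2, n).astype(float)
        pri_v = rng.normal(0, 1, n)
        ratio = 1.0 + 0.1 * tp53 + 0.2 * pri_v
        res = multivariate_ratio_model(ratio, tp53, pri_v)
        coefs = res.set_index("term")["coefficient"]
        assert coefs["tp53"] == pytest.approx(0.1)
        assert coefs["pri"] == pytest.approx(0.2)

    def test_permuted_pri_ci_covers_zero(self):
        rng = np.random.default_rng(6)
        n = 80
        tp53 = rng.integers(0, 2, n).astype(float)
        pri_v = rng.normal(0, 1, n)
        ratio = 1.0 + 0.3 * tp53 + rng.normal(0, 0.1, n)
        res = multivariate_ratio_model(ratio, tp53, rng.permutation(pri_v))
        row = res.set_index("term").loc["pri"]
        assert row["ci_low"] < 0 < row["ci_high"]

    def test_collinear_regressors_flagged(self):
        x = np.array([0, 1, 0, 1, 0, 1], dtype=float)
        res = multivariate_ratio_model(np.arange(6.0), x, x * 2 + 0.001)
        assert "collinear" in res["flag"].iloc[0]
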