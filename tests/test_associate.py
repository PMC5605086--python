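"""Context association statistics: cCNV, paired changes, SCNA/mutation tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from rdnacn import (
    SimulationConfig,
    ccnv_correlations,
    diploid_subset_test,
    direction_binomial,
    estimate_cn_table,
    locus_ploidy_vs_cn,
    mutation_association,
    paired_change_test,
    pancancer_model,
    per_mutation_model,
    scna_association,
    scna_calls,
    simulate_cohort,
)
from rdnacn.associate import nonsilent_presence, paired_samples
from rdnacn.simulate import DRIVER_GENE


def _cn_rows(values, tissue="tumor", cancer_type="CT1", plate="A",
             start=0, suffix="T"):
    rows = []
    for i, v in enumerate(values, start=start):
        rows.append(dict(sample_id=f"p{i}-{suffix}", patient_id=f"p{i}",
                         tissue=tissue, cancer_type=cancer_type, plate_id=plate,
                         CN_18S=v, CN_5_8S=v, CN_28S=v, CN_45S=v, CN_5S=v,
                         ratio_5S_45S=1.0))
    return rows


class TestCcnv:
    def test_identical_components_r_one(self):
        cn = pd.DataFrame(_cn_rows([1.0, 2.0, 3.0, 4.0]))
        res = ccnv_correlations(cn)
        assert np.allclose(res["r"], 1.0)

    def test_anticorrelated_toy(self):
        cn = pd.DataFrame(_cn_rows([1.0, 2.0, 3.0]))
        cn["CN_5S"] = [3.0, 2.0, 1.0]
        res = ccnv_correlations(cn)
        row = res[(res.component_a == "CN_28S") & (res.component_b == "CN_5S")]
        assert row["r"].iloc[0] == pytest.approx(-1.0)

    def test_constant_component_reported_missing(self):
        cn = pd.DataFrame(_cn_rows([1.0, 2.0, 3.0]))
        cn["CN_5S"] = 2.0
        res = ccnv_correlations(cn)
        assert res.loc[res.component_b == "CN_5S", "r"].isna().all()

    def test_simulated_rho_recovered(self):
        """5S-45S correlation of adjacent tissue tracks the generative rho."""
        cfg = SimulationConfig(n_patients=100, ccnv_rho=0.6, seed=17,
                               site_het_sd=0.0, n_cancer_types=1)
        c = simulate_cohort(cfg)
        cn = estimate_cn_table(c.depth_by_sample, c.regions, c.ploidy,
                               c.metadata)
        adj = cn[cn["tissue"] == "adjacent"]
        r = pearsonr(np.log(adj["CN_5S"]), np.log(adj["CN_45S"])).statistic
        # 95% sampling band of r at rho=0.6, n=100 (Fisher z +- 1.96/sqrt(97))
        z = np.arctanh(r)
        assert abs(z - np.arctanh(0.6)) < 1.96 / np.sqrt(97)


class TestPairedChange:
    def _paired_table(self, tumor_vals, adj_vals, plate_t=None):
        rows = _cn_rows(tumor_vals, tissue="tumor", suffix="T")
        rows += _cn_rows(adj_vals, tissue="adjacent", suffix="A")
        df = pd.DataFrame(rows)
        if plate_t:
            df.loc[df["tissue"] == "tumor", "plate_id"] = plate_t
        return df

    def test_six_pairs_all_loss_exact_p(self):
        cn = self._paired_table([1, 2, 3, 4, 5, 6], [2, 3, 4, 5, 6, 7])
        res = paired_change_test(cn, "CN_45S", "loss")
        assert res["pvalue"].iloc[0] == pytest.approx(1 / 64)

    def test_zero_difference_pairs_dropped(self):
        cn = self._paired_table([1, 2, 3, 5.0], [2, 3, 4, 5.0])
        res = paired_change_test(cn, "CN_45S", "loss")
        # the tied pair is dropped; 3 informative pairs -> p = 1/8
        assert res["pvalue"].iloc[0] == pytest.approx(1 / 8)

    def test_same_plate_filter_removes_cross_plate_pairs(self):
        cn = self._paired_table([1, 2, 3], [2, 3, 4], plate_t="B")
        assert paired_change_test(cn, "CN_45S", "loss").empty
        res = paired_change_test(cn, "CN_45S", "loss", same_plate_only=False)
        assert len(res) == 1

    def test_direction_argument_is_explicit(self):
        cn = self._paired_table([2, 3, 4], [1, 2, 3])
        gain = paired_change_test(cn, "CN_5S", "gain")["pvalue"].iloc[0]
        loss = paired_change_test(cn, "CN_5S", "loss")["pvalue"].iloc[0]
        assert gain < 0.2 < loss
        with pytest.raises(ValueError):
            paired_change_test(cn, "CN_5S", "up")

    def test_power_under_simulated_loss(self):
        """45S loss at fold 0.8 with 30 pairs is detected at p<0.01 in >=90%
        of replicates."""
        hits = 0
        reps = 10
        for rep in range(reps):
            cfg = SimulationConfig(n_patients=30, seed=300 + rep,
                                   site_het_sd=0.0, n_cancer_types=1,
                                   fraction_cross_plate=0.0)
            c = simulate_cohort(cfg)
            cn = estimate_cn_table(c.depth_by_sample, c.regions, c.ploidy,
                                   c.metadata)
            res = paired_change_test(cn, "CN_45S", "loss")
            if (res["pvalue"] < 0.01).all():
                hits += 1
        assert hits / reps >= 0.9


class TestScna:
    def test_calls_thresholds(self):
        vals = pd.DataFrame(
            {"s1": [0.15, -0.15, 0.05], "s2": [0.0, -2.0, 0.5]},
            index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
        )
        calls = scna_calls(vals, threshold=0.1)
        key = set(zip(calls.gene_id, calls.sample_id, calls.kind))
        assert ("gA", "s1", "amp") in key
        assert ("gB", "s1", "del") in key
        assert ("gC", "s1", "amp") not in key  # 0.05 below threshold
        assert ("gC", "s2", "amp") in key
        ext = calls.set_index(["gene_id", "sample_id", "kind"])["extent"]
        assert ext[("gB", "s2", "del")] == 2.0  # 2 - ploidy = -C

    def test_coefficient_is_group_mean_difference(self):
        res = scna_association(np.array([10, 12, 20, 22.0]),
                               np.array([0, 0, 1, 1]), feature="f", trait="t")
        assert res.statistic == pytest.approx(10.0)
        assert res.direction == 1

    def test_null_identical_groups(self):
        res = scna_association(np.array([5, 5, 5, 5.0]),
                               np.array([0, 0, 1, 1]))
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_constant_presence_returns_none(self):
        assert scna_association(np.ones(4), np.ones(4)) is None


class TestMutation:
    def test_exact_rank_sum_extreme(self):
        """(1,2,3) vs (4,5,6): 2 of 20 arrangements are as extreme."""
        res = mutation_association(
            np.array([1, 2, 3, 4, 5, 6.0]),
            np.array([1, 1, 1, 0, 0, 0]), min_patients=3,
        )
        assert res.pvalue == pytest.approx(0.1)
        assert res.direction == -1

    def test_recurrence_filter(self):
        cn = np.arange(20.0)
        presence = np.zeros(20, dtype=int)
        presence[:9] = 1
        assert mutation_association(cn, presence, min_patients=10) is None
        assert mutation_association(cn, presence, min_patients=9) is not None

    def test_nonsilent_filter(self):
        maf = pd.DataFrame(
            {
                "Hugo_Symbol": ["g1", "g1"],
                "Variant_Classification": ["Silent", "Missense_Mutation"],
                "Change": ["c1", "c2"],
                "Tumor_Sample_Barcode": ["s1", "s2"],
            }
        )
        pres = nonsilent_presence(maf, ["s1", "s2"], gene="g1")
        assert pres.tolist() == [0, 1]


class TestDirectionBinomial:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (19, 20, 4.005e-5),
            (49, 50, 9.059e-14),
            (32, 39, 7.025e-05),
            (71, 81, 1.799e-12),
            (26, 38, 0.034),
        ],
    )
    def test_reported_direction_tests(self, k, n, expected):
        """Directional consistency counts reproduce the reported p-values."""
        assert direction_binomial(k, n).pvalue == pytest.approx(expected,
                                                                rel=2e-2)

    def test_symmetric_center(self):
        assert direction_binomial(10, 20).pvalue == 1.0


class TestPancancer:
    def _balanced(self, effect=5.0, n=40):
        ct = np.array(["CT1", "CT2"] * (n // 2))
        base = np.where(ct == "CT1", 10.0, 30.0)
        presence = np.tile([0, 0, 1, 1], n // 4)
        return base + effect * presence, presence, ct

    def test_noise_free_effect_recovered_exactly(self):
        trait, presence, ct = self._balanced(effect=5.0)
        res = pancancer_model(trait, presence, ct)
        assert res.statistic == pytest.approx(5.0)
        assert res.direction == 1

    def test_null_effect(self):
        trait, presence, ct = self._balanced(effect=0.0)
        res = pancancer_model(trait, presence, ct)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)

    def test_confounded_presence_flagged(self):
        ct = np.array(["CT1"] * 10 + ["CT2"] * 10)
        presence = (ct == "CT1").astype(float)
        res = pancancer_model(np.arange(20.0), presence, ct)
        assert res.flag == "confounded_with_cancer_type"

    def test_single_cancer_type_rejected(self):
        with pytest.raises(ValueError):
            pancancer_model(np.arange(4.0), [0, 1, 0, 1], ["CT1"] * 4)

    def test_per_mutation_recurrence_gate(self):
        trait, presence, ct = self._balanced()
        few = np.zeros_like(presence)
        few[:4] = 1
        assert per_mutation_model(trait, few, ct, "m1") is None
        res = per_mutation_model(trait, presence, ct, "m1")
        assert res is not None and res.feature == "m1"

    def test_driver_effect_inside_ci(self):
        """The injected driver shift of the tumor log(5S/45S) change is
        recovered within the pan-cancer model's 95% CI.

        The trait is the paired tumor-minus-adjacent log-ratio change, whose
        generative driver effect is exactly 2 x driver_effect; the tumor
        ratio itself carries the adjacent baseline variance on top.
        """
        cfg = SimulationConfig(n_patients=150, driver_effect=0.2, seed=23,
                               locus_1q42_gain_rate=0.0, site_het_sd=0.0)
        c = simulate_cohort(cfg)
        cn = estimate_cn_table(c.depth_by_sample, c.regions, c.ploidy,
                               c.metadata)
        pivot = cn.pivot(index="patient_id", columns="tissue",
                         values="ratio_5S_45S")
        delta = np.log(pivot["tumor"] / pivot["adjacent"])
        tum = cn[cn["tissue"] == "tumor"].set_index("patient_id")
        pres = nonsilent_presence(
            c.mutations, list(tum.loc[delta.index, "sample_id"]),
            gene=DRIVER_GENE,
        )
        res = pancancer_model(
            delta.to_numpy(), pres.to_numpy(),
            tum.loc[delta.index, "cancer_type"],
        )
        lo, hi = res.conf_int
        assert res.statistic > 0
        assert lo < 2 * 0.2 < hi


class TestLocus1q42:
    def test_monotone_toy(self):
        res = locus_ploidy_vs_cn(np.arange(5.0) + 2, np.arange(5.0) * 10)
        assert res.statistic == pytest.approx(1.0)

    def test_permuted_pairing_null_calibration(self):
        """Breaking the pairing leaves |rho| inside the 95% null band in
        roughly 95% of permutations."""
        rng = np.random.default_rng(4)
        x = np.arange(50.0)
        inside = sum(
            abs(locus_ploidy_vs_cn(x, rng.permutation(x)).statistic)
            < 1.96 / np.sqrt(49)
            for _ in range(60)
        )
        assert inside / 60 >= 0.85

    def test_segmental_gain_drives_positive_rho(self):
        cfg = SimulationConfig(n_patients=100, locus_1q42_gain_rate=0.3,
                               seed=31, site_het_sd=0.0)
        c = simulate_cohort(cfg)
        cn = estimate_cn_table(c.depth_by_sample, c.regions, c.ploidy,
                               c.metadata)
        tum = cn[cn["tissue"] == "tumor"].set_index("sample_id")
        proxy = 2.0 + c.ploidy.values.loc[["RNF187", "RHOU"]].mean(axis=0)
        proxy = proxy.reindex(tum.index)
        res = locus_ploidy_vs_cn(proxy.to_numpy(), tum["CN_5S"].to_numpy())
        assert res.statistic > 0 and res.pvalue < 0.05


class TestDiploidSubset:
    def _table(self, tumor_vals, adj_vals):
        rows = _cn_rows(tumor_vals, tissue="tumor", suffix="T")
        rows += _cn_rows(adj_vals, tissue="adjacent", suffix="A")
        return pd.DataFrame(rows)

    def test_all_gain_exact_p(self):
        cn = self._table([2, 3, 4, 5, 6, 7], [1, 2, 3, 4, 5, 6])
        ploidy = pd.Series(2.0, index=[f"p{i}" for i in range(6)])
        res = diploid_subset_test(cn, ploidy)
        assert res["pvalue"] == pytest.approx(2.0**-6)
        assert res["n_patients"] == 6

    def test_out_of_window_patient_excluded(self):
        cn = self._table([2, 3, 4], [1, 2, 3])
        ploidy = pd.Series([2.0, 2.05, 2.0], index=["p0", "p1", "p2"])
        res = diploid_subset_test(cn, ploidy)
        assert res["n_patients"] == 2

    def test_empty_subset_returns_none(self):
        cn = self._table([2.0], [1.0])
        ploidy = pd.Series([3.0], index=["p0"])
        assert diploid_subset_test(cn, ploidy) is None

    def test_array_level_gain_detected_without_segmental_change(self):
        """5S array expansion stays detectable when 1q42 ploidy is diploid."""
        hits = 0
        reps = 10
        for rep in range(reps):
            cfg = SimulationConfig(n_patients=20, seed=500 + rep,
                                   locus_1q42_gain_rate=0.0,
                                   site_het_sd=0.0, n_cancer_types=1,
                                   fraction_cross_plate=0.0)
            c = simulate_cohort(cfg)
            cn = estimate_cn_table(c.depth_by_sample, c.regions, c.ploidy,
                                   c.metadata)
            ploidy = pd.Series(
                2.0, index=c.metadata.loc[c.metadata.tissue == "tumor",
                                          "patient_id"].to_numpy()
            )
            res = diploid_subset_test(cn, ploidy)
            if res is not None and res["pvalue"] < 0.05:
                hits += 1
        assert hits / reps >= 0.9


def test_paired_samples_plate_filter(default_cohort):
    c = default_cohort
    cn = estimate_cn_table(c.depth_by_sample, c.regions, c.ploidy, c.metadata)
    strict = paired_samples(cn, same_plate_only=True)
    loose = paired_samples(cn, same_plate_only=False)
    assert len(strict) <= len(loose)
    same = strict["plate_id_tumor"].astype(str) == \
        strict["plate_id_adjacent"].astype(str)
    assert same.all()
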