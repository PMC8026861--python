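"""Effect sizes, heterogeneity, model selection and pooled inference."""

import json
import subprocess

import numpy as np
import pandas as pd
import pytest

from sigmeta.meta import (
    DatasetEffect,
    MetaResult,
    cochran_q,
    collapse_probes,
    dataset_effect,
    dataset_effects,
    dl_tau2,
    forest_data,
    i_squared,
    mega_analysis,
    normalize_log2,
    pool,
    qq_check,
    results_table,
    significant_genes,
    volcano_table,
)
from sigmeta.synthdata import SimulationConfig, gen_expression

from conftest import make_dataset
from oracles import cochran_q_oracle, dl_tau2_oracle, pool_oracle


def effects_from(thetas, variances, gene="G"):
    return [
        DatasetEffect(f"d{i}", gene, float(t), float(v), 10, 10)
        for i, (t, v) in enumerate(zip(thetas, variances))
    ]


def random_effects(rng, k=None):
    k = k or int(rng.integers(2, 8))
    thetas = rng.normal(0, 2, k)
    variances = rng.uniform(0.01, 2.0, k)
    return thetas, variances


class TestNormalizeLog2:
    def test_log_scale_matrix_left_unchanged(self):
        ds = make_dataset([[14.2, 3.0]], [[5.0, 6.0]])
        out = normalize_log2(ds)
        assert not out.log_transformed
        assert out.matrix.equals(ds.matrix)

    def test_linear_scale_is_log2_transformed(self):
        ds = make_dataset([[1023.0, 0.0]], [[7.0, 3.0]])
        out = normalize_log2(ds)
        assert out.log_transformed
        assert out.matrix.iloc[0, 0] == pytest.approx(10.0)
        assert out.matrix.iloc[0, 1] == 0.0

    def test_all_zero_matrix_stays_zero(self):
        ds = make_dataset([[0.0, 0.0]], [[0.0, 0.0]])
        assert (normalize_log2(ds).matrix == 0).all().all()

    def test_negative_values_on_linear_branch_error(self):
        ds = make_dataset([[100.0, -1.0]], [[2.0, 3.0]])
        with pytest.raises(ValueError, match="negative"):
            normalize_log2(ds)


class TestCollapseProbes:
    def test_one_probe_per_gene_is_identity(self):
        mat = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["p1", "p2"], columns=["s1", "s2"])
        out = collapse_probes(mat, {"p1": "A", "p2": "B"})
        assert out.loc["A"].tolist() == [1.0, 2.0]
        assert out.loc["B"].tolist() == [3.0, 4.0]

    def test_median_over_probes(self):
        mat = pd.DataFrame([[1.0], [2.0], [9.0]], index=["p1", "p2", "p3"], columns=["s1"])
        out = collapse_probes(mat, {p: "A" for p in mat.index})
        assert out.loc["A", "s1"] == 2.0

    def test_empty_mapping_gives_empty_matrix(self):
        mat = pd.DataFrame([[1.0]], index=["p1"], columns=["s1"])
        assert collapse_probes(mat, {}).empty

    def test_matches_brute_force_groupby_median(self, rng):
        probes = [f"p{i}" for i in range(40)]
        mat = pd.DataFrame(
            rng.normal(size=(40, 5)), index=probes,
            columns=[f"s{j}" for j in range(5)],
        )
        mapping = {p: f"G{rng.integers(0, 8)}" for p in probes[:30]}  # 10 unmapped
        out = collapse_probes(mat, mapping)
        for gene in set(mapping.values()):
            members = [p for p, g in mapping.items() if g == gene]
            expected = np.median(mat.loc[members].to_numpy(), axis=0)
            np.testing.assert_allclose(out.loc[gene].to_numpy(), expected)


class TestDatasetEffect:
    def test_hand_computed_lfc_and_welch_variance(self):
        ds = make_dataset([[4.0, 6.0]], [[1.0, 3.0]], genes=["G1"])
        eff = dataset_effect(ds, "G1")
        assert eff.lfc == pytest.approx(3.0)
        assert eff.var == pytest.approx(2.0)  # s2=2 in each group of n=2

    def test_identical_groups_give_zero_lfc(self):
        ds = make_dataset([[5.0, 5.0, 5.0]], [[5.0, 5.0]], genes=["G1"])
        assert dataset_effect(ds, "G1").lfc == 0.0

    def test_translation_equivariance_of_lfc(self, rng):
        case = rng.normal(8, 1, (3, 6))
        ctrl = rng.normal(8, 1, (3, 7))
        base = dataset_effects(make_dataset(case, ctrl))
        shifted = dataset_effects(make_dataset(case + 1.7, ctrl))
        np.testing.assert_allclose(shifted["lfc"], base["lfc"] + 1.7, atol=1e-12)
        np.testing.assert_allclose(shifted["var"], base["var"], atol=1e-12)

    def test_absent_gene_contributes_nothing(self):
        ds = make_dataset([[1.0, 2.0]], [[3.0, 4.0]], genes=["G1"])
        assert dataset_effect(ds, "NOPE") is None

    def test_single_sample_group_is_an_error(self):
        ds = make_dataset([[1.0]], [[3.0, 4.0]], genes=["G1"])
        with pytest.raises(ValueError, match=">= 2 samples"):
            dataset_effect(ds, "G1")


class TestHeterogeneity:
    def test_single_study_q_zero(self):
        assert cochran_q(effects_from([1.0], [0.5])) == (0.0, 0)

    def test_equal_effects_q_zero(self):
        q, df = cochran_q(effects_from([2.0, 2.0, 2.0], [0.5, 1.0, 0.2]))
        assert q == pytest.approx(0.0, abs=1e-12) and df == 2

    @pytest.mark.parametrize(
        "Q, df, expected",
        [(3.0, 4, 0.0), (10.0, 4, 60.0), (5.0, 5, 0.0), (0.0, 0, 0.0)],
    )
    def test_isq_truncation_rule(self, Q, df, expected):
        assert i_squared(Q, df) == pytest.approx(expected)

    def test_tau2_truncated_at_zero_when_homogeneous(self):
        assert dl_tau2(effects_from([1.0, 1.0], [0.5, 0.5])) == 0.0

    def test_tau2_requires_two_studies(self):
        with pytest.raises(ValueError):
            dl_tau2(effects_from([1.0], [0.5]))

    def test_q_and_tau2_match_direct_formula_oracles(self, rng):
        for _ in range(200):
            thetas, variances = random_effects(rng)
            q, df = cochran_q(effects_from(thetas, variances))
            assert df == len(thetas) - 1
            assert q == pytest.approx(cochran_q_oracle(thetas, variances), rel=1e-10)
            assert dl_tau2(effects_from(thetas, variances)) == pytest.approx(
                dl_tau2_oracle(thetas, variances), rel=1e-10, abs=1e-12
            )


class TestPool:
    def test_equal_variance_fixed_model_is_arithmetic_mean(self):
        res = pool(effects_from([1.0, 3.0], [4.0, 4.0]))
        # Q = 0.5 <= df=1 -> fixed
        assert res.model == "fixed"
        assert res.pooled_lfc == pytest.approx(2.0)

    def test_zero_tau2_random_equals_fixed_weights(self):
        effects = effects_from([1.0, 1.1, 0.9], [0.5, 0.4, 0.6])
        res = pool(effects)
        assert res.tau2 == 0.0
        w = 1.0 / np.array([0.5, 0.4, 0.6])
        assert res.pooled_lfc == pytest.approx(
            float(np.sum(w * [1.0, 1.1, 0.9]) / w.sum())
        )

    def test_matches_inverse_variance_oracle_to_twelve_digits(self, rng):
        for _ in range(300):
            thetas, variances = random_effects(rng)
            res = pool(effects_from(thetas, variances))
            pooled, se, model = pool_oracle(thetas, variances)
            assert res.pooled_lfc == pytest.approx(pooled, rel=1e-12, abs=1e-14)
            assert res.se == pytest.approx(se, rel=1e-12)
            assert res.model == model

    def test_model_selection_consistency(self, rng):
        for _ in range(300):
            thetas, variances = random_effects(rng)
            res = pool(effects_from(thetas, variances))
            assert (res.model == "fixed") == (res.Q <= res.df) == (res.isq == 0.0)
            assert res.tau2 >= 0.0 and 0.0 < res.p <= 1.0

    def test_non_positive_variance_names_the_dataset(self):
        effects = effects_from([1.0, 2.0], [0.5, 0.0])
        with pytest.raises(ValueError, match="d1"):
            pool(effects)

    def test_agrees_with_metafor(self, tmp_path):
        """Cross-check both model branches against R metafor (DL / FE)."""
        het_t, het_v = [0.2, 1.5, -0.4, 2.1], [0.05, 0.1, 0.2, 0.08]
        hom_t, hom_v = [1.0, 1.1, 0.95], [0.5, 0.6, 0.55]
        script = tmp_path / "check.R"
        script.write_text(
            "suppressMessages(library(metafor))\n"
            f"r <- rma(yi=c({','.join(map(str, het_t))}), vi=c({','.join(map(str, het_v))}),"
            " method='DL', test='z')\n"
            f"f <- rma(yi=c({','.join(map(str, hom_t))}), vi=c({','.join(map(str, hom_v))}),"
            " method='FE')\n"
            "cat(sprintf('%.12g %.12g %.12g %.12g %.12g %.12g %.12g\\n',"
            " r$beta, r$se, r$tau2, r$QE, r$pval, f$beta, f$se))\n"
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, check=True
        )
        rb, rse, rtau2, rq, rp, fb, fse = map(float, out.stdout.split())
        het = pool(effects_from(het_t, het_v))
        assert het.model == "random"
        assert het.pooled_lfc == pytest.approx(rb, rel=1e-8)
        assert het.se == pytest.approx(rse, rel=1e-8)
        assert het.tau2 == pytest.approx(rtau2, rel=1e-8)
        assert het.Q == pytest.approx(rq, rel=1e-8)
        assert het.p == pytest.approx(rp, rel=1e-6)
        hom = pool(effects_from(hom_t, hom_v))
        assert hom.model == "fixed"
        assert hom.pooled_lfc == pytest.approx(fb, rel=1e-8)
        assert hom.se == pytest.approx(fse, rel=1e-8)


class TestMegaAnalysis:
    def make_two_datasets(self, rng):
        cfg = SimulationConfig(n_genes=10, seed=int(rng.integers(0, 2**31 - 1)))
        datasets, _ = gen_expression(cfg)
        return datasets

    def test_gene_in_single_dataset_is_unanalyzable(self, rng):
        datasets = self.make_two_datasets(rng)[:2]
        extra = datasets[0].matrix.iloc[[0]].rename(index={"G0010": "LONELY"})
        extra.index = ["LONELY"]
        datasets[0].matrix = pd.concat([datasets[0].matrix, extra])
        results, unanalyzable = mega_analysis(datasets)
        assert unanalyzable == ["LONELY"]
        assert all(r.k >= 2 for r in results)

    def test_results_sorted_by_p(self, rng):
        results, _ = mega_analysis(self.make_two_datasets(rng))
        ps = [r.p for r in results]
        assert ps == sorted(ps)

    def test_empty_gene_set(self, rng):
        assert mega_analysis(self.make_two_datasets(rng), genes=set()) == ([], [])

    def test_requires_two_datasets(self, rng):
        with pytest.raises(ValueError):
            mega_analysis(self.make_two_datasets(rng)[:1])

    def test_case_shift_moves_every_pooled_lfc_by_that_constant(self):
        cfg = SimulationConfig(n_genes=8, seed=5)
        datasets, _ = gen_expression(cfg)
        base, _ = mega_analysis(datasets)
        shifted_datasets, _ = gen_expression(cfg)
        for ds in shifted_datasets:
            ds.matrix.loc[:, ds.groups == "case"] += 2.5
        shifted, _ = mega_analysis(shifted_datasets)
        base_by_gene = {r.gene: r for r in base}
        for r in shifted:
            assert r.pooled_lfc == pytest.approx(
                base_by_gene[r.gene].pooled_lfc + 2.5, abs=1e-9
            )

    def test_results_table_has_q_bh_column(self, rng):
        results, _ = mega_analysis(self.make_two_datasets(rng))
        table = results_table(results)
        assert list(table.columns) == [
            "gene", "k", "pooled_lfc", "se", "p", "q_bh", "Q", "df", "isq", "tau2", "model",
        ]
        assert (table["q_bh"] >= table["p"] - 1e-15).all()


class TestSignificance:
    def make(self, lfc, p):
        return MetaResult("G", 7, lfc, 1.0, p, 1.0, 6, 0.0, 0.0, "fixed")

    @pytest.mark.parametrize(
        "lfc, p, called",
        [
            (-11.52, 0.016, True),   # the published pooled call
            (0.5, 0.001, False),     # fails the LFC bound
            (1.0, 0.001, False),     # strict: LFC must exceed 1
            (1.01, 0.05, False),     # strict: p must be below 0.05
            (-1.2, 0.049, True),
        ],
    )
    def test_rule_boundaries(self, lfc, p, called):
        assert (significant_genes([self.make(lfc, p)]) != []) is called

    def test_volcano_table(self):
        vt = volcano_table([self.make(2.0, 0.01)])
        assert vt.loc[0, "neg_log10_p"] == pytest.approx(2.0)


class TestForest:
    def test_weights_sum_to_100_and_ci_halfwidth(self, rng):
        thetas, variances = random_effects(rng, k=5)
        effects = effects_from(thetas, variances)
        table = forest_data("G", effects, pool(effects))
        studies = table[table["row"] == "study"]
        assert studies["weight_pct"].sum() == pytest.approx(100.0, abs=1e-9)
        half = (studies["ci_high"] - studies["ci_low"]) / 2
        np.testing.assert_allclose(half, 1.96 * np.sqrt(variances))

    def test_dominant_precision_gets_the_largest_weight(self):
        effects = effects_from([1.0, 1.0, 1.0], [0.01, 1.0, 1.0])
        table = forest_data("G", effects, pool(effects))
        studies = table[table["row"] == "study"]
        assert studies["weight_pct"].idxmax() == 0


class TestQQ:
    def null_dataset(self, n_genes=5000, seed=11):
        cfg = SimulationConfig(
            dataset_designs=(("qq", 20, 20),), n_genes=n_genes, seed=seed
        )
        return gen_expression(cfg)[0][0]

    def test_null_statistics_close_to_standard_normal(self):
        report = qq_check(self.null_dataset())
        assert report.deviation < 0.03
        assert not report.systematic_bias
        assert len(report.statistics) == len(report.theoretical_quantiles)
        assert 0.0 <= report.deviation <= 1.0

    def test_constant_matrix_is_degenerate(self):
        ds = make_dataset([[1.0, 1.0], [1.0, 1.0]], [[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="degenerate"):
            qq_check(ds)

    def test_single_outlier_gene_does_not_trip_the_bias_flag(self):
        ds = self.null_dataset(seed=12)
        ds.matrix.loc["G0001", ds.groups == "case"] += 50.0
        report = qq_check(ds)
        assert not report.systematic_bias
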