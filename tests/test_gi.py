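import numpy as np
import pandas as pd
import pytest

from psgkit import synthetic
from psgkit.errors import DataError
from psgkit.gi import (
    CONTROL_GENE,
    DOUBLE,
    SINGLE_ARRAY,
    SINGLE_QUERY,
    AnchorFit,
    anchor_regression,
    design_library,
    gene_gi_score,
    gi_table,
    guide_single_lfc,
    position_bias,
    score_gi,
    single_ko_fitness,
    zscore_residuals,
)


class TestDesignLibrary:
    def test_array_gene_gets_15_single_ko_constructs(self):
        lib = design_library(["Q1"], ["A1"])
        singles = lib.constructs[lib.constructs["construct_class"] == SINGLE_ARRAY]
        assert len(singles[singles["gene_B"] == "A1"]) == 15

    def test_query_gene_gets_15_per_orientation(self):
        lib = design_library(["Q1"], ["A1"])
        sq = lib.constructs[lib.constructs["construct_class"] == SINGLE_QUERY]
        assert len(sq[sq["gene_A"] == "Q1"]) == 15
        assert len(sq[sq["gene_B"] == "Q1"]) == 15

    def test_pair_gets_9_double_constructs(self):
        lib = design_library(["Q1"], ["A1"])
        doubles = lib.constructs[lib.constructs["construct_class"] == DOUBLE]
        assert len(doubles) == 9

    def test_8x100_design_yields_800_pairs(self):
        lib = design_library(
            [f"Q{i}" for i in range(8)], [f"A{i}" for i in range(100)]
        )
        doubles = lib.constructs[lib.constructs["construct_class"] == DOUBLE]
        assert doubles.groupby(["gene_A", "gene_B"]).ngroups == 800
        assert len(doubles) == 800 * 9

    def test_empty_gene_list_rejected(self):
        with pytest.raises(DataError):
            design_library([], ["A1"])


def _flat_lfc(lib, value=0.0):
    return pd.Series(value, index=lib.constructs.index, dtype=float)


class TestSingleKOFitness:
    def _lib(self):
        return design_library(["G1"], ["A1"], n_crRNA=3, n_controls=2)

    def test_arithmetic_example(self):
        # G1 singles at -2; controls alternate +/-0.5 (mean 0, pop s.d. 0.5)
        lib = self._lib()
        lfc = _flat_lfc(lib)
        cons = lib.constructs
        is_single_g1 = (cons["construct_class"] == SINGLE_QUERY)
        lfc[cons.index[is_single_g1]] = -2.0
        ctrl_idx = cons.index[cons["construct_class"] == "control_control"]
        lfc[ctrl_idx] = [0.5, -0.5, 0.5, -0.5][: len(ctrl_idx)]
        fits = {s.gene: s for s in single_ko_fitness(lfc, lib)}
        assert fits["G1"].mean_lfc == pytest.approx(-2.0)
        assert fits["G1"].z == pytest.approx(-4.0)

    def test_gene_matching_controls_scores_near_zero(self):
        lib = self._lib()
        rng = np.random.default_rng(1)
        lfc = pd.Series(rng.normal(0, 0.3, len(lib.constructs)),
                        index=lib.constructs.index)
        fits = {s.gene: s for s in single_ko_fitness(lfc, lib)}
        assert abs(fits["G1"].z) < 2.0

    def test_planted_positive_fitness_detected(self):
        lib = self._lib()
        rng = np.random.default_rng(2)
        lfc = pd.Series(rng.normal(0, 0.3, len(lib.constructs)),
                        index=lib.constructs.index)
        cons = lib.constructs
        g1 = cons.index[cons["construct_class"] == SINGLE_QUERY]
        lfc[g1] = rng.normal(1.5, 0.3, len(g1))
        fits = {s.gene: s for s in single_ko_fitness(lfc, lib)}
        assert fits["G1"].z > 2.0

    def test_no_controls_rejected(self):
        lib = self._lib()
        lib2 = type(lib)(
            lib.constructs[lib.constructs["construct_class"] != "control_control"],
            lib.query_genes, lib.array_genes, 3, 2,
        )
        with pytest.raises(DataError):
            single_ko_fitness(_flat_lfc(lib2), lib2)


class TestPositionBias:
    def test_identical_positions_zero_difference(self):
        lib = design_library(["Q1", "Q2"], ["A1"])
        lfc = _flat_lfc(lib, -1.0)
        report = position_bias(lfc, lib)
        assert report["mean_signed_difference"] == 0.0

    def test_planted_b_position_bias_detected(self):
        lib = design_library(["Q1", "Q2", "Q3"], ["A1"])
        rng = np.random.default_rng(3)
        lfc = pd.Series(rng.normal(0, 0.05, len(lib.constructs)),
                        index=lib.constructs.index)
        sq = lib.constructs[lib.constructs["construct_class"] == SINGLE_QUERY]
        in_b = sq.index[sq["gene_A"] == CONTROL_GENE]
        lfc[in_b] += 0.5
        report = position_bias(lfc, lib)
        assert report["mean_signed_difference"] == pytest.approx(-0.5, abs=0.05)

    def test_neutral_simulation_uncorrupted(self):
        lfc, lib, _ = synthetic.simulate_gi(synthetic.GIConfig(
            n_query=8, n_array=30, noise_sigma=0.1, seed=4))
        report = position_bias(lfc, lib)
        assert abs(report["mean_signed_difference"]) < 0.1
        assert report["pearson_r"] > 0.95


class TestAnchorRegression:
    def test_exact_line_zero_residuals(self):
        x = np.arange(5, dtype=float)
        pairs = [(f"p{i}", xi, 2 * xi + 1) for i, xi in enumerate(x)]
        fit = anchor_regression("a", pairs)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)

    def test_hand_ols_three_points(self):
        pairs = [("p0", 0.0, 0.0), ("p1", 1.0, 1.0), ("p2", 2.0, 4.0)]
        fit = anchor_regression("a", pairs)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(-1 / 3)
        np.testing.assert_allclose(fit.residuals, [1 / 3, -2 / 3, 1 / 3], atol=1e-12)

    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(5)
        pairs = [(f"p{i}", x, 0.5 * x + rng.normal()) for i, x in
                 enumerate(rng.normal(size=20))]
        fit = anchor_regression("a", pairs)
        assert fit.residuals.sum() == pytest.approx(0.0, abs=1e-9)

    def test_constant_x_is_degenerate(self):
        pairs = [("p0", 1.0, 0.0), ("p1", 1.0, 1.0), ("p2", 1.0, 2.0)]
        fit = anchor_regression("a", pairs)
        assert fit.degenerate

    def test_too_few_partners_rejected(self):
        with pytest.raises(DataError):
            anchor_regression("a", [("p0", 0.0, 0.0), ("p1", 1.0, 1.0)])


class TestZScoreResiduals:
    def _fit(self, residuals):
        r = np.asarray(residuals, dtype=float)
        return AnchorFit("a", 0.0, 0.0, [f"p{i}" for i in range(len(r))], r)

    def test_symmetric_triple(self):
        z = zscore_residuals(self._fit([-1.0, 0.0, 1.0]))
        np.testing.assert_allclose(z.to_numpy(), [-1.224744871, 0.0, 1.224744871],
                                   atol=1e-9)

    def test_equal_residuals_all_zero(self):
        z = zscore_residuals(self._fit([0.3, 0.3, 0.3]))
        np.testing.assert_array_equal(z.to_numpy(), 0.0)

    def test_standardized_output(self):
        rng = np.random.default_rng(6)
        z = zscore_residuals(self._fit(rng.normal(size=50))).to_numpy()
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)


class TestGeneGIScore:
    def _uniform_z_frame(self, lib):
        # every double construct carries residual z = 1 in both orientations
        doubles = lib.constructs[lib.constructs["construct_class"] == DOUBLE]
        rows = []
        for _, row in doubles.iterrows():
            rows.append({"anchor_guide": row["guide_A"],
                         "partner_guide": row["guide_B"], "z": 1.0})
            rows.append({"anchor_guide": row["guide_B"],
                         "partner_guide": row["guide_A"], "z": 1.0})
        return pd.DataFrame(rows)

    def test_uniform_unit_z_arithmetic(self):
        lib = design_library(["Q1"], ["A1"])
        score = gene_gi_score(self._uniform_z_frame(lib), lib, ("Q1", "A1"))
        assert score.score_I_anchor == pytest.approx(3.0)
        assert score.score_J_anchor == pytest.approx(3.0)
        assert score.combined_z == pytest.approx(6 / np.sqrt(2))

    def test_all_zero_z_gives_zero(self):
        lib = design_library(["Q1"], ["A1"])
        zf = self._uniform_z_frame(lib)
        zf["z"] = 0.0
        assert gene_gi_score(zf, lib, ("Q1", "A1")).combined_z == 0.0

    def test_symmetric_under_pair_swap(self):
        lib = design_library(["Q1"], ["A1"])
        zf = self._uniform_z_frame(lib)
        rng = np.random.default_rng(7)
        zf["z"] = rng.normal(size=len(zf))
        s1 = gene_gi_score(zf, lib, ("Q1", "A1"))
        s2 = gene_gi_score(zf, lib, ("A1", "Q1"))
        assert s1.combined_z == pytest.approx(s2.combined_z)

    def test_missing_orientation_flagged(self):
        lib = design_library(["Q1"], ["A1"])
        zf = self._uniform_z_frame(lib)
        zf = zf[zf["anchor_guide"].str.startswith("Q1")]
        score = gene_gi_score(zf, lib, ("Q1", "A1"))
        assert "single orientation only" in score.flags
        assert score.combined_z == pytest.approx(3.0)


class TestScoreGIPipeline:
    def test_additive_noiseless_data_scores_zero(self):
        lfc, lib, _ = synthetic.simulate_gi(synthetic.GIConfig(
            n_query=4, n_array=20, noise_sigma=0.0, interaction_fraction=0.0,
            guide_effect_sd=0.2, seed=8))
        scores = score_gi(lfc, lib)
        assert scores
        for s in scores:
            assert s.combined_z == pytest.approx(0.0, abs=1e-8)

    def test_scale_invariance(self):
        lfc, lib, _ = synthetic.simulate_gi(synthetic.GIConfig(
            n_query=4, n_array=15, noise_sigma=0.2, seed=9))
        t1 = gi_table(score_gi(lfc, lib)).set_index(["gene_I", "gene_J"])
        t2 = gi_table(score_gi(3.0 * lfc, lib)).set_index(["gene_I", "gene_J"])
        np.testing.assert_allclose(
            t1["combined_z"].to_numpy(), t2["combined_z"].to_numpy(), atol=1e-9
        )

    def test_planted_interactions_ranked_first_with_signs(self):
        """|combined Z| separates planted pairs (AUROC >= 0.95), signs recovered."""
        lfc, lib, truth = synthetic.simulate_gi(synthetic.GIConfig(seed=10))
        tab = gi_table(score_gi(lfc, lib))
        g = {}
        for (q, a), v in truth.interactions.items():
            g[(q, a)] = v
            g[(a, q)] = v
        tab["g"] = [g.get((r.gene_I, r.gene_J), 0.0) for r in tab.itertuples()]
        pos = tab.loc[tab["g"] != 0, "combined_z"].abs().to_numpy()
        neg = tab.loc[tab["g"] == 0, "combined_z"].abs().to_numpy()
        # rank-based AUROC (Mann-Whitney)
        from scipy.stats import mannwhitneyu
        u = mannwhitneyu(pos, neg).statistic
        assert u / (len(pos) * len(neg)) >= 0.95
        hits = tab[(tab["g"] != 0) & (tab["combined_z"].abs() > 3)]
        assert len(hits) > 0
        assert (np.sign(hits["combined_z"]) == np.sign(hits["g"])).all()

    def test_self_interaction_signs_track_single_ko_fitness(self):
        """PS-like genes score negative self-interactions, essentials positive."""
        lfc, lib, truth = synthetic.simulate_gi(synthetic.GIConfig(
            n_query=8, n_array=40, include_query_in_array=True,
            interaction_fraction=0.0, noise_sigma=0.1, seed=11))
        tab = gi_table(score_gi(lfc, lib))
        selfs = tab[tab["gene_I"] == tab["gene_J"]]
        assert len(selfs) == 8
        eff = truth.gene_effects
        for row in selfs.itertuples():
            if eff[row.gene_I] > 0.5:  # PS-like
                assert row.combined_z < 0
            elif eff[row.gene_I] < -0.5:  # essential-like
                assert row.combined_z > 0
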