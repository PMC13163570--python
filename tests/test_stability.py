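import numpy as np
import pandas as pd
import pytest

from buffatlas import (
    CqTable,
    bestkeeper,
    cq_to_relative_quantity,
    genorm,
    normfinder,
    reffinder,
    simulate_cq,
    stability_report,
)


@pytest.fixture
def worked_cq():
    """Three genes, three samples; A and B proportional, C twice as steep."""
    return pd.DataFrame(
        [[20.0, 21.0, 22.0], [20.0, 21.0, 22.0], [20.0, 22.0, 24.0]],
        index=list("ABC"), columns=["s1", "s2", "s3"],
    )


class TestRelativeQuantity:
    def test_direct_formula(self):
        q = cq_to_relative_quantity(pd.DataFrame([[20.0, 21.0, 22.0]]))
        assert list(q.iloc[0]) == [1.0, 0.5, 0.25]

    def test_constant_row_all_one(self):
        q = cq_to_relative_quantity(pd.DataFrame([[25.0, 25.0, 25.0]]))
        assert (q.iloc[0] == 1.0).all()

    def test_efficiency_one_rejected(self):
        with pytest.raises(ValueError, match="efficiency"):
            cq_to_relative_quantity(pd.DataFrame([[20.0, 21.0]]), efficiency=1.0)


class TestGenorm:
    def test_hand_computed_m(self, worked_cq):
        res = genorm(worked_cq)
        assert res.m_values["A"] == pytest.approx(0.5, abs=1e-12)
        assert res.m_values["B"] == pytest.approx(0.5, abs=1e-12)
        assert res.m_values["C"] == pytest.approx(1.0, abs=1e-12)
        assert res.exclusion_order[0] == "C"
        assert set(res.ranking[:2]) == {"A", "B"}

    def test_shifted_gene_pair_equal_m(self):
        # B = A + 2 cycles everywhere: their pairwise variation is zero, so
        # both inherit M purely from the third gene
        cq = pd.DataFrame(
            [[20.0, 21.0, 22.0], [22.0, 23.0, 24.0], [20.0, 22.0, 24.0]],
            index=list("ABC"), columns=["s1", "s2", "s3"],
        )
        res = genorm(cq)
        assert res.m_values["A"] == pytest.approx(res.m_values["B"], abs=1e-12)

    def test_per_sample_constant_invariance(self, worked_cq):
        shifted = worked_cq + np.array([3.0, -1.0, 0.5])
        pd.testing.assert_series_equal(genorm(worked_cq).m_values, genorm(shifted).m_values)

    def test_m_nonnegative_and_ranks_permute(self, worked_cq):
        res = genorm(worked_cq)
        assert (res.m_values >= 0).all()
        assert sorted(res.ranks) == [1, 2, 3]


class TestNormfinder:
    def test_perfect_additivity_all_zero(self):
        sample_effect = np.array([0.0, 1.5, -0.7, 2.0])
        cq = pd.DataFrame(
            [20 + sample_effect, 24 + sample_effect, 28 + sample_effect],
            index=list("ABC"),
        )
        stab = normfinder(cq)
        assert np.allclose(stab, 0.0, atol=1e-12)

    def test_noisy_gene_largest_matches_anova_oracle(self, rng):
        import statsmodels.formula.api as smf

        sample_effect = rng.normal(0, 1, 6)
        cq = pd.DataFrame(
            [20 + sample_effect, 24 + sample_effect, 28 + sample_effect,
             26 + sample_effect + rng.normal(0, 1.0, 6)],
            index=list("ABCD"),
        )
        stab = normfinder(cq)
        assert stab.idxmax() == "D"
        # oracle: residual SDs from an OLS fit with gene + sample dummies
        x = np.log2(cq_to_relative_quantity(cq))
        long = x.stack().rename("x").reset_index()
        long.columns = ["gene", "sample", "x"]
        fit = smf.ols("x ~ C(gene) + C(sample)", data=long).fit()
        long["resid"] = fit.resid
        oracle = long.groupby("gene")["resid"].std(ddof=1)
        for g in "ABCD":
            assert stab[g] == pytest.approx(oracle[g], abs=1e-9)

    def test_per_gene_constant_invariance(self, rng):
        cq = pd.DataFrame(rng.normal(25, 1, (4, 5)), index=list("ABCD"))
        shifted = cq + np.array([[1.0], [-2.0], [0.5], [3.0]])
        pd.testing.assert_series_equal(normfinder(cq), normfinder(shifted))

    def test_grouped_mode_needs_two_per_group(self, rng):
        cq = pd.DataFrame(rng.normal(25, 1, (3, 3)), index=list("ABC"))
        with pytest.raises(ValueError, match="per group"):
            normfinder(cq, groups=["g1", "g1", "g2"])

    def test_grouped_mode_flags_group_shifted_gene(self, rng):
        base = rng.normal(25, 0.05, (4, 8))
        cq = pd.DataFrame(base, index=list("ABCD"))
        groups = ["x"] * 4 + ["y"] * 4
        cq.iloc[3, 4:] += 2.0  # gene D shifts between groups
        stab = normfinder(cq, groups=groups)
        assert stab.idxmax() == "D"


class TestBestkeeper:
    def test_constant_gene_rank_one(self, rng):
        cq = pd.DataFrame(
            np.vstack([np.full(4, 22.0), rng.normal(25, 1, (2, 4))]),
            index=list("ABC"),
        )
        res = bestkeeper(cq)
        assert res.loc["A", "sd"] == 0.0
        assert res["sd"].idxmin() == "A"

    def test_hand_sd(self):
        res = bestkeeper(pd.DataFrame([[20.0, 21.0, 22.0], [25.0, 25.0, 25.0]]))
        assert res.iloc[0]["sd"] == pytest.approx(1.0)

    def test_single_gene_index_self_correlates(self):
        cq = pd.DataFrame([[20.0, 21.0, 22.0]], index=["A"])
        res = bestkeeper(cq)
        assert np.allclose(res.attrs["index"].to_numpy(), cq.iloc[0].to_numpy())
        assert res.loc["A", "r"] == pytest.approx(1.0)

    def test_per_gene_constant_invariance(self, rng):
        cq = pd.DataFrame(rng.normal(25, 1, (3, 5)), index=list("ABC"))
        shifted = cq + np.array([[2.0], [-1.0], [4.0]])
        assert np.allclose(bestkeeper(cq)["sd"], bestkeeper(shifted)["sd"])

    def test_mad_option(self):
        res = bestkeeper(pd.DataFrame([[20.0, 22.0, 24.0], [25.0, 25.0, 25.0]]), dispersion="mad")
        assert res.iloc[0]["sd"] == pytest.approx(4.0 / 3.0)


class TestReffinder:
    @staticmethod
    def _ranks(values):
        return {f"alg{i}": pd.Series(v, index=list("wxyz")) for i, v in enumerate(values)}

    def test_unanimous(self):
        ranks = self._ranks([[1, 2, 3, 4]] * 4)
        res = reffinder(ranks)
        assert res.loc["w", "reffinder_geomean"] == pytest.approx(1.0)
        assert res.loc["w", "final_rank"] == 1

    def test_closed_form_geometric_mean(self):
        ranks = self._ranks([[1, 2, 3, 4], [2, 3, 4, 1], [3, 4, 1, 2], [4, 1, 2, 3]])
        res = reffinder(ranks)
        assert res.loc["w", "reffinder_geomean"] == pytest.approx(24 ** 0.25, abs=1e-9)

    def test_order_of_lists_irrelevant(self):
        lists = [[1, 2, 3, 4], [2, 1, 4, 3], [1, 3, 2, 4], [4, 3, 2, 1]]
        a = reffinder(self._ranks(lists))
        b = reffinder(self._ranks(lists[::-1]))
        pd.testing.assert_series_equal(a["final_rank"], b["final_rank"])

    def test_mismatched_gene_sets_error(self):
        ranks = {
            "a": pd.Series([1, 2, 3], index=list("xyz")),
            "b": pd.Series([1, 2, 3], index=list("xyw")),
        }
        with pytest.raises(ValueError, match="gene sets"):
            reffinder(ranks)

    def test_geomean_bounded_by_rank_extremes(self, rng):
        perms = [pd.Series(rng.permutation(6) + 1, index=list("abcdef")) for _ in range(4)]
        res = reffinder({f"alg{i}": p for i, p in enumerate(perms)})
        R = pd.DataFrame({f"alg{i}": p for i, p in enumerate(perms)})
        assert (res["reffinder_geomean"] >= R.min(axis=1) - 1e-12).all()
        assert (res["reffinder_geomean"] <= R.max(axis=1) + 1e-12).all()


class TestPlantedRecovery:
    def test_zero_noise_perfect_proportionality(self):
        cq, _ = simulate_cq(noise_sds=[0.0] * 6, seed=0)
        res = genorm(cq)
        assert np.allclose(res.m_values, 0.0, atol=1e-9)

    def test_gene_relabeling_invariance(self):
        cq, _ = simulate_cq(seed=5)
        rep = stability_report(cq)
        flipped = CqTable(cq.cq.iloc[::-1])
        rep2 = stability_report(flipped)
        pd.testing.assert_frame_equal(rep.sort_index(), rep2.sort_index())

    def test_lowest_noise_gene_wins_aggregate(self):
        hits = 0
        for seed in range(30):
            cq, truth = simulate_cq(noise_sds=[0.05, 0.2, 0.4, 0.6, 0.8, 1.0], seed=seed)
            rep = stability_report(cq)
            best = truth.stability_order[0]
            worst = truth.stability_order[-1]
            hits += int(rep.loc[best, "final_rank"] <= 2)
            # the noisiest gene never wins the aggregate ranking
            assert rep.loc[worst, "final_rank"] > 1
        assert hits >= 27
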