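"""Alpha diversity, rarefaction, ANOVA/Tukey, property screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats as sps

from plastisphere import community as C
from plastisphere.synthgen import ScenarioConfig, gen_otu_table

skbio_alpha = pytest.importorskip("skbio.diversity.alpha")


class TestShannon:
    def test_single_otu_zero(self):
        assert C.shannon([10]) == 0.0

    def test_two_even_otus(self):
        assert C.shannon([5, 5]) == pytest.approx(np.log(2), abs=1e-12)

    def test_uniform_community_is_log_s(self):
        s = 37
        assert C.shannon([100] * s) == pytest.approx(np.log(s), abs=1e-12)

    def test_matches_direct_summation_oracle(self):
        counts = np.array([4, 3, 2, 1])
        p = counts / counts.sum()
        oracle = -(p * np.log(p)).sum()
        assert C.shannon(counts) == pytest.approx(oracle, abs=1e-14)
        assert C.shannon(counts) == pytest.approx(
            skbio_alpha.shannon(counts, base=np.e), abs=1e-12
        )

    def test_base2_option(self):
        assert C.shannon([5, 5], base=2) == pytest.approx(1.0)

    def test_zero_sample_errors(self):
        with pytest.raises(ValueError):
            C.shannon([0, 0])


class TestFisherAlpha:
    def test_residual_identity_smallest_case(self):
        alpha = C.fisher_alpha(1, 100)
        assert abs(alpha * np.log1p(100 / alpha) - 1) < 1e-8

    def test_matches_bisection_oracle(self):
        oracle = optimize.bisect(
            lambda a: a * np.log1p(100 / a) - 10, 1e-6, 1e6, xtol=1e-10
        )
        assert C.fisher_alpha(10, 100) == pytest.approx(oracle, abs=1e-6)

    def test_matches_skbio(self):
        counts = np.array([20, 10, 5, 3, 1, 1])
        s, n = (counts > 0).sum(), counts.sum()
        assert C.fisher_alpha(int(s), int(n)) == pytest.approx(
            float(skbio_alpha.fisher_alpha(counts)), rel=1e-6
        )

    def test_monotone_decreasing_in_depth(self):
        alphas = [C.fisher_alpha(50, n) for n in (100, 400, 1600, 6400)]
        assert all(a > b for a, b in zip(alphas, alphas[1:]))

    def test_residual_below_tolerance_on_grid(self):
        for s in (5, 50, 500):
            for n in (2 * s, 10 * s, 1000 * s):
                a = C.fisher_alpha(s, n)
                assert abs(a * np.log1p(n / a) - s) < 1e-8

    def test_s_not_below_n_errors(self):
        with pytest.raises(ValueError):
            C.fisher_alpha(10, 10)


class TestChao1:
    def test_no_singletons_equals_observed(self):
        counts = [5, 4, 3, 2]
        assert C.chao1(counts) == 4.0

    def test_classic_worked_example(self):
        # S_obs = 10, F1 = 4, F2 = 2 -> 10 + 16/4 = 14
        counts = [1, 1, 1, 1, 2, 2, 5, 6, 7, 8]
        assert C.chao1(counts, bias_corrected=False) == pytest.approx(14.0)

    def test_bias_corrected_worked_example(self):
        # 10 + 4*3/(2*3) = 12
        counts = [1, 1, 1, 1, 2, 2, 5, 6, 7, 8]
        assert C.chao1(counts, bias_corrected=True) == pytest.approx(12.0)
        assert C.chao1(counts) == pytest.approx(
            float(skbio_alpha.chao1(np.array(counts), bias_corrected=True))
        )

    def test_never_below_observed_richness(self, rng):
        for _ in range(200):
            counts = rng.integers(0, 10, size=30)
            if counts.sum() == 0:
                continue
            assert C.chao1(counts) >= (counts > 0).sum()

    def test_column_order_and_zero_padding_invariance(self, rng):
        counts = np.array([1, 1, 2, 5, 9])
        shuffled = counts[rng.permutation(5)]
        padded = np.concatenate([counts, np.zeros(7, dtype=int)])
        assert C.chao1(counts) == C.chao1(shuffled) == C.chao1(padded)


class TestAce:
    def test_all_abundant_equals_observed(self):
        counts = [50, 60, 70]
        assert C.ace(counts) == 3.0

    def test_hand_worked_micro_sample(self):
        # rare: (1, 1, 2); abundant: (20, 30, 40)
        counts = [1, 1, 2, 20, 30, 40]
        n_rare, f1, s_rare, s_abund = 4, 2, 3, 3
        c_ace = 1 - f1 / n_rare
        sum_i = 1 * 0 * 2 + 2 * 1 * 1  # sum i(i-1)F_i
        gamma2 = max(0.0, s_rare * sum_i / (c_ace * n_rare * (n_rare - 1)) - 1)
        oracle = s_abund + s_rare / c_ace + f1 * gamma2 / c_ace
        assert C.ace(counts) == pytest.approx(oracle, abs=1e-12)
        assert C.ace(counts) == pytest.approx(
            float(skbio_alpha.ace(np.array(counts))), rel=1e-9
        )

    def test_not_below_observed_when_singletons_exist(self, rng):
        for _ in range(200):
            counts = rng.integers(0, 15, size=25)
            if counts.sum() == 0 or not (counts == 1).any():
                continue
            rare = counts[(counts > 0) & (counts <= 10)]
            if rare.size and (rare == 1).all():
                continue  # C_ACE = 0 fallback case, checked separately
            assert C.ace(counts) >= (counts > 0).sum() - 1e-9

    def test_all_rare_singletons_falls_back_to_chao1(self):
        counts = [1, 1, 1, 50, 60]
        with pytest.warns(UserWarning):
            est = C.ace(counts)
        assert est == pytest.approx(C.chao1([1, 1, 1, 50, 60]))


class TestRarefaction:
    def test_depth_equal_row_sum_reproduces_sample(self):
        counts = pd.DataFrame([[5, 3, 2]], index=["s1"], columns=list("abc"))
        out = C.rarefy(counts, depth=10, n_perm=5, seed=0)
        assert out.loc["s1", "richness"] == 3.0
        assert out.loc["s1", "shannon"] == pytest.approx(C.shannon([5, 3, 2]))

    def test_single_otu_sample(self):
        counts = pd.DataFrame([[40, 0]], index=["s1"], columns=list("ab"))
        out = C.rarefy(counts, depth=10, n_perm=9, seed=0)
        assert out.loc["s1", "richness"] == 1.0
        assert out.loc["s1", "shannon"] == 0.0

    def test_rarefied_richness_matches_hypergeometric_closed_form(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 60, size=40)
        counts[0] = 200
        n = counts.sum()
        depth = int(n * 0.4)
        df = pd.DataFrame([counts], index=["s1"])
        got = C.rarefy(df, depth=depth, n_perm=999, seed=1).loc["s1", "richness"]
        # closed form E[S] = sum_i 1 - C(N - N_i, d) / C(N, d)
        from scipy.special import gammaln

        def log_comb(n_, k_):
            return gammaln(n_ + 1) - gammaln(k_ + 1) - gammaln(n_ - k_ + 1)

        expected = sum(
            1.0 - np.exp(log_comb(n - c, depth) - log_comb(n, depth))
            for c in counts if c > 0 and n - c >= depth
        ) + sum(1.0 for c in counts if c > 0 and n - c < depth)
        # Monte-Carlo tolerance: ~3 sd of the permutation mean
        assert got == pytest.approx(expected, abs=0.35)

    def test_depth_above_row_sum_names_sample(self):
        counts = pd.DataFrame([[3, 2]], index=["tiny"], columns=list("ab"))
        with pytest.raises(ValueError, match="tiny"):
            C.rarefy(counts, depth=10, n_perm=3, seed=0)

    def test_shannon_nondecreasing_in_depth_in_expectation(self):
        rng = np.random.default_rng(6)
        counts = pd.DataFrame([rng.integers(1, 50, size=30)], index=["s"])
        h = [
            C.rarefy(counts, depth=d, n_perm=300, seed=2).loc["s", "shannon"]
            for d in (50, 150, 400)
        ]
        assert h[0] <= h[1] + 0.02 and h[1] <= h[2] + 0.02


def balanced_design(rng, effects=None):
    """3 polymers x 4 indices x 3 replicates with optional planted effects."""
    rows = []
    effects = effects or {}
    for poly_i, poly in enumerate(["PE", "PP", "PS"]):
        for idx_i, idx in enumerate(["shannon", "fisher_alpha", "chao1", "ace"]):
            mu = 10 + 5 * poly_i + 20 * idx_i + effects.get((poly, idx), 0.0)
            for _ in range(3):
                rows.append({"polymer": poly, "index": idx,
                             "value": mu + rng.normal(0, 1)})
    return pd.DataFrame(rows)


class TestAnovaTukey:
    def test_constant_data_flagged(self):
        df = pd.DataFrame(
            {"polymer": ["PE", "PE", "PP", "PP"], "index": ["shannon"] * 4,
             "value": [3.0, 3.0, 3.0, 3.0]}
        )
        anova, tukey = C.anova_tukey(df)
        assert np.isnan(anova["F"]).all()
        assert (tukey["mean_diff"] == 0).all()
        assert not tukey["significant"].any()

    def test_ss_decomposition_matches_cell_means_oracle(self, rng):
        df = balanced_design(rng)
        anova, _ = C.anova_tukey(df)
        # brute-force cell-means oracle for the balanced two-way layout
        y = df["value"].to_numpy()
        grand = y.mean()
        cell = df.groupby(["polymer", "index"], observed=True)["value"].mean()
        a_means = df.groupby("polymer", observed=True)["value"].mean()
        b_means = df.groupby("index", observed=True)["value"].mean()
        n_rep, n_a, n_b = 3, 3, 4
        ss_a = n_rep * n_b * ((a_means - grand) ** 2).sum()
        ss_b = n_rep * n_a * ((b_means - grand) ** 2).sum()
        ss_cells = n_rep * ((cell - grand) ** 2).sum()
        ss_ab = ss_cells - ss_a - ss_b
        ss_total = ((y - grand) ** 2).sum()
        ss_resid = ss_total - ss_cells
        assert anova.loc["polymer", "SS"] == pytest.approx(ss_a, abs=1e-8)
        assert anova.loc["diversity index", "SS"] == pytest.approx(ss_b, abs=1e-8)
        assert anova.loc["interaction", "SS"] == pytest.approx(ss_ab, abs=1e-8)
        assert anova.loc["residual", "SS"] == pytest.approx(ss_resid, abs=1e-8)
        # and the full decomposition closes
        total = anova["SS"].sum()
        assert total == pytest.approx(ss_total, rel=1e-10)

    def test_two_group_tukey_equals_pairwise_t(self, rng):
        df = pd.DataFrame(
            {"polymer": ["PE"] * 5 + ["PP"] * 5,
             "value": np.concatenate([rng.normal(0, 1, 5),
                                      rng.normal(1.5, 1, 5)])}
        )
        _, tukey = C.anova_tukey(df, index_col=None)
        t, p = sps.ttest_ind(df.loc[df.polymer == "PE", "value"],
                             df.loc[df.polymer == "PP", "value"])
        assert tukey.loc[0, "p_adj"] == pytest.approx(p, abs=1e-8)

    def test_one_way_mode(self, rng):
        df = balanced_design(rng).query("index == 'chao1'")
        anova, tukey = C.anova_tukey(df, index_col=None)
        assert "polymer" in anova.index
        assert len(tukey) == 3  # three pairwise polymer comparisons

    def test_single_replicate_group_errors(self):
        df = pd.DataFrame(
            {"polymer": ["PE", "PP", "PP"], "index": ["shannon"] * 3,
             "value": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError):
            C.anova_tukey(df)


class TestDiversityPropertyScreen:
    def make_inputs(self, ordered=True):
        samples = [f"{p}_{i}" for p in ("PE", "PP", "PS") for i in range(3)]
        polymers = pd.Series([s.split("_")[0] for s in samples], index=samples)
        base = {"PE": 1.0, "PP": 2.0, "PS": 3.0}
        vals = [base[polymers[s]] + 0.01 * int(s[-1]) for s in samples]
        div = pd.DataFrame({"shannon": vals}, index=samples)
        props = pd.DataFrame(
            {"stiffness": [10.0, 20.0, 30.0] if ordered else [20.0, 20.0, 20.0]},
            index=["PE", "PP", "PS"],
        )
        return div, polymers, props

    def test_tied_rank_ceiling_for_perfect_ordering(self):
        div, polymers, props = self.make_inputs()
        out = C.diversity_property_screen(div, polymers, props)
        # samples strictly ordered, property tied within polymer:
        # rho equals the 3x3 tied-rank ceiling 54/sqrt(54*60)
        assert out.loc[0, "rho"] == pytest.approx(0.9487, abs=1e-3)

    def test_constant_property_flagged(self):
        div, polymers, props = self.make_inputs(ordered=False)
        out = C.diversity_property_screen(div, polymers, props)
        assert np.isnan(out.loc[0, "rho"])

    def test_missing_polymer_errors(self):
        div, polymers, props = self.make_inputs()
        with pytest.raises(ValueError):
            C.diversity_property_screen(div, polymers, props.drop("PS"))

    def test_polymer_means_mode_uses_three_points(self):
        div, polymers, props = self.make_inputs()
        out = C.diversity_property_screen(div, polymers, props,
                                          mode="polymer_means")
        assert (out["n"] == 3).all()
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_null_screen_false_positive_rate(self):
        """Shuffled labels: |rho| exceeds the n=9 exact critical value in
        about 5% of simulations."""
        rng = np.random.default_rng(17)
        samples = [f"s{i}" for i in range(9)]
        polymers = pd.Series(["PE"] * 3 + ["PP"] * 3 + ["PS"] * 3, index=samples)
        props = pd.DataFrame({"k": [1.0, 2.0, 3.0]}, index=["PE", "PP", "PS"])
        hits = 0
        n_sim = 300
        for _ in range(n_sim):
            div = pd.DataFrame({"h": rng.normal(0, 1, 9)}, index=samples)
            out = C.diversity_property_screen(div, polymers, props)
            hits += out.loc[0, "p"] < 0.05
        assert 0.01 <= hits / n_sim <= 0.10


class TestOtuTable:
    def test_metadata_alignment_enforced(self):
        counts = pd.DataFrame([[1, 2]], index=["s1"], columns=["a", "b"])
        meta = pd.DataFrame({"polymer": ["PE"]}, index=["other"])
        with pytest.raises(ValueError):
            C.OtuTable(counts=counts, metadata=meta)

    def test_generated_table_round_trips(self):
        table, truth = gen_otu_table(ScenarioConfig(seed=2, n_otus=100))
        assert table.counts.shape == (9, 100)
        assert set(table.metadata["polymer"]) == {"PE", "PP", "PS"}
        assert len(truth) == 7
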