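import numpy as np
import pandas as pd
import pytest

from whorlstat.differential import (
    SAMContrastAnalyzer,
    assign_specific,
    call_significant,
    d_statistics,
    expected_ranked_d,
    fit_contrast,
    make_contrasts,
    permute_labels,
)
from whorlstat.simulate import SimulationParams, generate_study

from conftest import make_expression

FIVE = ("SEP", "PET", "STA", "STD", "CAR")


def brute_force_fit(values, tissues, populations, group):
    """Independent loop-based implementation of the contrast fit."""
    coefs, ses = [], []
    pops = sorted(set(populations))
    for g in range(values.shape[0]):
        diffs = []
        for p in pops:
            grp, comp = [], []
            for a in range(values.shape[1]):
                if populations[a] != p:
                    continue
                if tissues[a] in group:
                    grp.append(values[g, a])
                else:
                    comp.append(values[g, a])
            diffs.append(sum(grp) / len(grp) - sum(comp) / len(comp))
        mean = sum(diffs) / len(diffs)
        var = sum((d - mean) ** 2 for d in diffs) / (len(diffs) - 1)
        coefs.append(mean)
        ses.append((var**0.5) / len(diffs) ** 0.5)
    return np.array(coefs), np.array(ses)


class TestMakeContrasts:
    def test_five_whorls_give_twelve(self):
        cs = {c.id: c for c in make_contrasts(FIVE)}
        assert len(cs) == 12
        assert cs[1].group == {"SEP"}
        assert cs[6].group == {"SEP", "PET"}
        assert cs[7].group == {"SEP", "PET", "STA"}
        assert cs[8].group == {"PET", "STA"}
        assert cs[9].group == {"PET", "STA", "STD"}
        assert cs[10].group == {"STA", "STD"}
        assert cs[12].group == {"STA", "CAR"}

    def test_four_whorls_give_seven(self):
        cs = {c.id: c for c in make_contrasts(("SEP", "PET", "STA", "CAR"))}
        assert len(cs) == 7
        assert cs[5].group == {"SEP", "PET"}
        assert cs[6].group == {"PET", "STA"}
        assert cs[7].group == {"STA", "CAR"}

    def test_contrast_11_complements_6(self):
        cs = {c.id: c for c in make_contrasts(FIVE)}
        assert cs[11].group == cs[6].complement

    def test_other_sizes_rejected(self):
        with pytest.raises(ValueError):
            make_contrasts(("SEP", "PET"))


def expr_for_contrast_toy(five_whorl_design, pet_vals, other_vals):
    vals = {}
    for aid in five_whorl_design.array_ids:
        t, p = aid.split("_")
        i = int(p[-1]) - 1
        vals[aid] = [pet_vals[i] if t == "PET" else other_vals[i]]
    return make_expression(vals, five_whorl_design, gene_ids=["g1"])


class TestFitContrast:
    def test_constant_differences(self, five_whorl_design):
        expr = expr_for_contrast_toy(five_whorl_design, [5, 6, 7], [1, 2, 3])
        c2 = [c for c in make_contrasts(FIVE) if c.id == 2][0]
        fit = fit_contrast(expr, c2)
        assert fit.loc["g1", "coefficient"] == pytest.approx(4.0)
        assert fit.loc["g1", "se"] == pytest.approx(0.0)

    def test_two_population_example(self):
        # block differences 3 and 5 -> coefficient 4, se = sd([3,5])/sqrt(2) = 1
        import whorlstat.io as wio

        rows = [
            (f"{t}_{p}", t, p) for t in FIVE for p in ("pop1", "pop2")
        ]
        design = wio.StudyDesign(
            entries=pd.DataFrame(
                rows, columns=["array_id", "tissue", "population"]
            )
        )
        vals = {}
        for aid in design.array_ids:
            t, p = aid.split("_")
            if p == "pop1":
                vals[aid] = [4.0] if t == "PET" else [1.0]
            else:
                vals[aid] = [7.0] if t == "PET" else [2.0]
        expr = make_expression(vals, design, gene_ids=["g1"])
        c2 = [c for c in make_contrasts(FIVE) if c.id == 2][0]
        fit = fit_contrast(expr, c2)
        assert fit.loc["g1", "coefficient"] == pytest.approx(4.0)
        assert fit.loc["g1", "se"] == pytest.approx(1.0)

    def test_swapping_group_negates(self, five_whorl_design):
        rng = np.random.default_rng(0)
        vals = {
            aid: rng.normal(size=5) for aid in five_whorl_design.array_ids
        }
        expr = make_expression(vals, five_whorl_design)
        cs = {c.id: c for c in make_contrasts(FIVE)}
        f6 = fit_contrast(expr, cs[6])
        f11 = fit_contrast(expr, cs[11])
        np.testing.assert_array_equal(
            f6["coefficient"].to_numpy(), -f11["coefficient"].to_numpy()
        )
        np.testing.assert_array_equal(f6["se"].to_numpy(), f11["se"].to_numpy())

    def test_matches_brute_force_oracle(self, five_whorl_design):
        rng = np.random.default_rng(5)
        vals = {
            aid: rng.normal(size=10) for aid in five_whorl_design.array_ids
        }
        expr = make_expression(vals, five_whorl_design)
        values = expr.values.to_numpy()
        tissues = [five_whorl_design.tissue_of()[a] for a in expr.array_ids]
        pops = [five_whorl_design.population_of()[a] for a in expr.array_ids]
        for c in make_contrasts(FIVE):
            fit = fit_contrast(expr, c)
            coef_bf, se_bf = brute_force_fit(values, tissues, pops, c.group)
            np.testing.assert_allclose(
                fit["coefficient"].to_numpy(), coef_bf, atol=1e-12
            )
            np.testing.assert_allclose(fit["se"].to_numpy(), se_bf, atol=1e-12)


class TestDStatistics:
    def test_zero_coefficient_gives_zero(self):
        d, _ = d_statistics([0.0, 1.0], [0.3, 0.3])
        assert d[0] == 0.0

    def test_s0_is_median_se(self):
        _, s0 = d_statistics([1, 1, 1], [0.1, 0.2, 0.3])
        assert s0 == pytest.approx(0.2)

    def test_direct_formula(self):
        d, _ = d_statistics([2.0], [0.5], s0=0.5)
        assert d[0] == pytest.approx(2.0)

    def test_zero_variance_floored(self):
        d, s0 = d_statistics([1.0], [0.0])
        assert s0 == 1e-9
        assert np.isfinite(d[0])


class TestPermutations:
    def test_multiset_preserved(self, five_whorl_design):
        perms = permute_labels(five_whorl_design, n_perm=99, seed=11)
        orig = sorted(five_whorl_design.entries["tissue"])
        assert len(perms) == 99
        for p in perms:
            assert sorted(p) == orig

    def test_deterministic(self, five_whorl_design):
        a = permute_labels(five_whorl_design, n_perm=10, seed=4)
        b = permute_labels(five_whorl_design, n_perm=10, seed=4)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_within_blocks_keeps_block_multisets(self, five_whorl_design):
        pops = five_whorl_design.entries["population"].to_numpy()
        tissues = five_whorl_design.entries["tissue"].to_numpy()
        for perm in permute_labels(
            five_whorl_design, n_perm=20, seed=2, within_blocks=True
        ):
            for p in np.unique(pops):
                assert sorted(perm[pops == p]) == sorted(tissues[pops == p])


class TestExpectedRankedD:
    def test_rank_wise_mean(self):
        exp = expected_ranked_d([[1, 2, 3], [3, 4, 5]])
        np.testing.assert_allclose(exp, [2, 3, 4])

    def test_single_permutation_is_its_own_sort(self):
        np.testing.assert_allclose(expected_ranked_d([[3, 1, 2]]), [1, 2, 3])

    def test_nondecreasing(self):
        rng = np.random.default_rng(0)
        exp = expected_ranked_d(rng.normal(size=(30, 50)))
        assert (np.diff(exp) >= 0).all()


class TestCallSignificant:
    def test_delta_zero_calls_everything_off_diagonal(self):
        obs = np.array([-2.0, 0.0, 3.0])
        exp = np.array([-1.0, 0.0, 1.0])
        call = call_significant(obs, exp, [obs], delta=0.0)
        assert call.n_called == 2

    def test_nothing_called_gives_zero_fdr(self):
        obs = np.array([0.1, 0.2])
        exp = np.array([0.1, 0.2])
        call = call_significant(obs, exp, [obs], delta=4.0)
        assert call.n_called == 0
        assert call.fdr == 0.0

    def test_pure_null_simulation_calls_almost_nothing_at_delta_4(self):
        p = SimulationParams(n_genes=500, probes_per_gene=(4, 6), seed=21)
        tables, design, _ = generate_study(p)
        from whorlstat.preprocess import preprocess_study

        expr = preprocess_study(tables, design, window=9)
        an = SAMContrastAnalyzer(delta=4.0, n_perm=99, seed=21).fit(expr)
        assert sum(c.n_called for c in an.calls_.values()) <= 5


TABLE1_COLUMNS = list(range(1, 13))
TABLE1 = {
    # printed D statistics of five Aquilegia floral genes over the 12
    # whorl contrasts (columns ordered SEP, PET, STA, STD, CAR, A, B, C,
    # B+SEP, B+STD, STA+STD, C+STD)
    "TC19085": [-4.5, 19.7, 1.2, -3.0, -5.1, 6.0, 13.3, -3.4, 7.4, 9.3, -1.3, -6.6],
    "TC13707": [-4.9, -3.7, -4.8, 27.9, -1.3, -6.0, -5.6, -4.3, -12.3, 4.4, 8.6, 7.5],
    "TC9974": [12.8, 9.1, -14.7, -2.7, -4.9, 29.1, -2.0, -18.4, 6.6, -4.0, -13.3, -19.6],
    "TC19725": [-5.6, 4.4, 6.1, 5.1, -12.5, -0.7, 9.6, -3.2, 3.8, 30.0, 8.3, 0.7],
    "TC16289": [1.1, -3.5, 2.3, 10.3, -5.9, -1.6, -0.6, -5.2, 0.2, 6.3, 9.8, 1.6],
}


class TestAssignSpecific:
    @pytest.mark.parametrize(
        "gene,contrast,direction",
        [
            ("TC19085", 2, 1),   # petal-specific AP3-3
            ("TC13707", 4, 1),   # staminodium-specific myb
            ("TC9974", 6, 1),    # A-domain anthocyanin gene
            ("TC19725", 10, 1),  # AP3-2, stamens+staminodia
            ("TC16289", 4, 1),   # AP3-1, staminodia
        ],
    )
    def test_published_worked_examples(self, gene, contrast, direction):
        dt = pd.DataFrame(TABLE1, index=TABLE1_COLUMNS).T
        spec = assign_specific(dt)
        assert spec.loc[gene, "specific_contrast"] == contrast
        assert spec.loc[gene, "direction"] == direction

    def test_tie_goes_to_lowest_contrast(self):
        dt = pd.DataFrame([[1.0, -1.0, 0.0]], columns=[1, 2, 3], index=["g"])
        spec = assign_specific(dt)
        assert spec.loc["g", "specific_contrast"] == 1
        assert spec.loc["g", "direction"] == 1


class TestAnalyzer:
    def test_antisymmetry_of_complementary_contrasts(self, five_whorl_design):
        rng = np.random.default_rng(8)
        vals = {
            aid: rng.normal(size=30) for aid in five_whorl_design.array_ids
        }
        expr = make_expression(vals, five_whorl_design)
        an = SAMContrastAnalyzer(n_perm=5, seed=1).fit(expr)
        np.testing.assert_array_equal(
            an.d_[11].to_numpy(), -an.d_[6].to_numpy()
        )
        assert an.s0_[11] == an.s0_[6]

    def test_block_shift_invariance(self, five_whorl_design):
        rng = np.random.default_rng(9)
        vals = {
            aid: rng.normal(size=20) for aid in five_whorl_design.array_ids
        }
        expr1 = make_expression(vals, five_whorl_design)
        shifted = {
            aid: v + (10.0 if aid.endswith("pop2") else 0.0)
            for aid, v in vals.items()
        }
        expr2 = make_expression(shifted, five_whorl_design)
        a1 = SAMContrastAnalyzer(n_perm=3, seed=1).fit(expr1)
        a2 = SAMContrastAnalyzer(n_perm=3, seed=1).fit(expr2)
        np.testing.assert_allclose(
            a1.d_.to_numpy(), a2.d_.to_numpy(), atol=1e-9
        )

    def test_sklearn_params_round_trip(self):
        an = SAMContrastAnalyzer(delta=3.0, n_perm=10)
        params = an.get_params()
        assert params["delta"] == 3.0
        an.set_params(delta=5.0)
        assert an.delta == 5.0

    def test_summary_layout(self, five_whorl_design):
        rng = np.random.default_rng(10)
        vals = {
            aid: rng.normal(size=15) for aid in five_whorl_design.array_ids
        }
        expr = make_expression(vals, five_whorl_design)
        an = SAMContrastAnalyzer(n_perm=5, seed=0).fit(expr)
        s = an.summary()
        assert list(s["contrast"]) == list(range(1, 13))
        assert set(s.columns) >= {
            "n_down", "n_up", "fdr", "n_specific_down", "n_specific_up"
        }
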