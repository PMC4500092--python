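"""Encoded model fits, effect extraction, model comparison and logos."""

import itertools

import numpy as np
import pandas as pd
import pytest
import sympy

from tfscape.epistasis import (
    EpistasisRegression,
    RankDeficiencyError,
    build_energy_logo,
    compare_nested,
    energy_logo_for_protein,
    fit_model,
    logo_comparisons,
    variance_partition,
)
from tfscape.genotype_space import (
    FULL_SPEC,
    RE_SPEC,
    JointGenotype,
    ModelSpec,
    enumerate_joint_genotypes,
    enumerate_re_genotypes,
    wyk_encode,
)
from tfscape.simulate import (
    LandscapeParams,
    generate_landscape,
    random_landscape_params,
)

NUCS = "ACGT"


def cell_means(table):
    return table.groupby(["protein", "re"])["dG_kcal_mol"].mean()


def oracle_state_effect(table, re_site, nuc):
    """Brute-force conditional-mean contrast over cell means."""
    cm = cell_means(table).reset_index()
    has = cm["re"].str[0 if re_site == 3 else 1] == nuc
    return cm.loc[has, "dG_kcal_mol"].mean() - cm["dG_kcal_mol"].mean()


def oracle_pair_epistasis(table, s3, s4):
    cm = cell_means(table).reset_index()
    both = (cm["re"].str[0] == s3) & (cm["re"].str[1] == s4)
    return (
        cm.loc[both, "dG_kcal_mol"].mean()
        - cm["dG_kcal_mol"].mean()
        - oracle_state_effect(table, 3, s3)
        - oracle_state_effect(table, 4, s4)
    )


class TestFitModel:
    def test_intercept_only_is_grand_mean(self):
        tab, _ = generate_landscape(random_landscape_params(3, noise_sd=0.3, replicates=2))
        fit = fit_model(tab, ModelSpec(("INTERCEPT",)))
        assert fit.coef_["u0"] == pytest.approx(tab["dG_kcal_mol"].mean(), rel=1e-12)

    def test_single_protein_effect_noiseless(self):
        # substitution effect 1.3 <=> coefficient a = 0.65
        params = LandscapeParams(
            protein_effects={25: 1.3}, noise_sd=0.0, replicates=1
        )
        tab, _ = generate_landscape(params)
        fit = fit_model(tab, FULL_SPEC)
        assert fit.coef_["a"] == pytest.approx(0.65, abs=1e-12)
        others = fit.coef_.drop(["u0", "a"])
        assert others.abs().max() < 1e-9
        assert fit.substitution_effect(25) == pytest.approx(1.3, abs=1e-12)

    def test_coefficients_invariant_to_group_inclusion(self):
        # complete-factorial orthogonality: a,b,c identical whether fitted
        # alone or inside the full third-order model
        tab, _ = generate_landscape(random_landscape_params(7, noise_sd=0.25, replicates=3))
        small = fit_model(tab, ModelSpec(("INTERCEPT", "P1")))
        big = fit_model(tab, FULL_SPEC)
        for term in ("a", "b", "c"):
            assert big.coef_[term] == pytest.approx(small.coef_[term], rel=1e-9)

    def test_rank_deficiency_names_collinear_terms(self):
        # one protein only: protein columns are constant multiples of u0
        tab, _ = generate_landscape(random_landscape_params(5, replicates=1))
        sub = tab[tab["protein"] == "glu-gly-ala"]
        with pytest.raises(RankDeficiencyError, match="collinear"):
            fit_model(sub, ModelSpec(("INTERCEPT", "P1", "R1_3")))

    def test_censored_rows_excluded(self):
        tab, _ = generate_landscape(random_landscape_params(11, replicates=1))
        tab = tab.copy()
        tab["censored"] = False
        tab.loc[tab.index[:5], "censored"] = True
        fit = fit_model(tab, ModelSpec(("INTERCEPT",)))
        assert fit.n_obs_ == len(tab) - 5

    def test_likelihood_invariant_to_row_order(self):
        tab, _ = generate_landscape(random_landscape_params(13, noise_sd=0.2, replicates=2))
        shuffled = tab.sample(frac=1.0, random_state=0)
        f1 = fit_model(tab, RE_SPEC.with_groups("P1"))
        f2 = fit_model(shuffled, RE_SPEC.with_groups("P1"))
        assert f1.llf_ == pytest.approx(f2.llf_, rel=1e-12)

    def test_predict_reproduces_cell_means_for_saturated_model(self):
        tab, _ = generate_landscape(random_landscape_params(17, noise_sd=0.3, replicates=3))
        sub = tab[tab["protein"] == "GLY-SER-VAL"]
        fit = fit_model(sub, RE_SPEC)  # 16 params, 16 cells
        cm = sub.groupby("re")["dG_kcal_mol"].mean()
        pred = fit.predict([f"GLY-SER-VAL:{re}" for re in cm.index])
        np.testing.assert_allclose(pred, cm.to_numpy(), rtol=1e-12)


@pytest.fixture(scope="module")
def fit():
    tab, _ = generate_landscape(
        random_landscape_params(23, noise_sd=0.1, replicates=3)
    )
    return fit_model(tab, FULL_SPEC)


class TestEffectFormulas:
    def test_c3_is_minus_w_plus_y_minus_k(self, fit):
        expected = -fit.coef_["w3"] + fit.coef_["y3"] - fit.coef_["k3"]
        assert fit.state_effect(3, "C") == pytest.approx(expected, rel=1e-12)

    def test_g3_is_minus_w_minus_y_plus_k(self, fit):
        expected = -fit.coef_["w3"] - fit.coef_["y3"] + fit.coef_["k3"]
        assert fit.state_effect(3, "G") == pytest.approx(expected, rel=1e-12)

    def test_state_effects_sum_to_zero(self, fit):
        for site in (3, 4):
            assert sum(fit.state_effect(site, n) for n in NUCS) == pytest.approx(0.0, abs=1e-9)

    def test_pair_contrasts_zero_margins(self, fit):
        mat = {
            (a, b): fit.pair_epistasis(a, b) for a in NUCS for b in NUCS
        }
        for a in NUCS:
            assert sum(mat[(a, b)] for b in NUCS) == pytest.approx(0.0, abs=1e-9)
            assert sum(mat[(b, a)] for b in NUCS) == pytest.approx(0.0, abs=1e-9)

    def test_c3_a4_symbolic_expansion(self):
        # independent symbolic oracle for the nine-term expansion
        w3, y3, k3, w4, y4, k4 = sympy.symbols("w3 y3 k3 w4 y4 k4")
        coefs = sympy.Matrix(
            [w3 * w4, w3 * y4, w3 * k4, y3 * w4, y3 * y4, y3 * k4,
             k3 * w4, k3 * y4, k3 * k4]
        )
        weights = sympy.Matrix(np.outer(wyk_encode("C"), wyk_encode("A")).ravel())
        computed = sympy.expand(coefs.dot(weights))
        published = sympy.expand(
            -w3 * w4 + w3 * y4 + w3 * k4 + y3 * w4 - y3 * y4 - y3 * k4
            - k3 * w4 + k3 * y4 + k3 * k4
        )
        assert sympy.simplify(computed - published) == 0

    def test_pair_epistasis_matches_cell_mean_oracle(self, fit):
        tab = pd.DataFrame(
            {
                "protein": [g.protein.label for g in fit.genotypes_],
                "re": [g.re.label for g in fit.genotypes_],
                "dG_kcal_mol": fit.y_,
            }
        )
        sub = tab[tab["protein"] == "glu-gly-ala"]
        re_fit = fit_model(sub, RE_SPEC)
        for s3, s4 in itertools.product(NUCS, repeat=2):
            assert re_fit.pair_epistasis(s3, s4) == pytest.approx(
                oracle_pair_epistasis(sub, s3, s4), abs=1e-9
            )

    def test_substitution_effect_matches_split_mean_oracle(self, fit):
        tab = pd.DataFrame(
            {
                "protein": [g.protein.label for g in fit.genotypes_],
                "dG": fit.y_,
            }
        )
        derived = tab["protein"].str.split("-").str[0] == "GLY"
        oracle = tab.loc[derived, "dG"].mean() - tab.loc[~derived, "dG"].mean()
        assert fit.substitution_effect(25) == pytest.approx(oracle, rel=1e-9)

    def test_protein_pair_epistasis_conventions(self, fit):
        marginal = fit.protein_pair_epistasis(25, 29)
        assert marginal == pytest.approx(2 * fit.coef_["ac"], rel=1e-12)
        cycle = fit.protein_pair_epistasis(25, 29, convention="double_mutant_cycle")
        assert cycle == pytest.approx(2 * marginal, rel=1e-12)

    def test_cross_interface_effect_matches_subset_refit_oracle(self, fit):
        tab = pd.DataFrame(
            {
                "protein": [g.protein.label for g in fit.genotypes_],
                "re": [g.re.label for g in fit.genotypes_],
                "dG_kcal_mol": fit.y_,
            }
        )
        derived = tab["protein"].str.split("-").str[0] == "GLY"
        f_der = fit_model(tab[derived], RE_SPEC)
        f_anc = fit_model(tab[~derived], RE_SPEC)
        for nuc in NUCS:
            oracle = f_der.state_effect(3, nuc) - f_anc.state_effect(3, nuc)
            assert fit.cross_interface_effect(25, 3, nuc) == pytest.approx(
                oracle, abs=1e-9
            )
            pair_oracle = f_der.pair_epistasis("G", nuc) - f_anc.pair_epistasis("G", nuc)
            assert fit.cross_interface_pair_effect(25, "G", nuc) == pytest.approx(
                pair_oracle, abs=1e-9
            )

    def test_cross_effects_sum_to_zero_over_states(self, fit):
        for p in (25, 26, 29):
            for site in (3, 4):
                total = sum(fit.cross_interface_effect(p, site, n) for n in NUCS)
                assert total == pytest.approx(0.0, abs=1e-9)

    def test_missing_group_raises(self):
        tab, _ = generate_landscape(random_landscape_params(2, replicates=1))
        fit = fit_model(tab, ModelSpec(("INTERCEPT", "P1")))
        with pytest.raises(ValueError, match="without term groups"):
            fit.pair_epistasis("G", "T")


class TestEncodingEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_binary_and_wyk_effects_agree(self, seed):
        tab, _ = generate_landscape(
            random_landscape_params(seed, noise_sd=0.15, replicates=2)
        )
        wyk = fit_model(tab, FULL_SPEC, "abc_wyk")
        binary = fit_model(tab, FULL_SPEC, "binary")
        for site in (3, 4):
            for n in NUCS:
                assert binary.state_effect(site, n) == pytest.approx(
                    wyk.state_effect(site, n), abs=1e-9
                )
        for s3, s4 in itertools.product(NUCS, repeat=2):
            assert binary.pair_epistasis(s3, s4) == pytest.approx(
                wyk.pair_epistasis(s3, s4), abs=1e-9
            )
        for p in (25, 26, 29):
            assert binary.substitution_effect(p) == pytest.approx(
                wyk.substitution_effect(p), abs=1e-9
            )
        for i, j in ((25, 26), (25, 29), (26, 29)):
            assert binary.protein_pair_epistasis(i, j) == pytest.approx(
                wyk.protein_pair_epistasis(i, j), abs=1e-9
            )
        for p in (25, 26, 29):
            for n in NUCS:
                assert binary.cross_interface_effect(p, 3, n) == pytest.approx(
                    wyk.cross_interface_effect(p, 3, n), abs=1e-9
                )


class TestNestedComparison:
    def test_identical_specs_give_zero_statistic(self):
        tab, _ = generate_landscape(random_landscape_params(3, noise_sd=0.2, replicates=2))
        f = fit_model(tab, RE_SPEC)
        comp = compare_nested(f, f)
        assert comp.statistic == 0.0 and comp.p_value == 1.0 and comp.df == 0

    def test_non_nested_rejected(self):
        tab, _ = generate_landscape(random_landscape_params(3, noise_sd=0.2, replicates=2))
        f1 = fit_model(tab, ModelSpec(("INTERCEPT", "P1")))
        f2 = fit_model(tab, ModelSpec(("INTERCEPT", "R1_3")))
        with pytest.raises(ValueError, match="not nested"):
            compare_nested(f1, f2)

    def test_mismatched_observations_rejected(self):
        tab, _ = generate_landscape(random_landscape_params(3, noise_sd=0.2, replicates=2))
        f1 = fit_model(tab.iloc[: len(tab) // 2], ModelSpec(("INTERCEPT",)))
        f2 = fit_model(tab, ModelSpec(("INTERCEPT", "P1")))
        with pytest.raises(ValueError, match="identical observations"):
            compare_nested(f1, f2)

    def test_power_against_strong_pair_contrast(self):
        params = LandscapeParams(
            re_pair_contrasts={
                (a, b): (0.8 if (a, b) == ("G", "T") else v)
                for (a, b), v in _gt_matrix().items()
            },
            noise_sd=0.1,
            replicates=3,
            seed=42,
        )
        tab, _ = generate_landscape(params)
        sub = tab[tab["protein"] == "glu-gly-ala"]
        simple = fit_model(sub, ModelSpec(("INTERCEPT", "R1_3", "R1_4")))
        complx = fit_model(sub, RE_SPEC)
        comp = compare_nested(simple, complx)
        assert comp.p_value < 1e-6

    def test_bonferroni_adjustment(self):
        tab, _ = generate_landscape(random_landscape_params(9, noise_sd=0.3, replicates=3))
        simple = fit_model(tab, ModelSpec(("INTERCEPT", "P1")))
        complx = fit_model(tab, ModelSpec(("INTERCEPT", "P1", "P2")))
        comp = compare_nested(simple, complx, family_size=7)
        assert comp.p_adjusted == pytest.approx(min(1.0, comp.p_value * 7))


def _gt_matrix():
    from tfscape.simulate import pair_contrast_matrix

    return pair_contrast_matrix("G", {"T": 0.8})


class TestVariancePartition:
    def test_noiseless_single_group_landscape(self):
        params = LandscapeParams(
            re_site_effects={3: {"A": 0.5, "C": -0.5, "G": 0.3, "T": -0.3}},
            noise_sd=0.0,
            replicates=1,
        )
        tab, _ = generate_landscape(params)
        vp = variance_partition(tab, RE_SPEC).set_index("group")
        assert vp.loc["R1_3", "r2_increment"] == pytest.approx(1.0, abs=1e-9)
        assert abs(vp.loc["R1_4", "r2_increment"]) < 1e-9
        assert abs(vp.loc["R2", "r2_increment"]) < 1e-9

    def test_raw_increments_telescope_to_total_r2(self):
        tab, _ = generate_landscape(random_landscape_params(31, noise_sd=0.2, replicates=3))
        vp = variance_partition(tab, FULL_SPEC)
        total = fit_model(tab, FULL_SPEC).r2_
        assert vp["r2_increment"].sum() == pytest.approx(total, rel=1e-9)

    def test_raw_increments_order_invariant_on_complete_factorial(self):
        # a group's raw-R2 increment is the same added first or last
        tab, _ = generate_landscape(random_landscape_params(37, noise_sd=0.2, replicates=3))
        for g in ("P1", "R2", "X2"):
            first = (
                fit_model(tab, ModelSpec(("INTERCEPT", g))).r2_
                - fit_model(tab, ModelSpec(("INTERCEPT",))).r2_
            )
            without = ModelSpec(tuple(x for x in FULL_SPEC.groups if x != g))
            last = fit_model(tab, FULL_SPEC).r2_ - fit_model(tab, without).r2_
            assert first == pytest.approx(last, rel=1e-9)


class TestEnergyLogo:
    def test_single_effect_landscape_logo(self):
        params = LandscapeParams(
            re_site_effects={3: {"G": 1.0, "A": -1 / 3, "C": -1 / 3, "T": -1 / 3}},
            noise_sd=0.0,
            replicates=1,
        )
        tab, _ = generate_landscape(params)
        sub = tab[tab["protein"] == "glu-gly-ala"]
        fit = fit_model(sub, RE_SPEC)
        logo = build_energy_logo(fit, protein="glu-gly-ala")
        t = logo.table
        site3 = t[t["column"] == "site3"]
        assert site3.iloc[0]["state"] == "G"  # ranked by |height|
        assert site3.iloc[0]["height"] == pytest.approx(1.0, abs=1e-9)
        assert t[t["column"] == "site4"]["height"].abs().max() < 1e-9
        assert t[t["column"] == "epistasis"]["height"].abs().max() < 1e-9

    def test_main_column_heights_sum_to_zero(self, preset_noiseless_table):
        tab, _ = preset_noiseless_table
        logo = energy_logo_for_protein(
            pd.concat([tab]* 3, ignore_index=True), "glu-gly-ala"
        )
        for col in ("site3", "site4"):
            s = logo.table[logo.table["column"] == col]["height"].sum()
            assert s == pytest.approx(0.0, abs=1e-9)

    def test_stars_require_comparisons(self):
        params = random_landscape_params(41, noise_sd=0.2, replicates=3)
        tab, _ = generate_landscape(params)
        sub = tab[tab["protein"] == "glu-gly-ala"]
        fit = fit_model(sub, RE_SPEC)
        logo = build_energy_logo(fit)  # logs a warning, stars omitted
        assert logo.table["star"].isnull().all()
        starred = build_energy_logo(fit, logo_comparisons(sub))
        assert starred.table["star"].isin([True, False]).all()

    def test_logo_equal_between_encodings(self):
        tab, _ = generate_landscape(
            random_landscape_params(43, noise_sd=0.15, replicates=3)
        )
        sub = tab[tab["protein"] == "GLY-gly-ala"]
        wyk = build_energy_logo(fit_model(sub, RE_SPEC, "abc_wyk"))
        binary = build_energy_logo(fit_model(sub, RE_SPEC, "binary"))
        merged = wyk.table.merge(
            binary.table, on=["column", "state"], suffixes=("_w", "_b")
        )
        np.testing.assert_allclose(
            merged["height_w"], merged["height_b"], atol=1e-9
        )


class TestSamplingProperties:
    def test_recovered_effect_unbiased_and_cis_calibrated(self):
        # 500 seeded per-protein simulations: the G3 effect estimate is
        # unbiased and its normal 95% CI covers the injected value ~95%
        injected = 1.0
        params_base = dict(
            re_site_effects={3: {"G": 1.0, "A": -1 / 3, "C": -1 / 3, "T": -1 / 3}},
        )
        estimates, covered = [], 0
        for seed in range(500):
            params = LandscapeParams(
                **params_base, noise_sd=0.2, replicates=3, seed=seed
            )
            tab, _ = generate_landscape(params)
            sub = tab[tab["protein"] == "glu-gly-ala"]
            fit = fit_model(sub, RE_SPEC)
            est = fit.state_effect(3, "G")
            se = fit.state_effect_se(3, "G")
            estimates.append(est)
            if est - 1.96 * se <= injected <= est + 1.96 * se:
                covered += 1
        bias = np.mean(estimates) - injected
        assert abs(bias) < 0.01
        assert 0.92 <= covered / 500 <= 0.98

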