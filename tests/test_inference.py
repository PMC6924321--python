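"""Tests for the ANOVA / AICc-selection / R^2 inference battery."""

import math

import numpy as np
import pandas as pd
import pytest

from cvmove.inference import (
    aicc_select,
    ancova_candidates,
    apply_parsimony,
    delta_models,
    dispersal_r2,
    model_frequency_table,
    one_way_anova,
    speed_linearity_covariation,
    three_way_anova,
)
from cvmove.synthetic import ExperimentConfig, gen_experiment, gen_genotype_panel


def _balanced_fixture(seed=7, g=2, r=3, status_effect=0.8, interaction=0.3):
    rng = np.random.default_rng(seed)
    rows = []
    for gi in range(g):
        for ri in range(1, r + 1):
            base = rng.normal(0, 1)
            for s in ("resident", "disperser"):
                y = base + rng.normal(0, 0.5)
                if s == "disperser":
                    y += status_effect + (interaction if gi == 1 else 0.0)
                rows.append(
                    {"genotype": f"g{gi}", "replicate": ri, "status": s, "y": y}
                )
    return pd.DataFrame(rows)


class TestThreeWayAnova:
    def test_df_column_matches_design_arithmetic(self, summary_experiment):
        # 44 genotypes x 3 replicates x 2 statuses minus one failed system
        exp, _ = summary_experiment
        tab = three_way_anova(exp.tubes, "ln_speed")
        assert tab.table["df"].tolist() == [43, 1, 43, 87, 87]
        assert tab.total_df == 261 == tab.n - 1

    def test_constant_response_gives_zero_ss(self):
        df = _balanced_fixture()
        df["y"] = 3.0
        tab = three_way_anova(df, "y")
        assert np.allclose(tab.table["ss"], 0.0, atol=1e-18)

    def test_status_f_matches_difference_based_hand_identities(self):
        # the Table-1 error structure, recomputed independently from the
        # per-system disperser-minus-resident differences d_i:
        #   SS_status = (sum d)^2 / (2m),  SS_RxS = sum_g sum (d - dbar_g)^2 / 2
        df = _balanced_fixture()
        tab = three_way_anova(df, "y").table.set_index("effect")
        w = df.pivot_table(index=["genotype", "replicate"], columns="status", values="y")
        d = w["disperser"] - w["resident"]
        m = len(d)
        ss_s = d.sum() ** 2 / (2 * m)
        dbar_g = d.groupby(level="genotype").transform("mean")
        ss_rxs = ((d - dbar_g) ** 2).sum() / 2
        g, r = 2, 3
        F = ss_s / (ss_rxs / (g * (r - 1)))
        assert tab.loc["Dispersal status", "ss"] == pytest.approx(ss_s)
        assert tab.loc["Replicate x dispersal status (genotype)", "ss"] == pytest.approx(ss_rxs)
        assert tab.loc["Dispersal status", "F"] == pytest.approx(F)

    def test_status_f_equals_paired_t_squared_without_interaction(self):
        # with the genotype x status stratum identically zero, the paired t
        # on system differences and the nested-ANOVA F coincide
        rng = np.random.default_rng(3)
        rows = []
        for gi in range(4):
            for ri in range(1, 4):
                base = rng.normal(0, 1)
                diff = 0.6  # identical for every genotype -> no interaction
                rows.append({"genotype": f"g{gi}", "replicate": ri, "status": "resident",
                             "y": base})
                rows.append({"genotype": f"g{gi}", "replicate": ri, "status": "disperser",
                             "y": base + diff + rng.normal(0, 0.3)})
        df = pd.DataFrame(rows)
        w = df.pivot_table(index=["genotype", "replicate"], columns="status", values="y")
        d = (w["disperser"] - w["resident"]).to_numpy()
        # centre genotype means to kill the interaction stratum exactly
        d_centred = d - d.reshape(4, 3).mean(axis=1).repeat(3) + d.mean()
        w["disperser"] = w["resident"] + d_centred
        df = w.stack().rename("y").reset_index()
        from scipy import stats

        tab = three_way_anova(df, "y").table.set_index("effect")
        t, _ = stats.ttest_1samp(d_centred, 0)
        # interaction SS is ~0, so the paired t's error sum of squares equals
        # the RxS stratum's; only the df normalisations differ (11 vs 8)
        assert tab.loc["Genotype x dispersal status", "ss"] == pytest.approx(0.0, abs=1e-18)
        f_anova = tab.loc["Dispersal status", "F"]
        assert f_anova == pytest.approx(t**2 * (8 / 11), rel=1e-9)

    def test_unpaired_system_is_dropped(self):
        df = _balanced_fixture(g=3)
        df = df[~((df["genotype"] == "g2") & (df["replicate"] == 3)
                  & (df["status"] == "disperser"))]
        tab = three_way_anova(df, "y")
        assert tab.n == 16  # 18 tubes minus the dropped system's pair
        assert tab.total_df == 15


class TestOneWayAnova:
    def test_hand_computed_fixture(self):
        df = pd.DataFrame(
            {"genotype": ["a"] * 3 + ["b"] * 3, "dispersal_rate": [0.1, 0.2, 0.3, 0.5, 0.6, 0.7]}
        )
        tab = one_way_anova(df).table.set_index("effect")
        # grand mean 0.4; SSB = 3*(0.2-0.4)^2 + 3*(0.6-0.4)^2 = 0.24; SSW = 0.04
        assert tab.loc["Genotype", "ss"] == pytest.approx(0.24)
        assert tab.loc["Error", "ss"] == pytest.approx(0.04)
        assert tab.loc["Genotype", "F"] == pytest.approx(0.24 / (0.04 / 4))

    def test_default_design_df(self, summary_tubes):
        systems = summary_tubes.drop_duplicates(["genotype", "replicate"])
        tab = one_way_anova(systems).table
        assert tab["df"].tolist() == [43, 87]

    def test_zero_within_group_variance(self):
        df = pd.DataFrame(
            {"genotype": ["a", "a", "b", "b"], "dispersal_rate": [0.2, 0.2, 0.5, 0.5]}
        )
        tab = one_way_anova(df).table.set_index("effect")
        assert math.isinf(tab.loc["Genotype", "F"])
        assert tab.loc["Genotype", "p"] == 0.0

    def test_single_genotype_errors(self):
        with pytest.raises(ValueError):
            one_way_anova(pd.DataFrame({"genotype": ["a"] * 3, "dispersal_rate": [0.1, 0.2, 0.3]}))


class TestAiccSelection:
    def test_candidate_set_obeys_marginality(self):
        cands = ancova_candidates()
        assert "1" in cands and len(cands) == 13
        for rhs in cands:
            terms = [t.strip() for t in rhs.split("+")]
            if "C(status):size" in terms:
                assert "C(status)" in terms and "size" in terms
            if "C(status):shape" in terms:
                assert "C(status)" in terms and "shape" in terms

    def test_aicc_small_sample_correction(self):
        # n=10, k=3 (intercept + slope + variance): AICc = AIC + 4
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=10)})
        df["y"] = 1.0 + df["x"] + rng.normal(0, 0.5, 10)
        from cvmove.inference import _ols_aicc

        fit, k, aicc = _ols_aicc("y ~ x", df)
        assert k == 3
        aic = 2 * k - 2 * fit.llf
        assert aicc == pytest.approx(aic + 4.0)

    def test_parsimony_rule_on_forced_table(self):
        table = pd.DataFrame(
            {"model": ["A", "B", "C"], "k": [5, 3, 2], "aicc": [100.0, 101.5, 103.0]}
        )
        out = apply_parsimony(table)
        assert out.loc[out["selected"], "model"].iloc[0] == "B"
        assert out["weight"].sum() == pytest.approx(1.0)
        assert out["delta"].min() == 0.0

    def test_order_invariance_and_weight_normalisation(self, summary_tubes):
        cands = ancova_candidates()
        a = aicc_select(cands, summary_tubes, "ln_speed")
        b = aicc_select(list(reversed(cands)), summary_tubes, "ln_speed")
        assert a.selected == b.selected
        assert a.table["weight"].sum() == pytest.approx(1.0)

    def test_selection_power_with_true_size_and_status_effects(self):
        # strong size effect + status offset, no shape effect, n = 262
        hits = 0
        n_rep = 20
        for s in range(n_rep):
            rng = np.random.default_rng(1000 + s)
            n = 262
            df = pd.DataFrame(
                {
                    "size": rng.normal(1500, 200, n),
                    "shape": rng.normal(2.0, 0.25, n),
                    "status": rng.permutation(["disperser", "resident"] * (n // 2)),
                }
            )
            df["ln_speed"] = (
                4.9
                + 0.0008 * (df["size"] - 1500)
                + 0.2 * (df["status"] == "disperser")
                + rng.normal(0, 0.15, n)
            )
            sel = aicc_select(ancova_candidates(), df, "ln_speed").selected
            if "size" in sel and "C(status)" in sel and "shape" not in sel:
                hits += 1
        assert hits >= int(0.9 * n_rep)


class TestDeltaModels:
    @staticmethod
    def _tubes(seed=0, coef=0.0, noise=0.1, n_geno=20):
        rng = np.random.default_rng(seed)
        rows = []
        for gi in range(n_geno):
            for ri in (1, 2):
                size_r, size_d = rng.normal(1500, 100, 2)
                shape_r, shape_d = rng.normal(2.0, 0.2, 2)
                base = rng.normal(5.0, 0.2)
                rows.append({"genotype": f"g{gi}", "replicate": ri, "status": "resident",
                             "ln_speed": base, "ln_tau": -2.8, "size": size_r, "shape": shape_r})
                rows.append({"genotype": f"g{gi}", "replicate": ri, "status": "disperser",
                             "ln_speed": base + coef * (size_d - size_r) + rng.normal(0, noise),
                             "ln_tau": -2.8, "size": size_d, "shape": shape_d})
        return pd.DataFrame(rows)

    def test_identical_statuses_select_intercept_only(self):
        df = self._tubes(coef=0.0, noise=0.0)
        df_sym = df.copy()
        wide = df_sym.pivot_table(index=["genotype", "replicate"], columns="status")
        # force disperser rows identical to residents
        res = df_sym[df_sym["status"] == "resident"].copy()
        disp = res.copy()
        disp["status"] = "disperser"
        out = delta_models(pd.concat([res, disp], ignore_index=True))
        assert out["ln_speed"].selected == "1"
        assert out["ln_tau"].selected == "1"

    def test_delta_computation_matches_hand_subtraction(self):
        df = pd.DataFrame(
            [
                {"genotype": "g", "replicate": 1, "status": "resident",
                 "ln_speed": 5.0, "ln_tau": -2.9, "size": 1400.0, "shape": 2.1},
                {"genotype": "g", "replicate": 1, "status": "disperser",
                 "ln_speed": 5.3, "ln_tau": -2.5, "size": 1550.0, "shape": 2.0},
                {"genotype": "g", "replicate": 2, "status": "resident",
                 "ln_speed": 4.8, "ln_tau": -3.0, "size": 1350.0, "shape": 2.2},
                {"genotype": "g", "replicate": 2, "status": "disperser",
                 "ln_speed": 5.0, "ln_tau": -2.8, "size": 1500.0, "shape": 2.3},
            ]
        )
        from cvmove.inference import _drop_incomplete_systems

        wide = df.pivot_table(index=["genotype", "replicate"], columns="status",
                              values=["ln_speed", "size"])
        d_speed = wide[("ln_speed", "disperser")] - wide[("ln_speed", "resident")]
        assert d_speed.tolist() == pytest.approx([0.3, 0.2])

    def test_positive_size_link_recovered(self):
        hits = 0
        for s in range(20):
            df = self._tubes(seed=s, coef=0.002, noise=0.05)
            sel = delta_models(df)["ln_speed"]
            if "d_size" in sel.selected:
                fit_tab = sel.table
                hits += 1
        assert hits >= 18


class TestDispersalR2:
    @staticmethod
    def _geno(seed=0, n=20):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "genotype": [f"g{i}" for i in range(n)],
                "activity": rng.uniform(0.4, 0.7, n),
                "speed": rng.uniform(75, 289, n),
                "tau": rng.uniform(0.039, 0.13, n),
            }
        )

    def test_collinear_predictor_gives_r2_one(self):
        geno = self._geno()
        geno["dispersal_rate"] = 0.001 * geno["speed"]
        dec = dispersal_r2(geno)
        assert dec.r2("speed") == pytest.approx(1.0)
        assert dec.r2("full") == pytest.approx(1.0)

    def test_permutation_null_mean_r2(self):
        # for a single irrelevant predictor, E[R^2] = 1/(n-1)
        n = 20
        geno = self._geno(seed=1, n=n)
        rng = np.random.default_rng(2)
        base = rng.uniform(0.1, 0.7, n)
        r2s = []
        for _ in range(200):
            geno["dispersal_rate"] = rng.permutation(base)
            dec = dispersal_r2(geno)
            r2s.append(dec.r2("speed"))
        assert np.all(np.asarray(r2s) >= 0)
        assert np.mean(r2s) == pytest.approx(1 / (n - 1), abs=0.02)

    def test_full_model_dominates_nested_models(self, summary_tubes):
        geno = (
            summary_tubes.assign(
                speed=np.exp(summary_tubes["ln_speed"]), tau=np.exp(summary_tubes["ln_tau"])
            )
            .groupby("genotype", as_index=False)
            .agg({"dispersal_rate": "mean", "activity": "mean", "speed": "mean", "tau": "mean"})
        )
        dec = dispersal_r2(geno)
        singles = [dec.r2(m) for m in ("activity", "linearity", "speed")]
        assert all(dec.r2("full") >= r for r in singles)
        assert all(0 <= r <= 1 for r in singles)

    def test_too_few_genotypes_error(self):
        with pytest.raises(ValueError):
            dispersal_r2(self._geno(n=5).assign(dispersal_rate=0.3))


class TestCovariation:
    @staticmethod
    def _means(seed=0, slope=4e-4, status_offset=0.0, noise=0.005, n_geno=44):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_geno):
            sp = rng.uniform(75, 289)
            for s in ("resident", "disperser"):
                rows.append(
                    {
                        "genotype": f"g{i}",
                        "status": s,
                        "speed": sp + rng.normal(0, 10),
                        "tau": 0.02 + slope * sp + (status_offset if s == "disperser" else 0)
                        + rng.normal(0, noise),
                    }
                )
        return pd.DataFrame(rows)

    def test_exact_linear_relation(self):
        df = self._means(noise=0.0, slope=5e-4)
        df["tau"] = 5e-4 * df["speed"]  # exactly proportional
        res = speed_linearity_covariation(df)
        assert res.slope == pytest.approx(5e-4, rel=1e-6)
        assert res.p < 1e-12

    def test_positive_coupling_recovered(self):
        signs = [speed_linearity_covariation(self._means(seed=s)).slope > 0 for s in range(20)]
        assert sum(signs) == 20

    def test_interaction_type_one_error_near_nominal(self):
        # status-symmetric generator: the slope-difference test should
        # reject at ~ the nominal 5% level
        rejections = 0
        n_rep = 400
        for s in range(n_rep):
            res = speed_linearity_covariation(self._means(seed=s, status_offset=0.0))
            rejections += res.slope_diff_p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.03)

    def test_zero_speed_variance_errors(self):
        df = self._means()
        df["speed"] = 150.0
        with pytest.raises(ValueError):
            speed_linearity_covariation(df)


class TestModelFrequencies:
    def test_all_ucvm_row(self):
        fits = pd.DataFrame(
            {
                "genotype": ["g1"] * 5,
                "status": ["resident"] * 5,
                "model": ["UCVM"] * 5,
                "selected": [True] * 5,
            }
        )
        freq = model_frequency_table(fits)
        assert freq.iloc[0][["UCVM", "RCVM", "ACVM", "RACVM"]].tolist() == [1.0, 0, 0, 0]

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        fits = pd.DataFrame(
            {
                "genotype": rng.choice(["g1", "g2", "g3"], 200),
                "status": rng.choice(["resident", "disperser"], 200),
                "model": rng.choice(["UCVM", "RCVM", "ACVM", "RACVM"], 200),
                "selected": True,
            }
        )
        freq = model_frequency_table(fits)
        assert np.allclose(freq[["UCVM", "RCVM", "ACVM", "RACVM"]].sum(axis=1), 1.0)
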