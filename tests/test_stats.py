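"""Split-plot ANOVA layer: hand-computed oracle, cross-checks against an
independent mixed-ANOVA implementation, sphericity machinery, effect
sizes, power and Sidak post-hocs."""

import numpy as np
import pandas as pd
import pytest

from pmsway.stats import (
    AnovaResult,
    analyze_measures,
    apply_correction,
    assumption_checks,
    mauchly_epsilon,
    observed_power,
    partial_eta_sq,
    pivot_measure,
    sidak_posthoc,
    split_plot_anova,
)

pg = pytest.importorskip("pingouin")


class TestSplitPlotAnova:
    def test_hand_computed_toy(self):
        """2 groups x 2 subjects x 2 conditions with exact rational SS.

        Hand decomposition (frozen): SS_group=8, SS_err_between=8,
        SS_cond=8, SS_inter=2, SS_err_within=2 -> F = 2, 8, 2 on dfs
        (1,2), (1,2), (1,2).
        """
        Y = np.array([[3.0, 5.0], [4.0, 8.0], [7.0, 9.0], [6.0, 6.0]])
        res = split_plot_anova(Y, np.array(["young", "young", "old", "old"]))
        assert res["group"].F == pytest.approx(2.0, abs=1e-10)
        assert res["condition"].F == pytest.approx(8.0, abs=1e-10)
        assert res["condition:group"].F == pytest.approx(2.0, abs=1e-10)
        assert (res["group"].df1, res["group"].df2) == (1, 2)
        assert (res["condition"].df1, res["condition"].df2) == (1, 2)

    def test_df_structure_41_subjects(self, rng):
        """23+18 subjects x 5 conditions: between df (1,39), within df (4,156)."""
        Y = rng.standard_normal((41, 5))
        groups = np.array(["young"] * 23 + ["old"] * 18)
        res = split_plot_anova(Y, groups)
        assert (res["group"].df1, res["group"].df2) == (1, 39)
        assert (res["condition"].df1, res["condition"].df2) == (4, 156)
        assert (res["condition:group"].df1, res["condition:group"].df2) == (4, 156)

    def test_matches_independent_implementation_balanced(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            Y = r.standard_normal((12, 4)) + 0.7 * r.standard_normal((12, 1))
            groups = np.array(["young"] * 6 + ["old"] * 6)
            df = pd.DataFrame(
                [{"subject": s, "cond": f"c{j}", "group": groups[s], "y": Y[s, j]}
                 for s in range(12) for j in range(4)])
            aov = pg.mixed_anova(data=df, dv="y", within="cond", subject="subject",
                                 between="group")
            res = split_plot_anova(Y, groups)
            for src, key in [("group", "group"), ("cond", "condition"),
                             ("Interaction", "condition:group")]:
                assert res[key].F == pytest.approx(
                    float(aov.loc[aov.Source == src, "F"].iloc[0]), rel=1e-9)

    def test_ss_decomposition_conserved(self, rng):
        # balanced design: effect SS are orthogonal and sum to SS_total
        Y = rng.standard_normal((12, 5)) + rng.standard_normal((12, 1))
        groups = np.array(["young"] * 6 + ["old"] * 6)
        res = split_plot_anova(Y, groups)
        ss_total = float(((Y - Y.mean()) ** 2).sum())
        parts = (res["group"].ss_effect + res["group"].ss_error
                 + res["condition"].ss_effect + res["condition:group"].ss_effect
                 + res["condition"].ss_error)
        assert parts == pytest.approx(ss_total, rel=1e-8)
        # unbalanced: the two error strata still partition SS_total exactly
        Yu = rng.standard_normal((11, 5))
        gu = np.array(["young"] * 6 + ["old"] * 5)
        ru = split_plot_anova(Yu, gu)
        ss_between_stratum = ru["group"].ss_effect + ru["group"].ss_error
        ss_within_stratum = float(((Yu - Yu.mean(axis=1, keepdims=True)) ** 2).sum())
        assert ss_between_stratum + ss_within_stratum == pytest.approx(
            float(((Yu - Yu.mean()) ** 2).sum()), rel=1e-8)

    def test_input_validation(self, rng):
        with pytest.raises(ValueError, match="2 subjects"):
            split_plot_anova(rng.standard_normal((3, 4)),
                             np.array(["a", "a", "b"]))
        Y = rng.standard_normal((6, 3))
        Y[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            split_plot_anova(Y, np.array(["a"] * 3 + ["b"] * 3))

    def test_single_group_omits_between_effect(self, rng):
        res = split_plot_anova(rng.standard_normal((8, 4)), np.zeros(8))
        assert "group" not in res and "condition" in res


class TestSphericity:
    def test_epsilons_match_independent_implementation(self, rng):
        Y = rng.standard_normal((10, 4)) @ np.diag([1.0, 1.5, 0.6, 1.2])
        df = pd.DataFrame([{"subject": s, "cond": f"c{j}", "y": Y[s, j]}
                           for s in range(10) for j in range(4)])
        p, gg, hf = mauchly_epsilon(Y)
        assert gg == pytest.approx(
            float(pg.epsilon(df, dv="y", within="cond", subject="subject", correction="gg")),
            abs=1e-10)
        assert hf == pytest.approx(
            float(pg.epsilon(df, dv="y", within="cond", subject="subject", correction="hf")),
            abs=1e-10)
        sp = pg.sphericity(df, dv="y", within="cond", subject="subject")
        # first-order vs second-order chi-square approximations
        assert p == pytest.approx(float(sp.pval), abs=0.02)

    def test_compound_symmetry_epsilon_to_one(self, rng):
        n = 4000
        subj = rng.standard_normal((n, 1))
        Y = subj + rng.standard_normal((n, 5))
        _, gg, hf = mauchly_epsilon(Y)
        assert gg > 0.99
        assert hf == 1.0

    def test_rank_one_covariance_lower_bound(self, rng):
        base = rng.standard_normal(40)
        load = np.array([1.0, -0.5, 2.0, 0.3, -1.2])
        Y = np.outer(base, load) + 1e-9 * rng.standard_normal((40, 5))
        _, gg, _ = mauchly_epsilon(Y)
        assert gg == pytest.approx(0.25, abs=1e-3)

    def test_hf_at_least_gg(self, rng):
        for seed in range(20):
            Y = np.random.default_rng(seed).standard_normal((12, 5))
            _, gg, hf = mauchly_epsilon(Y)
            assert hf >= gg - 1e-12


class TestCorrectionRule:
    base = AnovaResult("condition", F=3.0, df1=4, df2=156, p=0.02)

    def test_gg_below_threshold(self):
        out = apply_correction(self.base, mauchly_p=0.001, eps_gg=0.6, eps_hf=0.7)
        assert out.correction == "GG"
        assert out.df1_corr == pytest.approx(2.4)
        assert out.df2_corr == pytest.approx(93.6)
        assert out.p > self.base.p  # fewer dfs, less significant

    def test_hf_at_or_above_threshold(self):
        out = apply_correction(self.base, mauchly_p=0.001, eps_gg=0.9, eps_hf=0.95)
        assert out.correction == "HF"
        assert out.df1_corr == pytest.approx(4 * 0.95)

    def test_no_correction_when_mauchly_ns(self):
        out = apply_correction(self.base, mauchly_p=0.5, eps_gg=0.6, eps_hf=0.7)
        assert out.correction == "none"
        assert out.p == pytest.approx(self.base.p)

    def test_always_correct_flag(self):
        out = apply_correction(self.base, mauchly_p=0.5, eps_gg=0.6, eps_hf=0.7,
                               always_correct=True)
        assert out.correction == "GG"


class TestEffectSizeAndPower:
    def test_printed_pairings(self):
        """The published (F, df) pairs reproduce their printed eta_p2 and power."""
        assert round(partial_eta_sq(8.74, 1, 39), 2) == 0.18
        assert round(observed_power(8.74, 1, 39), 2) == 0.82
        assert round(partial_eta_sq(5.93, 1, 39), 2) == 0.13
        assert round(observed_power(5.93, 1, 39), 2) == 0.66
        assert round(partial_eta_sq(7.09, 1, 39), 2) == 0.15
        assert round(observed_power(7.09, 1, 39), 2) == 0.74
        # rounded published F (3.14 on df 4,156): pairing holds to ~0.01-0.02
        assert partial_eta_sq(3.14, 4, 156) == pytest.approx(0.08, abs=0.015)
        assert observed_power(3.14, 4, 156) == pytest.approx(0.79, abs=0.03)
        # GG-corrected dfs used directly for the interaction pairing
        assert round(partial_eta_sq(3.01, 3.45, 134.0), 2) == 0.07
        assert round(observed_power(3.01, 3.45, 134.0), 2) == 0.74

    def test_limits(self):
        assert partial_eta_sq(0.0, 4, 100) == 0.0
        assert partial_eta_sq(1e9, 4, 100) == pytest.approx(1.0, abs=1e-4)
        assert observed_power(0.0, 4, 100) == pytest.approx(0.05, abs=1e-9)

    def test_power_half_at_critical_value(self):
        from scipy import stats as st

        crit = float(st.f.ppf(0.95, 1, 2000))
        assert observed_power(crit, 1, 2000) == pytest.approx(0.5, abs=0.02)


class TestSidak:
    def test_formula_and_identical_conditions(self, rng):
        # p_raw = 0.005 with family 10 -> 0.0489
        assert 1 - (1 - 0.005) ** 10 == pytest.approx(0.04888987, abs=1e-7)
        Y = np.tile(rng.standard_normal((12, 1)), (1, 5)) + 1e-12 * rng.standard_normal((12, 5))
        out = sidak_posthoc(Y, ["ST", "DT1", "DT2", "DT3", "DT4"])
        assert len(out) == 10
        assert all(r.p_sidak > 0.5 for r in out)
        assert all(r.p_sidak >= r.p_raw for r in out)
        assert all(r.family_size == 10 for r in out)

    def test_planted_peak_pattern(self, rng):
        """Extreme-vs-peak contrasts significant; adjacent ones mostly not."""
        shape = np.array([0.0, 0.5, 1.0, 0.5, 0.0])
        Y = shape[None, :] + 0.35 * rng.standard_normal((40, 5))
        out = {(r.condition_a, r.condition_b): r for r in
               sidak_posthoc(Y, ["ST", "DT1", "DT2", "DT3", "DT4"])}
        assert out[("ST", "DT2")].p_sidak < 0.05
        assert out[("DT2", "DT4")].p_sidak < 0.05
        assert out[("DT1", "DT3")].p_sidak > 0.05  # equal planted means
        assert out[("ST", "DT2")].percent_change != 0


class TestAssumptionChecks:
    def test_gaussian_vs_heavy_tailed(self, rng):
        groups = np.array(["young"] * 10 + ["old"] * 10)
        conds = ["ST", "DT1"]
        g_rej = h_rej = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            rep_g = assumption_checks(r.standard_normal((20, 2)), groups, conds)
            rep_h = assumption_checks(r.standard_t(1, size=(20, 2)), groups, conds)
            g_rej += (rep_g.loc[rep_g.test == "normality", "shapiro_p"] < 0.05).sum()
            h_rej += (rep_h.loc[rep_h.test == "normality", "shapiro_p"] < 0.05).sum()
        assert h_rej > g_rej  # heavy tails rejected far more often
        assert g_rej / (40 * 4) < 0.15  # near-nominal on Gaussian cells

    def test_small_cells_skipped(self):
        Y = np.array([[1.0, 2.0], [2.0, 3.0], [0.5, 1.0], [1.5, 2.5]])
        rep = assumption_checks(Y, np.array(["a", "a", "b", "b"]), ["c1", "c2"])
        assert (rep["note"] == "skipped (<3 obs or constant)").all()


class TestAnalyzeMeasures:
    def _table(self, rng, effect=0.0):
        rows = []
        for s in range(16):
            grp = "young" if s < 8 else "old"
            base = rng.standard_normal()
            for ci, cond in enumerate(["ST", "DT1", "DT2", "DT3", "DT4"]):
                bump = effect * [0, 0.5, 1, 0.5, 0][ci]
                rows.append({"subject_id": f"S{s}", "group": grp, "condition": cond,
                             "pm": 1, "saen_pp": base + bump + 0.3 * rng.standard_normal(),
                             "saen_pa": rng.standard_normal(),
                             "n_crossings": 100 + rng.integers(0, 10),
                             "sigma_s": abs(rng.standard_normal())})
        return pd.DataFrame(rows)

    def test_planted_effect_found_with_posthoc(self, rng):
        eff, ph = analyze_measures(self._table(rng, effect=1.0))
        row = eff[(eff.variable == "saen_pp") & (eff.effect == "condition")].iloc[0]
        assert row.p < 0.05
        assert not ph[(ph.variable == "saen_pp")].empty

    def test_listwise_deletion(self, rng):
        tab = self._table(rng)
        tab.loc[(tab.subject_id == "S3") & (tab.condition == "DT2"), "saen_pp"] = np.nan
        with pytest.warns(RuntimeWarning, match="dropping 1 subject"):
            Y, groups, subjects, conds = pivot_measure(tab, "saen_pp", 1)
        assert Y.shape == (15, 5)
        assert "S3" not in subjects
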