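import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dorsitrack.core import MUSCLES
from dorsitrack.univariate_stats import (UnbalancedDesignError,
                                         greenhouse_geisser, mauchly,
                                         mixed_anova,
                                         posthoc_level_contrasts,
                                         within_subject_anova)

from _oracles import brute_force_mixed, brute_force_two_way_rm


def make_table(Y, groups, sexes=None, timepoint="baseline"):
    n = len(Y)
    tab = pd.DataFrame({
        "subject": [f"s{i}" for i in range(n)],
        "group": groups,
        "sex": sexes if sexes is not None else ["F"] * n,
        "age": 40.0, "wad_grade": 2, "timepoint": timepoint,
        "direction": "right"})
    for j, m in enumerate(MUSCLES[:Y.shape[1]]):
        tab[f"{m}_total"] = Y[:, j]
    return tab


def random_dataset(rng, k=5, with_sex=True):
    n1, n2 = rng.integers(3, 9, 2)
    n = n1 + n2
    g = np.array(["WAD"] * n1 + ["control"] * n2)
    s = rng.choice(["F", "M"], n) if with_sex else None
    Y = rng.normal(5, 1, (n, k)) * rng.uniform(0.5, 2, k)
    return Y, g, s


class TestMixedAnova:
    def test_constant_dv_guarded_to_zero(self):
        Y = np.full((8, 5), 3.0)
        tab = make_table(Y, ["WAD"] * 4 + ["control"] * 4)
        for r in mixed_anova(tab, "total", adjust=None):
            assert r.F == 0.0 and r.eta_p2 == 0.0

    def test_group_shift_detected_interaction_null(self):
        rng = np.random.default_rng(5)
        n = 40
        g = np.array(["WAD"] * n + ["control"] * n)
        Y = rng.normal(5, 1, (2 * n, 5)) + (g == "WAD")[:, None] * 1.5
        tab = make_table(Y, g)
        res = {r.effect: r for r in mixed_anova(tab, "total", adjust=None)}
        assert res["group"].p < 0.001
        assert res["muscle x group"].F < 3.0

    def test_matches_brute_force_oracle(self):
        """F, df and eta_p2 agree with an independent projection-matrix
        sums-of-squares computation."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            k = int(rng.integers(3, 6))
            Y, g, s = random_dataset(rng, k=k)
            tab = make_table(Y, g, s)
            res = {r.effect: r for r in mixed_anova(
                tab, "total", within_levels=MUSCLES[:k])}
            oracle = brute_force_mixed(Y, g, s)
            for name, (ss, df1, ss_err, df2) in oracle.items():
                r = res[name if name != "sex" else "sex"]
                F_ref = (ss / df1) / (ss_err / df2) if ss_err > 0 else 0.0
                assert r.F == pytest.approx(F_ref, abs=1e-8), name
                assert r.eta_p2 == pytest.approx(
                    ss / (ss + ss_err), abs=1e-8), name
                if not r.corrected:
                    assert (r.df1, r.df2) == (df1, df2)

    def test_matches_pingouin_balanced(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(0, 1, (12, 5))
        g = np.array(["WAD"] * 6 + ["control"] * 6)
        tab = make_table(Y, g)
        res = {r.effect: r for r in mixed_anova(tab, "total", adjust=None)}
        long = tab.melt(id_vars=["subject", "group"],
                        value_vars=[f"{m}_total" for m in MUSCLES],
                        var_name="muscle")
        ref = pg.mixed_anova(long, dv="value", within="muscle",
                             subject="subject", between="group").set_index("Source")
        assert res["group"].F == pytest.approx(ref.loc["group", "F"], abs=1e-8)
        assert res["muscle"].F == pytest.approx(ref.loc["muscle", "F"], abs=1e-8)
        assert res["muscle x group"].F == pytest.approx(
            ref.loc["Interaction", "F"], abs=1e-8)

    def test_missing_cells_rejected(self):
        Y = np.random.default_rng(0).normal(size=(8, 5))
        Y[2, 3] = np.nan
        tab = make_table(Y, ["WAD"] * 4 + ["control"] * 4)
        with pytest.raises(UnbalancedDesignError):
            mixed_anova(tab, "total")


class TestSphericity:
    def test_two_levels_trivially_spherical(self):
        Y = np.random.default_rng(0).normal(size=(10, 2))
        assert mauchly(Y) == (1.0, 1.0)
        assert greenhouse_geisser(Y) == 1.0

    def test_matches_pingouin_one_group(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(0, 1, (12, 4)) * np.array([1, 1, 2, 3])
        w, p = mauchly(Y)
        df = pd.DataFrame(Y)
        df["subject"] = range(12)
        long = df.melt(id_vars="subject", var_name="level")
        ref = pg.sphericity(long, dv="value", within="level", subject="subject")
        assert w == pytest.approx(ref.W, abs=1e-8)
        assert p == pytest.approx(ref.pval, abs=5e-3)
        eps_ref = pg.epsilon(long, dv="value", within="level",
                             subject="subject", correction="gg")
        assert greenhouse_geisser(Y) == pytest.approx(eps_ref, abs=1e-8)

    def test_exactly_spherical_epsilon_one(self):
        """Data constructed with an exactly identity contrast covariance
        gives epsilon = 1 to numerical precision."""
        rng = np.random.default_rng(8)
        n, k = 12, 5
        A = rng.normal(size=(n, k - 1))
        A -= A.mean(axis=0)
        Q, _ = np.linalg.qr(A)
        C = np.linalg.qr(np.vstack([np.ones(k), np.eye(k - 1, k)]).T)[0][:, 1:]
        Y = Q @ C.T
        assert greenhouse_geisser(Y) == pytest.approx(1.0, abs=1e-9)

    def test_null_type_one_rate(self):
        """Under compound symmetry the Mauchly test rejects ~5% of the
        time; under strong heterogeneity it rejects nearly always."""
        rng = np.random.default_rng(3)
        rej_null = rej_het = 0
        n_rep = 300
        for _ in range(n_rep):
            Y0 = rng.normal(0, 1, (30, 4)) + rng.normal(0, 1, (30, 1))
            rej_null += mauchly(Y0)[1] < 0.05
            Yh = rng.normal(0, 1, (30, 4)) * np.array([0.3, 1, 2, 4])
            rej_het += mauchly(Yh)[1] < 0.05
        assert 0.02 < rej_null / n_rep < 0.09
        assert rej_het / n_rep > 0.9

    @given(st.integers(0, 2**31 - 1), st.integers(3, 6))
    def test_epsilon_bounds(self, seed, k):
        rng = np.random.default_rng(seed)
        Y = rng.normal(0, 1, (k + 3, k)) * rng.uniform(0.2, 3, k)
        eps = greenhouse_geisser(Y)
        assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12


class TestPosthocContrasts:
    def test_bonferroni_definition_and_monotonicity(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(5, 1, (20, 5))
        tab = make_table(Y, ["WAD"] * 10 + ["control"] * 10)
        for c in posthoc_level_contrasts(tab, "total", adjust=None):
            assert c.p_bonferroni == pytest.approx(min(1.0, 3 * c.p_raw))
            assert c.p_bonferroni >= c.p_raw

    def test_deep_deficit_hits_superficial_vs_deep(self):
        """A planted deep-muscle reduction makes the superficial-vs-deep
        contrast the most significant one on average."""
        rng = np.random.default_rng(7)
        wins = 0
        for _ in range(30):
            n = 30
            g = np.array(["WAD"] * n + ["control"] * n)
            Y = rng.normal(6, 1.2, (2 * n, 5))
            Y[:n, 3:] -= 1.5  # Scerv, MF reduced in WAD
            tab = make_table(Y, g)
            cons = {c.contrast: c.p_raw
                    for c in posthoc_level_contrasts(tab, "total", adjust=None)}
            if cons[("superficial", "deep")] == min(cons.values()):
                wins += 1
        assert wins >= 24


class TestWithinSubjectAnova:
    def _table_two_timepoints(self, Y0, Y1):
        t0 = make_table(Y0, ["WAD"] * len(Y0))
        t1 = make_table(Y1, ["WAD"] * len(Y1), timepoint="followup")
        return pd.concat([t0, t1], ignore_index=True)

    def test_identical_timepoints_zero_f(self):
        Y = np.random.default_rng(0).normal(size=(8, 5))
        tab = self._table_two_timepoints(Y, Y.copy())
        res = {r.effect: r for r in within_subject_anova(tab, "total")}
        assert res["timepoint"].F == pytest.approx(0.0, abs=1e-20)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = int(rng.integers(5, 10))
            Y0 = rng.normal(5, 1, (n, 5))
            Y1 = rng.normal(5.5, 1, (n, 5))
            tab = self._table_two_timepoints(Y0, Y1)
            res = {r.effect: r for r in within_subject_anova(tab, "total")}
            oracle = brute_force_two_way_rm(np.stack([Y0, Y1], axis=1))
            for name, (ss, df1, ss_err, df2) in oracle.items():
                F_ref = (ss / df1) / (ss_err / df2)
                assert res[name].F == pytest.approx(F_ref, abs=1e-8), name
                assert res[name].eta_p2 == pytest.approx(
                    ss / (ss + ss_err), abs=1e-8)

    def test_matches_pingouin_two_way_rm(self):
        rng = np.random.default_rng(12)
        n = 10
        Y0 = rng.normal(5, 1, (n, 5))
        Y1 = rng.normal(6, 1, (n, 5))
        tab = self._table_two_timepoints(Y0, Y1)
        res = {r.effect: r for r in within_subject_anova(tab, "total")}
        long = tab.melt(id_vars=["subject", "timepoint"],
                        value_vars=[f"{m}_total" for m in MUSCLES],
                        var_name="muscle")
        ref = pg.rm_anova(long, dv="value", within=["timepoint", "muscle"],
                          subject="subject").set_index("Source")
        assert res["timepoint"].F == pytest.approx(
            ref.loc["timepoint", "F"], abs=1e-6)
        assert res["muscle"].F == pytest.approx(
            ref.loc["muscle", "F"], abs=1e-6)
        assert res["timepoint x muscle"].F == pytest.approx(
            ref.loc["timepoint * muscle", "F"], abs=1e-6)

    def test_unpaired_subjects_dropped(self, caplog):
        import logging
        Y = np.random.default_rng(0).normal(size=(6, 5))
        tab = self._table_two_timepoints(Y, Y + 0.5)
        tab = tab.drop(tab.index[(tab.subject == "s0")
                                 & (tab.timepoint == "followup")])
        with caplog.at_level(logging.WARNING):
            res = within_subject_anova(tab, "total")
        assert "unpaired" in caplog.text
        assert len(res) == 3

    def test_planted_followup_improvement_recovered(self):
        rng = np.random.default_rng(21)
        hits = 0
        for _ in range(20):
            n = 30
            Y0 = rng.normal(5, 1.5, (n, 5))
            Y1 = Y0 + rng.normal(0, 1.0, (n, 5))
            Y1[:, 3:] += 1.5  # deep muscles improve at follow-up
            tab = self._table_two_timepoints(Y0, Y1)
            res = {r.effect: r for r in within_subject_anova(tab, "total")}
            if res["timepoint"].p < 0.05 and res["timepoint x muscle"].p < 0.05:
                hits += 1
        assert hits >= 16
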