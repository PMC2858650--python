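"""Repeated-measures ANOVA: brute-force oracle agreement, classical
identities (t^2 = F), Greenhouse-Geisser epsilon, post-hoc machinery, and
an independent cross-check against pingouin."""

import itertools

import numpy as np
import pandas as pd
import pytest

from aepstats.anova import RepeatedMeasuresAnova, gg_epsilon
from aepstats.behavior import paired_t
from aepstats.errors import DesignError, MissingDesignError


# ---------------------------------------------------------------------------
# independent brute-force oracle: classical marginal-mean formulas
# ---------------------------------------------------------------------------

def brute_force_mixed(y):
    """SS for a (group x subject x A x B) balanced design from explicit
    marginal means.  y has shape (G, n, a, b)."""
    G, n, a, b = y.shape
    gm = y.mean()
    m_g = y.mean(axis=(1, 2, 3))
    m_gs = y.mean(axis=(2, 3))
    m_a = y.mean(axis=(0, 1, 3))
    m_b = y.mean(axis=(0, 1, 2))
    m_ga = y.mean(axis=(1, 3))
    m_gb = y.mean(axis=(1, 2))
    m_ab = y.mean(axis=(0, 1))
    m_gsa = y.mean(axis=3)
    m_gsb = y.mean(axis=2)
    m_gab = y.mean(axis=1)

    ss = {}
    ss["G"] = n * a * b * ((m_g - gm) ** 2).sum()
    ss["S(G)"] = a * b * ((m_gs - m_g[:, None]) ** 2).sum()
    ss["A"] = G * n * b * ((m_a - gm) ** 2).sum()
    ss["GA"] = n * b * ((m_ga - m_a[None, :] - m_g[:, None] + gm) ** 2).sum()
    ss["AS(G)"] = b * ((m_gsa - m_gs[:, :, None] - m_ga[:, None, :]
                        + m_g[:, None, None]) ** 2).sum()
    ss["B"] = G * n * a * ((m_b - gm) ** 2).sum()
    ss["GB"] = n * a * ((m_gb - m_b[None, :] - m_g[:, None] + gm) ** 2).sum()
    ss["BS(G)"] = a * ((m_gsb - m_gs[:, :, None] - m_gb[:, None, :]
                        + m_g[:, None, None]) ** 2).sum()
    ss["AB"] = G * n * ((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2).sum()
    ss["GAB"] = n * ((m_gab - m_ga[:, :, None] - m_gb[:, None, :]
                      - m_ab[None, :, :] + m_a[None, :, None]
                      + m_b[None, None, :] + m_g[:, None, None, None].squeeze(-1)
                      - gm) ** 2).sum()
    resid = (y - m_gsa[..., None] - m_gsb[:, :, None, :]
             - m_gab[:, None, :, :] + m_gs[..., None, None]
             + m_ga[:, None, :, None] + m_gb[:, None, None, :]
             - m_g[:, None, None, None])
    ss["ABS(G)"] = (resid ** 2).sum()
    return ss


def _long(y):
    G, n, a, b = y.shape
    rows = []
    for g, i, j, k in itertools.product(range(G), range(n), range(a),
                                        range(b)):
        rows.append(dict(subject=f"g{g}s{i}", group=g, A=j, B=k,
                         y=y[g, i, j, k]))
    return pd.DataFrame(rows)


class TestBruteForceAgreement:
    @pytest.mark.parametrize("shape", [(2, 4, 2, 3), (2, 3, 2, 2),
                                       (1, 5, 2, 3)])
    def test_all_ss_and_f_match_oracle(self, shape):
        rng = np.random.default_rng(sum(shape))
        y = rng.normal(size=shape)
        res = RepeatedMeasuresAnova(_long(y), dv="y", subject="subject",
                                    within=["A", "B"],
                                    between="group" if shape[0] > 1 else None
                                    ).fit()
        ss = brute_force_mixed(y)
        G, n, a, b = shape
        tab = res.anova_table.set_index("effect")
        checks = {"A": ("A", "AS(G)", a - 1),
                  "B": ("B", "BS(G)", b - 1),
                  "A:B": ("AB", "ABS(G)", (a - 1) * (b - 1))}
        for effect, (num, err, df1) in checks.items():
            row = tab.loc[effect]
            assert row["SS"] == pytest.approx(ss[num], abs=1e-8)
            df2 = (n * G - G) * df1
            f_ref = (ss[num] / df1) / (ss[err] / df2)
            assert row["F"] == pytest.approx(f_ref, abs=1e-8)
            eta_ref = ss[num] / (ss[num] + ss[err])
            assert row["partial_eta_sq"] == pytest.approx(eta_ref, abs=1e-10)
        if G > 1:
            row = tab.loc["group"]
            f_ref = (ss["G"] / (G - 1)) / (ss["S(G)"] / (G * (n - 1)))
            assert row["F"] == pytest.approx(f_ref, abs=1e-8)
            for effect, (num, err, df1) in {
                    "group:A": ("GA", "AS(G)", (G - 1) * (a - 1)),
                    "group:B": ("GB", "BS(G)", (G - 1) * (b - 1)),
                    "group:A:B": ("GAB", "ABS(G)",
                                  (G - 1) * (a - 1) * (b - 1))}.items():
                row = tab.loc[effect]
                df2 = (n * G - G) * df1 // (G - 1)
                f_ref = (ss[num] / df1) / (ss[err] / df2)
                assert row["F"] == pytest.approx(f_ref, abs=1e-8)

    def test_two_level_factor_f_is_paired_t_squared(self):
        rng = np.random.default_rng(1)
        rows = [dict(subject=f"s{i}", session=s, y=rng.normal() + 0.4 * s)
                for i in range(9) for s in (1, 2)]
        df = pd.DataFrame(rows)
        res = RepeatedMeasuresAnova(df, dv="y", subject="subject",
                                    within=["session"]).fit()
        piv = df.pivot(index="subject", columns="session", values="y")
        t = paired_t(piv[2].to_numpy(), piv[1].to_numpy())
        assert res.effect("session")["F"] == pytest.approx(t["t"] ** 2,
                                                           abs=1e-10)
        assert res.effect("session")["p_unc"] == pytest.approx(t["p"],
                                                               abs=1e-12)

    def test_constant_response_gives_zero_f(self):
        rows = [dict(subject=f"g{g}s{i}", group=g, session=s, y=3.5)
                for g in (1, 2) for i in range(4) for s in (1, 2, 3)]
        res = RepeatedMeasuresAnova(pd.DataFrame(rows), dv="y",
                                    subject="subject", within=["session"],
                                    between="group").fit()
        assert (res.anova_table["F"] == 0.0).all()

    def test_constant_shift_invariance(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(2, 4, 2, 3))
        a = RepeatedMeasuresAnova(_long(y), dv="y", subject="subject",
                                  within=["A", "B"], between="group").fit()
        b = RepeatedMeasuresAnova(_long(y + 11.0), dv="y", subject="subject",
                                  within=["A", "B"], between="group").fit()
        for col in ("F", "eps", "partial_eta_sq"):
            np.testing.assert_allclose(a.anova_table[col],
                                       b.anova_table[col], atol=1e-9)


class TestGreenhouseGeisser:
    def test_two_levels_epsilon_one(self):
        eps, flag = gg_epsilon(np.array([[2.3]]))
        assert eps == 1.0 and not flag

    def test_compound_symmetry_epsilon_one(self):
        # CS covariance in the original k=3 space maps to a spherical
        # contrast covariance
        from scipy.linalg import helmert
        k, sigma2, rho = 3, 2.0, 0.4
        cov = sigma2 * ((1 - rho) * np.eye(k) + rho * np.ones((k, k)))
        C = helmert(k, full=False)
        eps, _ = gg_epsilon(C @ cov @ C.T)
        assert eps == pytest.approx(1.0, abs=1e-12)

    def test_rank_one_contrast_covariance_lower_bound(self):
        eps, _ = gg_epsilon(np.diag([5.0, 0.0]))
        assert eps == pytest.approx(0.5)

    def test_degenerate_zero_covariance_flagged(self):
        eps, flag = gg_epsilon(np.zeros((2, 2)))
        assert eps == pytest.approx(0.5) and flag

    def test_epsilon_and_gg_p_match_pingouin_single_group(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        rows = [dict(subject=f"s{i}", session=s,
                     y=rng.normal() * (1 + 0.3 * s))
                for i in range(10) for s in (1, 2, 3, 4)]
        df = pd.DataFrame(rows)
        mine = RepeatedMeasuresAnova(df, dv="y", subject="subject",
                                     within=["session"]).fit()
        ref = pg.rm_anova(df, dv="y", within="session", subject="subject",
                          correction=True)
        assert mine.effect("session")["F"] == pytest.approx(
            float(ref["F"].iloc[0]))
        assert mine.effect("session")["eps"] == pytest.approx(
            float(ref["eps"].iloc[0]))
        assert mine.effect("session")["p_gg"] == pytest.approx(
            float(ref["p_GG_corr"].iloc[0]))

    def test_mixed_design_ss_f_match_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        rows = [dict(subject=f"g{g}s{i}", group=g, session=s,
                     y=rng.normal() + 0.5 * s * (g == 2))
                for g in (1, 2) for i in range(8) for s in (1, 2, 3)]
        df = pd.DataFrame(rows)
        mine = RepeatedMeasuresAnova(df, dv="y", subject="subject",
                                     within=["session"],
                                     between="group").fit()
        ref = pg.mixed_anova(df, dv="y", within="session",
                             subject="subject", between="group")
        for eff, src in (("group", "group"), ("session", "session"),
                         ("group:session", "Interaction")):
            r = ref[ref["Source"] == src].iloc[0]
            assert mine.effect(eff)["SS"] == pytest.approx(float(r["SS"]))
            assert mine.effect(eff)["F"] == pytest.approx(float(r["F"]))


class TestPosthoc:
    def _planted(self, seed=0, g2_gain=(0.0, 1.5, 3.0), noise=0.5):
        rng = np.random.default_rng(seed)
        rows = [dict(subject=f"g{g}s{i}", group=g, session=s,
                     y=(g2_gain[s - 1] if g == 2 else 0.0)
                     + rng.normal(0, noise))
                for g in (1, 2) for i in range(8) for s in (1, 2, 3)]
        return pd.DataFrame(rows)

    def test_three_sessions_three_comparisons_bonferroni(self):
        df = self._planted()
        res = RepeatedMeasuresAnova(df, dv="y", subject="subject",
                                    within=["session"],
                                    between="group").fit()
        pw = res.pairwise("session")
        assert len(pw) == 3
        assert (pw["n_comparisons"] == 3).all()
        np.testing.assert_allclose(pw["p_bonferroni"],
                                   np.minimum(1.0, pw["p_raw"] * 3))
        assert (pw["p_bonferroni"] <= 1.0).all()

    def test_two_level_factor_single_unadjusted_comparison(self):
        rng = np.random.default_rng(5)
        rows = [dict(subject=f"s{i}", session=s, y=rng.normal())
                for i in range(6) for s in (1, 2)]
        res = RepeatedMeasuresAnova(pd.DataFrame(rows), dv="y",
                                    subject="subject",
                                    within=["session"]).fit()
        pw = res.pairwise("session")
        assert len(pw) == 1
        assert pw["p_bonferroni"].iloc[0] == pytest.approx(
            pw["p_raw"].iloc[0])

    def test_simple_effects_find_group2_only_growth(self):
        df = self._planted(seed=6)
        res = RepeatedMeasuresAnova(df, dv="y", subject="subject",
                                    within=["session"],
                                    between="group").fit()
        se = res.simple_effects("session", by="group")
        se = se.set_index("slice")
        assert se.loc["group=2", "p_gg"] < 0.001
        assert se.loc["group=1", "F"] < se.loc["group=2", "F"]


class TestValidation:
    def test_missing_cell_raises(self):
        rows = [dict(subject="s0", session=1, y=1.0),
                dict(subject="s0", session=2, y=2.0),
                dict(subject="s1", session=1, y=1.0)]
        with pytest.raises(MissingDesignError):
            RepeatedMeasuresAnova(pd.DataFrame(rows), dv="y",
                                  subject="subject", within=["session"])

    def test_unequal_group_sizes_raise(self):
        rows = [dict(subject=f"g{g}s{i}", group=g, session=s, y=0.0)
                for g, n in ((1, 3), (2, 2)) for i in range(n)
                for s in (1, 2)]
        with pytest.raises(MissingDesignError):
            RepeatedMeasuresAnova(pd.DataFrame(rows), dv="y",
                                  subject="subject", within=["session"],
                                  between="group")

    def test_planted_interaction_recovered_from_peak_pipeline(self):
        # group-2-only P2 growth at the study's size and noise level:
        # the Group x Session interaction on detected peaks is significant
        import aepstats as ap
        from aepstats.peaks import build_peak_table
        plan = ap.EffectPlan(p2_gain={(2, 2): 0.5, (2, 3): 1.0})
        hits = 0
        for rep in range(5):
            cfg = ap.SimConfig(n_subjects_per_group=10, sessions=(1, 2, 3),
                               noise_sd=1.0, seed=300 + rep)
            ev, _ = ap.simulate_study_evoked(cfg, plan=plan)
            table = build_peak_table(ev, electrodes=["TP9", "IZ", "TP10"],
                                     components=("P2",))
            res = RepeatedMeasuresAnova(table, dv="amplitude",
                                        subject="subject",
                                        within=["session", "electrode"],
                                        between="group").fit()
            hits += res.effect("group:session")["p_gg"] < 0.05
        assert hits == 5
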