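"""Mixed ANOVA, pairwise tests, FDR and state-change correlations."""

import numpy as np
import pandas as pd
import pytest

from semifc import stats as st


def make_table(values: dict, region="global", index="SMP") -> pd.DataFrame:
    """values: {(subject, group, state): value}"""
    rows = [
        {"subject": s, "group": g, "state": c, "region": region,
         "index": index, "value": v}
        for (s, g, c), v in values.items()
    ]
    return pd.DataFrame(rows)


def balanced_2x2(n_per=6, g_eff=0.0, s_eff=0.0, inter=0.0, noise=1.0, seed=0):
    rng = np.random.default_rng(seed)
    vals = {}
    for gi, g in enumerate(("student", "nurse")):
        for k in range(n_per):
            sid = f"{g}{k}"
            subj = rng.normal(0, 1.0)
            for si, s in enumerate(("affective", "neutral")):
                mu = gi * g_eff + si * s_eff + gi * si * inter
                vals[(sid, g, s)] = mu + subj + noise * rng.normal()
    return make_table(vals)


class TestMixedAnova:
    def test_all_equal_gives_zero_f(self):
        df = make_table({(f"s{i}", "student" if i < 4 else "nurse", s): 1.0
                         for i in range(8) for s in ("affective", "neutral")})
        res = st.mixed_anova(df)
        assert np.allclose(res["F"], 0.0)

    def test_matches_pingouin_two_way(self):
        pg = pytest.importorskip("pingouin")
        df = balanced_2x2(n_per=8, g_eff=0.4, s_eff=0.7, inter=0.5, seed=3)
        ours = st.mixed_anova(df).set_index("effect")
        theirs = pg.mixed_anova(
            data=df, dv="value", within="state", between="group", subject="subject"
        ).set_index("Source")
        for mine, its in (("group", "group"), ("state", "state"),
                          ("group * state", "Interaction")):
            assert ours.loc[mine, "F"] == pytest.approx(theirs.loc[its, "F"], rel=1e-9)
            assert ours.loc[mine, "p"] == pytest.approx(
                theirs.loc[its, "p_unc"], rel=1e-9
            )

    def test_closed_form_cell_mean_oracle(self):
        # independent SS computation from cell means on a tiny fixture
        df = balanced_2x2(n_per=4, inter=1.2, seed=11)
        piv = df.pivot_table(index="subject", columns="state", values="value")
        groups = df.groupby("subject")["group"].first().reindex(piv.index)
        y = piv.to_numpy()
        g = (groups == "student").to_numpy().astype(int)
        grand = y.mean()
        subj = y.mean(1)
        gm = np.array([subj[g == i].mean() for i in (0, 1)])
        sm = y.mean(0)
        cm = np.array([y[g == i].mean(0) for i in (0, 1)])
        n_per, b = 4, 2
        ss_a = b * n_per * ((gm - grand) ** 2).sum()
        ss_s = b * ((subj - gm[g]) ** 2).sum()
        ss_b = 2 * n_per * ((sm - grand) ** 2).sum()
        ss_ab = n_per * ((cm - gm[:, None] - sm[None, :] + grand) ** 2).sum()
        ss_err = ((y - subj[:, None] - cm[g] + gm[g][:, None]) ** 2).sum()
        res = st.mixed_anova(df).set_index("effect")
        assert res.loc["group", "F"] == pytest.approx(
            (ss_a / 1) / (ss_s / 6), rel=1e-9
        )
        assert res.loc["state", "F"] == pytest.approx(
            (ss_b / 1) / (ss_err / 6), rel=1e-9
        )
        assert res.loc["group * state", "F"] == pytest.approx(
            (ss_ab / 1) / (ss_err / 6), rel=1e-9
        )
        assert res.loc["group * state", "np2"] == pytest.approx(
            ss_ab / (ss_ab + ss_err), rel=1e-9
        )

    def test_planted_interaction_detected(self):
        hits = 0
        for seed in range(20):
            df = balanced_2x2(n_per=10, inter=3.0, noise=0.5, seed=seed)
            res = st.mixed_anova(df).set_index("effect")
            hits += res.loc["group * state", "p"] < 0.001
        assert hits == 20

    def test_three_way_matches_explicit_decomposition(self):
        rng = np.random.default_rng(4)
        rows = []
        for gi, g in enumerate(("student", "nurse")):
            for k in range(5):
                sid = f"{g}{k}"
                subj = rng.normal()
                for si, s in enumerate(("affective", "neutral")):
                    for ri, r in enumerate(("left", "right")):
                        mu = 0.3 * gi + 0.5 * si + 0.2 * ri + 0.8 * gi * si * ri
                        rows.append({"subject": sid, "group": g, "state": s,
                                     "region": r, "index": "SMP",
                                     "value": mu + subj + 0.6 * rng.normal()})
        df = pd.DataFrame(rows)
        res = st.mixed_anova(df, within=["state", "region"]).set_index("effect")
        # oracle: explicit mean decomposition on the subject x state x region cube
        piv = df.pivot_table(index="subject", columns=["state", "region"],
                             values="value")
        y = piv.to_numpy().reshape(10, 2, 2)
        groups = df.groupby("subject")["group"].first().reindex(piv.index)
        g = (groups.to_numpy() == "student").astype(int)
        gof = np.array([0 if gi else 1 for gi in (g == 0)])
        # recompute the three-way interaction SS explicitly
        grand = y.mean()
        m_gbc = np.stack([y[g == 0].mean(0), y[g == 1].mean(0)])
        m_gb = m_gbc.mean(2); m_gc = m_gbc.mean(1)
        m_bc = y.mean(0); m_b = m_bc.mean(1); m_c = m_bc.mean(0)
        m_g = m_gbc.mean((1, 2))
        ss_abc = 5 * ((m_gbc - m_gb[:, :, None] - m_gc[:, None, :]
                       - m_bc[None] + m_g[:, None, None] + m_b[None, :, None]
                       + m_c[None, None, :] - grand) ** 2).sum()
        subj = y.mean((1, 2))
        m_sb = y.mean(2); m_sc = y.mean(1)
        gidx = (g == 0).astype(int)
        gsel = np.where(g == 1, 0, 1)
        m_gbc_of = m_gbc[np.where(g == 0, 0, 1)]
        m_gb_of = m_gb[np.where(g == 0, 0, 1)]
        m_gc_of = m_gc[np.where(g == 0, 0, 1)]
        m_g_of = m_g[np.where(g == 0, 0, 1)]
        resid = (y - m_sb[:, :, None] - m_sc[:, None, :] - m_gbc_of
                 + subj[:, None, None] + m_gb_of[:, :, None]
                 + m_gc_of[:, None, :] - m_g_of[:, None, None])
        ss_err = (resid ** 2).sum()
        f_abc = (ss_abc / 1) / (ss_err / 8)
        assert res.loc["group * state * region", "F"] == pytest.approx(f_abc, rel=1e-9)

    def test_missing_cell_rejected(self):
        df = balanced_2x2(n_per=3)
        df = df.iloc[:-1]
        with pytest.raises(ValueError, match="not complete"):
            st.mixed_anova(df)


class TestSimpleEffects:
    def test_two_level_simple_effect_equals_paired_t_squared(self):
        df = balanced_2x2(n_per=7, s_eff=0.9, seed=5)
        se = st.simple_effects(df, split_by="group").set_index("level")
        for g, sub in df.groupby("group"):
            piv = sub.pivot_table(index="subject", columns="state", values="value")
            t = st.paired_t(piv["affective"], piv["neutral"])
            assert se.loc[g, "F"] == pytest.approx(t.statistic**2, rel=1e-9)


class TestPairwise:
    def test_identical_vectors_give_zero(self):
        x = np.array([1.0, 2.0, 3.0, 2.5])
        y = x + np.array([0.1, -0.1, 0.05, -0.05])
        res = st.paired_t(x, x + 0 * y)
        assert res.statistic == 0.0 and res.effect_size == 0.0

    def test_constant_difference_rejected(self):
        with pytest.raises(ValueError):
            st.paired_t(np.array([2.0, 3.0, 4.0]), np.array([1.0, 2.0, 3.0]))

    def test_paired_matches_textbook_formula(self):
        x = np.array([5.1, 4.8, 6.0, 5.5, 5.9])
        y = np.array([4.6, 4.9, 5.2, 5.0, 5.4])
        d = x - y
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        res = st.paired_t(x, y)
        assert res.statistic == pytest.approx(t_expected, rel=1e-12)
        assert res.effect_size == pytest.approx(d.mean() / d.std(ddof=1), rel=1e-12)

    def test_independent_matches_textbook_formula(self):
        x = np.array([3.0, 4.0, 5.0, 4.5])
        y = np.array([2.0, 2.5, 3.5])
        nx, ny = 4, 3
        sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
        t_expected = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
        res = st.independent_t(x, y)
        assert res.statistic == pytest.approx(t_expected, rel=1e-12)


class TestBHFDR:
    @staticmethod
    def step_up_oracle(p):
        # classic step-up with monotonicity enforcement
        p = np.asarray(p, float)
        m = p.size
        order = np.argsort(p)
        adj = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            val = min(prev, p[i] * m / rank)
            adj[i] = val
            prev = val
        return adj

    def test_single_p_unchanged(self):
        assert st.bh_fdr([0.031])[0] == pytest.approx(0.031)

    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            st.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(st.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_matches_step_up_oracle_on_random_lists(self):
        rng = np.random.default_rng(20)
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.uniform(0, 1, m)
            np.testing.assert_allclose(st.bh_fdr(p), self.step_up_oracle(p),
                                       rtol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            st.bh_fdr([0.5, 1.2])


class TestDeltaCorrelation:
    @staticmethod
    def study_with_deltas(d_smp, d_rmssd):
        rows = []
        for i, (ds, dr) in enumerate(zip(d_smp, d_rmssd)):
            for index, aff, neu in (("SMP", 0.5 + ds, 0.5), ("RMSSD", 40 + dr, 40)):
                for state, v in (("affective", aff), ("neutral", neu)):
                    rows.append({"subject": f"s{i}", "group": "student",
                                 "state": state, "region": "global",
                                 "index": index, "value": v})
        return pd.DataFrame(rows)

    def test_perfect_negative_linear(self):
        rng = np.random.default_rng(2)
        dr = rng.standard_normal(10)
        df = self.study_with_deltas(-0.01 * dr, dr)
        out = st.delta_correlation(df, ["SMP"])
        assert out.loc[0, "r"] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_hand_computed_covariance_ratio(self):
        ds = np.array([0.1, -0.05, 0.2, 0.0, -0.1])
        dr = np.array([-3.0, 1.0, -4.0, 0.5, 2.0])
        df = self.study_with_deltas(ds, dr)
        out = st.delta_correlation(df, ["SMP"])
        expected = np.corrcoef(ds, dr)[0, 1]
        assert out.loc[0, "r"] == pytest.approx(expected, rel=1e-12)

    def test_null_deltas_stay_small_on_average(self):
        rng = np.random.default_rng(31)
        rs = []
        for _ in range(200):
            ds = rng.standard_normal(38)
            dr = rng.standard_normal(38)
            rs.append(abs(np.corrcoef(ds, dr)[0, 1]))
        # |r| under independence at n = 38 concentrates near 1/sqrt(n)
        assert np.mean(rs) < 0.2
        df = self.study_with_deltas(rng.standard_normal(38),
                                    rng.standard_normal(38))
        out = st.delta_correlation(df, ["SMP"])
        assert abs(out.loc[0, "r"]) < 0.5

    def test_zero_variance_rejected(self):
        df = self.study_with_deltas(np.zeros(5), np.arange(5.0))
        with pytest.raises(ValueError):
            st.delta_correlation(df, ["SMP"])


def test_validate_study_table_duplicates():
    df = pd.DataFrame([
        {"subject": "a", "group": "g", "state": "s", "region": "r",
         "index": "SMP", "value": 1.0},
        {"subject": "a", "group": "g", "state": "s", "region": "r",
         "index": "SMP", "value": 2.0},
    ])
    with pytest.raises(ValueError, match="duplicate"):
        st.validate_study_table(df)
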