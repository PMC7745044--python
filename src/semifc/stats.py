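"""Mixed-design statistical comparisons of FC and HRV indices.

The study design is one between-subject factor (group: student vs nurse)
crossed with one or two within-subject factors (emotional state; optionally
brain region). For balanced, complete designs the mixed ANOVA has a
closed-form sums-of-squares decomposition, which is what this module
implements:

* between stratum: effect A tested against subjects-within-groups S(A);
* within strata: each within effect W and its interaction A x W tested
  against the W x S(A) error term.

Effect sizes are partial eta squared, eta_p^2 = SS_eff / (SS_eff + SS_err).
Pairwise follow-ups use paired / independent t-tests with Cohen's d, and
multiplicity is handled with Benjamini-Hochberg step-up FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "validate_study_table",
    "mixed_anova",
    "simple_effects",
    "paired_t",
    "independent_t",
    "bh_fdr",
    "delta_correlation",
]

STUDY_COLUMNS = ["subject", "group", "state", "region", "index", "value"]


@dataclass
class TestResult:
    effect: str
    statistic: float  # F or t
    df1: float
    df2: float | None
    p: float
    effect_size: float  # partial eta squared (F) or Cohen's d (t)
    p_adjusted: float | None = None


def validate_study_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format study table for shape and duplicates."""
    missing = [c for c in STUDY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"study table is missing columns {missing}")
    dup = df.duplicated(subset=["subject", "state", "region", "index"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate cell for subject={row['subject']!r}, state={row['state']!r}, "
            f"region={row['region']!r}, index={row['index']!r}"
        )
    if not np.all(np.isfinite(df["value"].to_numpy(dtype=float))):
        raise ValueError("study table contains non-finite values")
    return df


def _balanced_cube(
    df: pd.DataFrame, dv: str, subject: str, between: str, within: list[str]
):
    """Pivot to Y[subject, w1(, w2)] plus per-subject group labels."""
    subjects = sorted(df[subject].unique())
    levels = [sorted(df[w].unique()) for w in within]
    groups = df.groupby(subject)[between].first()
    if groups.index.tolist() != subjects:
        groups = groups.reindex(subjects)
    shape = [len(subjects)] + [len(lv) for lv in levels]
    y = np.full(shape, np.nan)
    idx = {s: i for i, s in enumerate(subjects)}
    lvl_idx = [{v: i for i, v in enumerate(lv)} for lv in levels]
    for _, row in df.iterrows():
        key = (idx[row[subject]],) + tuple(
            lvl_idx[k][row[w]] for k, w in enumerate(within)
        )
        y[key] = row[dv]
    if np.isnan(y).any():
        miss = np.argwhere(np.isnan(y))[0]
        raise ValueError(
            f"design not complete: subject {subjects[miss[0]]!r} lacks cell "
            + ", ".join(f"{w}={levels[k][miss[k + 1]]!r}" for k, w in enumerate(within))
        )
    g_labels = groups.to_numpy()
    g_names = sorted(pd.unique(g_labels))
    counts = {g: int((g_labels == g).sum()) for g in g_names}
    if len(set(counts.values())) > 1:
        raise ValueError(f"unbalanced group sizes {counts}")
    return y, g_labels, g_names, levels


def mixed_anova(
    df: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    between: str = "group",
    within: list[str] | str = "state",
) -> pd.DataFrame:
    """Balanced mixed-design ANOVA (1 between x 1-2 within factors).

    Returns a table with F, degrees of freedom, p and partial eta squared
    for every main effect and interaction.
    """
    if isinstance(within, str):
        within = [within]
    if not 1 <= len(within) <= 2:
        raise ValueError("mixed_anova supports 1 or 2 within factors")
    y, g_labels, g_names, levels = _balanced_cube(df, dv, subject, between, within)
    n_subj = y.shape[0]
    a = len(g_names)
    n_per = n_subj // a
    w_sizes = [len(lv) for lv in levels]
    cells_per_subj = int(np.prod(w_sizes))

    grand = y.mean()
    subj_mean = y.reshape(n_subj, -1).mean(axis=1)
    g_of = np.array([g_names.index(g) for g in g_labels])
    group_mean = np.array([subj_mean[g_of == gi].mean() for gi in range(a)])

    rows = []

    def add(effect, ss, df1, ss_err, df2):
        ms, ms_e = ss / df1, ss_err / df2
        f = ms / ms_e if ms_e > 0 else 0.0
        p = float(sps.f.sf(f, df1, df2)) if ms_e > 0 else 1.0
        np2 = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
        rows.append(
            {"effect": effect, "F": f, "df1": df1, "df2": df2, "p": p, "np2": np2,
             "SS": ss, "SS_error": ss_err}
        )

    # between stratum
    ss_a = cells_per_subj * n_per * ((group_mean - grand) ** 2).sum()
    ss_s = cells_per_subj * ((subj_mean - group_mean[g_of]) ** 2).sum()
    add(between, ss_a, a - 1, ss_s, n_subj - a)

    def axis_mean(arr, keep_axes):
        all_axes = tuple(range(arr.ndim))
        drop = tuple(ax for ax in all_axes if ax not in keep_axes)
        return arr.mean(axis=drop) if drop else arr

    for k, w in enumerate(within):
        b = w_sizes[k]
        other = cells_per_subj // b
        wk_axis = 1 + k
        m_w = axis_mean(y, (wk_axis,))  # (b,)
        m_sw = axis_mean(y, (0, wk_axis))  # (n_subj, b)
        m_gw = np.stack([m_sw[g_of == gi].mean(axis=0) for gi in range(a)])  # (a, b)
        ss_w = n_subj * other * ((m_w - grand) ** 2).sum()
        ss_aw = n_per * other * (
            (m_gw - group_mean[:, None] - m_w[None, :] + grand) ** 2
        ).sum()
        ss_err = other * (
            (m_sw - subj_mean[:, None] - m_gw[g_of] + group_mean[g_of][:, None]) ** 2
        ).sum()
        df_err = (n_subj - a) * (b - 1)
        add(w, ss_w, b - 1, ss_err, df_err)
        add(f"{between} * {w}", ss_aw, (a - 1) * (b - 1), ss_err, df_err)

    if len(within) == 2:
        b, c = w_sizes
        m_bc = y.mean(axis=0)  # (b, c)
        m_b = m_bc.mean(axis=1)
        m_c = m_bc.mean(axis=0)
        m_gbc = np.stack([y[g_of == gi].mean(axis=0) for gi in range(a)])  # (a, b, c)
        m_gb = m_gbc.mean(axis=2)
        m_gc = m_gbc.mean(axis=1)
        ss_bc = n_subj * (
            (m_bc - m_b[:, None] - m_c[None, :] + grand) ** 2
        ).sum()
        ss_abc = n_per * (
            (
                m_gbc
                - m_gb[:, :, None]
                - m_gc[:, None, :]
                - m_bc[None, :, :]
                + group_mean[:, None, None]
                + m_b[None, :, None]
                + m_c[None, None, :]
                - grand
            )
            ** 2
        ).sum()
        m_sb = y.mean(axis=2)
        m_sc = y.mean(axis=1)
        resid = (
            y
            - m_sb[:, :, None]
            - m_sc[:, None, :]
            - m_gbc[g_of]
            + subj_mean[:, None, None]
            + m_gb[g_of][:, :, None]
            + m_gc[g_of][:, None, :]
            - group_mean[g_of][:, None, None]
        )
        ss_err_bc = (resid**2).sum()
        df_err_bc = (n_subj - a) * (b - 1) * (c - 1)
        name = f"{within[0]} * {within[1]}"
        add(name, ss_bc, (b - 1) * (c - 1), ss_err_bc, df_err_bc)
        add(f"{between} * {name}", ss_abc, (a - 1) * (b - 1) * (c - 1), ss_err_bc, df_err_bc)

    return pd.DataFrame(rows)


def simple_effects(
    df: pd.DataFrame,
    split_by: str,
    dv: str = "value",
    subject: str = "subject",
    within: str = "state",
) -> pd.DataFrame:
    """Follow-up one-way repeated-measures ANOVA of ``within`` at each level
    of ``split_by`` (the usual decomposition of a significant interaction)."""
    out = []
    for level, sub in df.groupby(split_by):
        piv = sub.pivot_table(index=subject, columns=within, values=dv)
        if piv.isna().any().any():
            raise ValueError(f"incomplete within-subject data at {split_by}={level!r}")
        y = piv.to_numpy()
        n, b = y.shape
        grand = y.mean()
        ss_w = n * ((y.mean(axis=0) - grand) ** 2).sum()
        ss_err = (
            (y - y.mean(axis=0)[None, :] - y.mean(axis=1)[:, None] + grand) ** 2
        ).sum()
        df1, df2 = b - 1, (n - 1) * (b - 1)
        f = (ss_w / df1) / (ss_err / df2) if ss_err > 0 else 0.0
        p = float(sps.f.sf(f, df1, df2)) if ss_err > 0 else 1.0
        out.append(
            {
                "level": level,
                "effect": within,
                "F": f,
                "df1": df1,
                "df2": df2,
                "p": p,
                "np2": ss_w / (ss_w + ss_err) if ss_w + ss_err > 0 else 0.0,
            }
        )
    return pd.DataFrame(out)


def paired_t(x: np.ndarray, y: np.ndarray, label: str = "paired") -> TestResult:
    """Paired t-test; Cohen's d = mean(diff) / sd(diff)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.all(diff == 0):  # identical vectors: no effect, not degenerate
            return TestResult(label, 0.0, float(x.size - 1), None, 1.0, 0.0)
        raise ValueError("zero variance of paired differences")
    t, p = sps.ttest_rel(x, y)
    d = diff.mean() / sd
    return TestResult(label, float(t), float(x.size - 1), None, float(p), float(d))


def independent_t(x: np.ndarray, y: np.ndarray, label: str = "independent") -> TestResult:
    """Two-sample t-test (pooled SD); Cohen's d with pooled SD."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    t, p = sps.ttest_ind(x, y)
    d = (x.mean() - y.mean()) / np.sqrt(sp2)
    return TestResult(label, float(t), float(nx + ny - 2), None, float(p), float(d))


def bh_fdr(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[1]


def delta_correlation(
    df: pd.DataFrame,
    indices: list[str],
    against: str = "RMSSD",
    state_a: str = "affective",
    state_b: str = "neutral",
    region: str = "global",
) -> pd.DataFrame:
    """Pearson r between per-subject state changes of FC indices and HRV.

    For each subject, Delta = value(state_a) - value(state_b); correlations
    of each index's Delta with the ``against`` index's Delta are computed
    across all subjects (groups pooled) and BH-adjusted as one family.
    """
    def deltas(index_name: str) -> pd.Series:
        sub = df[(df["index"] == index_name) & (df["region"] == region)]
        piv = sub.pivot_table(index="subject", columns="state", values="value")
        for st in (state_a, state_b):
            if st not in piv.columns or piv[st].isna().any():
                raise ValueError(f"missing {st!r} values for index {index_name!r}")
        return piv[state_a] - piv[state_b]

    d_ref = deltas(against)
    rows = []
    for name in indices:
        d = deltas(name).reindex(d_ref.index)
        if d.std(ddof=1) == 0 or d_ref.std(ddof=1) == 0:
            raise ValueError(f"zero-variance state change for {name!r} or {against!r}")
        r, p = sps.pearsonr(d.to_numpy(), d_ref.to_numpy())
        rows.append({"index": name, "r": float(r), "p": float(p), "n": int(d.size)})
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_fdr(out["p"].to_numpy())
    return out
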