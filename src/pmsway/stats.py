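"""Split-plot (mixed-design) repeated-measures ANOVA layer.

One between-subjects factor (age group) crosses one within-subjects
factor (dual-task condition).  For every outcome variable and principal
movement the module reports, per effect, the F statistic with its two
error strata (subjects-within-group for the between effect; condition x
subjects-within-group for the within and interaction effects), Mauchly's
sphericity test with Greenhouse-Geisser / Huynh-Feldt epsilon, the
corrected p-value (GG when eps_GG < 0.75, HF otherwise, applied only
when Mauchly rejects), partial eta squared, observed power from the
noncentral F distribution (lambda = F * df1, the convention of standard
statistics packages, on corrected dfs), and Sidak-corrected pairwise
condition contrasts for significant omnibus effects.

Within- and interaction sums of squares are Type III (sum-to-zero
coding, each term adjusted for all others), so unequal group sizes are
handled the way mainstream statistics packages do.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as st

__all__ = [
    "AnovaResult",
    "PosthocResult",
    "split_plot_anova",
    "mauchly_epsilon",
    "apply_correction",
    "partial_eta_sq",
    "observed_power",
    "sidak_posthoc",
    "assumption_checks",
    "analyze_measures",
    "pivot_measure",
]

MEASURE_VARIABLES = ("saen_pp", "saen_pa", "n_crossings", "sigma_s")


@dataclass
class AnovaResult:
    """One effect's test: F, error strata dfs, sphericity correction, size, power."""

    effect: str  # 'condition', 'group', 'condition:group'
    F: float
    df1: float
    df2: float
    p: float
    ss_effect: float = float("nan")
    ss_error: float = float("nan")
    epsilon_gg: float = float("nan")
    epsilon_hf: float = float("nan")
    mauchly_p: float = float("nan")
    correction: str = "none"
    df1_corr: float = float("nan")
    df2_corr: float = float("nan")
    eta_p2: float = float("nan")
    power: float = float("nan")


@dataclass
class PosthocResult:
    """One Sidak-corrected pairwise condition contrast."""

    condition_a: str
    condition_b: str
    mean_a: float
    mean_b: float
    mean_diff: float
    percent_change: float
    p_raw: float
    p_sidak: float
    family_size: int


def pivot_measure(
    table: pd.DataFrame, variable: str, pm: int, conditions: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Wide (subjects x conditions) slice of one variable/PM with listwise deletion.

    Subjects with any missing or non-finite cell are dropped (counts are
    reported via a warning).  Returns (Y, groups, subjects, conditions).
    """
    sl = table[table["pm"] == pm]
    if conditions is None:
        conditions = sorted(sl["condition"].unique(), key=list(sl["condition"].unique()).index)
    wide = sl.pivot_table(index="subject_id", columns="condition", values=variable, aggfunc="mean")
    wide = wide.reindex(columns=conditions)
    complete = np.isfinite(wide.to_numpy(float)).all(axis=1)
    n_drop = int((~complete).sum())
    if n_drop:
        warnings.warn(f"{variable}/PM{pm}: dropping {n_drop} subject(s) with undefined cells",
                      RuntimeWarning, stacklevel=2)
    wide = wide.loc[complete]
    grp_map = sl.drop_duplicates("subject_id").set_index("subject_id")["group"]
    groups = grp_map.reindex(wide.index).to_numpy()
    return wide.to_numpy(float), groups, list(wide.index), conditions


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    if X.shape[1] == 0:
        return float(y @ y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def split_plot_anova(
    Y: np.ndarray, groups: np.ndarray, alpha: float = 0.05
) -> dict[str, AnovaResult]:
    """Two-strata ANOVA on a (subjects x conditions) response array.

    Between stratum: the group effect is tested on subject means against
    subjects-within-group variation.  Within stratum: subject-centered
    responses are regressed on sum-coded condition and group-by-condition
    designs; Type III sums of squares come from model comparisons and
    are tested against the condition-by-subjects-within-group residual.
    """
    Y = np.asarray(Y, float)
    groups = np.asarray(groups)
    if Y.ndim != 2:
        raise ValueError("Y must be subjects x conditions")
    n, c = Y.shape
    if not np.isfinite(Y).all():
        raise ValueError("split_plot_anova requires complete data; see pivot_measure")
    levels = list(dict.fromkeys(groups))
    g = len(levels)
    if any(np.sum(groups == lv) < 2 for lv in levels):
        raise ValueError("need at least 2 subjects per group")

    results: dict[str, AnovaResult] = {}

    # --- between stratum: subject means ---------------------------------
    m = Y.mean(axis=1)
    grand = m.mean()
    ss_err_b = 0.0
    ss_group = 0.0
    for lv in levels:
        sel = groups == lv
        ss_group += c * sel.sum() * (m[sel].mean() - grand) ** 2
        ss_err_b += c * float(((m[sel] - m[sel].mean()) ** 2).sum())
    df_err_b = n - g
    if g > 1:
        df_g = g - 1
        F_g = (ss_group / df_g) / (ss_err_b / df_err_b)
        results["group"] = AnovaResult(
            "group", F_g, df_g, df_err_b, float(st.f.sf(F_g, df_g, df_err_b)),
            ss_effect=ss_group, ss_error=ss_err_b,
        )

    # --- within stratum: subject-centered responses ---------------------
    Z = (Y - m[:, None]).ravel()
    cond_idx = np.tile(np.arange(c), n)
    # sum-to-zero condition coding
    Dc = np.zeros((n * c, c - 1))
    for l in range(c - 1):
        Dc[:, l] = (cond_idx == l).astype(float) - (cond_idx == c - 1)
    # sum-to-zero group coding, expanded to rows
    Ag = np.zeros((n, g - 1))
    for l in range(g - 1):
        Ag[:, l] = (groups == levels[l]).astype(float) - (groups == levels[-1])
    Ag_rows = np.repeat(Ag, c, axis=0)
    Di = np.einsum("ij,ik->ijk", Ag_rows, Dc).reshape(n * c, -1) if g > 1 else np.zeros((n * c, 0))

    X_full = np.hstack([Dc, Di])
    rss_full = _rss(Z, X_full)
    df_err_w = (n - g) * (c - 1)
    mse_w = rss_full / df_err_w

    ss_cond = _rss(Z, Di) - rss_full
    df_c = c - 1
    F_c = (ss_cond / df_c) / mse_w
    results["condition"] = AnovaResult(
        "condition", F_c, df_c, df_err_w, float(st.f.sf(F_c, df_c, df_err_w)),
        ss_effect=ss_cond, ss_error=rss_full,
    )
    if g > 1:
        ss_int = _rss(Z, Dc) - rss_full
        df_i = (g - 1) * (c - 1)
        F_i = (ss_int / df_i) / mse_w
        results["condition:group"] = AnovaResult(
            "condition:group", F_i, df_i, df_err_w, float(st.f.sf(F_i, df_i, df_err_w)),
            ss_effect=ss_int, ss_error=rss_full,
        )
    return results


def _orthonormal_contrasts(c: int) -> np.ndarray:
    """(c-1) x c orthonormal rows, each orthogonal to the unit vector."""
    H = np.zeros((c - 1, c))
    for i in range(c - 1):
        H[i, : i + 1] = 1.0
        H[i, i + 1] = -(i + 1)
        H[i] /= np.linalg.norm(H[i])
    return H


def mauchly_epsilon(Y: np.ndarray, groups: np.ndarray | None = None) -> tuple[float, float, float]:
    """Mauchly's sphericity test and GG/HF epsilons.

    The within-subject covariance is pooled across groups (each group's
    rows centered on its own mean), projected onto orthonormal contrasts
    ``C``; Mauchly's ``W = det(M) / (tr(M)/(c-1))**(c-1)`` with
    ``M = C S C'`` is referred to the standard chi-square approximation
    with error df ``N - g``.  ``eps_GG`` comes from the eigenvalues of
    ``M``; ``eps_HF`` is the small-sample adjustment of ``eps_GG``
    capped at 1.  Returns ``(mauchly_p, eps_gg, eps_hf)``.
    """
    Y = np.asarray(Y, float)
    n, c = Y.shape
    if c < 3:
        return float("nan"), 1.0, 1.0
    if groups is None:
        groups = np.zeros(n)
    levels = list(dict.fromkeys(groups))
    g = len(levels)
    S = np.zeros((c, c))
    for lv in levels:
        R = Y[groups == lv]
        R = R - R.mean(axis=0)
        S += R.T @ R
    d_err = n - g
    S /= d_err
    C = _orthonormal_contrasts(c)
    M = C @ S @ C.T
    lam = np.clip(np.linalg.eigvalsh(M), 0.0, None)
    tr = lam.sum()
    if tr <= 0 or lam.max() <= 0:
        warnings.warn("singular within-subject covariance; epsilon at lower bound",
                      RuntimeWarning, stacklevel=2)
        return float("nan"), 1.0 / (c - 1), 1.0 / (c - 1)
    eps_gg = float(tr**2 / ((c - 1) * (lam**2).sum()))
    # small-sample (Huynh-Feldt) adjustment, group-corrected, capped at 1
    num = (d_err + 1) * (c - 1) * eps_gg - 2
    den = (c - 1) * (d_err - (c - 1) * eps_gg)
    eps_hf = float(min(1.0, num / den)) if den > 0 else 1.0
    eps_hf = max(eps_hf, eps_gg)

    detM = float(np.prod(lam))
    if detM <= 0:
        warnings.warn("rank-deficient contrast covariance; Mauchly p undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan"), eps_gg, eps_hf
    W = detM / (tr / (c - 1)) ** (c - 1)
    q = c - 1
    f_corr = 1.0 - (2 * q**2 + q + 2) / (6.0 * q * d_err)
    chi2 = -f_corr * d_err * np.log(W)
    df_w = q * (q + 1) // 2 - 1
    p = float(st.chi2.sf(chi2, df_w))
    return p, eps_gg, eps_hf


def apply_correction(
    result: AnovaResult,
    mauchly_p: float,
    eps_gg: float,
    eps_hf: float,
    rule_threshold: float = 0.75,
    alpha: float = 0.05,
    always_correct: bool = False,
) -> AnovaResult:
    """Apply the GG/HF df correction when sphericity is rejected.

    Rule: if Mauchly's p < alpha (or ``always_correct``), scale both dfs
    by eps_GG when eps_GG < ``rule_threshold``, else by eps_HF, and
    recompute the p-value; otherwise leave the uncorrected test.
    """
    out = AnovaResult(**{**result.__dict__})
    out.mauchly_p = mauchly_p
    out.epsilon_gg = eps_gg
    out.epsilon_hf = eps_hf
    correct = always_correct or (np.isfinite(mauchly_p) and mauchly_p < alpha)
    if correct:
        if eps_gg < rule_threshold:
            eps, out.correction = eps_gg, "GG"
        else:
            eps, out.correction = eps_hf, "HF"
        out.df1_corr = eps * result.df1
        out.df2_corr = eps * result.df2
        out.p = float(st.f.sf(result.F, out.df1_corr, out.df2_corr))
    else:
        out.correction = "none"
        out.df1_corr, out.df2_corr = result.df1, result.df2
    return out


def partial_eta_sq(F: float, df1: float, df2: float) -> float:
    """Partial eta squared from the F statistic: F*df1 / (F*df1 + df2)."""
    if F < 0:
        raise ValueError("F must be non-negative")
    return float(F * df1 / (F * df1 + df2))


def observed_power(F: float, df1: float, df2: float, alpha: float = 0.05) -> float:
    """Post-hoc power: noncentral-F tail beyond the alpha critical value.

    Noncentrality lambda = F*df1 (the convention of standard statistics
    packages); corrected dfs should be passed when a sphericity
    correction was applied.  F = 0 returns the alpha floor.
    """
    if F < 0:
        raise ValueError("F must be non-negative")
    crit = st.f.ppf(1 - alpha, df1, df2)
    lam = F * df1
    if lam == 0:  # central case: scipy's ncf is unreliable at nc=0
        return float(alpha)
    return float(st.ncf.sf(crit, df1, df2, lam))


def sidak_posthoc(
    Y: np.ndarray, conditions: list[str], alpha: float = 0.05,
    family_size: int | None = None,
) -> list[PosthocResult]:
    """All pairwise condition contrasts (paired t-tests), Sidak-corrected.

    ``p_sidak = 1 - (1 - p_raw)**k`` with family size ``k`` defaulting
    to the number of pairs; percent change is taken on condition means.
    """
    Y = np.asarray(Y, float)
    c = Y.shape[1]
    pairs = [(a, b) for a in range(c) for b in range(a + 1, c)]
    k = family_size if family_size is not None else len(pairs)
    out = []
    for a, b in pairs:
        diff = Y[:, b] - Y[:, a]
        t, p = st.ttest_rel(Y[:, b], Y[:, a])
        ma, mb = float(Y[:, a].mean()), float(Y[:, b].mean())
        pct = float("nan") if ma == 0 else 100.0 * (mb - ma) / ma
        out.append(PosthocResult(
            conditions[a], conditions[b], ma, mb, mb - ma, pct,
            float(p), float(1 - (1 - p) ** k), k,
        ))
    return out


def assumption_checks(
    Y: np.ndarray, groups: np.ndarray, conditions: list[str]
) -> pd.DataFrame:
    """Advisory normality (Lilliefors KS, Shapiro-Wilk) and Levene checks.

    One row per group x condition cell with both normality p-values,
    plus one row per condition for Levene's test (center = mean) across
    groups.  Cells with fewer than 3 observations are skipped.
    """
    from statsmodels.stats.diagnostic import lilliefors

    Y = np.asarray(Y, float)
    rows = []
    levels = list(dict.fromkeys(groups))
    for ci, cond in enumerate(conditions):
        for lv in levels:
            cell = Y[np.asarray(groups) == lv, ci]
            if cell.size < 3 or np.allclose(cell, cell[0]):
                rows.append({"condition": cond, "group": lv, "test": "normality",
                             "ks_p": float("nan"), "shapiro_p": float("nan"),
                             "note": "skipped (<3 obs or constant)"})
                continue
            _, ks_p = lilliefors(cell, dist="norm")
            _, sw_p = st.shapiro(cell)
            rows.append({"condition": cond, "group": lv, "test": "normality",
                         "ks_p": float(ks_p), "shapiro_p": float(sw_p), "note": ""})
        if len(levels) > 1:
            cells = [Y[np.asarray(groups) == lv, ci] for lv in levels]
            if all(cl.size >= 3 for cl in cells):
                _, lev_p = st.levene(*cells, center="mean")
                rows.append({"condition": cond, "group": "all", "test": "levene",
                             "ks_p": float("nan"), "shapiro_p": float("nan"),
                             "levene_p": float(lev_p), "note": ""})
    return pd.DataFrame(rows)


@dataclass
class MeasureAnalysis:
    """Full inferential output for one variable x PM."""

    variable: str
    pm: int
    n_subjects: int
    results: dict[str, AnovaResult]
    posthoc: dict[str, list[PosthocResult]] = field(default_factory=dict)


def analyze_measures(
    table: pd.DataFrame,
    variables: tuple[str, ...] = MEASURE_VARIABLES,
    conditions: list[str] | None = None,
    alpha: float = 0.05,
    rule_threshold: float = 0.75,
    always_correct: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the whole inferential layer on a tidy measure table.

    Per variable x PM: split-plot ANOVA, sphericity correction of the
    within-subject effects, partial eta squared and observed power (on
    corrected dfs), and Sidak post-hocs for significant condition
    effects.  Returns (effects table, post-hoc table).
    """
    eff_rows, ph_rows = [], []
    for variable in variables:
        for pm in sorted(table["pm"].unique()):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                Y, groups, subjects, conds = pivot_measure(table, variable, pm, conditions)
            if Y.shape[0] < 4:
                continue
            single_group = len(set(groups)) < 2
            res = split_plot_anova(Y, groups if not single_group else np.zeros(len(groups)))
            mau_p, e_gg, e_hf = mauchly_epsilon(Y, groups)
            for name in list(res):
                r = res[name]
                if name in ("condition", "condition:group"):
                    r = apply_correction(r, mau_p, e_gg, e_hf, rule_threshold, alpha,
                                         always_correct)
                else:
                    r.df1_corr, r.df2_corr = r.df1, r.df2
                r.eta_p2 = partial_eta_sq(r.F, r.df1, r.df2)
                r.power = observed_power(r.F, r.df1_corr, r.df2_corr, alpha)
                res[name] = r
                eff_rows.append({"variable": variable, "pm": pm, "effect": name,
                                 "n_subjects": Y.shape[0], **r.__dict__})
            if res["condition"].p < alpha:
                for ph in sidak_posthoc(Y, conds, alpha):
                    ph_rows.append({"variable": variable, "pm": pm, **ph.__dict__})
    return pd.DataFrame(eff_rows), pd.DataFrame(ph_rows)
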