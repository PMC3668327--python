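"""The study's statistical surface.

Group/day repeated-measures analysis of the sleep-architecture variables:
a multivariate Wilks'-lambda test per variable subgroup (between/within
cross-product matrices, Rao's F approximation), univariate mixed-model
F tests as follow-ups, and Bonferroni-corrected contrasts (each
post-shock day vs baseline within group; shocked vs non-shocked per
day).  Plus pooled-variance t-tests, Pearson/Spearman correlations (no
multiplicity correction, as in the original analysis) and OLS variance
explained.

No sphericity correction is applied to the univariate within-subject
tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

NOMINAL_ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test: statistic, degrees of freedom, p-value."""

    statistic: float
    df: tuple
    p: float
    tail: str = "two"
    correction: str = "none"
    adjusted_alpha: float = NOMINAL_ALPHA
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p < self.adjusted_alpha


def bonferroni_alpha(n_contrasts: int, alpha: float = NOMINAL_ALPHA) -> float:
    """Per-contrast alpha keeping the family-wise error at ``alpha``."""
    if n_contrasts < 1:
        raise ValueError("need at least one contrast")
    return alpha / n_contrasts


def ttest_independent(x, y, tail: str = "two") -> TestResult:
    """Pooled-variance two-sample t-test, one- or two-tailed.

    The one-tailed p tests the alternative mean(x) > mean(y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    res = sps.ttest_ind(x, y, equal_var=True)
    df = x.size + y.size - 2
    if tail == "two":
        p = float(res.pvalue)
    elif tail == "one":
        p = float(res.pvalue / 2 if res.statistic > 0 else 1 - res.pvalue / 2)
    else:
        raise ValueError(f"tail must be 'one' or 'two', got {tail!r}")
    return TestResult(statistic=float(res.statistic), df=(df,), p=p, tail=tail)


def ttest_paired(x, y, tail: str = "two") -> TestResult:
    """Paired t-test (used for day-vs-baseline contrasts)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("paired samples must have equal length n >= 2")
    res = sps.ttest_rel(x, y)
    p = float(res.pvalue)
    if tail == "one":
        p = p / 2 if res.statistic > 0 else 1 - p / 2
    return TestResult(statistic=float(res.statistic), df=(x.size - 1,), p=p, tail=tail)


def correlation(x, y, method: str = "pearson") -> TestResult:
    """Pearson or Spearman correlation with a two-tailed p-value.

    Spearman is Pearson on average ranks (ties averaged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("correlation inputs must be finite")
    if method == "pearson":
        res = sps.pearsonr(x, y)
    elif method == "spearman":
        res = sps.spearmanr(x, y)
    else:
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    r = float(res.statistic)
    return TestResult(statistic=r, df=(x.size - 2,), p=float(res.pvalue), extra={"r": r})


def variance_explained(x, y) -> float:
    """Coefficient of determination of the OLS fit y ~ x.

    Equals the squared Pearson r for a simple linear regression; NaN with
    a warning when x is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0:
        warnings.warn("x is constant; r^2 undefined", stacklevel=2)
        return float("nan")
    res = sps.linregress(x, y)
    return float(res.rvalue**2)


# ---------------------------------------------------------------------------
# Multivariate repeated-measures analysis
# ---------------------------------------------------------------------------


def wilks_test(Y: np.ndarray, X: np.ndarray, L: np.ndarray) -> TestResult:
    """Wilks' lambda for the general linear hypothesis L @ beta = 0.

    ``Y`` (n x p) responses, ``X`` (n x k) design, ``L`` (q x k) contrast.
    Error SSCP from the full model's residuals; hypothesis SSCP from the
    estimable contrast.  P-value via Rao's F approximation (exact for
    q = 1 or p <= 2).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, p = Y.shape
    k = X.shape[1]
    q = L.shape[0]
    XtX = X.T @ X
    XtX_inv = np.linalg.pinv(XtX)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    E = resid.T @ resid
    v = n - np.linalg.matrix_rank(X)
    if v < p:
        raise ValueError(
            f"singular error cross-product matrix: {p} responses but only {v} error df"
        )
    M = L @ XtX_inv @ L.T
    LB = L @ beta
    H = LB.T @ np.linalg.solve(M, LB)
    lam = float(np.linalg.det(E) / np.linalg.det(E + H))

    # Rao's F approximation
    t = 1.0
    if p**2 + q**2 - 5 > 0:
        t = math.sqrt((p**2 * q**2 - 4) / (p**2 + q**2 - 5))
    w = v + q - (p + q + 1) / 2
    df1 = p * q
    df2 = w * t - (p * q - 2) / 2
    lam_t = lam ** (1 / t)
    F = (1 - lam_t) / lam_t * df2 / df1
    pval = float(sps.f.sf(F, df1, df2))
    return TestResult(statistic=F, df=(df1, df2), p=pval, extra={"wilks_lambda": lam})


def default_subgroups(variables) -> dict[str, list[str]]:
    """Partition architecture variables by family to avoid collinearity.

    Occupancies, episode metrics, transition counts and band powers are
    tested in separate multivariate blocks.
    """
    groups: dict[str, list[str]] = {}
    for v in variables:
        name = v.lower()
        if "occupancy" in name:
            key = "occupancy"
        elif "episode" in name or "duration" in name:
            key = "episodes"
        elif "transition" in name:
            key = "transitions"
        elif "auc" in name or "power" in name:
            key = "power"
        else:
            key = "other"
        groups.setdefault(key, []).append(v)
    return groups


@dataclass
class RMAnalysis:
    """Results bundle of the group/day repeated-measures analysis."""

    multivariate: dict  # subgroup -> effect -> TestResult
    univariate: pd.DataFrame
    contrasts: pd.DataFrame

    def summary(self) -> str:
        lines = ["Multivariate tests (Wilks' lambda, Rao F):"]
        for sub, effects in self.multivariate.items():
            for eff, res in effects.items():
                lines.append(
                    f"  [{sub}] {eff}: Lambda={res.extra['wilks_lambda']:.4f} "
                    f"F({res.df[0]:.0f}, {res.df[1]:.1f})={res.statistic:.3f} p={res.p:.4f}"
                )
        if len(self.univariate):
            lines.append("Univariate follow-ups (mixed ANOVA, Bonferroni-gated):")
            for _, r in self.univariate.iterrows():
                lines.append(
                    f"  {r['variable']} {r['effect']}: F={r['F']:.3f} p={r['p']:.4f} "
                    f"(alpha'={r['adjusted_alpha']:.4f})"
                )
        if len(self.contrasts):
            lines.append("Contrasts (Bonferroni):")
            for _, r in self.contrasts.iterrows():
                lines.append(
                    f"  {r['variable']} {r['contrast']}: t={r['t']:.3f} p={r['p']:.4f} "
                    f"(alpha'={r['adjusted_alpha']:.4f})"
                )
        return "\n".join(lines)


def _pivot_complete(tbl: pd.DataFrame, variables, days) -> tuple[pd.DataFrame, pd.Series]:
    wide = tbl.pivot_table(
        index=["animal", "group"], columns=["variable", "day"], values="value",
        aggfunc="first",
    )
    missing = [c for c in ((v, d) for v in variables for d in days) if c not in wide.columns]
    if missing or wide.isna().any().any():
        nan_cells = [str(c) for c in wide.columns[wide.isna().any()]] + [str(m) for m in missing]
        raise ValueError(f"unbalanced/missing cells in the long table: {nan_cells}")
    return wide, wide.index.get_level_values("group")


def rm_group_day_analysis(
    tbl: pd.DataFrame,
    variables=None,
    subgroups: dict | None = None,
    baseline_day: str = "baseline",
    alpha: float = NOMINAL_ALPHA,
    gate_followups: bool = True,
) -> RMAnalysis:
    """Group, day and group x day analysis of a long-format variable table.

    ``tbl`` needs columns animal, group, day, variable, value with one
    value per cell (complete cases).  Per variable subgroup a Wilks'
    lambda multivariate test of each effect is computed; univariate mixed
    ANOVAs and pairwise contrasts follow only where the multivariate
    tests reach ``alpha`` (the original gating), each family Bonferroni
    corrected.
    """
    import pingouin as pg

    required = {"animal", "group", "day", "variable", "value"}
    if not required.issubset(tbl.columns):
        raise ValueError(f"long table must have columns {sorted(required)}")
    if variables is None:
        variables = sorted(tbl["variable"].unique())
    days = sorted(tbl["day"].unique(), key=lambda d: (d != baseline_day, str(d)))
    if baseline_day not in days:
        raise ValueError(f"baseline day {baseline_day!r} absent from the table")
    groups_present = sorted(tbl["group"].unique())
    if len(groups_present) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups_present}")

    sub = tbl[tbl["variable"].isin(variables)]
    wide, group_labels = _pivot_complete(sub, variables, days)
    n = len(wide)
    g = (np.asarray(group_labels) == groups_present[1]).astype(float)
    if min((g == 0).sum(), (g == 1).sum()) < 2:
        raise ValueError("need >= 2 animals per group")
    X = np.column_stack([np.ones(n), g - g.mean()])  # centered group code
    L_int = np.array([[1.0, 0.0]])
    L_grp = np.array([[0.0, 1.0]])
    d = len(days)
    # day-vs-baseline within-subject contrast matrix (d-1) x d
    C = np.zeros((d - 1, d))
    C[:, 0] = -1.0
    C[np.arange(d - 1), np.arange(1, d)] = 1.0

    if subgroups is None:
        subgroups = default_subgroups(variables)

    multivariate: dict[str, dict[str, TestResult]] = {}
    any_significant: dict[str, bool] = {}
    for name, mem in subgroups.items():
        Yb = np.column_stack([
            np.mean([wide[(v, day)].to_numpy() for day in days], axis=0) for v in mem
        ])
        Yw = np.column_stack([
            (np.column_stack([wide[(v, day)].to_numpy() for day in days]) @ C.T)
            for v in mem
        ])
        effects = {
            "group": wilks_test(Yb, X, L_grp),
            "day": wilks_test(Yw, X, L_int),
            "group_x_day": wilks_test(Yw, X, L_grp),
        }
        multivariate[name] = effects
        any_significant[name] = any(r.p < alpha for r in effects.values())

    uni_rows = []
    contrast_rows = []
    for name, mem in subgroups.items():
        if gate_followups and not any_significant[name]:
            continue
        alpha_uni = bonferroni_alpha(len(mem), alpha)
        for v in mem:
            long_v = sub[sub["variable"] == v]
            aov = pg.mixed_anova(
                data=long_v, dv="value", within="day", between="group", subject="animal"
            )
            sig_any = False
            for _, row in aov.iterrows():
                eff = {"group": "group", "day": "day", "Interaction": "group_x_day"}[row["Source"]]
                uni_rows.append({
                    "subgroup": name, "variable": v, "effect": eff,
                    "F": float(row["F"]), "df1": float(row["DF1"]), "df2": float(row["DF2"]),
                    "p": float(row["p_unc"]), "correction": "bonferroni",
                    "adjusted_alpha": alpha_uni,
                })
                sig_any = sig_any or float(row["p_unc"]) < alpha_uni
            if not (sig_any or not gate_followups):
                continue
            # day-vs-baseline within each group: family of 2 * (d-1)
            a_day = bonferroni_alpha(2 * (d - 1), alpha)
            for grp in groups_present:
                gv = long_v[long_v["group"] == grp].pivot(
                    index="animal", columns="day", values="value"
                )
                for day in days[1:]:
                    res = ttest_paired(gv[day], gv[baseline_day])
                    contrast_rows.append({
                        "variable": v, "contrast": f"{grp}: {day} vs {baseline_day}",
                        "t": res.statistic, "df": res.df[0], "p": res.p,
                        "correction": "bonferroni", "adjusted_alpha": a_day,
                        "family_size": 2 * (d - 1),
                    })
            # shocked vs non-shocked per day: family of d
            a_grp = bonferroni_alpha(d, alpha)
            for day in days:
                dv = long_v[long_v["day"] == day]
                x = dv[dv["group"] == groups_present[0]]["value"]
                y = dv[dv["group"] == groups_present[1]]["value"]
                res = ttest_independent(x, y)
                contrast_rows.append({
                    "variable": v, "contrast": f"{day}: {groups_present[0]} vs {groups_present[1]}",
                    "t": res.statistic, "df": res.df[0], "p": res.p,
                    "correction": "bonferroni", "adjusted_alpha": a_grp,
                    "family_size": d,
                })

    uni_cols = ["subgroup", "variable", "effect", "F", "df1", "df2", "p",
                "correction", "adjusted_alpha"]
    con_cols = ["variable", "contrast", "t", "df", "p", "correction",
                "adjusted_alpha", "family_size"]
    return RMAnalysis(
        multivariate=multivariate,
        univariate=pd.DataFrame(uni_rows, columns=uni_cols),
        contrasts=pd.DataFrame(contrast_rows, columns=con_cols),
    )


def fisher_z_mean(rs) -> float:
    """Average correlations on the Fisher z scale."""
    rs = np.asarray(rs, dtype=float)
    return float(np.tanh(np.mean(np.arctanh(rs))))
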