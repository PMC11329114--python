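"""Factorial group comparisons: two-way ANOVA, Dunnett, Bonferroni.

These are the tests applied to the day-averaged per-fly measures: a
two-way fixed-effects ANOVA (typically age cohort x sex, within
strain), Dunnett's many-to-one comparisons of each age group against
the youngest (2-week) control, and Bonferroni adjustment for simple
pairwise designs.

ANOVA uses Type II sums of squares (marginal effects), which reduce to
the classical decomposition on balanced designs; the cohorts here are
unbalanced (17-32 flies per condition), where Type II is the standard
marginal choice.  Dunnett family-wise p-values are evaluated from the
multivariate t distribution of the contrast vector by seed-controlled
Monte Carlo, with the Monte-Carlo standard error reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from damsleep.errors import DataError, ParameterError


def _design(codes: pd.Series) -> np.ndarray:
    """Treatment-coded dummy columns (first level dropped)."""
    d = pd.get_dummies(codes, drop_first=True)
    return d.to_numpy(dtype=float)


def _rss(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and residual df of an OLS fit."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), len(y) - rank


def two_way_anova(
    data: pd.DataFrame,
    value: str = "value",
    factor_a: str = "age_weeks",
    factor_b: str = "sex",
) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA with Type II sums of squares.

    Returns a table with rows ``factor_a``, ``factor_b``,
    ``interaction`` and ``residual`` and columns ``sum_sq``, ``df``,
    ``F`` and ``p``.  Every factor-level cell must be non-empty; a zero
    residual variance leaves the F statistics NaN (flagged via the
    table, not raised).
    """
    df = data[[value, factor_a, factor_b]].dropna()
    y = df[value].to_numpy(dtype=float)
    a = df[factor_a].astype(str)
    b = df[factor_b].astype(str)
    if a.nunique() < 2 or b.nunique() < 2:
        raise ParameterError("both factors need at least two levels")
    cells = df.groupby([factor_a, factor_b], observed=True).size()
    expected_cells = a.nunique() * b.nunique()
    if len(cells) < expected_cells:
        have = set(cells.index)
        missing = [
            (la, lb)
            for la in a.unique()
            for lb in b.unique()
            if (la, lb) not in have
        ]
        raise DataError(f"empty design cell(s): {missing}")

    one = np.ones((len(y), 1))
    A = _design(a)
    B = _design(b)
    AB = np.column_stack(
        [A[:, i] * B[:, j] for i in range(A.shape[1]) for j in range(B.shape[1])]
    )
    X_full = np.hstack([one, A, B, AB])
    X_ab = np.hstack([one, A, B])
    X_a = np.hstack([one, A])
    X_b = np.hstack([one, B])

    rss_full, df_resid = _rss(y, X_full)
    rss_ab, _ = _rss(y, X_ab)
    rss_a, _ = _rss(y, X_a)
    rss_b, _ = _rss(y, X_b)

    # Type II: each main effect adjusted for the other, ignoring the
    # interaction; the interaction adjusted for both main effects.
    ss_a = rss_b - rss_ab
    ss_b = rss_a - rss_ab
    ss_inter = rss_ab - rss_full
    df_a = a.nunique() - 1
    df_b = b.nunique() - 1
    df_inter = df_a * df_b

    mse = rss_full / df_resid if df_resid > 0 else float("nan")
    rows = []
    for name, ss, dof in (
        (factor_a, ss_a, df_a),
        (factor_b, ss_b, df_b),
        ("interaction", ss_inter, df_inter),
    ):
        if df_resid > 0 and mse > 0:
            F = (ss / dof) / mse
            p = float(stats.f.sf(F, dof, df_resid))
        else:
            F, p = float("nan"), float("nan")
        rows.append((name, ss, dof, F, p))
    rows.append(("residual", rss_full, df_resid, float("nan"), float("nan")))
    return pd.DataFrame(
        rows, columns=["effect", "sum_sq", "df", "F", "p"]
    ).set_index("effect")


@dataclass
class DunnettResult:
    """Many-to-one comparisons of each level against the control."""

    comparisons: pd.DataFrame  # level, n, t, p_unadjusted, p_adjusted
    control_level: str
    df_resid: int
    mc_draws: int
    mc_error: float  # Monte-Carlo standard error at p = 0.05


def dunnett_test(
    data: pd.DataFrame,
    value: str = "value",
    factor: str = "age_weeks",
    control_level: str = "2",
    *,
    seed: int = 0,
    n_mc: int = 100_000,
) -> DunnettResult:
    """Dunnett's test of every non-control level versus the control.

    t statistics use the pooled residual variance across all levels.
    Family-wise adjusted p-values are P(max_j |T_j| >= |t_obs|) under
    the joint null, where (T_1..T_k) follow the multivariate t
    distribution induced by the shared control group; the probability
    is evaluated by Monte Carlo with ``n_mc`` seeded draws.  With a
    single comparison this reduces to the ordinary two-sided pooled
    t-test.
    """
    df = data[[value, factor]].dropna()
    df[factor] = df[factor].astype(str)
    control_level = str(control_level)
    levels = sorted(df[factor].unique())
    if control_level not in levels:
        raise ParameterError(f"control level {control_level!r} not present")
    others = [lv for lv in levels if lv != control_level]
    if not others:
        raise ParameterError("no non-control levels to compare")

    groups = {lv: df.loc[df[factor] == lv, value].to_numpy(float) for lv in levels}
    ns = {lv: len(g) for lv, g in groups.items()}
    if min(ns.values()) < 2:
        raise DataError("every level needs at least two observations")
    k = len(others)
    n_total = sum(ns.values())
    df_resid = n_total - len(levels)
    pooled_var = (
        sum((len(g) - 1) * g.var(ddof=1) for g in groups.values()) / df_resid
    )
    if pooled_var == 0:
        raise DataError("zero pooled variance")

    m0 = groups[control_level].mean()
    n0 = ns[control_level]
    t_obs = np.array(
        [
            (groups[lv].mean() - m0)
            / np.sqrt(pooled_var * (1.0 / ns[lv] + 1.0 / n0))
            for lv in others
        ]
    )
    p_unadj = 2.0 * stats.t.sf(np.abs(t_obs), df_resid)

    # Joint null draws: T_j = (Z_j - lam_j Z_0) / sqrt(W/df), with the
    # correlation structure induced by the shared control mean.
    lam = np.array([np.sqrt(ns[lv] / (n0 + ns[lv])) for lv in others])
    rng = np.random.default_rng(seed)
    z0 = rng.standard_normal(n_mc)
    zj = rng.standard_normal((n_mc, k))
    chi = rng.chisquare(df_resid, n_mc)
    tmat = (
        np.sqrt(1.0 - lam**2) * zj - lam * z0[:, None]
    ) / np.sqrt(chi / df_resid)[:, None]
    max_abs = np.abs(tmat).max(axis=1)
    p_adj = np.array([(max_abs >= abs(t)).mean() for t in t_obs])
    p_adj = np.maximum(p_adj, p_unadj)  # adjusted never below unadjusted
    mc_error = float(np.sqrt(0.05 * 0.95 / n_mc))

    table = pd.DataFrame(
        {
            "level": others,
            "n": [ns[lv] for lv in others],
            "mean_diff": [groups[lv].mean() - m0 for lv in others],
            "t": t_obs,
            "p_unadjusted": p_unadj,
            "p_adjusted": p_adj,
        }
    ).set_index("level")
    return DunnettResult(
        comparisons=table,
        control_level=control_level,
        df_resid=df_resid,
        mc_draws=n_mc,
        mc_error=mc_error,
    )


def dunnett_critical_value(
    ns: dict[str, int],
    control_level: str,
    alpha: float = 0.05,
    *,
    seed: int = 0,
    n_mc: int = 100_000,
) -> float:
    """Two-sided family-wise critical value for given group sizes."""
    others = [lv for lv in ns if lv != control_level]
    n0 = ns[control_level]
    df_resid = sum(ns.values()) - len(ns)
    lam = np.array([np.sqrt(ns[lv] / (n0 + ns[lv])) for lv in others])
    rng = np.random.default_rng(seed)
    z0 = rng.standard_normal(n_mc)
    zj = rng.standard_normal((n_mc, len(others)))
    chi = rng.chisquare(df_resid, n_mc)
    tmat = (
        np.sqrt(1.0 - lam**2) * zj - lam * z0[:, None]
    ) / np.sqrt(chi / df_resid)[:, None]
    return float(np.quantile(np.abs(tmat).max(axis=1), 1.0 - alpha))


def bonferroni_adjust(pvalues) -> list[float]:
    """min(1, m * p) for each of the m p-values."""
    p = np.asarray(list(pvalues), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    return list(np.minimum(1.0, len(p) * p))


def significance_stars(p: float) -> str:
    """Asterisk notation at the conventional thresholds."""
    if np.isnan(p):
        return ""
    for thresh, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p < thresh:
            return stars
    return "ns"
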