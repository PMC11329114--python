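"""Lifespan statistics: Kaplan-Meier, log-rank and Cox proportional hazards.

The module keeps the bookkeeping conventions of fly lifespan assays:
cohorts are scored at vial transfers (deaths and censors per transfer),
vial-level tallies are expanded to individual records, and medians are
read off the product-limit curve as the first time survival drops to
one half or below.

The Cox model is fitted by Newton-Raphson on the partial likelihood
with the Efron correction for tied death times (the default of the R
``survival`` package, kept here for comparability); the sex-by-strain
interaction is tested with a likelihood-ratio test of the interaction
terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from damsleep.errors import DataError, FitError, ParameterError


@dataclass(frozen=True)
class SurvivalRecord:
    """One individual's event time and status with group labels."""

    subject_id: str
    time: float  # days since cohort start
    event: str  # "death" or "censor"
    strain: str = ""
    sex: str = ""
    vial: str | None = None

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise DataError("event time must be positive")
        if self.event not in ("death", "censor"):
            raise DataError("event must be 'death' or 'censor'")


@dataclass
class KMCurve:
    """Product-limit survival estimate."""

    times: np.ndarray  # distinct death times, increasing
    at_risk: np.ndarray  # subjects at risk just before each death time
    deaths: np.ndarray  # deaths at each time
    survival: np.ndarray  # S(t) just after each death time
    n_subjects: int

    def survival_at(self, t: float) -> float:
        """S(t) of the right-continuous step function."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def median(self) -> float:
        """Smallest death time with S(t) <= 0.5 (NaN if never reached)."""
        below = np.flatnonzero(self.survival <= 0.5)
        return float(self.times[below[0]]) if len(below) else float("nan")


def _to_arrays(records: list[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event == "death" for r in records], dtype=bool)
    return t, e


def expand_vial_tallies(table: pd.DataFrame) -> list[SurvivalRecord]:
    """Expand per-transfer vial tallies into individual records.

    ``table`` needs columns ``time_days``, ``deaths``, ``censors`` and
    optionally ``strain``, ``sex``, ``vial``.  Each tallied death or
    censor becomes one record with event time equal to the day of the
    transfer at which it was scored.
    """
    records: list[SurvivalRecord] = []
    for i, row in table.iterrows():
        common = dict(
            strain=str(row.get("strain", "")),
            sex=str(row.get("sex", "")),
            vial=str(row["vial"]) if "vial" in row else None,
        )
        for k in range(int(row["deaths"])):
            records.append(
                SurvivalRecord(f"r{i}d{k}", float(row["time_days"]), "death", **common)
            )
        for k in range(int(row.get("censors", 0))):
            records.append(
                SurvivalRecord(f"r{i}c{k}", float(row["time_days"]), "censor", **common)
            )
    return records


def kaplan_meier(records: list[SurvivalRecord]) -> KMCurve:
    """Product-limit estimator; censored subjects leave the risk set silently."""
    if not records:
        raise DataError("no survival records")
    t, e = _to_arrays(records)
    death_times = np.unique(t[e])
    n = len(t)
    at_risk = np.array([(t >= dt).sum() for dt in death_times], dtype=int)
    deaths = np.array([((t == dt) & e).sum() for dt in death_times], dtype=int)
    with np.errstate(invalid="ignore"):
        surv = np.cumprod(1.0 - deaths / at_risk) if len(death_times) else np.array([])
    return KMCurve(
        times=death_times,
        at_risk=at_risk,
        deaths=deaths,
        survival=surv,
        n_subjects=n,
    )


def median_lifespan(curve: KMCurve) -> float:
    """Median survival time (first time S(t) <= 0.5); NaN when undefined."""
    return curve.median


def percent_median_decrease(reference_median: float, comparison_median: float) -> float:
    """100 x (reference - comparison) / reference; sign-preserving."""
    if not reference_median > 0:
        raise ParameterError("reference median must be positive")
    return 100.0 * (reference_median - comparison_median) / reference_median


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float


def log_rank_test(groups: list[list[SurvivalRecord]]) -> LogRankResult:
    """k-sample log-rank test on pooled event times.

    Accumulates observed minus expected deaths per group at every
    pooled death time, with the hypergeometric covariance, and forms
    the chi-square statistic on k-1 degrees of freedom.
    """
    k = len(groups)
    if k < 2:
        raise ParameterError("need at least two groups")
    for g in groups:
        if not g:
            raise DataError("a group has zero subjects")
    times = []
    events = []
    labels = []
    for gi, g in enumerate(groups):
        t, e = _to_arrays(g)
        times.append(t)
        events.append(e)
        labels.append(np.full(len(t), gi))
    t = np.concatenate(times)
    e = np.concatenate(events)
    lab = np.concatenate(labels)
    if not e.any():
        raise DataError("no deaths in any group")

    death_times = np.unique(t[e])
    OmE = np.zeros(k)
    V = np.zeros((k, k))
    for dt in death_times:
        risk = t >= dt
        n_j = risk.sum()
        d_j = (e & (t == dt)).sum()
        n_ij = np.array([(risk & (lab == gi)).sum() for gi in range(k)], dtype=float)
        d_ij = np.array(
            [((e & (t == dt)) & (lab == gi)).sum() for gi in range(k)], dtype=float
        )
        p = n_ij / n_j
        OmE += d_ij - d_j * p
        if n_j > 1:
            mult = d_j * (n_j - d_j) / (n_j - 1)
            V += mult * (np.diag(p) - np.outer(p, p))
    sub = slice(0, k - 1)
    v = V[sub, sub]
    o = OmE[sub]
    # Pseudo-inverse guards degenerate risk sets (e.g. a group exhausted early).
    stat = float(o @ np.linalg.pinv(v) @ o)
    df = k - 1
    return LogRankResult(
        statistic=stat, df=df, p_value=float(stats.chi2.sf(stat, df))
    )


@dataclass
class CoxResult:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    loglik: float
    loglik_null: float
    n_iter: int
    n: int
    n_events: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "z": self.z, "p": self.p},
            index=self.names,
        )


def _cox_loglik(
    beta: np.ndarray, t: np.ndarray, e: np.ndarray, X: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Efron partial log-likelihood with gradient and information matrix."""
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # overflow guard; partial likelihood is shift-invariant
    w = np.exp(eta)
    order = np.argsort(-t, kind="stable")  # decreasing time
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    i = 0
    while i < n:
        # add everyone tied at this time to the risk set
        ti = t[order[i]]
        j = i
        tied_deaths = []
        while j < n and t[order[j]] == ti:
            idx = order[j]
            S0 += w[idx]
            S1 += w[idx] * X[idx]
            S2 += w[idx] * np.outer(X[idx], X[idx])
            if e[idx]:
                tied_deaths.append(idx)
            j += 1
        d = len(tied_deaths)
        if d:
            D = np.array(tied_deaths)
            S0D = w[D].sum()
            S1D = (w[D, None] * X[D]).sum(axis=0)
            S2D = np.einsum("i,ij,ik->jk", w[D], X[D], X[D])
            ll += eta[D].sum()
            for l in range(d):
                f = l / d
                phi = S0 - f * S0D
                s1 = S1 - f * S1D
                s2 = S2 - f * S2D
                ll -= np.log(phi)
                grad_term = s1 / phi
                grad -= grad_term
                info += s2 / phi - np.outer(grad_term, grad_term)
            grad += X[D].sum(axis=0)
        i = j
    return ll, grad, info


def cox_ph(
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    names: list[str] | None = None,
    *,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxResult:
    """Fit a Cox proportional-hazards model by Newton-Raphson (Efron ties)."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if not e.any():
        raise DataError("no deaths: Cox model cannot be fitted")

    beta = np.zeros(p)
    ll, grad, info = _cox_loglik(beta, t, e, X)
    ll_null = ll
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise FitError(
                "singular information matrix (possible complete separation)"
            ) from exc
        # step-halving keeps the partial likelihood increasing
        factor = 1.0
        rel_tol = 1e-9 * (1.0 + abs(ll))
        for _ in range(30):
            new_beta = beta + factor * step
            new_ll, new_grad, new_info = _cox_loglik(new_beta, t, e, X)
            if new_ll >= ll - rel_tol:
                break
            factor /= 2.0
        else:
            if np.max(np.abs(step)) < 1e-6:
                break  # at the optimum up to round-off
            raise FitError("step-halving failed to increase the likelihood")
        delta = new_ll - ll
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if abs(delta) < tol:
            break
    else:
        raise FitError(
            f"Newton-Raphson did not converge in {max_iter} iterations "
            f"(|grad|={np.max(np.abs(grad)):.3g})"
        )
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return CoxResult(
        names=list(names),
        coef=beta,
        se=se,
        z=z,
        p=pvals,
        loglik=float(ll),
        loglik_null=float(ll_null),
        n_iter=it,
        n=n,
        n_events=int(e.sum()),
    )


@dataclass
class CoxInteractionResult:
    fit: CoxResult
    lr_statistic: float
    lr_df: int
    interaction_p: float


def cox_ph_fit(
    records: list[SurvivalRecord],
    terms: tuple[str, ...] = ("sex", "strain", "sex:strain"),
) -> CoxInteractionResult:
    """Cox model on sex, strain and (optionally) their interaction.

    Factors are dummy-coded against their first (alphabetical) level.
    When the interaction term is included, its p-value comes from the
    likelihood-ratio test of the model with versus without the
    interaction columns.
    """
    if not records:
        raise DataError("no survival records")
    df = pd.DataFrame(
        {
            "time": [r.time for r in records],
            "event": [r.event == "death" for r in records],
            "sex": [r.sex for r in records],
            "strain": [r.strain for r in records],
        }
    )
    for factor in ("sex", "strain"):
        if factor in terms or any(factor in t for t in terms):
            if df[factor].nunique() < 2:
                raise ParameterError(
                    f"factor '{factor}' needs at least two levels"
                )

    def dummies(col: str) -> pd.DataFrame:
        d = pd.get_dummies(df[col], prefix=col, drop_first=True)
        return d.astype(float)

    main = pd.concat([dummies("sex"), dummies("strain")], axis=1)
    X_main = main.to_numpy()
    names_main = list(main.columns)
    want_interaction = any(t in ("sex:strain", "strain:sex") for t in terms)
    sex_d = dummies("sex")
    strain_d = dummies("strain")
    inter_cols = {}
    for sc in sex_d.columns:
        for tc in strain_d.columns:
            inter_cols[f"{sc}:{tc}"] = sex_d[sc] * strain_d[tc]
    inter = pd.DataFrame(inter_cols)

    t = df["time"].to_numpy()
    e = df["event"].to_numpy()
    if want_interaction:
        X_full = np.hstack([X_main, inter.to_numpy()])
        names_full = names_main + list(inter.columns)
        fit_full = cox_ph(t, e, X_full, names_full)
        fit_red = cox_ph(t, e, X_main, names_main)
        lr = 2.0 * (fit_full.loglik - fit_red.loglik)
        lr_df = inter.shape[1]
        p_int = float(stats.chi2.sf(lr, lr_df))
        return CoxInteractionResult(
            fit=fit_full, lr_statistic=float(lr), lr_df=lr_df, interaction_p=p_int
        )
    fit = cox_ph(t, e, X_main, names_main)
    lr = 2.0 * (fit.loglik - fit.loglik_null)
    return CoxInteractionResult(
        fit=fit,
        lr_statistic=float(lr),
        lr_df=len(names_main),
        interaction_p=float(stats.chi2.sf(lr, len(names_main))),
    )
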