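"""Survival statistics for model evaluation: Harrell's C-index with
bootstrap CI, two-group log-rank, Kaplan–Meier estimates, time-dependent
ROC/AUC, calibration curves, and univariate/multivariate Cox regression
over tabular covariates.

Cox fits and Kaplan–Meier curves are delegated to lifelines; the C-index,
log-rank statistic (needed in the cutoff scan's hot loop), time-dependent
AUC (simple cumulative-cases / dynamic-controls estimator, no censoring
weights) and calibration binning are implemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------


def c_index(
    scores, times, events, n_bootstrap: int = 1000, seed: int = 0
) -> tuple[float, tuple[float, float] | None]:
    """Harrell's concordance index with a percentile bootstrap 95% CI.

    Usable pairs are (i, j) with t_i < t_j and event_i observed; the pair
    is concordant when the earlier-failing subject has the higher score,
    and score ties count 0.5. Set ``n_bootstrap=0`` to skip the CI.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(scores) < 2 or not events.any():
        raise ValueError("need ≥ 2 subjects and ≥ 1 event")

    def harrell(s, t, e):
        usable = (t[:, None] < t[None, :]) & e[:, None]
        if not usable.any():
            return None
        diff = s[:, None] - s[None, :]
        conc = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
        return float(conc[usable].sum() / usable.sum())

    c = harrell(scores, times, events)
    if c is None:
        raise ValueError("no usable pairs")
    if n_bootstrap <= 0:
        return c, None
    rng = np.random.default_rng(seed)
    n = len(scores)
    boots = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        cb = harrell(scores[idx], times[idx], events[idx])
        if cb is not None:
            boots.append(cb)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return c, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Kaplan–Meier and log-rank
# ---------------------------------------------------------------------------


@dataclass
class KMEstimate:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0


def km_estimate(times, events) -> KMEstimate:
    """Product-limit survival estimate (lifelines-backed)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = np.array(
        [(times >= t).sum() for t in grid], dtype=int
    )
    return KMEstimate(times=grid, survival=surv, at_risk=at_risk,
                      censor_times=np.sort(times[~events]))


def logrank(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test: chi-square statistic (1 df) and p-value.

    Observed-minus-expected events in group A over the pooled event-time
    grid, with the hypergeometric variance at each event time.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=bool)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be nonempty")
    if not (ea.any() or eb.any()):
        raise ValueError("no events: log-rank undefined")
    t_all = np.concatenate([ta, tb])
    e_all = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones(len(ta), bool), np.zeros(len(tb), bool)])

    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(t_all[e_all]):
        at_risk = t_all >= t
        n = at_risk.sum()
        n1 = (at_risk & in_a).sum()
        deaths = (e_all & (t_all == t)).sum()
        d1 = (e_all & (t_all == t) & in_a).sum()
        o_minus_e += d1 - deaths * n1 / n
        if n > 1:
            var += deaths * (n1 / n) * (1 - n1 / n) * (n - deaths) / (n - 1)
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Time-dependent ROC and calibration
# ---------------------------------------------------------------------------


def td_roc(scores, times, events, horizons=(12.0, 24.0, 60.0)) -> dict[float, float | None]:
    """AUC(t) at each horizon with cumulative cases and dynamic controls.

    Cases are subjects with an observed event by t; controls are subjects
    still event-free past t; subjects censored before t are excluded
    (simple unweighted estimator). AUC is the Mann–Whitney rank statistic.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    out: dict[float, float | None] = {}
    for t in horizons:
        cases = (times <= t) & events
        controls = times > t
        if not cases.any() or not controls.any():
            out[float(t)] = None
            continue
        sc, sk = scores[cases], scores[controls]
        diff = sc[:, None] - sk[None, :]
        wins = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
        out[float(t)] = float(wins.mean())
    return out


def calibration(
    predicted_risk, times, events, horizon: float, n_bins: int = 5
) -> pd.DataFrame:
    """Per-quantile-bin predicted event probability vs 1 − KM at horizon.

    Bins with no events information (empty after quantile cuts) are merged
    with their lower neighbor, which is logged.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be ≥ 2")
    pred = np.asarray(predicted_risk, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    edges = np.unique(np.quantile(pred, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 2:  # constant predictions → one bin spanning everything
        edges = np.array([edges[0] - 0.5, edges[0] + 0.5])
    if len(edges) - 1 < n_bins:
        log.info("calibration: merged empty/duplicate quantile bins "
                 f"({n_bins} requested, {len(edges) - 1} effective)")
    bins = np.clip(np.searchsorted(edges, pred, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = bins == b
        if not sel.any():
            continue
        km = km_estimate(times[sel], events[sel])
        rows.append({
            "bin": b,
            "n": int(sel.sum()),
            "predicted": float(pred[sel].mean()),
            "observed": 1.0 - km.survival_at(horizon),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cox regression on tabular covariates
# ---------------------------------------------------------------------------


@dataclass
class SurvivalFitResult:
    """Cox model summary: per-covariate β, HR=exp(β), Wald 95% CI and p."""

    summary: pd.DataFrame
    c_index: float
    n: int
    n_events: int
    model: object = field(default=None, repr=False)

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


def _check_collinearity(df: pd.DataFrame, variables) -> None:
    X = df[list(variables)].to_numpy(dtype=float)
    for i in range(len(variables)):
        for j in range(i + 1, len(variables)):
            xi, xj = X[:, i], X[:, j]
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                continue
            r = np.corrcoef(xi, xj)[0, 1]
            if abs(r) > 0.999:
                raise ValueError(
                    f"collinear covariates: {variables[i]!r} and {variables[j]!r} "
                    f"(|r| = {abs(r):.4f})"
                )


def cox_fit(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    variables: list[str] | None = None,
) -> SurvivalFitResult:
    """Multivariate Cox proportional-hazards fit (Breslow ties, Wald CIs)."""
    if variables is None:
        variables = [c for c in data.columns if c not in (duration_col, event_col)]
    n_events = int(data[event_col].sum())
    if n_events < len(variables):
        raise ValueError(
            f"{n_events} events for {len(variables)} covariates: underdetermined"
        )
    _check_collinearity(data, variables)
    cph = CoxPHFitter()
    cph.fit(data[[duration_col, event_col] + variables],
            duration_col=duration_col, event_col=event_col)
    s = cph.summary
    summary = pd.DataFrame({
        "beta": s["coef"],
        "hr": s["exp(coef)"],
        "ci_low": s["exp(coef) lower 95%"],
        "ci_high": s["exp(coef) upper 95%"],
        "se": s["se(coef)"],
        "z": s["z"],
        "p": s["p"],
    })
    return SurvivalFitResult(
        summary=summary, c_index=float(cph.concordance_index_),
        n=len(data), n_events=n_events, model=cph,
    )


def univariate_screen(
    data: pd.DataFrame, duration_col: str, event_col: str,
    variables: list[str], alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Univariate Cox per covariate; returns the screen table and the
    covariates significant at ``alpha`` (candidates for the multivariate
    model)."""
    rows = []
    for v in variables:
        fit = cox_fit(data, duration_col, event_col, [v])
        row = fit.summary.loc[v].to_dict()
        row["covariate"] = v
        rows.append(row)
    table = pd.DataFrame(rows).set_index("covariate")
    selected = [v for v in variables if table.loc[v, "p"] < alpha]
    return table, selected


def uni_multi_cox(
    data: pd.DataFrame, duration_col: str, event_col: str,
    variables: list[str], alpha: float = 0.05,
) -> tuple[pd.DataFrame, SurvivalFitResult | None]:
    """Univariate screening then multivariate Cox on the significant set."""
    table, selected = univariate_screen(data, duration_col, event_col, variables, alpha)
    multi = cox_fit(data, duration_col, event_col, selected) if selected else None
    return table, multi


def subgroup_forest(
    data: pd.DataFrame, duration_col: str, event_col: str,
    score_col: str, subgroup_cols: list[str],
) -> pd.DataFrame:
    """Per-subgroup univariate Cox of a score (forest-plot data)."""
    rows = []
    for col in subgroup_cols:
        for value in sorted(data[col].unique()):
            sub = data[data[col] == value]
            if sub[event_col].sum() < 2 or len(sub) < 10:
                continue
            try:
                fit = cox_fit(sub, duration_col, event_col, [score_col])
            except Exception:
                continue
            rows.append({
                "subgroup": col, "value": value, "n": len(sub),
                "hr": fit.hr(score_col),
                "ci_low": float(fit.summary.loc[score_col, "ci_low"]),
                "ci_high": float(fit.summary.loc[score_col, "ci_high"]),
                "p": float(fit.summary.loc[score_col, "p"]),
            })
    return pd.DataFrame(rows)
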