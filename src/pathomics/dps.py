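"""Deep pathomics score (DPS): aggregate the per-tissue risk scores into a
single recurrence predictor via a proportional-hazards weighting over all
tissue categories except normal liver tissue (NLT), derive the immune score
(IS) from the immune-cell category alone, locate the optimal cutoff by the
maximally selected log-rank statistic, and assign high/low risk groups.

DPS is the multivariate Cox linear predictor over the five included
per-tissue scores, min–max normalized on the training cohort to a [0,1]
scale so a cutoff like 0.516 is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .prognostic import TissueRiskProfile
from .surv import cox_fit, logrank
from .tissues import TissueClass, CLASS_ORDER

#: Tissue categories entering the DPS weighting (all except NLT).
INCLUDED_CLASSES: tuple[TissueClass, ...] = tuple(
    c for c in CLASS_ORDER if c is not TissueClass.NLT
)


@dataclass
class DPSWeights:
    """Cox coefficients over the included per-tissue scores plus the
    training-cohort normalization bounds and imputation medians."""

    beta: dict[TissueClass, float]
    hr: dict[TissueClass, float]
    ci: dict[TissueClass, tuple[float, float]]
    z: dict[TissueClass, float]
    p: dict[TissueClass, float]
    included_classes: tuple[TissueClass, ...] = INCLUDED_CLASSES
    lp_min: float = 0.0
    lp_max: float = 1.0
    is_min: float = 0.0
    is_max: float = 1.0
    medians: dict[TissueClass, float] = field(default_factory=dict)

    def __post_init__(self):
        if TissueClass.NLT in self.included_classes:
            raise ValueError("NLT must not enter the DPS weighting")


@dataclass
class DPSResult:
    patient_id: str
    dps: float
    is_score: float
    risk_group: str | None = None
    cutoff_used: float | None = None


def _profiles_to_frame(profiles: Sequence[TissueRiskProfile]) -> pd.DataFrame:
    rows = {p.patient_id: {c.value: p.s.get(c, np.nan) for c in INCLUDED_CLASSES}
            for p in profiles}
    return pd.DataFrame.from_dict(rows, orient="index")


def fit_dps_weights(
    profiles: Sequence[TissueRiskProfile], times, events
) -> DPSWeights:
    """Multivariate Cox fit of TTR on the five included per-tissue scores.

    Missing scores are imputed with the training-cohort median before the
    fit; the linear-predictor range and the IS range over the training
    cohort are stored for normalization at application time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(profiles) < 20:
        raise ValueError("need ≥ 20 patients to fit DPS weights")
    if events.sum() < 5:
        raise ValueError("need ≥ 5 events to fit DPS weights")
    X = _profiles_to_frame(profiles)
    medians = X.median()
    X = X.fillna(medians)

    df = X.copy()
    df["time"] = times
    df["event"] = events.astype(int)
    fit = cox_fit(df, "time", "event", list(X.columns))

    beta = {TissueClass(c): float(fit.summary.loc[c, "beta"]) for c in X.columns}
    lp = X.to_numpy() @ np.array([beta[TissueClass(c)] for c in X.columns])
    ic = X[TissueClass.IC.value].to_numpy(dtype=float)
    return DPSWeights(
        beta=beta,
        hr={TissueClass(c): float(fit.summary.loc[c, "hr"]) for c in X.columns},
        ci={TissueClass(c): (float(fit.summary.loc[c, "ci_low"]),
                             float(fit.summary.loc[c, "ci_high"]))
            for c in X.columns},
        z={TissueClass(c): float(fit.summary.loc[c, "z"]) for c in X.columns},
        p={TissueClass(c): float(fit.summary.loc[c, "p"]) for c in X.columns},
        lp_min=float(lp.min()), lp_max=float(lp.max()),
        is_min=float(ic.min()), is_max=float(ic.max()),
        medians={TissueClass(c): float(medians[c]) for c in X.columns},
    )


def _normalize(value: float, lo: float, hi: float) -> float:
    span = hi - lo
    return float((value - lo) / span) if span > 0 else 0.5


def compute_dps(profile: TissueRiskProfile, w: DPSWeights) -> DPSResult:
    """DPS and IS for one patient (deterministic; missing scores imputed by
    the training-cohort median)."""
    lp = 0.0
    for c in w.included_classes:
        s = profile.s.get(c, np.nan)
        if not np.isfinite(s):
            s = w.medians.get(c, 0.5)
        lp += w.beta[c] * s
    ic = profile.s.get(TissueClass.IC, np.nan)
    if not np.isfinite(ic):
        ic = w.medians.get(TissueClass.IC, 0.5)
    return DPSResult(
        patient_id=profile.patient_id,
        dps=_normalize(lp, w.lp_min, w.lp_max),
        is_score=_normalize(ic, w.is_min, w.is_max),
    )


def compute_dps_batch(
    profiles: Sequence[TissueRiskProfile], w: DPSWeights
) -> pd.DataFrame:
    rows = [compute_dps(p, w) for p in profiles]
    return pd.DataFrame(
        {"patient_id": [r.patient_id for r in rows],
         "dps": [r.dps for r in rows],
         "is_score": [r.is_score for r in rows]}
    ).set_index("patient_id")


def optimal_cutoff(
    dps_values, times, events, min_prop: float = 0.10,
    return_scan: bool = False,
):
    """Maximally selected log-rank cutpoint over the DPS distribution.

    Candidates are midpoints between consecutive sorted unique values whose
    implied low-risk fraction lies in [min_prop, 1 − min_prop]; the
    candidate maximizing the two-group log-rank chi-square wins, ties going
    to the lower cutoff. Note the selected cutoff is an extreme statistic:
    under the null it lands essentially anywhere in the admissible range,
    so the associated log-rank p-value is optimistic.
    """
    dps_values = np.asarray(dps_values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(dps_values) < 20:
        raise ValueError("need ≥ 20 patients for cutoff selection")
    uniq = np.unique(dps_values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    n = len(dps_values)
    admissible = []
    for m in mids:
        frac_low = (dps_values <= m).mean()
        if min_prop <= frac_low <= 1 - min_prop:
            admissible.append(m)
    if not admissible:
        raise ValueError("no admissible cutoff candidate in the inner "
                         f"quantile range [{min_prop}, {1 - min_prop}]")
    best_c, best_stat = None, -np.inf
    scan = []
    for m in admissible:
        high = dps_values > m
        try:
            chi2, _ = logrank(times[high], events[high], times[~high], events[~high])
        except ValueError:
            chi2 = 0.0
        scan.append((float(m), float(chi2)))
        if chi2 > best_stat + 1e-12:   # strict improvement → ties keep lower m
            best_stat, best_c = chi2, float(m)
    if return_scan:
        return best_c, pd.DataFrame(scan, columns=["cutoff", "chi2"])
    return best_c


def assign_groups(dps_values, cutoff: float) -> np.ndarray:
    """'high' iff DPS strictly exceeds the cutoff; boundary values are low."""
    dps_values = np.asarray(dps_values, dtype=float)
    if not np.isfinite(dps_values).all() or not np.isfinite(cutoff):
        raise ValueError("DPS values and cutoff must be finite")
    return np.where(dps_values > cutoff, "high", "low")
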