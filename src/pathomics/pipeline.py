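"""End-to-end deep-pathomics pipeline over a patient cohort.

Per tissue category, a risk network is trained on the training cohort with
the joint Cox + cross-entropy loss. The DPS weights (multivariate Cox over
the five non-NLT per-tissue scores) are fitted on *pre-validated*
(out-of-fold) training scores so in-sample overfitting of the risk
networks cannot inflate the weights; held-out patients are scored with the
full-training-cohort networks. The optimal DPS cutoff is then selected on
the training cohort by the maximally selected log-rank statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import dps as dps_mod
from . import prognostic, surv
from .prognostic import (JointLossConfig, PatientRecord, RiskNetConfig,
                         TissueRiskModel, TissueRiskProfile)
from .tissues import TissueClass, CLASS_ORDER


@dataclass
class PipelineResult:
    models: dict[TissueClass, TissueRiskModel]
    weights: dps_mod.DPSWeights
    cutoff: float
    train_scores: pd.DataFrame       # per-tissue scores + dps/is, train cohort
    val_scores: pd.DataFrame         # same for validation cohort
    train_cindex: tuple[float, tuple[float, float] | None]
    val_cindex: tuple[float, tuple[float, float] | None]
    extras: dict = field(default_factory=dict)


def _survival_arrays(patients: Sequence[PatientRecord]):
    t = np.array([p.ttr_months for p in patients])
    e = np.array([p.recurrence_event for p in patients])
    return t, e


def _score_table(patients, scores_by_class, profiles, dps_table):
    df = pd.DataFrame({"patient_id": [p.patient_id for p in patients]}).set_index(
        "patient_id"
    )
    for c in CLASS_ORDER:
        df[f"s_{c.value}"] = [scores_by_class[c][p.patient_id] for p in patients]
    df["dps"] = dps_table["dps"]
    df["is_score"] = dps_table["is_score"]
    t, e = _survival_arrays(patients)
    df["ttr_months"] = t
    df["recurrence_event"] = e.astype(int)
    rfs_t = [p.rfs_months for p in patients]
    rfs_e = [int(p.rfs_event) for p in patients]
    df["rfs_months"] = rfs_t
    df["rfs_event"] = rfs_e
    return df


def fit_deep_pathomics(
    train: Sequence[PatientRecord],
    val: Sequence[PatientRecord],
    loss_cfg: JointLossConfig | None = None,
    net_cfg: RiskNetConfig | None = None,
    n_crossfit_folds: int = 5,
    seed: int = 0,
    n_bootstrap: int = 200,
) -> PipelineResult:
    """Train per-tissue risk networks, fit DPS weights, score both cohorts."""
    loss_cfg = loss_cfg or JointLossConfig()
    net_cfg = net_cfg or RiskNetConfig()

    models: dict[TissueClass, TissueRiskModel] = {}
    prevalidated: dict[TissueClass, dict[str, float]] = {}
    train_scores: dict[TissueClass, dict[str, float]] = {}
    val_scores: dict[TissueClass, dict[str, float]] = {}
    for i, c in enumerate(CLASS_ORDER):
        model, s_train = prognostic.train_tissue_risk(
            train, c, loss_cfg, net_cfg, seed=seed * 101 + i
        )
        models[c] = model
        train_scores[c] = s_train
        val_scores[c] = prognostic.score_cohort(model, val)
        prevalidated[c] = prognostic.crossfit_scores(
            train, c, n_folds=n_crossfit_folds, loss_cfg=loss_cfg,
            net_cfg=net_cfg, seed=seed * 101 + i,
        )

    t_tr, e_tr = _survival_arrays(train)
    t_va, e_va = _survival_arrays(val)

    preval_profiles = prognostic.build_profiles(train, prevalidated)
    weights = dps_mod.fit_dps_weights(preval_profiles, t_tr, e_tr)

    train_profiles = prognostic.build_profiles(train, train_scores)
    val_profiles = prognostic.build_profiles(val, val_scores)
    dps_tr = dps_mod.compute_dps_batch(train_profiles, weights)
    dps_va = dps_mod.compute_dps_batch(val_profiles, weights)

    cutoff = dps_mod.optimal_cutoff(dps_tr["dps"].to_numpy(), t_tr, e_tr)
    dps_tr["risk_group"] = dps_mod.assign_groups(dps_tr["dps"].to_numpy(), cutoff)
    dps_va["risk_group"] = dps_mod.assign_groups(dps_va["dps"].to_numpy(), cutoff)

    c_tr = surv.c_index(dps_tr["dps"].to_numpy(), t_tr, e_tr,
                        n_bootstrap=n_bootstrap, seed=seed)
    c_va = surv.c_index(dps_va["dps"].to_numpy(), t_va, e_va,
                        n_bootstrap=n_bootstrap, seed=seed)

    return PipelineResult(
        models=models,
        weights=weights,
        cutoff=cutoff,
        train_scores=_score_table(train, train_scores, train_profiles, dps_tr),
        val_scores=_score_table(val, val_scores, val_profiles, dps_va),
        train_cindex=c_tr,
        val_cindex=c_va,
        extras={
            "prevalidated_scores": prevalidated,
            "train_risk_group": dps_tr["risk_group"],
            "val_risk_group": dps_va["risk_group"],
        },
    )
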