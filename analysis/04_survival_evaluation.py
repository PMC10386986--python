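#!/usr/bin/env python
"""Survival evaluation of the fitted DPS (run 03_fit_dps_pipeline.py
first): Kaplan–Meier by risk group with log-rank, time-dependent ROC,
calibration, and univariate→multivariate Cox over DPS plus clinical
covariates.

Writes under results/survival/: km_groups.csv, td_auc.csv,
calibration.csv, cox_univariate.csv, cox_multivariate.csv, km_plot.png.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from pathomics import dps as dps_mod
from pathomics import surv

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "survival"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    scores = pd.concat([
        pd.read_csv(BASE / "dps" / "train_scores.csv"),
        pd.read_csv(BASE / "dps" / "val_scores.csv"),
    ], ignore_index=True)
    cutoff = float(
        (BASE / "dps" / "summary.txt").read_text().splitlines()[2].split()[-1]
    )
    groups = dps_mod.assign_groups(scores["dps"].to_numpy(), cutoff)
    scores["risk_group"] = groups
    t = scores["ttr_months"].to_numpy()
    e = scores["recurrence_event"].to_numpy(dtype=bool)
    high = groups == "high"

    chi2, p = surv.logrank(t[high], e[high], t[~high], e[~high])
    rows, fig = [], plt.figure(figsize=(5, 4))
    for name, sel in (("high", high), ("low", ~high)):
        km = surv.km_estimate(t[sel], e[sel])
        rows.append({"group": name, "n": int(sel.sum()),
                     "recurrence_5y_pct": 100 * (1 - km.survival_at(60.0))})
        plt.step(km.times, km.survival, where="post", label=f"{name} (n={sel.sum()})")
    plt.xlabel("months since transplant")
    plt.ylabel("recurrence-free probability (TTR)")
    plt.title(f"log-rank chi2={chi2:.1f}, p={p:.2e}")
    plt.legend()
    fig.savefig(OUT / "km_plot.png", dpi=120, bbox_inches="tight")
    km_df = pd.DataFrame(rows)
    km_df["logrank_chi2"] = chi2
    km_df["logrank_p"] = p
    km_df.to_csv(OUT / "km_groups.csv", index=False, float_format="%.4f")
    print(km_df.to_string(index=False))

    aucs = surv.td_roc(scores["dps"].to_numpy(), t, e, horizons=(12.0, 24.0, 60.0))
    pd.Series(aucs, name="auc").rename_axis("horizon_months").to_csv(OUT / "td_auc.csv")
    print("time-dependent AUC:", {k: round(v, 3) for k, v in aucs.items() if v})

    cal = surv.calibration(scores["dps"].to_numpy(), t, e, horizon=60.0, n_bins=5)
    cal.to_csv(OUT / "calibration.csv", index=False, float_format="%.4f")

    # DPS against clinical covariates: univariate screen then multivariate
    from pathomics.synthetic import SyntheticCohortSpec, generate_cohort

    cov = generate_cohort(SyntheticCohortSpec(n_patients=380, seed=7),
                          with_tiles=False).to_frame()
    df = scores.merge(cov[["patient_id", "age", "male", "hbv",
                           "tumor_diameter_cm", "mvi", "afp_over_400"]],
                      on="patient_id")
    variables = ["dps", "age", "male", "hbv", "tumor_diameter_cm", "mvi",
                 "afp_over_400"]
    uni, multi = surv.uni_multi_cox(df, "rfs_months", "rfs_event", variables)
    uni.to_csv(OUT / "cox_univariate.csv", float_format="%.4f")
    if multi is not None:
        multi.summary.to_csv(OUT / "cox_multivariate.csv", float_format="%.4f")
        print("multivariate RFS model:")
        print(multi.summary[["hr", "ci_low", "ci_high", "p"]].round(3).to_string())


if __name__ == "__main__":
    main()
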