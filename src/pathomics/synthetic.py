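"""Synthetic inputs for the full pipeline: labelled tissue tiles, survival
cohorts with known per-tissue hazard effects, and two-group mIF point
patterns.

The tile generator produces procedural textures (class-specific base color,
blob scale and noise spectrum) that are visually separable but make no
claim to realistic H&E appearance. The cohort generator draws latent
per-class scores i.i.d. N(0,1) per patient, gives each patient an
exponential event time with hazard baseline·exp(Σ β_t·z_t) and an
independent exponential censoring time, and renders tiles whose contrast is
modulated by the latent score so the risk networks have a learnable signal.
The mIF generator produces homogeneous Poisson point patterns per phenotype
with an optional NK-ward attraction of CD8 cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .mif import BorderAnnotation, REQUIRED_MARKERS, markers_for_phenotype
from .prognostic import PatientRecord
from .tissues import TissueClass, CLASS_ORDER, as_tissue_class
from .wsi import Tile

# ---------------------------------------------------------------------------
# Tissue tiles
# ---------------------------------------------------------------------------

#: Per-class procedural palette: base RGB, accent RGB, blob scale (px at
#: 64 px tile; scaled with tile size), fine-noise amplitude. Hues are spread
#: far apart so classes are separable by construction.
CLASS_PALETTES: dict[TissueClass, dict] = {
    TissueClass.TR: dict(base=(158, 82, 160), accent=(96, 40, 110), blob=6.0, noise=14.0),
    TissueClass.NLT: dict(base=(232, 170, 185), accent=(205, 130, 150), blob=12.0, noise=8.0),
    TissueClass.PA: dict(base=(176, 196, 222), accent=(120, 140, 190), blob=4.0, noise=10.0),
    TissueClass.FT: dict(base=(214, 208, 185), accent=(180, 170, 140), blob=18.0, noise=6.0),
    TissueClass.HNT: dict(base=(186, 74, 70), accent=(120, 35, 35), blob=9.0, noise=18.0),
    TissueClass.IC: dict(base=(84, 80, 168), accent=(40, 36, 110), blob=3.0, noise=12.0),
}


def generate_tissue_tile(
    cls: TissueClass | str,
    size_px: int = 512,
    seed: int = 0,
    contrast: float = 1.0,
    patient_id: str = "",
) -> Tile:
    """Procedural RGB tile of one tissue class; deterministic in its inputs.

    ``contrast`` scales the deviation of the texture from its mean color
    (the cohort generator uses it to encode the latent risk signal).
    """
    cls = as_tissue_class(cls)
    if size_px < 32:
        raise ValueError(f"size_px must be ≥ 32; got {size_px}")
    pal = CLASS_PALETTES[cls]
    cls_idx = CLASS_ORDER.index(cls)
    rng = np.random.default_rng(np.random.SeedSequence([cls_idx, size_px, int(seed)]))

    blob_sigma = pal["blob"] * size_px / 64.0
    blobs = gaussian_filter(rng.standard_normal((size_px, size_px)), blob_sigma)
    span = blobs.max() - blobs.min()
    blobs = (blobs - blobs.min()) / span if span > 0 else np.zeros_like(blobs)

    base = np.asarray(pal["base"], dtype=float)
    accent = np.asarray(pal["accent"], dtype=float)
    img = base[None, None, :] * (1 - blobs[:, :, None]) + accent[None, None, :] * blobs[:, :, None]
    img += rng.normal(0.0, pal["noise"], size=(size_px, size_px, 3))

    mean = img.mean(axis=(0, 1), keepdims=True)
    img = mean + (img - mean) * float(contrast)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return Tile(pixels=pixels, true_class=cls, patient_id=patient_id)


# ---------------------------------------------------------------------------
# Survival cohorts
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohortSpec:
    """Conditions of a synthetic transplant cohort.

    Hazard per patient is baseline_hazard_rate · exp(Σ β_t z_t) with latent
    per-class scores z ~ N(0,1); event and censoring times are exponential
    and administratively capped at the recurrence horizon. Defaults emulate
    a post-transplant HCC cohort: a per-month baseline giving roughly a
    quarter of patients an observed recurrence within the 84-month horizon.
    """

    n_patients: int = 380
    tiles_per_patient_per_class: int = 2
    true_beta: dict[TissueClass, float] = field(
        default_factory=lambda: {c: 0.0 for c in CLASS_ORDER}
    )
    baseline_hazard_rate: float = 0.006     # events per month at z = 0
    censoring_rate: float = 0.008           # drop-out per month
    death_rate: float = 0.002               # non-recurrence deaths (RFS only)
    recurrence_horizon: float = 84.0        # months of follow-up
    tile_size_px: int = 48
    contrast_slope: float = 0.45            # latent score → tile contrast
    seed: int = 0

    def __post_init__(self):
        self.true_beta = {as_tissue_class(k): float(v) for k, v in self.true_beta.items()}
        for c in CLASS_ORDER:
            self.true_beta.setdefault(c, 0.0)
        if self.n_patients < 2:
            raise ValueError("n_patients must be ≥ 2")
        for name in ("baseline_hazard_rate", "censoring_rate", "death_rate",
                     "recurrence_horizon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class SyntheticCohort:
    patients: list[PatientRecord]
    latent_scores: pd.DataFrame     # patients × tissue classes, the true z
    spec: SyntheticCohortSpec

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            row = {
                "patient_id": p.patient_id,
                "ttr_months": p.ttr_months,
                "recurrence_event": int(p.recurrence_event),
                "rfs_months": p.rfs_months,
                "rfs_event": int(p.rfs_event),
            }
            row.update(p.covariates)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


def generate_cohort(spec: SyntheticCohortSpec, with_tiles: bool = True) -> SyntheticCohort:
    """Draw a full synthetic cohort (survival table + class-labelled tiles)."""
    rng = np.random.default_rng(np.random.SeedSequence([20230408, int(spec.seed)]))
    n = spec.n_patients
    z = rng.standard_normal((n, len(CLASS_ORDER)))
    beta = np.array([spec.true_beta[c] for c in CLASS_ORDER])
    hazard = spec.baseline_hazard_rate * np.exp(z @ beta)

    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.exponential(1.0 / spec.censoring_rate, size=n)
    t_death = rng.exponential(1.0 / spec.death_rate, size=n)
    horizon = spec.recurrence_horizon

    obs_end = np.minimum(t_censor, horizon)
    ttr = np.minimum(t_event, obs_end)
    rec_event = t_event <= obs_end
    first_fail = np.minimum(t_event, t_death)
    rfs = np.minimum(first_fail, obs_end)
    rfs_event = first_fail <= obs_end

    patients = []
    for i in range(n):
        pid = f"P{i:04d}"
        tiles: dict[TissueClass, list[Tile]] = {}
        if with_tiles:
            for j, c in enumerate(CLASS_ORDER):
                contrast = float(np.exp(spec.contrast_slope * np.clip(z[i, j], -3, 3)))
                tiles[c] = [
                    generate_tissue_tile(
                        c, spec.tile_size_px,
                        seed=int(rng.integers(2**31)),
                        contrast=contrast, patient_id=pid,
                    )
                    for _ in range(spec.tiles_per_patient_per_class)
                ]
        covars = {
            "age": float(np.round(rng.normal(52, 9), 1)),
            "male": int(rng.random() < 0.85),
            "hbv": int(rng.random() < 0.82),
            "tumor_diameter_cm": float(np.round(rng.lognormal(1.1, 0.45), 1)),
            "mvi": int(rng.random() < 0.35),
            "afp_over_400": int(rng.random() < 0.2),
        }
        patients.append(PatientRecord(
            patient_id=pid,
            ttr_months=float(ttr[i]),
            recurrence_event=bool(rec_event[i]),
            rfs_months=float(rfs[i]),
            rfs_event=bool(rfs_event[i]),
            covariates=covars,
            tiles=tiles,
        ))
    latent = pd.DataFrame(z, columns=[c.value for c in CLASS_ORDER],
                          index=[p.patient_id for p in patients])
    return SyntheticCohort(patients=patients, latent_scores=latent, spec=spec)


def split_cohort(cohort: SyntheticCohort, train_fraction: float = 0.7,
                 seed: int = 0) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Random patient-level train/validation split (default 7:3)."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(cohort.patients))
    n_train = int(round(train_fraction * len(idx)))
    train = [cohort.patients[i] for i in idx[:n_train]]
    val = [cohort.patients[i] for i in idx[n_train:]]
    return train, val


# ---------------------------------------------------------------------------
# mIF point patterns
# ---------------------------------------------------------------------------

#: Intratumoral baseline densities (cells/mm²). Macrophages dominate, then
#: CD4+/CD8+ T cells and monocytes; NK density is group-specific.
DEFAULT_MIF_DENSITIES: dict[str, float] = {
    "Macrophage": 300.0,
    "CD4T": 200.0,
    "CD8T": 150.0,
    "MemoryT": 150.0,
    "Monocyte": 120.0,
    "B": 60.0,
    "Treg": 50.0,
    "Neutrophil": 50.0,
    "cDC": 40.0,
    "CD11b_CD68": 40.0,
    "NKT": 20.0,
    "other": 80.0,
}


@dataclass
class SyntheticMIFSpec:
    """Conditions of one synthetic mIF field.

    The two study groups differ in NK density and NK–CD8 attraction: the
    non-recurrence group has denser intratumoral NK cells and CD8+T cells
    drawn closer to them.
    """

    group: str = "none_recurrence"          # or "early_recurrence"
    field_size_um: float = 2000.0
    densities: dict[str, float] = field(default_factory=dict)
    nk_cd8_attraction: float | None = None  # None → group default
    attraction_sigma_um: float = 40.0
    seed: int = 0

    def __post_init__(self):
        if self.group not in ("none_recurrence", "early_recurrence"):
            raise ValueError("group must be 'none_recurrence' or 'early_recurrence'")
        if self.field_size_um <= 0:
            raise ValueError("field_size_um must be > 0")
        defaults = dict(DEFAULT_MIF_DENSITIES)
        defaults["NK"] = 25.0 if self.group == "none_recurrence" else 8.0
        defaults.update(self.densities)
        self.densities = defaults
        if any(v < 0 for v in self.densities.values()):
            raise ValueError("densities must be nonnegative")
        if self.nk_cd8_attraction is None:
            self.nk_cd8_attraction = 1.0 if self.group == "none_recurrence" else 0.0
        if self.nk_cd8_attraction < 0:
            raise ValueError("nk_cd8_attraction must be nonnegative")


def generate_mif_field(spec: SyntheticMIFSpec) -> tuple[pd.DataFrame, BorderAnnotation]:
    """Simulate one mIF field: cell table (µm, marker booleans, phenotype)
    plus a straight tumor-border annotation down the field's middle
    (tumor on the +x side).

    Each phenotype is a homogeneous Poisson process at its requested
    density. When ``nk_cd8_attraction`` a > 0, a fraction a/(1+a) of CD8+T
    cells is relocated next to a random NK cell (Gaussian offset), which
    shortens NK–CD8 nearest distances without changing marginal counts.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        [991, int(spec.seed), 0 if spec.group == "none_recurrence" else 1]
    ))
    size = spec.field_size_um
    area_mm2 = (size / 1000.0) ** 2

    rows = []
    nk_xy = np.zeros((0, 2))
    order = sorted(spec.densities)           # deterministic phenotype order
    order.remove("NK")
    order.insert(0, "NK")                    # NK first: CD8 may attach to it
    for pheno in order:
        lam = spec.densities[pheno]
        n_cells = rng.poisson(lam * area_mm2)
        xy = rng.uniform(0.0, size, size=(n_cells, 2))
        if pheno == "NK":
            nk_xy = xy
        if pheno == "CD8T" and spec.nk_cd8_attraction > 0 and len(nk_xy) > 0:
            p_move = spec.nk_cd8_attraction / (1.0 + spec.nk_cd8_attraction)
            move = rng.random(n_cells) < p_move
            anchors = nk_xy[rng.integers(0, len(nk_xy), size=int(move.sum()))]
            jitter = rng.normal(0.0, spec.attraction_sigma_um, size=anchors.shape)
            xy[move] = np.clip(anchors + jitter, 0.0, size)
        profile = markers_for_phenotype(pheno)
        for x, y in xy:
            row = {"x_um": float(x), "y_um": float(y), "phenotype": pheno}
            row.update({m: bool(v) for m, v in profile.items()})
            rows.append(row)

    columns = ["x_um", "y_um", *REQUIRED_MARKERS, "phenotype"]
    cells = pd.DataFrame(rows, columns=columns) if rows else pd.DataFrame(
        {c: pd.Series(dtype=float if c.endswith("_um") else object) for c in columns}
    )
    # border down the middle; direction +y puts the tumor (x > mid) on the right
    border = BorderAnnotation(
        coords=[(size / 2.0, 0.0), (size / 2.0, size)], tumor_side="right"
    )
    return cells, border


def save_mif_field(cells: pd.DataFrame, border: BorderAnnotation, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells.to_csv(out / "cells.csv", index=False, float_format="%.3f")
    border.save(out / "border.geojson")
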