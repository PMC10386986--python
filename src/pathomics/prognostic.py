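"""Per-tissue survival risk networks (modified DeepSurv stage).

For each tissue category a small network maps that category's tiles to a
patient-level risk score. Training minimizes a joint loss: the Cox
partial-likelihood term uses the recurrence time (TTR) and event flag, and
a binary cross-entropy term on sigmoid(score) uses the recurrence status as
a binary label. Per-tile scores are mean-pooled into the patient score.
Training stops early once the validation loss starts to rise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import nn
from .tissues import TissueClass, CLASS_ORDER
from .wsi import Tile

# ---------------------------------------------------------------------------
# Patient-level records
# ---------------------------------------------------------------------------


@dataclass
class PatientRecord:
    """Survival endpoints, covariates and tiles for one patient.

    TTR is time to recurrence (months); RFS is recurrence-free survival
    (recurrence, metastasis or death). Event flags are True when the event
    was observed rather than censored.
    """

    patient_id: str
    ttr_months: float
    recurrence_event: bool
    rfs_months: float
    rfs_event: bool
    covariates: dict = field(default_factory=dict)
    tiles: dict[TissueClass, list[Tile]] = field(default_factory=dict)

    def __post_init__(self):
        if self.ttr_months < 0 or self.rfs_months < 0:
            raise ValueError("survival times must be nonnegative")


@dataclass
class JointLossConfig:
    """Mixing of the Cox partial likelihood with binary cross-entropy."""

    lambda_bce: float = 1.0
    tie_method: str = "breslow"

    def __post_init__(self):
        if self.lambda_bce < 0:
            raise ValueError("lambda_bce must be nonnegative")
        if self.tie_method not in ("breslow", "efron"):
            raise ValueError("tie_method must be 'breslow' or 'efron'")


@dataclass
class TissueRiskProfile:
    """Per-patient vector of per-tissue risk scores s_t (NaN = missing)."""

    patient_id: str
    s: dict[TissueClass, float]
    missing: set = field(default_factory=set)


# ---------------------------------------------------------------------------
# Loss functions
# ---------------------------------------------------------------------------


def cox_npll(
    scores: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    tie_method: str = "breslow",
) -> float:
    """Negative Cox partial log-likelihood of per-patient risk scores.

    The risk set of an event at time t is every subject with time ≥ t.
    Breslow's approximation (default) charges every tied event the full
    risk-set sum; Efron's discounts the tied contributions progressively.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    n = len(scores)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if not events.any():
        raise ValueError("no events: partial likelihood undefined")
    exp_s = np.exp(scores)
    npll = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        tied = events & (times == t)
        d = int(tied.sum())
        risk_sum = exp_s[at_risk].sum()
        if tie_method == "breslow":
            npll += d * np.log(risk_sum) - scores[tied].sum()
        elif tie_method == "efron":
            tied_sum = exp_s[tied].sum()
            ls = np.log(risk_sum - (np.arange(d) / d) * tied_sum).sum()
            npll += ls - scores[tied].sum()
        else:
            raise ValueError(f"unknown tie method {tie_method!r}")
    return float(npll)


def cox_npll_grad(scores, times, events) -> np.ndarray:
    """Gradient of the Breslow negative partial log-likelihood."""
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    exp_s = np.exp(scores)
    grad = -events.astype(float)
    for t in np.unique(times[events]):
        at_risk = times >= t
        d = int((events & (times == t)).sum())
        risk_sum = exp_s[at_risk].sum()
        grad[at_risk] += d * exp_s[at_risk] / risk_sum
    return grad


def bce(prob, label) -> float:
    """Binary cross-entropy, probabilities clipped at 1e-7; mean over a batch."""
    p = np.clip(np.asarray(prob, dtype=float), 1e-7, 1.0 - 1e-7)
    y = np.asarray(label, dtype=float)
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


def joint_loss(
    scores, times, events, cfg: JointLossConfig | None = None
) -> float:
    """cox_npll + lambda_bce · BCE(sigmoid(score), event)."""
    cfg = cfg or JointLossConfig()
    loss = cox_npll(scores, times, events, cfg.tie_method)
    if cfg.lambda_bce > 0:
        loss += cfg.lambda_bce * bce(nn.sigmoid(np.asarray(scores, dtype=float)),
                                     np.asarray(events, dtype=float))
    return loss


def joint_loss_grad(scores, times, events, cfg: JointLossConfig) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    events_f = np.asarray(events, dtype=float)
    grad = cox_npll_grad(scores, times, events)
    if cfg.lambda_bce > 0:
        p = nn.sigmoid(scores)
        grad = grad + cfg.lambda_bce * (p - events_f) / len(scores)
    return grad


# ---------------------------------------------------------------------------
# Tile features and the risk network
# ---------------------------------------------------------------------------


def tile_features(pixels: np.ndarray) -> np.ndarray:
    """Compact per-tile summary fed to the risk network.

    Channel means and standard deviations, overall luminance spread and a
    local-gradient magnitude — enough to carry the texture/contrast signal
    without convolution at the survival stage.
    """
    px = np.asarray(pixels, dtype=float) / 255.0
    means = px.mean(axis=(0, 1))
    stds = px.std(axis=(0, 1))
    gray = px.mean(axis=2)
    grad = 0.5 * (np.abs(np.diff(gray, axis=0)).mean()
                  + np.abs(np.diff(gray, axis=1)).mean())
    return np.concatenate([means, stds, [gray.std(), grad]])


N_TILE_FEATURES = 8


@dataclass
class RiskNetConfig:
    hidden: tuple[int, ...] = (16,)
    learning_rate: float = 0.02
    max_epochs: int = 80
    steps_per_epoch: int = 10       # full-batch gradient steps per epoch
    patience: int = 3               # epochs of non-improving validation loss
    val_fraction: float = 0.25
    seed: int = 0


@dataclass
class TissueRiskModel:
    """Trained risk network for one tissue category."""

    tissue: TissueClass
    net: nn.Sequential
    feat_mean: np.ndarray
    feat_std: np.ndarray
    score_min: float
    score_max: float
    train_log: list = field(default_factory=list)

    def tile_scores(self, tiles: Sequence[Tile]) -> np.ndarray:
        """Raw per-tile risk scores (no pooling, no normalization)."""
        X = np.stack([tile_features(t.pixels) for t in tiles])
        X = (X - self.feat_mean) / self.feat_std
        return self.net.forward(X, train=False)[:, 0]

    def raw_score(self, tiles: Sequence[Tile]) -> float:
        """Mean-pooled patient score for one patient's tiles of this class."""
        return float(self.tile_scores(tiles).mean())

    def normalized_score(self, tiles: Sequence[Tile]) -> float:
        span = self.score_max - self.score_min
        if span <= 0:
            return 0.5
        return float((self.raw_score(tiles) - self.score_min) / span)


def _pool_matrix(patients, cls):
    """Stack tile features for all patients holding tiles of ``cls``.

    Returns (X, group_index, kept_patient_positions)."""
    feats, group, kept = [], [], []
    for idx, p in enumerate(patients):
        tiles = p.tiles.get(cls, [])
        if not tiles:
            continue
        kept.append(idx)
        for t in tiles:
            feats.append(tile_features(t.pixels))
            group.append(len(kept) - 1)
    if not feats:
        return np.zeros((0, N_TILE_FEATURES)), np.zeros(0, int), []
    return np.stack(feats), np.asarray(group), kept


def train_tissue_risk(
    patients: Sequence[PatientRecord],
    cls: TissueClass,
    loss_cfg: JointLossConfig | None = None,
    net_cfg: RiskNetConfig | None = None,
    seed: int | None = None,
) -> tuple[TissueRiskModel, dict[str, float]]:
    """Fit the risk network of one tissue category on a patient cohort.

    Per-tile scores are mean-pooled per patient; the joint Cox+BCE loss is
    minimized full-batch with Adam; training stops once the validation loss
    has not improved for ``patience`` epochs and the best checkpoint is
    restored. Returns the model and the min–max-normalized score of every
    patient in the cohort (NaN for patients without tiles of this class).
    """
    loss_cfg = loss_cfg or JointLossConfig()
    net_cfg = net_cfg or RiskNetConfig()
    if seed is None:
        seed = net_cfg.seed

    X, group, kept = _pool_matrix(patients, cls)
    if len(kept) < 10:
        raise ValueError(f"need ≥ 10 patients with {cls} tiles; got {len(kept)}")
    times = np.array([patients[i].ttr_months for i in kept])
    events = np.array([patients[i].recurrence_event for i in kept])
    if events.sum() < 3:
        raise ValueError("need at least 3 recurrence events")

    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std < 1e-8] = 1.0
    Xn = (X - mean) / std

    rng = np.random.default_rng(seed)
    n_pat = len(kept)
    perm = rng.permutation(n_pat)
    n_val = max(2, int(round(net_cfg.val_fraction * n_pat)))
    # ensure events on both sides of the split when possible
    val_idx = np.zeros(n_pat, dtype=bool)
    val_idx[perm[:n_val]] = True
    if not events[val_idx].any() or not events[~val_idx].any():
        ev_pos = np.flatnonzero(events)
        val_idx[:] = False
        val_idx[perm[:n_val]] = True
        val_idx[ev_pos[0]] = True
        val_idx[ev_pos[-1]] = False

    layers: list[nn.Layer] = []
    d_in = Xn.shape[1]
    for h in net_cfg.hidden:
        layers += [nn.Dense(d_in, h, rng), nn.ReLU()]
        d_in = h
    layers.append(nn.Dense(d_in, 1, rng))
    net = nn.Sequential(layers)
    opt = nn.Adam(net.params, net.grads, lr=net_cfg.learning_rate)

    counts = np.bincount(group, minlength=n_pat).astype(float)
    tr_mask, va_mask = ~val_idx, val_idx
    best_val, best_state, since_best = np.inf, nn.get_state(net), 0
    log = []
    for epoch in range(net_cfg.max_epochs):
        for _ in range(net_cfg.steps_per_epoch):
            tile_scores = net.forward(Xn, train=True)[:, 0]
            pat_scores = np.bincount(group, weights=tile_scores, minlength=n_pat) / counts

            g_pat = np.zeros(n_pat)
            g_pat[tr_mask] = joint_loss_grad(
                pat_scores[tr_mask], times[tr_mask], events[tr_mask], loss_cfg
            )
            g_tile = g_pat[group] / counts[group]
            net.backward(g_tile[:, None])
            opt.step()

        eval_scores = net.forward(Xn, train=False)[:, 0]
        pat_eval = np.bincount(group, weights=eval_scores, minlength=n_pat) / counts
        tr_loss = joint_loss(pat_eval[tr_mask], times[tr_mask], events[tr_mask], loss_cfg)
        if events[va_mask].any():
            va_loss = joint_loss(pat_eval[va_mask], times[va_mask], events[va_mask], loss_cfg)
        else:
            va_loss = tr_loss
        log.append({"epoch": epoch, "train_loss": tr_loss, "val_loss": va_loss})
        if va_loss < best_val - 1e-9:
            best_val, best_state, since_best = va_loss, nn.get_state(net), 0
        else:
            since_best += 1
            if since_best > net_cfg.patience:
                break
    nn.set_state(net, best_state)

    final_tiles = net.forward(Xn, train=False)[:, 0]
    final_pat = np.bincount(group, weights=final_tiles, minlength=n_pat) / counts
    lo, hi = float(final_pat.min()), float(final_pat.max())
    model = TissueRiskModel(
        tissue=cls, net=net, feat_mean=mean, feat_std=std,
        score_min=lo, score_max=hi, train_log=log,
    )
    span = hi - lo
    scores_out: dict[str, float] = {}
    for idx, p in enumerate(patients):
        if idx in kept:
            raw = final_pat[kept.index(idx)]
            scores_out[p.patient_id] = (raw - lo) / span if span > 0 else 0.5
        else:
            scores_out[p.patient_id] = float("nan")
    return model, scores_out


def crossfit_scores(
    patients: Sequence[PatientRecord],
    cls: TissueClass,
    n_folds: int = 3,
    loss_cfg: JointLossConfig | None = None,
    net_cfg: RiskNetConfig | None = None,
    seed: int = 0,
) -> dict[str, float]:
    """Out-of-fold (pre-validated) risk scores for one tissue class.

    Each patient's score comes from a network that never saw them, so a
    downstream Cox fit over the scores is not biased by in-sample
    overfitting of the risk networks. Use these for weight fitting; use the
    full-cohort model from :func:`train_tissue_risk` for scoring new data.
    """
    rng = np.random.default_rng(seed)
    n = len(patients)
    fold_of = rng.integers(0, n_folds, size=n)
    # guard: every fold needs a trainable complement
    scores: dict[str, float] = {}
    for k in range(n_folds):
        fit_patients = [p for p, f in zip(patients, fold_of) if f != k]
        out_patients = [p for p, f in zip(patients, fold_of) if f == k]
        if not out_patients:
            continue
        model, _ = train_tissue_risk(
            fit_patients, cls, loss_cfg, net_cfg,
            seed=seed * n_folds + k + 1,
        )
        scores.update(score_cohort(model, out_patients))
    return scores


def score_cohort(
    model: TissueRiskModel, patients: Sequence[PatientRecord]
) -> dict[str, float]:
    """Normalized risk score of ``model``'s tissue class for each patient
    (NaN where a patient has no tiles of that class). Normalization uses
    the training-cohort min–max stored on the model."""
    out: dict[str, float] = {}
    for p in patients:
        tiles = p.tiles.get(model.tissue, [])
        out[p.patient_id] = model.normalized_score(tiles) if tiles else float("nan")
    return out


def build_profiles(
    patients: Sequence[PatientRecord],
    scores_by_class: dict[TissueClass, dict[str, float]],
) -> list[TissueRiskProfile]:
    """Assemble per-patient TissueRiskProfiles from per-class score maps."""
    profiles = []
    for p in patients:
        s, missing = {}, set()
        for cls in CLASS_ORDER:
            val = scores_by_class.get(cls, {}).get(p.patient_id, float("nan"))
            s[cls] = val
            if not np.isfinite(val):
                missing.add(cls)
        profiles.append(TissueRiskProfile(patient_id=p.patient_id, s=s, missing=missing))
    return profiles


# ---------------------------------------------------------------------------
# Attention visualization
# ---------------------------------------------------------------------------


def normalize_attention(values: np.ndarray) -> np.ndarray:
    """Min–max normalize attention values to [0,1]; constant maps → 0."""
    v = np.asarray(values, dtype=float)
    span = v.max() - v.min()
    if span <= 0:
        return np.zeros_like(v)
    return (v - v.min()) / span


def attention_map(
    model: TissueRiskModel, tiles: Sequence[Tile],
    grid_shape: Optional[tuple[int, int]] = None,
) -> np.ndarray:
    """Per-tile attention in [0,1]: each tile's risk contribution, min–max
    normalized across the slide (red-high when rendered)."""
    scores = model.tile_scores(tiles)
    att = normalize_attention(scores)
    if grid_shape is not None:
        att = att.reshape(grid_shape)
    return att
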