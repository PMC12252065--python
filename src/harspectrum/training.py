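"""Constraint sampling, label budgets, and one trainer per learning paradigm.

Paradigms
---------
``supervised``      residual TCN + cross-entropy on raw windows
``unsupervised``    residual autoencoder + reconstruction loss on features
``weak_single``     Siamese TCN + activity contrastive loss on raw windows
``weak_multi``      two-head Siamese TCN + weighted activity/person contrastive
``selfsup``         residual autoencoder + joint consistency loss on features
``weak_selfsup``    two stages: the self-supervised joint loss on all features,
                    then the joint loss plus the activity contrastive term on
                    pairs drawn from a small label budget

All stochastic choices (initialization, batch order, pair sampling) flow from
``TrainingConfig.seed`` through explicit generators, so identical
config + seed + data reproduces the final parameters bit for bit.  Trainers
optimize the mean-reduction form of each printed objective and log a per-epoch
decomposition of the loss terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data_synth import SensorWindow, windows_to_arrays
from .features import FeatureScaler, NeighborhoodIndex, build_neighborhood_index, features_matrix
from .losses import (LossWeights, contrastive_loss, cross_entropy_from_logits,
                     multitask_loss, reconstruction_loss, selfsup_loss,
                     weak_selfsup_loss)
from .models import (EncoderSpec, ModelBundle, build_residual_autoencoder,
                     build_siamese, build_tcn_encoder)
from .nn import make_optimizer

__all__ = [
    "TrainingConfig", "ConstraintSet", "sample_pairs", "sample_quadruples",
    "subsample_label_budget", "train_supervised", "train_autoencoder",
    "train_weak_single", "train_weak_multi", "train_selfsup",
    "train_weak_selfsup", "history_to_csv",
]

PARADIGMS = ("supervised", "unsupervised", "weak_single", "weak_multi",
             "selfsup", "weak_selfsup")


@dataclass(frozen=True)
class TrainingConfig:
    paradigm: str = "supervised"
    epochs_stage1: int = 50
    epochs_stage2: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    label_fraction: float = 1.0
    pairs_per_epoch: int | None = None  # defaults to 4x the window count
    weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    embedding_dim: int = 32
    knn_k: int = 5
    temporal_radius: int = 2

    def __post_init__(self):
        if self.paradigm not in PARADIGMS:
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if self.epochs_stage1 < 1 or self.epochs_stage2 < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 < self.label_fraction <= 1:
            raise ValueError("label_fraction must be in (0, 1]")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class ConstraintSet:
    """Weak-supervision pairs (or quadruples) indexing into a window set."""

    idx_a: np.ndarray
    idx_b: np.ndarray
    y_act: np.ndarray
    y_pers: np.ndarray | None = None
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.idx_a)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), 11, stream]))


# ---------------------------------------------------------------------------
# constraint sampling and label budgets
# ---------------------------------------------------------------------------

def sample_pairs(y_act: np.ndarray, n_pairs: int,
                 positive_fraction: float = 0.5, seed: int = 0,
                 allowed: np.ndarray | None = None) -> ConstraintSet:
    """Uniformly sample index pairs (with replacement, a != b) until the
    positive/negative quota is met; labels are set from the ground truth.

    ``allowed`` restricts sampling to a subset of window indices (the label
    budget of the weakly self-supervised second stage).
    """
    y_act = np.asarray(y_act)
    pool = np.arange(len(y_act)) if allowed is None else np.asarray(allowed)
    if len(pool) < 2:
        raise ValueError("need at least two windows to form pairs")
    n_pos = int(round(positive_fraction * n_pairs))
    n_neg = n_pairs - n_pos
    labels_pool = y_act[pool]
    classes, counts = np.unique(labels_pool, return_counts=True)
    if n_pos > 0 and not np.any(counts >= 2):
        raise ValueError("no class has two windows: cannot form positive pairs")
    if n_neg > 0 and len(classes) < 2:
        raise ValueError("dataset has a single class: cannot form negative pairs")
    rng = _rng(seed, 1)
    got_pos: list[tuple[int, int]] = []
    got_neg: list[tuple[int, int]] = []
    while len(got_pos) < n_pos or len(got_neg) < n_neg:
        a = pool[rng.integers(0, len(pool), size=4 * n_pairs + 8)]
        b = pool[rng.integers(0, len(pool), size=4 * n_pairs + 8)]
        ok = a != b
        same = (y_act[a] == y_act[b]) & ok
        diff = (y_act[a] != y_act[b]) & ok
        got_pos.extend(zip(a[same], b[same]))
        got_neg.extend(zip(a[diff], b[diff]))
    pairs = got_pos[:n_pos] + got_neg[:n_neg]
    idx_a = np.array([p[0] for p in pairs], dtype=np.int64)
    idx_b = np.array([p[1] for p in pairs], dtype=np.int64)
    return ConstraintSet(idx_a, idx_b,
                         (y_act[idx_a] == y_act[idx_b]).astype(np.int64),
                         provenance="activity labels")


def sample_quadruples(y_act: np.ndarray, y_pers: np.ndarray, n_pairs: int,
                      quota: dict[tuple[int, int], float] | None = None,
                      seed: int = 0) -> ConstraintSet:
    """Sample pairs with a quota over the four (y_act, y_pers) cells
    (default: balanced quarters) so both tasks see both label values."""
    y_act, y_pers = np.asarray(y_act), np.asarray(y_pers)
    if quota is None:
        quota = {(1, 1): 0.25, (1, 0): 0.25, (0, 1): 0.25, (0, 0): 0.25}
    targets = {cell: int(round(f * n_pairs)) for cell, f in quota.items()}
    # distribute rounding remainder deterministically
    short = n_pairs - sum(targets.values())
    for cell in sorted(targets):
        if short == 0:
            break
        targets[cell] += 1 if short > 0 else -1
        short += -1 if short > 0 else 1
    rng = _rng(seed, 2)
    got: dict[tuple[int, int], list[tuple[int, int]]] = {c: [] for c in targets}
    n = len(y_act)
    for attempt in range(200):
        if all(len(got[c]) >= t for c, t in targets.items()):
            break
        a = rng.integers(0, n, size=8 * n_pairs + 8)
        b = rng.integers(0, n, size=8 * n_pairs + 8)
        ok = a != b
        cell_act = (y_act[a] == y_act[b]).astype(int)
        cell_pers = (y_pers[a] == y_pers[b]).astype(int)
        for (ca, cp), t in targets.items():
            if len(got[(ca, cp)]) >= t:
                continue
            m = ok & (cell_act == ca) & (cell_pers == cp)
            got[(ca, cp)].extend(zip(a[m], b[m]))
    for cell, t in targets.items():
        if len(got[cell]) < t:
            raise ValueError(
                f"cannot satisfy quadruple quota for (y_act, y_pers)={cell}; "
                "the dataset lacks such pairs")
    pairs: list[tuple[int, int]] = []
    for cell in sorted(targets):
        pairs.extend(got[cell][: targets[cell]])
    idx_a = np.array([p[0] for p in pairs], dtype=np.int64)
    idx_b = np.array([p[1] for p in pairs], dtype=np.int64)
    return ConstraintSet(idx_a, idx_b,
                         (y_act[idx_a] == y_act[idx_b]).astype(np.int64),
                         (y_pers[idx_a] == y_pers[idx_b]).astype(np.int64),
                         provenance="activity + person labels")


def subsample_label_budget(y_act: np.ndarray, fraction: float,
                           seed: int = 0) -> np.ndarray:
    """Stratified label budget: per class, ceil(fraction * n_class) windows,
    at least one per class."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    y_act = np.asarray(y_act)
    rng = _rng(seed, 3)
    chosen: list[np.ndarray] = []
    for cls in np.unique(y_act):
        idx = np.where(y_act == cls)[0]
        n_take = max(1, int(np.ceil(fraction * len(idx))))
        chosen.append(rng.choice(idx, size=min(n_take, len(idx)), replace=False))
    return np.sort(np.concatenate(chosen))


# ---------------------------------------------------------------------------
# shared trainer machinery
# ---------------------------------------------------------------------------

def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _default_spec_raw(x: np.ndarray, config: TrainingConfig) -> EncoderSpec:
    return EncoderSpec(input_shape=(x.shape[1], x.shape[2]),
                       embedding_dim=config.embedding_dim)


def _default_spec_features(f: np.ndarray, config: TrainingConfig) -> EncoderSpec:
    # feature-space encoders keep a tight bottleneck well below the 7C input
    # width: compression is what forces the choice between stationary and
    # nuisance directions that the consistency objectives steer
    h = min(config.embedding_dim, 8, max(2, f.shape[1] - 1))
    return EncoderSpec(input_shape=f.shape[1], embedding_dim=h, kernel_size=5)


def _prepare_features(windows_or_features, config: TrainingConfig):
    """Standardized feature matrix + scaler (z-scoring with training stats)."""
    if isinstance(windows_or_features, np.ndarray):
        feats = windows_or_features
    else:
        feats = features_matrix(windows_or_features)
    scaler = FeatureScaler().fit(feats)
    return scaler.transform(feats), scaler


def _attach_scaler(bundle: ModelBundle, scaler: FeatureScaler) -> None:
    bundle.extras["scaler_mean"] = scaler.mean_.tolist()
    bundle.extras["scaler_std"] = scaler.std_.tolist()


def _finalize(bundle: ModelBundle, paradigm: str, history: list[dict]) -> ModelBundle:
    bundle.paradigm = paradigm
    bundle.extras["history"] = history
    bundle.eval()
    return bundle


def history_to_csv(history: list[dict], path: str | Path) -> None:
    """Per-epoch loss decomposition as ``epoch,term,value`` rows."""
    rows = [{"epoch": h["epoch"], "term": term, "value": v}
            for h in history for term, v in h.items()
            if term != "epoch" and isinstance(v, (int, float))]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# trainers
# ---------------------------------------------------------------------------

def train_supervised(windows: list[SensorWindow] | tuple, config: TrainingConfig,
                     spec: EncoderSpec | None = None) -> ModelBundle:
    """Residual TCN classifier trained with cross-entropy on raw windows."""
    x, y_act, _, _ = (windows_to_arrays(windows) if isinstance(windows, list)
                      else windows)
    n_classes = int(y_act.max()) + 1
    spec = spec or _default_spec_raw(x, config)
    bundle = build_tcn_encoder(spec, seed=config.seed, n_classes=n_classes)
    onehot = np.eye(n_classes)[y_act]
    opt = make_optimizer(config.optimizer, bundle.parameters(), config.learning_rate)
    rng = _rng(config.seed, 10)
    history = []
    for epoch in range(config.epochs_stage1):
        bundle.train()
        losses = []
        for idx in _batches(len(x), config.batch_size, rng):
            opt.zero_grad()
            logits = bundle.classifier(bundle.encoder(x[idx]))
            loss = cross_entropy_from_logits(logits, onehot[idx])
            loss.backward()
            opt.step()
            losses.append(float(loss.value))
        m = float(np.mean(losses))
        history.append({"epoch": epoch, "ce": m, "total": m})
    return _finalize(bundle, "supervised", history)


def train_autoencoder(features, config: TrainingConfig,
                      spec: EncoderSpec | None = None) -> ModelBundle:
    """Plain residual autoencoder on handcrafted features (unsupervised)."""
    f, scaler = _prepare_features(features, config)
    spec = spec or _default_spec_features(f, config)
    bundle = build_residual_autoencoder(spec, seed=config.seed)
    _attach_scaler(bundle, scaler)
    opt = make_optimizer(config.optimizer, bundle.parameters(), config.learning_rate)
    rng = _rng(config.seed, 11)
    history = []
    for epoch in range(config.epochs_stage1):
        bundle.train()
        losses = []
        for idx in _batches(len(f), config.batch_size, rng):
            opt.zero_grad()
            _, recon = bundle.encoder(f[idx])
            loss = reconstruction_loss(f[idx], recon, reduction="mean")
            loss.backward()
            opt.step()
            losses.append(float(loss.value))
        m = float(np.mean(losses))
        history.append({"epoch": epoch, "ae": m, "total": m})
    return _finalize(bundle, "unsupervised", history)


def _train_siamese_contrastive(x: np.ndarray, constraints: ConstraintSet,
                               config: TrainingConfig, heads: int,
                               spec: EncoderSpec | None) -> ModelBundle:
    spec = spec or _default_spec_raw(x, config)
    base = build_tcn_encoder(spec, seed=config.seed)
    bundle = build_siamese(base, heads=heads, seed=config.seed)
    opt = make_optimizer(config.optimizer, bundle.parameters(), config.learning_rate)
    rng = _rng(config.seed, 12)
    w = config.weights
    history = []
    for epoch in range(config.epochs_stage1):
        bundle.train()
        terms: dict[str, list[float]] = {"simi_act": [], "simi_pers": [], "total": []}
        for bidx in _batches(len(constraints), config.batch_size, rng):
            opt.zero_grad()
            ia, ib = constraints.idx_a[bidx], constraints.idx_b[bidx]
            out = bundle.siamese(x[ia], x[ib])
            fa, fb = out["act"]
            act_loss, _ = contrastive_loss(fa, fb, constraints.y_act[bidx],
                                           delta=w.margin_delta, reduction="mean")
            if heads == 2:
                pa, pb = out["pers"]
                pers_loss, _ = contrastive_loss(pa, pb, constraints.y_pers[bidx],
                                                delta=w.margin_delta,
                                                reduction="mean")
                loss = multitask_loss(act_loss, pers_loss, w.alpha, w.beta)
                terms["simi_pers"].append(float(pers_loss.value))
            else:
                loss = act_loss
            loss.backward()
            opt.step()
            terms["simi_act"].append(float(act_loss.value))
            terms["total"].append(float(loss.value))
        entry = {"epoch": epoch,
                 "simi_act": float(np.mean(terms["simi_act"])),
                 "total": float(np.mean(terms["total"]))}
        if heads == 2:
            entry["simi_pers"] = float(np.mean(terms["simi_pers"]))
        history.append(entry)
    return bundle, history


def train_weak_single(windows, constraints: ConstraintSet,
                      config: TrainingConfig,
                      spec: EncoderSpec | None = None) -> ModelBundle:
    """Siamese TCN trained with the activity contrastive loss on pairs."""
    x = windows if isinstance(windows, np.ndarray) else windows_to_arrays(windows)[0]
    bundle, history = _train_siamese_contrastive(x, constraints, config,
                                                 heads=1, spec=spec)
    return _finalize(bundle, "weak_single", history)


def train_weak_multi(windows, constraints: ConstraintSet,
                     config: TrainingConfig,
                     spec: EncoderSpec | None = None) -> ModelBundle:
    """Two-head Siamese TCN with the weighted activity+person objective."""
    if constraints.y_pers is None:
        raise ValueError("weak_multi needs quadruple constraints with y_pers")
    x = windows if isinstance(windows, np.ndarray) else windows_to_arrays(windows)[0]
    bundle, history = _train_siamese_contrastive(x, constraints, config,
                                                 heads=2, spec=spec)
    return _finalize(bundle, "weak_multi", history)


def _moment_tables(f: np.ndarray, index: NeighborhoodIndex):
    """Precompute neighbor-moment tables for the consistency terms."""
    from .losses import neighbor_moments_table
    tc = neighbor_moments_table(f, index.temporal)
    fc = neighbor_moments_table(f, index.feature)
    return tc, fc


def _run_selfsup_epochs(bundle: ModelBundle, f: np.ndarray,
                        index: NeighborhoodIndex, config: TrainingConfig,
                        weights: LossWeights, opt, rng, epochs: int,
                        history: list[dict], stage: str) -> None:
    (tc_mean, tc_msn), (fc_mean, fc_msn) = _moment_tables(f, index)
    for epoch in range(epochs):
        bundle.train()
        totals: dict[str, list[float]] = {"ae": [], "tc": [], "fc": [], "total": []}
        for idx in _batches(len(f), config.batch_size, rng):
            opt.zero_grad()
            _, recon = bundle.encoder(f[idx])
            loss, parts = selfsup_loss(
                f[idx], recon,
                (tc_mean[idx], tc_msn[idx]),
                (fc_mean[idx], fc_msn[idx]),
                weights, reduction="mean")
            loss.backward()
            opt.step()
            for k in ("ae", "tc", "fc"):
                totals[k].append(parts[k])
            totals["total"].append(float(loss.value))
        history.append({"epoch": len(history), "stage": stage,
                        **{k: float(np.mean(v)) for k, v in totals.items()}})


def train_selfsup(features, neighborhoods: NeighborhoodIndex | None,
                  config: TrainingConfig,
                  spec: EncoderSpec | None = None,
                  windows: list[SensorWindow] | None = None) -> ModelBundle:
    """Residual autoencoder trained with the joint self-supervised loss
    (reconstruction + temporal and feature consistency)."""
    f, scaler = _prepare_features(features, config)
    if neighborhoods is None:
        if windows is None:
            raise ValueError("need a NeighborhoodIndex or the window list")
        neighborhoods = build_neighborhood_index(
            windows, radius=config.temporal_radius, k=config.knn_k)
    spec = spec or _default_spec_features(f, config)
    bundle = build_residual_autoencoder(spec, seed=config.seed)
    _attach_scaler(bundle, scaler)
    opt = make_optimizer(config.optimizer, bundle.parameters(), config.learning_rate)
    rng = _rng(config.seed, 13)
    history: list[dict] = []
    w = replace(config.weights, gamma=0.0)
    _run_selfsup_epochs(bundle, f, neighborhoods, config, w, opt, rng,
                        config.epochs_stage1, history, stage="selfsup")
    return _finalize(bundle, "selfsup", history)


def train_weak_selfsup(features, neighborhoods: NeighborhoodIndex | None,
                       constraints: ConstraintSet | None,
                       config: TrainingConfig,
                       spec: EncoderSpec | None = None,
                       windows: list[SensorWindow] | None = None) -> ModelBundle:
    """Two-stage weakly self-supervised training.

    Stage 1 minimizes the self-supervised joint loss on all features (no
    activity labels read).  Stage 2 wraps the autoencoder in a Siamese model
    and minimizes the joint loss plus the activity contrastive term on the
    supplied constraints, which must reference only budget-labeled windows.
    """
    f, scaler = _prepare_features(features, config)
    if neighborhoods is None:
        if windows is None:
            raise ValueError("need a NeighborhoodIndex or the window list")
        neighborhoods = build_neighborhood_index(
            windows, radius=config.temporal_radius, k=config.knn_k)
    spec = spec or _default_spec_features(f, config)
    base = build_residual_autoencoder(spec, seed=config.seed)
    _attach_scaler(base, scaler)
    opt = make_optimizer(config.optimizer, base.parameters(), config.learning_rate)
    rng = _rng(config.seed, 13)  # same stream as train_selfsup: identical stage 1
    history: list[dict] = []
    stage1_w = LossWeights(alpha=0.3, beta=0.3, gamma=0.0,
                           margin_delta=config.weights.margin_delta)
    _run_selfsup_epochs(base, f, neighborhoods, config, stage1_w, opt, rng,
                        config.epochs_stage1, history, stage="stage1")

    if constraints is None or len(constraints) == 0:
        warnings.warn("empty constraint set: returning the stage-1 model",
                      stacklevel=2)
        return _finalize(base, "weak_selfsup", history)

    bundle = build_siamese(base, heads=1, seed=config.seed)
    bundle.decoder_of = base.encoder
    # the optimizer restarts for stage 2 with the new head parameters
    opt = make_optimizer(config.optimizer, bundle.parameters(), config.learning_rate)
    rng2 = _rng(config.seed, 14)
    w = config.weights
    ae = base.encoder  # the shared residual autoencoder trunk
    (tc_mean, tc_msn), (fc_mean, fc_msn) = _moment_tables(f, neighborhoods)
    for epoch in range(config.epochs_stage2):
        bundle.train()
        totals: dict[str, list[float]] = {k: [] for k in
                                          ("ae", "tc", "fc", "simi_act", "total")}
        for bidx in _batches(len(constraints), config.batch_size, rng2):
            opt.zero_grad()
            ia, ib = constraints.idx_a[bidx], constraints.idx_b[bidx]
            n = len(ia)
            both_z, both_recon = ae(np.concatenate([f[ia], f[ib]], axis=0))
            za, zb = both_z[:n], both_z[n:]
            ra, rb = both_recon[:n], both_recon[n:]
            ea, eb = bundle.siamese.act_head(za), bundle.siamese.act_head(zb)
            loss, parts = weak_selfsup_loss(
                f[ia], f[ib], ra, rb, ea, eb, constraints.y_act[bidx],
                (tc_mean[ia], tc_msn[ia]), (fc_mean[ia], fc_msn[ia]),
                (tc_mean[ib], tc_msn[ib]), (fc_mean[ib], fc_msn[ib]),
                w, reduction="mean")
            loss.backward()
            opt.step()
            for k in ("ae", "tc", "fc", "simi_act"):
                totals[k].append(parts[k])
            totals["total"].append(float(loss.value))
        history.append({"epoch": len(history), "stage": "stage2",
                        **{k: float(np.mean(v)) for k, v in totals.items()}})
    return _finalize(bundle, "weak_selfsup", history)
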