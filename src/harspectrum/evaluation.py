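"""Embedding, k-means clustering with optimal cluster-to-class mapping, and
the experiment harness.

Representation quality is scored the standard way for clustering-based
evaluation: embed every window, run k-means with k equal to the number of
classes, build the cluster-by-class contingency table, find the injective
cluster-to-class mapping that maximizes the matched count (Hungarian
assignment), and report the mapped accuracy and macro-F1.  Samples in
clusters left unmapped (possible when k differs from the class count) are
counted as errors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import f1_score

from .data_synth import SynthConfig, generate_streams, segment_windows, windows_to_arrays
from .features import build_neighborhood_index, features_matrix
from .losses import LossWeights
from .models import ModelBundle
from .training import (ConstraintSet, TrainingConfig, sample_pairs,
                       sample_quadruples, subsample_label_budget,
                       train_autoencoder, train_selfsup, train_supervised,
                       train_weak_multi, train_weak_selfsup, train_weak_single)

__all__ = [
    "RepresentationSet", "ClusteringResult", "embed_dataset", "kmeans_cluster",
    "cluster_accuracy", "classification_report", "run_experiment",
    "run_ablation", "evaluate_paradigm", "export_embeddings_csv",
    "plot_embeddings",
]


@dataclass
class RepresentationSet:
    embeddings: np.ndarray   # (N, H)
    activity: np.ndarray
    person: np.ndarray
    paradigm: str = ""

    def __post_init__(self):
        if len(self.embeddings) != len(self.activity):
            raise ValueError("row count must match label count")
        if not np.all(np.isfinite(self.embeddings)):
            raise ValueError("embeddings contain non-finite values")


@dataclass
class ClusteringResult:
    assignments: np.ndarray
    k: int
    mapping: dict[int, int]      # cluster id -> class id (injective)
    accuracy: float
    macro_f1: float
    contingency: np.ndarray      # (k, M)


def embed_dataset(model: ModelBundle, data: np.ndarray, activity: np.ndarray,
                  person: np.ndarray, head: str = "act") -> RepresentationSet:
    """Evaluation-mode forward pass over a dataset; deterministic."""
    emb = model.embed(data, head=head)
    return RepresentationSet(emb, np.asarray(activity), np.asarray(person),
                             paradigm=model.paradigm)


def kmeans_cluster(reps: RepresentationSet, k: int, n_init: int = 10,
                   seed: int = 0) -> np.ndarray:
    """Best-inertia k-means assignments over ``n_init`` seeded restarts."""
    n = len(reps.embeddings)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available samples")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(reps.embeddings)


def cluster_accuracy(assignments: np.ndarray, true_labels: np.ndarray,
                     n_classes: int | None = None) -> ClusteringResult:
    """Map clusters to classes by optimal injective assignment and score.

    Accuracy is the matched fraction; macro-F1 is computed on the mapped
    predictions with samples of unmapped clusters counted as errors.
    """
    assignments = np.asarray(assignments)
    true_labels = np.asarray(true_labels)
    clusters = np.unique(assignments)
    k = len(clusters)
    m = n_classes if n_classes is not None else int(true_labels.max()) + 1
    cont = np.zeros((k, m), dtype=np.int64)
    for ci, c in enumerate(clusters):
        for cls in range(m):
            cont[ci, cls] = np.sum((assignments == c) & (true_labels == cls))
    row, col = linear_sum_assignment(cont, maximize=True)
    mapping = {int(clusters[r]): int(c) for r, c in zip(row, col)}
    mapped = np.array([mapping.get(int(a), -1) for a in assignments])
    accuracy = float(np.mean(mapped == true_labels))
    macro_f1 = float(f1_score(true_labels, mapped, labels=np.arange(m),
                              average="macro", zero_division=0.0))
    return ClusteringResult(assignments=assignments, k=k, mapping=mapping,
                            accuracy=accuracy, macro_f1=macro_f1,
                            contingency=cont)


def classification_report(model: ModelBundle, x: np.ndarray,
                          y: np.ndarray) -> tuple[float, float]:
    """Accuracy and macro-F1 of the supervised classifier head."""
    proba = model.predict_proba(x)
    pred = proba.argmax(axis=1)
    y = np.asarray(y)
    acc = float(np.mean(pred == y))
    f1 = float(f1_score(y, pred, average="macro", zero_division=0.0))
    return acc, f1


# ---------------------------------------------------------------------------
# experiment harness
# ---------------------------------------------------------------------------

def _make_windows(synth_cfg: SynthConfig, window_seconds: float = 2.56,
                  step_seconds: float = 1.28):
    streams = generate_streams(synth_cfg)
    windows = [w for s in streams for w in segment_windows(s, window_seconds,
                                                           step_seconds)]
    return windows


def _stratified_split(y: np.ndarray, test_fraction: float, seed: int):
    rng = np.random.default_rng(np.random.SeedSequence([seed, 55]))
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        idx = rng.permutation(np.where(y == cls)[0])
        n_test = max(1, int(round(test_fraction * len(idx))))
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def _paradigm_weights(paradigm: str, ablation: str | None = None) -> LossWeights:
    """Package defaults per paradigm (the printed equations give none)."""
    if paradigm == "weak_multi":
        return LossWeights(alpha=0.5, beta=0.5, gamma=0.0)
    if paradigm == "weak_selfsup":
        # the similarity term dominates stage 2
        return LossWeights(alpha=0.1, beta=0.1, gamma=0.6)
    if paradigm == "selfsup":
        if ablation == "ae":
            return LossWeights(alpha=0.0, beta=0.0)
        if ablation == "tc+ae":
            return LossWeights(alpha=0.3, beta=0.0)
        if ablation == "fc+ae":
            return LossWeights(alpha=0.0, beta=0.3)
        return LossWeights(alpha=0.3, beta=0.3)
    return LossWeights()


def evaluate_paradigm(paradigm: str, windows, seed: int,
                      label_fraction: float = 1.0,
                      config: TrainingConfig | None = None,
                      ablation: str | None = None,
                      kmeans_seed: int = 0) -> dict:
    """Train one paradigm on a window set and evaluate it.

    Clustering paradigms are scored by mapped k-means accuracy/macro-F1 over
    all windows; the supervised paradigm trains on a stratified 80% split and
    reports held-out classification metrics.
    """
    x, y_act, y_pers, _ = windows_to_arrays(windows)
    n_classes = int(y_act.max()) + 1
    feats = features_matrix(windows)
    if config is None:
        # CPU-scale experiment settings: the raw-window TCN paradigms get
        # fewer, larger-cost epochs; feature-space paradigms keep the longer
        # default schedule (they are orders of magnitude cheaper per step)
        raw = paradigm in ("supervised", "weak_single", "weak_multi")
        config = TrainingConfig(
            paradigm=paradigm, seed=seed, label_fraction=label_fraction,
            epochs_stage1=12 if raw else 60,
            epochs_stage2=60,
            pairs_per_epoch=2 * len(windows) if raw else None,
            weights=_paradigm_weights(paradigm, ablation))
    else:
        config = replace(config, paradigm=paradigm, seed=seed,
                         label_fraction=label_fraction,
                         weights=_paradigm_weights(paradigm, ablation))
    n_pairs = config.pairs_per_epoch or 4 * len(windows)

    if paradigm == "supervised":
        tr, te = _stratified_split(y_act, 0.2, seed)
        sub = [windows[i] for i in tr]
        model = train_supervised(sub, config)
        acc, f1 = classification_report(model, x[te], y_act[te])
        return {"paradigm": paradigm, "fraction": label_fraction, "seed": seed,
                "acc": acc, "f1": f1, "model": model}

    if paradigm == "unsupervised":
        model = train_autoencoder(feats, config)
    elif paradigm == "selfsup":
        index = build_neighborhood_index(windows, features=feats,
                                         radius=config.temporal_radius,
                                         k=config.knn_k)
        model = train_selfsup(feats, index, config)
    elif paradigm == "weak_single":
        cons = sample_pairs(y_act, n_pairs, seed=seed)
        model = train_weak_single(x, cons, config)
    elif paradigm == "weak_multi":
        cons = sample_quadruples(y_act, y_pers, n_pairs, seed=seed)
        model = train_weak_multi(x, cons, config)
    elif paradigm == "weak_selfsup":
        index = build_neighborhood_index(windows, features=feats,
                                         radius=config.temporal_radius,
                                         k=config.knn_k)
        budget = subsample_label_budget(y_act, label_fraction, seed=seed)
        try:
            cons = sample_pairs(y_act, n_pairs, seed=seed, allowed=budget)
        except ValueError:
            cons = None
        model = train_weak_selfsup(feats, index, cons, config)
    else:
        raise ValueError(f"unknown paradigm {paradigm!r}")

    data = x if paradigm in ("weak_single", "weak_multi") else feats
    reps = embed_dataset(model, data, y_act, y_pers)
    assign = kmeans_cluster(reps, k=n_classes, seed=kmeans_seed)
    res = cluster_accuracy(assign, y_act, n_classes=n_classes)
    out = {"paradigm": paradigm if ablation is None else f"{paradigm}[{ablation}]",
           "fraction": label_fraction, "seed": seed,
           "acc": res.accuracy, "f1": res.macro_f1, "model": model}
    if paradigm == "weak_multi":
        reps_p = embed_dataset(model, x, y_act, y_pers, head="pers")
        n_persons = int(y_pers.max()) + 1
        assign_p = kmeans_cluster(reps_p, k=n_persons, seed=kmeans_seed)
        out["pers_acc"] = cluster_accuracy(assign_p, y_pers,
                                           n_classes=n_persons).accuracy
    return out


def run_experiment(paradigms: list[str], fractions: list[float],
                   synth_cfg: SynthConfig, seeds: list[int],
                   config: TrainingConfig | None = None) -> pd.DataFrame:
    """Paradigm grid x label fractions x seeds -> tidy results table.

    Label fractions only affect the weakly self-supervised paradigm; other
    paradigms are run once per seed at fraction 1.0.
    """
    rows = []
    for seed in seeds:
        windows = _make_windows(replace(synth_cfg, seed=seed))
        for paradigm in paradigms:
            fr_list = fractions if paradigm == "weak_selfsup" else [1.0]
            for fr in fr_list:
                r = evaluate_paradigm(paradigm, windows, seed,
                                      label_fraction=fr, config=config)
                r.pop("model")
                rows.append(r)
    return pd.DataFrame(rows)


def run_ablation(synth_cfg: SynthConfig, seeds: list[int],
                 config: TrainingConfig | None = None) -> pd.DataFrame:
    """Self-supervised loss ablation grid {ae, tc+ae, fc+ae, tc+fc+ae}."""
    rows = []
    for seed in seeds:
        windows = _make_windows(replace(synth_cfg, seed=seed))
        for ablation in ("ae", "tc+ae", "fc+ae", "tc+fc+ae"):
            r = evaluate_paradigm("selfsup", windows, seed, ablation=ablation,
                                  config=config)
            r.pop("model")
            r["losses"] = ablation
            rows.append(r)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# export / plotting helpers
# ---------------------------------------------------------------------------

def export_embeddings_csv(reps: RepresentationSet, path) -> None:
    df = pd.DataFrame({"id": np.arange(len(reps.embeddings)),
                       "act": reps.activity, "pers": reps.person})
    for j in range(reps.embeddings.shape[1]):
        df[f"e{j}"] = reps.embeddings[:, j]
    df.to_csv(path, index=False)


def plot_embeddings(reps: RepresentationSet, path) -> None:
    """2-D PCA scatter of the embeddings, colored by activity (visual aid)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.decomposition import PCA

    xy = PCA(n_components=2, random_state=0).fit_transform(reps.embeddings)
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls in np.unique(reps.activity):
        m = reps.activity == cls
        ax.scatter(xy[m, 0], xy[m, 1], s=8, label=f"activity {cls}")
    ax.legend(fontsize=7)
    ax.set_title(reps.paradigm or "embeddings")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
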