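"""Two-tiered cell-type classification.

Tier 1 is reference-projection label transfer over coarse cell types: the
query is normalized and scaled with the reference's fitted state, projected
onto the reference PCA, anchored to reference cells by mutual nearest
neighbors, and labeled by anchor-weighted voting (with a k-nearest-reference
fallback for cells without usable anchors).  Cells receiving a routed label
(neuron, motoneuron, or doublet) are passed to Tier 2, a shallow softmax
network over fine neuronal types plus a doublet class, trained on
log-transformed counts scaled by each cell's maximum value.  The default
Tier-2 architecture is one hidden layer of 256 units trained with SGD at
batch size 32.  A linear SVM (max-abs-scaled counts, dual=False,
max_iter=10000) is provided as a baseline, and an unknown-cluster rule
identifies query clusters whose cells are at least 80% classified into one
non-junk, non-doublet reference type.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import MaxAbsScaler
from sklearn.svm import LinearSVC

from .integration import Embedding, find_anchors, pca
from .qc import ScaleState, log_normalize

__all__ = [
    "Tier1Model",
    "Tier2Model",
    "UnknownRuleParams",
    "split_train_test",
    "train_tier1",
    "predict_tier1",
    "two_phase_transfer",
    "preprocess_tier2",
    "train_tier2",
    "train_svm_baseline",
    "predict_two_tier",
    "evaluate",
    "benchmark_expectation",
    "identify_unknown_clusters",
]

DEFAULT_ROUTING = ("neuron", "motoneuron", "doublet")


@dataclass
class UnknownRuleParams:
    majority_threshold: float = 0.8
    excluded_classes: tuple[str, ...] = ("junk", "low_quality", "doublet")

    def __post_init__(self) -> None:
        if not (0 < self.majority_threshold <= 1):
            raise ValueError("majority_threshold must be in (0, 1]")


def split_train_test(
    labels: np.ndarray, holdout_frac: float = 0.1, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified-by-class random split; returns (train_idx, test_idx)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        n_test = int(round(holdout_frac * len(idx)))
        if len(idx) - n_test < 1:
            warnings.warn(f"class {c!r} too small to hold out; kept fully in train")
            n_test = 0
        test.append(idx[:n_test])
        train.append(idx[n_test:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


@dataclass
class Tier1Model:
    """Reference projection + labels for label transfer."""

    genes: list[str]
    scale_state: ScaleState
    embedding: Embedding  # PCA of the reference (coords = reference cells)
    labels: np.ndarray  # reference cell labels
    routing_set: tuple[str, ...] = DEFAULT_ROUTING
    n_dims: int = 28

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(
            path / "arrays.npz",
            coords=self.embedding.coords,
            loadings=self.embedding.loadings,
            explained_variance=self.embedding.explained_variance,
            emb_mean=self.embedding.mean,
            labels=self.labels.astype(str),
            beta=self.scale_state.beta,
            mean=self.scale_state.mean,
            std=self.scale_state.std,
            cov_center=self.scale_state.cov_center,
            cov_scale=self.scale_state.cov_scale,
        )
        meta = {
            "genes": self.genes,
            "covariates": list(self.scale_state.covariates),
            "clip_value": self.scale_state.clip_value,
            "routing_set": list(self.routing_set),
            "n_dims": self.n_dims,
        }
        (path / "params.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "Tier1Model":
        path = Path(path)
        meta = json.loads((path / "params.json").read_text())
        z = np.load(path / "arrays.npz", allow_pickle=False)
        state = ScaleState(
            genes=meta["genes"],
            covariates=tuple(meta["covariates"]),
            beta=z["beta"],
            mean=z["mean"],
            std=z["std"],
            clip_value=meta["clip_value"],
            cov_center=z["cov_center"],
            cov_scale=z["cov_scale"],
        )
        emb = Embedding(
            coords=z["coords"],
            loadings=z["loadings"],
            explained_variance=z["explained_variance"],
            mean=z["emb_mean"],
        )
        return cls(
            genes=meta["genes"],
            scale_state=state,
            embedding=emb,
            labels=z["labels"].astype(object),
            routing_set=tuple(meta["routing_set"]),
            n_dims=meta["n_dims"],
        )


def train_tier1(
    X_scaled: np.ndarray,
    labels: np.ndarray,
    scale_state: ScaleState,
    n_dims: int = 28,
    routing_set: tuple[str, ...] = DEFAULT_ROUTING,
) -> Tier1Model:
    """Fit the Tier-1 reference: PCA loadings + embedding + labels."""
    emb = pca(X_scaled, n_dims)
    return Tier1Model(
        genes=scale_state.genes,
        scale_state=scale_state,
        embedding=emb,
        labels=np.asarray(labels, dtype=object),
        routing_set=routing_set,
        n_dims=emb.loadings.shape[1],
    )


def _scale_query(model: Tier1Model, query) -> tuple[np.ndarray, list[str]]:
    """Normalize/scale query counts with the reference's fitted state.

    Genes absent from the query are imputed as zero (recorded and returned).
    """
    norm = log_normalize(query) if "counts" not in query.layers else query
    missing = [g for g in model.genes if g not in norm.var_names]
    if missing:
        import anndata as ad

        pad = ad.AnnData(
            X=sp.csr_matrix((norm.n_obs, len(missing)), dtype=np.float64),
            obs=norm.obs,
            var=pd.DataFrame(index=missing),
        )
        norm = ad.concat([norm, pad], axis=1, merge="first")
    Z = model.scale_state.transform(norm)
    return Z, missing


def predict_tier1(
    model: Tier1Model,
    query,
    k_anchor: int = 5,
    k_score: int = 30,
    k_weight: int = 50,
    k_fallback: int = 15,
) -> pd.DataFrame:
    """Label transfer by projection + MNN anchors + weighted voting.

    Returns a frame with columns: label, score, routed, fallback, plus the
    imputed-gene count in ``.attrs``.
    """
    if not set(model.genes) & set(query.var_names):
        raise ValueError("query shares no genes with the reference")
    Zq, missing = _scale_query(model, query)
    emb_q = model.embedding.project(Zq)
    emb_ref = model.embedding.coords

    labels_ref = model.labels.astype(str)
    classes = np.unique(labels_ref)
    n_q = emb_q.shape[0]
    out_label = np.empty(n_q, dtype=object)
    out_score = np.zeros(n_q)
    fallback = np.zeros(n_q, dtype=bool)

    anchors = find_anchors(emb_ref, emb_q, k_anchor=k_anchor, k_score=k_score)
    if len(anchors) > 0:
        anchor_q = emb_q[anchors.pairs[:, 1]]
        anchor_lab = labels_ref[anchors.pairs[:, 0]]
        kw = min(k_weight, len(anchors))
        nn = NearestNeighbors(n_neighbors=kw).fit(anchor_q)
        dist, idx = nn.kneighbors(emb_q)
        bw = np.maximum(dist[:, -1:], 1e-12)
        w = np.exp(-0.5 * (dist / bw) ** 2) * anchors.scores[idx]
        code = pd.Categorical(anchor_lab, categories=classes).codes
        for i in range(n_q):
            scores = np.bincount(code[idx[i]], weights=w[i], minlength=len(classes))
            tot = scores.sum()
            if tot <= 0:
                fallback[i] = True
                continue
            best = scores.argmax()
            out_label[i] = classes[best]
            out_score[i] = scores[best] / tot
    else:
        fallback[:] = True

    if fallback.any():
        kf = min(k_fallback, emb_ref.shape[0])
        nn_ref = NearestNeighbors(n_neighbors=kf).fit(emb_ref)
        idx = nn_ref.kneighbors(emb_q[fallback], return_distance=False)
        for row, i in zip(idx, np.flatnonzero(fallback)):
            vals, counts = np.unique(labels_ref[row], return_counts=True)
            out_label[i] = vals[counts.argmax()]
            out_score[i] = counts.max() / kf

    routed = np.isin(out_label.astype(str), model.routing_set)
    df = pd.DataFrame(
        {"label": out_label.astype(str), "score": out_score, "routed": routed,
         "fallback": fallback},
        index=query.obs_names,
    )
    df.attrs["n_imputed_genes"] = len(missing)
    return df


def two_phase_transfer(
    model_all: Tier1Model,
    model_midventral: Tier1Model,
    query,
    merged_label: str = "midventral",
) -> pd.DataFrame:
    """Two-step fine-group transfer: dorsal types + one merged mid/ventral
    label first, then mid/ventral cells resolved against the focused
    reference."""
    phase1 = predict_tier1(model_all, query, k_weight=50)
    labels = phase1["label"].to_numpy(dtype=object)
    mv = labels == merged_label
    if mv.any():
        sub = query[mv].copy()
        phase2 = predict_tier1(model_midventral, sub, k_weight=50)
        labels[mv] = phase2["label"].to_numpy(dtype=object)
    out = phase1.copy()
    out["label"] = labels.astype(str)
    out["phase2"] = mv
    return out


def preprocess_tier2(
    counts, gene_list: list[str] | None = None
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Tier-2 feature transform: drop empty genes, ln(1+x), per-cell max scale.

    Training mode (``gene_list=None``) drops genes with zero total count and
    records the retained list; prediction mode reuses the fitted list (genes
    absent from the query become zero columns).  Each cell's transformed
    vector is divided by its own maximum; all-zero cells yield zero vectors
    and are flagged.
    """
    X = counts.X if hasattr(counts, "X") else counts
    names = list(counts.var_names) if hasattr(counts, "var_names") else None
    dense = X.toarray() if sp.issparse(X) else np.asarray(X, float)
    if gene_list is None:
        keep = dense.sum(axis=0) > 0
        dense = dense[:, keep]
        genes = [names[i] for i in np.flatnonzero(keep)] if names else \
            [str(i) for i in np.flatnonzero(keep)]
    else:
        genes = list(gene_list)
        if names is not None:
            idx = pd.Index(names).get_indexer(genes)
            out = np.zeros((dense.shape[0], len(genes)))
            ok = idx >= 0
            out[:, ok] = dense[:, idx[ok]]
            dense = out
    F = np.log1p(dense)
    mx = F.max(axis=1)
    zero_cells = mx <= 0
    mx_safe = np.where(zero_cells, 1.0, mx)
    F = F / mx_safe[:, None]
    F[zero_cells] = 0.0
    return F, genes, zero_cells


def _parse_architecture(token: str) -> tuple[list[int], str]:
    """Parse an architecture token into (hidden sizes, l2 mode)."""
    t = token.lower()
    l2 = "none"
    if t.endswith("+l2first"):
        l2, t = "first", t[: -len("+l2first")]
    elif t.endswith("+l2"):
        l2, t = "all", t[: -len("+l2")]
    if t == "linear":
        return [], l2
    if t.startswith("h"):
        try:
            return [int(s) for s in t[1:].split("x")], l2
        except ValueError:
            pass
    raise ValueError(f"unknown architecture token {token!r}")


@dataclass
class Tier2Model:
    """Shallow softmax network over fine types (+ doublet)."""

    architecture: str
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    genes: list[str]
    classes: list[str]
    history: dict = field(default_factory=dict)

    def predict_proba(self, F: np.ndarray) -> np.ndarray:
        A = np.asarray(F, float)
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            A = np.maximum(A @ W + b, 0.0)
        logits = A @ self.weights[-1] + self.biases[-1]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, F: np.ndarray) -> np.ndarray:
        p = self.predict_proba(F)
        return np.asarray(self.classes, dtype=object)[p.argmax(axis=1)]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        np.savez(path / "weights.npz", **arrays)
        meta = {
            "architecture": self.architecture,
            "genes": self.genes,
            "classes": self.classes,
            "n_layers": len(self.weights),
        }
        (path / "params.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "Tier2Model":
        path = Path(path)
        meta = json.loads((path / "params.json").read_text())
        z = np.load(path / "weights.npz")
        W = [z[f"W{i}"] for i in range(meta["n_layers"])]
        b = [z[f"b{i}"] for i in range(meta["n_layers"])]
        return cls(
            architecture=meta["architecture"], weights=W, biases=b,
            genes=meta["genes"], classes=meta["classes"],
        )


def train_tier2(
    F: np.ndarray,
    labels: np.ndarray,
    genes: list[str],
    architecture: str = "h256",
    optimizer: str = "sgd",
    batch_size: int = 32,
    epochs: int = 50,
    l2: float = 1e-4,
    learning_rate: float | None = None,
    seed: int = 0,
    validation_frac: float = 0.1,
    patience: int = 8,
) -> Tier2Model:
    """Mini-batch training of the Tier-2 softmax classifier.

    Cross-entropy loss over the given architecture (ReLU hidden layers),
    with SGD (momentum 0.9) or Adam, optional L2 on all or the first hidden
    layer, and early stopping on a held-out validation split.  Deterministic
    in ``seed``.
    """
    hidden, l2_mode = _parse_architecture(architecture)
    if optimizer not in ("sgd", "adam"):
        raise ValueError(f"unknown optimizer {optimizer!r}")
    lr = learning_rate if learning_rate is not None else (0.05 if optimizer == "sgd" else 1e-3)
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels).astype(str)
    classes = sorted(set(labels.tolist()))
    y = np.searchsorted(np.asarray(classes), labels)
    n, d = F.shape
    k = len(classes)
    sizes = [d] + hidden + [k]
    W = [
        rng.normal(0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
        for i in range(len(sizes) - 1)
    ]
    b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
    l2_per_layer = [
        l2 if (l2_mode == "all" or (l2_mode == "first" and i == 0)) else 0.0
        for i in range(len(W))
    ]

    perm = rng.permutation(n)
    n_val = int(round(validation_frac * n)) if epochs > 0 else 0
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Ftr, ytr = F[tr_idx], y[tr_idx]
    Fval, yval = F[val_idx], y[val_idx]

    vel = [np.zeros_like(w) for w in W] + [np.zeros_like(x) for x in b]
    mom1 = [np.zeros_like(w) for w in W] + [np.zeros_like(x) for x in b]
    mom2 = [np.zeros_like(w) for w in W] + [np.zeros_like(x) for x in b]
    t_step = 0

    def _forward(A):
        acts = [A]
        for Wi, bi in zip(W[:-1], b[:-1]):
            A = np.maximum(A @ Wi + bi, 0.0)
            acts.append(A)
        logits = A @ W[-1] + b[-1]
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return acts, e / e.sum(axis=1, keepdims=True)

    best = {"acc": -1.0, "W": [w.copy() for w in W], "b": [x.copy() for x in b], "epoch": -1}
    history = {"train_acc": [], "val_acc": []}
    stale = 0
    for epoch in range(epochs):
        order = rng.permutation(len(tr_idx))
        for start in range(0, len(order), batch_size):
            bi = order[start : start + batch_size]
            A, P = _forward(Ftr[bi])
            G = P.copy()
            G[np.arange(len(bi)), ytr[bi]] -= 1.0
            G /= len(bi)
            grads_W, grads_b = [], []
            delta = G
            for li in range(len(W) - 1, -1, -1):
                grads_W.insert(0, A[li].T @ delta + l2_per_layer[li] * W[li])
                grads_b.insert(0, delta.sum(axis=0))
                if li > 0:
                    delta = (delta @ W[li].T) * (A[li] > 0)
            t_step += 1
            params = W + b
            grads = grads_W + grads_b
            if optimizer == "sgd":
                for pi, (p_arr, g_arr) in enumerate(zip(params, grads)):
                    vel[pi] = 0.9 * vel[pi] - lr * g_arr
                    p_arr += vel[pi]
            else:
                b1, b2, eps = 0.9, 0.999, 1e-8
                for pi, (p_arr, g_arr) in enumerate(zip(params, grads)):
                    mom1[pi] = b1 * mom1[pi] + (1 - b1) * g_arr
                    mom2[pi] = b2 * mom2[pi] + (1 - b2) * g_arr**2
                    m_hat = mom1[pi] / (1 - b1**t_step)
                    v_hat = mom2[pi] / (1 - b2**t_step)
                    p_arr -= lr * m_hat / (np.sqrt(v_hat) + eps)

        _, P_tr = _forward(Ftr)
        train_acc = float((P_tr.argmax(1) == ytr).mean())
        if len(val_idx):
            _, P_val = _forward(Fval)
            val_acc = float((P_val.argmax(1) == yval).mean())
        else:
            val_acc = train_acc
        history["train_acc"].append(train_acc)
        history["val_acc"].append(val_acc)
        if val_acc > best["acc"]:
            best = {"acc": val_acc, "W": [w.copy() for w in W],
                    "b": [x.copy() for x in b], "epoch": epoch}
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break

    return Tier2Model(
        architecture=architecture,
        weights=best["W"],
        biases=best["b"],
        genes=list(genes),
        classes=classes,
        history=history,
    )


def train_svm_baseline(counts, labels, seed: int = 0):
    """Linear SVM baseline on max-abs-scaled counts (one-vs-rest hinge loss)."""
    X = counts.X if hasattr(counts, "X") else counts
    X = sp.csr_matrix(X) if not sp.issparse(X) else X
    scaler = MaxAbsScaler(copy=True)
    Xs = scaler.fit_transform(X.astype(np.float64))
    clf = LinearSVC(dual=False, max_iter=10_000, random_state=seed)
    clf.fit(Xs, np.asarray(labels).astype(str))
    return {"scaler": scaler, "model": clf}


def predict_svm(bundle, counts) -> np.ndarray:
    X = counts.X if hasattr(counts, "X") else counts
    X = sp.csr_matrix(X) if not sp.issparse(X) else X
    return bundle["model"].predict(bundle["scaler"].transform(X.astype(np.float64)))


def predict_two_tier(
    tier1: Tier1Model,
    tier2: Tier2Model,
    query,
) -> pd.DataFrame:
    """Classify query cells: Tier-1 labels everyone, routed cells go to Tier 2.

    Returns a frame with columns tier1_label, final_label, confidence, tier.
    """
    p1 = predict_tier1(tier1, query)
    final = p1["label"].to_numpy(dtype=object)
    conf = p1["score"].to_numpy(dtype=float)
    tier = np.ones(len(final), dtype=int)
    routed = p1["routed"].to_numpy(bool)
    if routed.any():
        sub = query[routed]
        raw = sub.layers["counts"] if "counts" in sub.layers else sub.X
        F, _, _ = preprocess_tier2(_CountsView(raw, list(sub.var_names)), tier2.genes)
        proba = tier2.predict_proba(F)
        final[routed] = np.asarray(tier2.classes, dtype=object)[proba.argmax(axis=1)]
        conf[routed] = proba.max(axis=1)
        tier[routed] = 2
    return pd.DataFrame(
        {"tier1_label": p1["label"], "final_label": final.astype(str),
         "confidence": conf, "tier": tier},
        index=query.obs_names,
    )


class _CountsView:
    """Minimal (X, var_names) view so preprocess_tier2 accepts raw layers."""

    def __init__(self, X, var_names):
        self.X = X
        self.var_names = var_names


def evaluate(predictions: np.ndarray, truth: np.ndarray,
             confidence: np.ndarray | None = None) -> dict:
    """Accuracy, per-class precision/recall/F1, confusion matrix."""
    predictions = np.asarray(predictions).astype(str)
    truth = np.asarray(truth).astype(str)
    classes = sorted(set(truth.tolist()) | set(predictions.tolist()))
    cm = confusion_matrix(truth, predictions, labels=classes)
    prec, rec, f1, support = precision_recall_fscore_support(
        truth, predictions, labels=classes, zero_division=0
    )
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f1": f1, "support": support},
        index=classes,
    )
    if confidence is not None:
        per_class["mean_confidence"] = [
            float(np.mean(confidence[truth == c])) if (truth == c).any() else np.nan
            for c in classes
        ]
    return {
        "accuracy": float((predictions == truth).mean()),
        "per_class": per_class,
        "confusion": pd.DataFrame(cm, index=classes, columns=classes),
    }


def benchmark_expectation(
    per_class_f1: pd.Series, cocluster_freq: dict[str, float]
) -> dict:
    """Relate per-class F1 to co-clustering robustness.

    Returns the paired table, the Spearman rank correlation (None when either
    side is constant), and the mean co-clustering frequency (the robustness
    floor the classifier is benchmarked against).
    """
    from scipy.stats import spearmanr

    common = [c for c in per_class_f1.index if c in cocluster_freq
              and np.isfinite(cocluster_freq[c])]
    table = pd.DataFrame(
        {"f1": [per_class_f1[c] for c in common],
         "cocluster_frequency": [cocluster_freq[c] for c in common]},
        index=common,
    )
    rho = None
    if len(common) >= 3:
        f1v = table["f1"].to_numpy()
        cf = table["cocluster_frequency"].to_numpy()
        if np.ptp(f1v) > 0 and np.ptp(cf) > 0:
            rho = float(spearmanr(f1v, cf).statistic)
    mean_freq = float(np.mean([v for v in cocluster_freq.values() if np.isfinite(v)])) \
        if cocluster_freq else float("nan")
    return {"table": table, "spearman": rho, "mean_cocluster_frequency": mean_freq}


def identify_unknown_clusters(
    query_clusters: np.ndarray,
    predictions: np.ndarray,
    params: UnknownRuleParams = UnknownRuleParams(),
) -> dict[str, str | None]:
    """80%-majority rule: an unknown cluster is identified with reference type
    X when at least ``majority_threshold`` of its cells are predicted X and X
    is a true cell type (not junk/low-quality or doublet)."""
    query_clusters = np.asarray(query_clusters).astype(str)
    predictions = np.asarray(predictions).astype(str)
    out: dict[str, str | None] = {}
    for c in np.unique(query_clusters):
        m = query_clusters == c
        vals, counts = np.unique(predictions[m], return_counts=True)
        best = counts.argmax()
        frac = counts[best] / m.sum()
        label = vals[best]
        if frac >= params.majority_threshold and label not in params.excluded_classes:
            out[c] = label
        else:
            out[c] = None
    return out
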