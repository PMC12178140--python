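"""Losses, the self-supervised training loop, prediction, cross-validation
and the six evaluation metrics.

Training is a masked-graph-autoencoder loop: each epoch draws a fresh edge
mask, encodes the residual graph, scores the masked edges against sampled
non-edges with a binary cross-entropy loss, and regresses each affected
node's masked degree with an auxiliary loss weighted by mu (default 0.006).
Prediction encodes the *full* graph and scores query pairs symmetrically.
Evaluation uses stratified k-fold cross-validation over the labeled pairs;
each fold's training graph contains only training-fold positive edges, so
test interactions are never seen by the encoder.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .encoder import EncoderConfig, grcn_forward, init_encoder_params
from .features import FeatureConfig, featurize
from .graph import RNAGraph, RNARecord, build_graph, canonical_pair
from .kan import (
    FusionConfig,
    KANLayerParams,
    degree_decode,
    init_kan_params,
    init_mlp_decoder,
    init_score_head,
    score_pairs,
)
from .masking import MaskConfig, mask_graph

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "ModelState",
    "sample_negatives",
    "bce_loss",
    "degree_loss",
    "total_loss",
    "train",
    "predict",
    "metrics",
    "kfold_cv",
]


@dataclass
class TrainConfig:
    """Optimization settings for the self-supervised loop."""

    mu: float = 0.006
    epochs: int = 300
    lr: float = 1e-3
    neg_ratio: int = 1
    seed: int = 0
    clip_eps: float = 1e-7
    dropout: float = 0.3
    decoder_head: str = "kan"  # "kan" | "mlp" (ablation)
    kan_grid_size: int = 5
    kan_order: int = 3
    kan_range: float = 1.0

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.neg_ratio < 1:
            raise ValueError("neg_ratio must be >= 1")
        if self.decoder_head not in ("kan", "mlp"):
            raise ValueError("decoder_head must be 'kan' or 'mlp'")


@dataclass
class MetricsReport:
    """AUC/AUPR plus thresholded confusion-matrix metrics for one evaluation."""

    auc: float
    aupr: float
    acc: float
    pre: float
    f1: float
    mcc: float
    threshold: float = 0.5

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass
class ModelState:
    """Everything needed to score new pairs: parameters + configs + node order."""

    params: dict[str, Tensor]
    kan_params: KANLayerParams | None
    enc_cfg: EncoderConfig
    fusion_cfg: FusionConfig
    train_cfg: TrainConfig
    node_ids: list[str]


# ----------------------------------------------------------------------
def sample_negatives(
    graph: RNAGraph,
    count: int,
    rng: np.random.Generator,
    exclude: Iterable[tuple[str, str]] = (),
) -> list[tuple[str, str]]:
    """Uniformly sample ``count`` distinct non-edges avoiding ``exclude``."""
    if count < 0:
        raise ValueError("count must be >= 0")
    n = graph.n_nodes
    forbidden = set(graph.edges)
    if isinstance(exclude, (set, frozenset)):
        forbidden.update(exclude)  # assumed already canonical
    else:
        forbidden.update(canonical_pair(a, b) for a, b in exclude)
    total_pairs = n * (n - 1) // 2
    available = total_pairs - len(forbidden)
    if count > available:
        raise ValueError(
            f"cannot sample {count} negatives: only {available} non-excluded "
            f"non-edges exist"
        )
    ids = graph.ids
    chosen: set[tuple[str, str]] = set()
    out: list[tuple[str, str]] = []
    # rejection sampling; fall back to exhaustive enumeration on dense graphs
    max_tries = 50 * max(count, 1) + 100
    tries = 0
    while len(out) < count and tries < max_tries:
        tries += 1
        i = int(rng.integers(n))
        j = int(rng.integers(n))
        if i == j:
            continue
        pair = canonical_pair(ids[i], ids[j])
        if pair in forbidden or pair in chosen:
            continue
        chosen.add(pair)
        out.append(pair)
    if len(out) < count:
        pool = sorted(
            canonical_pair(ids[i], ids[j])
            for i in range(n)
            for j in range(i + 1, n)
            if canonical_pair(ids[i], ids[j]) not in forbidden
            and canonical_pair(ids[i], ids[j]) not in chosen
        )
        extra = rng.choice(len(pool), size=count - len(out), replace=False)
        out.extend(pool[k] for k in sorted(extra))
    return out


def _clip_val(x, eps: float):
    if isinstance(x, Tensor):
        return ad.clip(x, eps, 1.0 - eps)
    return np.clip(np.asarray(x, dtype=float), eps, 1.0 - eps)


def bce_loss(pos_scores, neg_scores, clip_eps: float = 1e-7):
    """-(mean log p_pos + mean log (1 - p_neg)) with probability clamping."""
    pos_arr = pos_scores.data if isinstance(pos_scores, Tensor) else np.asarray(pos_scores, float)
    neg_arr = neg_scores.data if isinstance(neg_scores, Tensor) else np.asarray(neg_scores, float)
    if pos_arr.size == 0 or neg_arr.size == 0:
        raise ValueError("bce_loss requires nonempty positive and negative scores")
    if isinstance(pos_scores, Tensor) or isinstance(neg_scores, Tensor):
        lp = ad.tmean(ad.log(_clip_val(pos_scores, clip_eps)))
        ln = ad.tmean(ad.log(1.0 - _clip_val(neg_scores, clip_eps)))
        return -(lp + ln)
    lp = np.mean(np.log(_clip_val(pos_arr, clip_eps)))
    ln = np.mean(np.log(1.0 - _clip_val(neg_arr, clip_eps)))
    return float(-(lp + ln))


def degree_loss(
    pred: Mapping[str, float],
    target: Mapping[str, float],
    nodes: Sequence[str],
) -> float:
    """Mean squared error over the (multiset) node list V_M ⊎ V_D."""
    if len(nodes) == 0:
        raise ValueError("degree_loss requires a nonempty node list")
    total = 0.0
    for node in nodes:
        if node not in pred:
            raise ValueError(f"missing degree prediction for node {node!r}")
        total += (float(pred[node]) - float(target.get(node, 0.0))) ** 2
    return total / len(nodes)


def total_loss(l_bce: float, l_deg: float, mu: float) -> float:
    """Composite objective: reconstruction BCE plus mu-weighted degree loss."""
    if mu < 0:
        raise ValueError("mu must be >= 0")
    return l_bce + mu * l_deg


# ----------------------------------------------------------------------
def _init_params(
    f0: int,
    enc_cfg: EncoderConfig,
    fusion_cfg: FusionConfig,
    train_cfg: TrainConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, Tensor], KANLayerParams | None]:
    params = init_encoder_params(enc_cfg, f0, rng)
    params.update(init_score_head(fusion_cfg.fused_width, rng, fusion_cfg.score_hidden))
    kan_params = None
    if train_cfg.decoder_head == "kan":
        kan_params = init_kan_params(
            enc_cfg.hidden_dim,
            1,
            rng,
            grid_size=train_cfg.kan_grid_size,
            order=train_cfg.kan_order,
            grid_range=train_cfg.kan_range,
        )
        params.update(kan_params.named_params())
    else:
        params.update(init_mlp_decoder(enc_cfg.hidden_dim, rng))
    return params, kan_params


def _decoder_params(state: ModelState):
    if state.train_cfg.decoder_head == "kan":
        return state.kan_params
    return {k: v for k, v in state.params.items() if k.startswith("mlp.")}


def train(
    graph: RNAGraph,
    mask_cfg: MaskConfig | None = None,
    enc_cfg: EncoderConfig | None = None,
    fusion_cfg: FusionConfig | None = None,
    train_cfg: TrainConfig | None = None,
    exclude_pairs: Iterable[tuple[str, str]] = (),
) -> tuple[ModelState, list[dict[str, float]]]:
    """Self-supervised training on one graph; returns model state + loss trace.

    Negative sampling avoids the graph's labeled pairs plus any
    ``exclude_pairs`` — evaluation harnesses pass every labeled pair of the
    full dataset here so held-out pairs are never pushed toward score zero.
    Fully reproducible: all randomness (init, masking, negative sampling,
    dropout) derives from train_cfg.seed / mask_cfg.seed.
    """
    mask_cfg = mask_cfg or MaskConfig()
    enc_cfg = enc_cfg or EncoderConfig()
    train_cfg = train_cfg or TrainConfig()
    fusion_cfg = fusion_cfg or FusionConfig(K=enc_cfg.K, f=enc_cfg.hidden_dim)
    if fusion_cfg.K != enc_cfg.K or fusion_cfg.f != enc_cfg.hidden_dim:
        raise ValueError("fusion config (K, f) must match the encoder")
    if len(graph.edges) < 1:
        raise ValueError("training requires a graph with at least one edge")

    ss = np.random.SeedSequence(entropy=train_cfg.seed, spawn_key=(mask_cfg.seed,))
    rng_init, rng_mask, rng_neg, rng_drop = [
        np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(4)
    ]
    f0 = graph.X.shape[1]
    params, kan_params = _init_params(f0, enc_cfg, fusion_cfg, train_cfg, rng_init)
    opt = Adam({k: v for k, v in params.items() if v.requires_grad}, lr=train_cfg.lr)

    idx = graph.index
    labeled = frozenset(
        set(graph.labels) | {canonical_pair(a, b) for a, b in exclude_pairs}
    )
    dec_params = kan_params if train_cfg.decoder_head == "kan" else {
        k: v for k, v in params.items() if k.startswith("mlp.")
    }
    trace: list[dict[str, float]] = []
    for epoch in range(train_cfg.epochs):
        mres = mask_graph(graph, mask_cfg, rng_mask)
        pos = sorted(mres.masked_edges)
        if not pos:
            warnings.warn(f"epoch {epoch}: masking removed no edges; skipping")
            continue
        neg = sample_negatives(graph, len(pos) * train_cfg.neg_ratio, rng_neg, exclude=labeled)

        X = graph.X
        if mask_cfg.feature_mask_p > 0:
            keep = rng_drop.random(X.shape[1]) >= mask_cfg.feature_mask_p
            X = X * keep[None, :]
        Z_list = grcn_forward(Tensor(X), mres.residual.adjacency(), params, enc_cfg)

        pairs = pos + neg
        ii = np.fromiter((idx[a] for a, _ in pairs), dtype=int, count=len(pairs))
        jj = np.fromiter((idx[b] for _, b in pairs), dtype=int, count=len(pairs))
        scores = score_pairs(Z_list, ii, jj, params, fusion_cfg)
        l_bce = bce_loss(scores[: len(pos)], scores[len(pos) :], train_cfg.clip_eps)

        deg_nodes = sorted(mres.V_M) + sorted(mres.V_D)
        node_rows = np.fromiter((idx[n] for n in deg_nodes), dtype=int, count=len(deg_nodes))
        targets = np.array([mres.masked_degree.get(n, 0) for n in deg_nodes], dtype=float)
        # decode unique rows once, then gather the multiset
        uniq_rows, inverse = np.unique(node_rows, return_inverse=True)
        pred_uniq = degree_decode(
            Z_list[-1][uniq_rows], dec_params, train_cfg.dropout, mode="train", rng=rng_drop
        )
        pred = pred_uniq[inverse]
        diff = pred - targets
        l_deg = ad.tmean(diff * diff)

        loss = l_bce + train_cfg.mu * l_deg
        if not math.isfinite(loss.item()):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        trace.append(
            {
                "epoch": epoch,
                "bce": float(l_bce.item()),
                "degree": float(l_deg.item()),
                "total": float(loss.item()),
            }
        )
    state = ModelState(
        params=params,
        kan_params=kan_params,
        enc_cfg=enc_cfg,
        fusion_cfg=fusion_cfg,
        train_cfg=train_cfg,
        node_ids=list(graph.ids),
    )
    return state, trace


def predict(
    state: ModelState,
    graph: RNAGraph,
    query_pairs: Sequence[tuple[str, str]],
) -> np.ndarray:
    """Score query pairs on the full (unmasked) graph; deterministic."""
    if list(graph.ids) != list(state.node_ids):
        raise ValueError("graph node order does not match the trained model")
    idx = graph.index
    for a, b in query_pairs:
        for rid in (a, b):
            if rid not in idx:
                raise ValueError(f"unknown id {rid!r} in query pairs")
    Z_list = grcn_forward(Tensor(graph.X), graph.adjacency(), state.params, state.enc_cfg)
    ii = np.fromiter((idx[a] for a, _ in query_pairs), dtype=int, count=len(query_pairs))
    jj = np.fromiter((idx[b] for _, b in query_pairs), dtype=int, count=len(query_pairs))
    scores = score_pairs(Z_list, ii, jj, state.params, state.fusion_cfg)
    return scores.data


# ----------------------------------------------------------------------
def metrics(scores, labels, threshold: float = 0.5) -> MetricsReport:
    """Six-metric evaluation report.

    AUC is the tie-corrected rank statistic, AUPR the step-integrated
    precision-recall area; ACC/PRE/F1/MCC use the decision threshold.
    With single-class labels AUC/AUPR are NaN (with a warning) while the
    thresholded metrics are still computed.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if len(np.unique(labels)) < 2:
        warnings.warn("single-class labels: AUC/AUPR undefined (NaN)")
        auc = aupr = float("nan")
    else:
        auc = float(roc_auc_score(labels, scores))
        aupr = float(average_precision_score(labels, scores))
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    acc = (tp + tn) / len(labels)
    pre = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * pre * rec / (pre + rec) if pre + rec else 0.0
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = ((tp * tn - fp * fn) / denom) if denom else 0.0
    return MetricsReport(auc=auc, aupr=aupr, acc=acc, pre=pre, f1=f1, mcc=mcc, threshold=threshold)


def kfold_cv(
    records: list[RNARecord],
    pairs: list[tuple[str, str, int]],
    k: int = 10,
    seed: int = 0,
    feat_cfg: FeatureConfig | None = None,
    mask_cfg: MaskConfig | None = None,
    enc_cfg: EncoderConfig | None = None,
    fusion_cfg: FusionConfig | None = None,
    train_cfg: TrainConfig | None = None,
    X: np.ndarray | None = None,
) -> tuple[list[MetricsReport], dict[str, tuple[float, float]]]:
    """Stratified k-fold cross-validation over labeled pairs.

    Per fold the training graph contains only training-fold positive edges;
    held-out pairs (both classes) are scored by the trained model.  Returns
    the per-fold reports and a mean/sd summary keyed by metric name.
    """
    labels = np.array([label for _, _, label in pairs], dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos < k or n_neg < k:
        raise ValueError(
            f"need at least k={k} pairs of each class, got {n_pos} positives "
            f"and {n_neg} negatives"
        )
    if X is None:
        X = featurize(records, feat_cfg)
    base_train_cfg = train_cfg or TrainConfig()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports: list[MetricsReport] = []
    pair_arr = list(pairs)
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(pairs)), labels)):
        train_pairs = [pair_arr[i] for i in train_idx]
        test_pairs = [pair_arr[i] for i in test_idx]
        graph = build_graph(records, train_pairs, X)
        test_pos = {canonical_pair(a, b) for a, b, lab in test_pairs if lab == 1}
        leaked = test_pos & graph.edges
        if leaked:
            raise AssertionError(f"fold {fold}: test edges leaked into training graph: {sorted(leaked)[:3]}")
        fold_cfg = TrainConfig(**{**asdict(base_train_cfg), "seed": base_train_cfg.seed + 7919 * fold})
        all_labeled = {canonical_pair(a, b) for a, b, _ in pairs}
        state, _ = train(
            graph, mask_cfg, enc_cfg, fusion_cfg, fold_cfg, exclude_pairs=all_labeled
        )
        query = [(a, b) for a, b, _ in test_pairs]
        scores = predict(state, graph, query)
        reports.append(metrics(scores, [lab for _, _, lab in test_pairs]))
    summary = {
        name: (
            float(np.mean([getattr(r, name) for r in reports])),
            float(np.std([getattr(r, name) for r in reports], ddof=1)),
        )
        for name in ("auc", "aupr", "acc", "pre", "f1", "mcc")
    }
    return reports, summary
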