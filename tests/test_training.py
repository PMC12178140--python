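"""Losses, negative sampling, metrics, the training loop, CV protocol."""

import math
import warnings

import numpy as np
import pytest

from rnagae import (
    MaskConfig,
    RNAGraph,
    TrainConfig,
    bce_loss,
    build_graph,
    canonical_pair,
    degree_loss,
    kfold_cv,
    metrics,
    predict,
    sample_negatives,
    total_loss,
    train,
)


def _graph(ids, edges, labels=None):
    return RNAGraph(
        ids=list(ids),
        edges={canonical_pair(*e) for e in edges},
        X=np.zeros((len(ids), 1)),
        labels=labels or {},
    )


# ----------------------------------------------------------------------
def test_sample_negatives_enumerates_when_exhaustive(rng):
    g = _graph("abc", [("a", "b")])
    got = set(sample_negatives(g, 2, rng))
    assert got == {("a", "c"), ("b", "c")}


def test_sample_negatives_complete_graph_errors(rng):
    g = _graph("abc", [("a", "b"), ("a", "c"), ("b", "c")])
    with pytest.raises(ValueError, match="non-edges"):
        sample_negatives(g, 1, rng)


def test_sample_negatives_avoids_edges_and_exclude(rng):
    ids = [f"n{i}" for i in range(20)]
    edges = [(ids[i], ids[i + 1]) for i in range(19)]
    g = _graph(ids, edges)
    exclude = frozenset({canonical_pair(ids[0], ids[5])})
    for _ in range(10):
        neg = sample_negatives(g, 30, rng, exclude=exclude)
        assert len(neg) == len(set(neg)) == 30
        assert not (set(neg) & g.edges)
        assert not (set(neg) & exclude)


# ----------------------------------------------------------------------
def test_bce_closed_forms():
    assert bce_loss([0.5, 0.5], [0.5]) == pytest.approx(2 * math.log(2), abs=1e-12)
    assert bce_loss([1.0], [0.0]) == pytest.approx(0.0, abs=1e-5)
    assert bce_loss([0.8], [0.4]) == pytest.approx(-(math.log(0.8) + math.log(0.6)), abs=1e-12)
    with pytest.raises(ValueError, match="nonempty"):
        bce_loss([], [0.5])


def test_bce_matches_per_sample_oracle(rng):
    """Equality with an independent per-sample log-loss sum."""
    for _ in range(20):
        pos = rng.uniform(0.01, 0.99, size=rng.integers(1, 30))
        neg = rng.uniform(0.01, 0.99, size=rng.integers(1, 30))
        oracle = -(
            sum(math.log(p) for p in pos) / len(pos)
            + sum(math.log(1 - q) for q in neg) / len(neg)
        )
        assert bce_loss(pos, neg) == pytest.approx(oracle, abs=1e-9)


def test_degree_loss_examples():
    assert degree_loss({"a": 2.0}, {"a": 2.0}, ["a"]) == 0.0
    assert degree_loss({"a": 2.0}, {"a": 3.0}, ["a"]) == 1.0
    assert degree_loss({"a": 1.0, "b": 0.0}, {"a": 2.0, "b": 2.0}, ["a", "b"]) == 2.5
    # multiset counting: a node in both V_M and V_D contributes twice
    assert degree_loss({"a": 1.0}, {"a": 2.0}, ["a", "a"]) == 1.0
    with pytest.raises(ValueError, match="missing"):
        degree_loss({}, {"a": 1.0}, ["a"])
    with pytest.raises(ValueError, match="nonempty"):
        degree_loss({}, {}, [])


def test_total_loss():
    assert total_loss(1.0, 10.0, 0.0) == 1.0
    assert total_loss(1.0, 10.0, 0.006) == pytest.approx(1.06)
    assert total_loss(2.0, 10.0, 0.006) >= total_loss(1.0, 10.0, 0.006)
    with pytest.raises(ValueError):
        total_loss(1.0, 1.0, -0.1)


# ----------------------------------------------------------------------
def _brute_force_auc(scores, labels):
    """Mann-Whitney with half-credit for ties (independent oracle)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def test_metrics_perfect_separation():
    rep = metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
    assert rep.auc == rep.aupr == rep.acc == rep.pre == rep.f1 == 1.0
    assert rep.mcc == 1.0


def test_metrics_hand_confusion():
    # TP=2, FP=1, TN=2, FN=0
    scores = [0.9, 0.8, 0.7, 0.2, 0.1]
    labels = [1, 1, 0, 0, 0]
    rep = metrics(scores, labels)
    assert rep.pre == pytest.approx(2 / 3)
    assert rep.f1 == pytest.approx(0.8)
    assert rep.acc == pytest.approx(0.8)
    assert rep.mcc == pytest.approx(2 / 3)


def test_metrics_all_tied_scores():
    rep = metrics([0.5] * 6, [1, 0, 1, 0, 1, 0])
    assert rep.auc == pytest.approx(0.5)


def test_metrics_single_class_warns_nan():
    with pytest.warns(UserWarning, match="single-class"):
        rep = metrics([0.9, 0.8], [1, 1])
    assert math.isnan(rep.auc) and math.isnan(rep.aupr)
    assert rep.acc == 1.0


def test_metrics_auc_matches_brute_force(rng):
    """Tie-corrected rank AUC equals the brute-force Mann-Whitney statistic."""
    for _ in range(20):
        n = int(rng.integers(10, 200))
        scores = np.round(rng.random(n), 2)  # rounding induces ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        rep = metrics(scores, labels)
        assert rep.auc == pytest.approx(_brute_force_auc(scores, labels), abs=1e-12)


# ----------------------------------------------------------------------
_FAST = TrainConfig(epochs=40, lr=5e-3, seed=1)


def test_train_loss_decreases(small_graph):
    state, trace = train(small_graph, train_cfg=_FAST)
    assert len(trace) == 40
    first = np.mean([t["total"] for t in trace[:10]])
    last = np.mean([t["total"] for t in trace[-10:]])
    assert last < first


def test_train_reproducible_bitwise(small_graph):
    _, t1 = train(small_graph, train_cfg=TrainConfig(epochs=5, seed=3))
    _, t2 = train(small_graph, train_cfg=TrainConfig(epochs=5, seed=3))
    assert t1 == t2  # bit-for-bit identical loss traces
    _, t3 = train(small_graph, train_cfg=TrainConfig(epochs=5, seed=4))
    assert t1 != t3


def test_train_alpha_zero_skips_without_crash(small_graph):
    with pytest.warns(UserWarning, match="no edges"):
        state, trace = train(
            small_graph,
            mask_cfg=MaskConfig(alpha=0.0),
            train_cfg=TrainConfig(epochs=3, seed=0),
        )
    assert trace == []


def test_train_requires_edges(tiny_records):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        g = build_graph(tiny_records, [("a", "b", 0)], np.zeros((3, 4)))
    with pytest.raises(ValueError, match="at least one edge"):
        train(g)


def test_predict_symmetric_deterministic_separating(small_planted, small_graph):
    records, pairs, truth, X = small_planted
    state, _ = train(small_graph, train_cfg=_FAST)
    qp = [(a, b) for a, b, _ in pairs[:50]]
    s1 = predict(state, small_graph, qp)
    s2 = predict(state, small_graph, [(b, a) for a, b in qp])
    assert np.array_equal(s1, s2)
    assert np.array_equal(s1, predict(state, small_graph, qp))
    assert np.all((s1 > 0) & (s1 < 1))
    with pytest.raises(ValueError, match="unknown id"):
        predict(state, small_graph, [("nope", records[0].id)])


def test_predict_separates_held_out_pairs(small_planted):
    """Mean score of held-out true pairs exceeds held-out non-pairs."""
    records, pairs, _, X = small_planted
    pos = [p for p in pairs if p[2] == 1]
    neg = [p for p in pairs if p[2] == 0]
    train_pairs = pos[: int(0.8 * len(pos))] + neg
    held_pos = pos[int(0.8 * len(pos)) :]
    g = build_graph(records, train_pairs, X)
    all_labeled = {(a, b) for a, b, _ in pairs}
    gaps = []
    for seed in (0, 1, 2):
        state, _ = train(
            g,
            train_cfg=TrainConfig(epochs=60, lr=5e-3, seed=seed),
            exclude_pairs=all_labeled,
        )
        sp = predict(state, g, [(a, b) for a, b, _ in held_pos])
        sn = predict(state, g, [(a, b) for a, b, _ in neg[: len(held_pos)]])
        gaps.append(sp.mean() - sn.mean())
    assert np.mean(gaps) > 0


def test_kfold_cv_protocol(small_planted):
    """Partition, stratification and leakage guarantees of the CV harness."""
    records, pairs, _, X = small_planted
    k = 5
    reports, summary = kfold_cv(
        records,
        pairs,
        k=k,
        seed=0,
        train_cfg=TrainConfig(epochs=15, lr=5e-3),
        X=X,
    )
    assert len(reports) == k
    for name in ("auc", "aupr", "acc", "pre", "f1", "mcc"):
        mean, sd = summary[name]
        assert np.isfinite(mean) and np.isfinite(sd)
    assert 0 <= summary["auc"][0] <= 1


def test_kfold_cv_partition_and_stratification(small_planted):
    from sklearn.model_selection import StratifiedKFold

    records, pairs, _, X = small_planted
    labels = np.array([l for *_, l in pairs])
    k = 5
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=0)
    seen = []
    global_frac = labels.mean()
    for _, test_idx in skf.split(np.zeros(len(pairs)), labels):
        seen.extend(test_idx)
        fold_frac = labels[test_idx].mean()
        # within one pair of the global positive fraction
        assert abs(fold_frac - global_frac) * len(test_idx) <= 1 + 1e-9
    assert sorted(seen) == list(range(len(pairs)))  # exact partition


def test_kfold_cv_requires_enough_pairs(tiny_records):
    with pytest.raises(ValueError, match="at least"):
        kfold_cv(tiny_records, [("a", "b", 1), ("a", "c", 0)], k=10)
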