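"""Self-supervision signal: Bernoulli root sampling and random-walk edge masking.

Each training epoch removes a subset ``E_mask`` of edges from the interaction
graph and asks the model to reconstruct them.  The default ("path") strategy
samples root nodes with probability alpha and walks up to ``l_walk`` steps
from each root, deleting every traversed edge, so masked edges are locally
correlated along paths.  The baseline ("edge") strategy deletes each edge
independently with probability alpha.  The per-node count of removed incident
edges is the regression target of the degree decoder.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .graph import RNAGraph, canonical_pair

__all__ = ["MaskConfig", "MaskResult", "sample_roots", "mask_path", "mask_edges", "mask_graph"]


@dataclass
class MaskConfig:
    """Masking hyperparameters.

    alpha is the Bernoulli root-sampling (or edge-removal) probability;
    l_walk the walk length; strategy one of {"path", "edge"}.  The optional
    feature_mask_p zeroes a Bernoulli subset of feature columns per epoch as
    a feature-level augmentation (off by default).
    """

    alpha: float = 0.6
    l_walk: int = 2
    strategy: str = "path"
    seed: int = 0
    walks_per_root: int = 1
    feature_mask_p: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.l_walk < 0:
            raise ValueError(f"l_walk must be >= 0, got {self.l_walk}")
        if self.strategy not in ("path", "edge"):
            raise ValueError(f"strategy must be 'path' or 'edge', got {self.strategy!r}")
        if self.walks_per_root < 1:
            raise ValueError("walks_per_root must be >= 1")
        if not 0.0 <= self.feature_mask_p < 1.0:
            raise ValueError("feature_mask_p must be in [0, 1)")


@dataclass
class MaskResult:
    """Outcome of one masking draw.

    masked_edges and residual.edges partition the original edge set;
    masked_degree maps each node to its count of removed incident edges;
    V_M are endpoints of masked edges and V_D the sampled roots.
    """

    roots: frozenset[str]
    masked_edges: set[tuple[str, str]]
    residual: RNAGraph
    masked_degree: dict[str, int] = field(default_factory=dict)

    @property
    def V_M(self) -> frozenset[str]:
        return frozenset(n for edge in self.masked_edges for n in edge)

    @property
    def V_D(self) -> frozenset[str]:
        return self.roots


def sample_roots(graph: RNAGraph, alpha: float, rng: np.random.Generator) -> set[str]:
    """Include each node independently with probability alpha."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    keep = rng.random(graph.n_nodes) < alpha
    return {rid for rid, k in zip(graph.ids, keep) if k}


def _result(graph: RNAGraph, roots: set[str], masked: set[tuple[str, str]]) -> MaskResult:
    degree = Counter()
    for a, b in masked:
        degree[a] += 1
        degree[b] += 1
    return MaskResult(
        roots=frozenset(roots),
        masked_edges=masked,
        residual=graph.replace_edges(graph.edges - masked),
        masked_degree=dict(degree),
    )


def mask_path(
    graph: RNAGraph,
    roots: set[str],
    l_walk: int,
    rng: np.random.Generator,
    walks_per_root: int = 1,
) -> MaskResult:
    """Random-walk masking: from each root, walk up to l_walk steps over
    not-yet-removed edges, removing each traversed edge exactly once.

    A walk halts early when its current node has no remaining incident
    edges.  Roots are visited in graph node order for reproducibility.
    """
    unknown = roots - set(graph.ids)
    if unknown:
        raise ValueError(f"roots not in graph: {sorted(unknown)}")
    nbrs = graph.neighbor_map()
    masked: set[tuple[str, str]] = set()
    order = [rid for rid in graph.ids if rid in roots]
    for root in order:
        for _ in range(walks_per_root):
            cur = root
            for _ in range(l_walk):
                choices = sorted(nbrs[cur])
                if not choices:
                    break
                nxt = choices[rng.integers(len(choices))]
                nbrs[cur].discard(nxt)
                nbrs[nxt].discard(cur)
                masked.add(canonical_pair(cur, nxt))
                cur = nxt
    return _result(graph, roots, masked)


def mask_edges(graph: RNAGraph, alpha: float, rng: np.random.Generator) -> MaskResult:
    """Baseline strategy: remove each edge independently with probability alpha."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    edges = sorted(graph.edges)
    drop = rng.random(len(edges)) < alpha
    masked = {e for e, d in zip(edges, drop) if d}
    return _result(graph, set(), masked)


def mask_graph(graph: RNAGraph, cfg: MaskConfig, rng: np.random.Generator) -> MaskResult:
    """Draw one MaskResult according to the configured strategy."""
    if cfg.strategy == "edge":
        return mask_edges(graph, cfg.alpha, rng)
    roots = sample_roots(graph, cfg.alpha, rng)
    return mask_path(graph, roots, cfg.l_walk, rng, walks_per_root=cfg.walks_per_root)
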