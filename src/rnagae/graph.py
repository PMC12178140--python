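"""Data model for the RNA–RNA interaction graph and the file formats around it.

The interaction network is an undirected graph ``G = {V, E, X}`` whose nodes
are RNA molecules (miRNAs and lncRNAs), whose edges are known interactions,
and whose rows of ``X`` are per-node feature vectors.  Node order follows the
FASTA file and is canonical: every matrix in the package is indexed by it.
Pairs are undirected and stored with the lexicographically smaller id first.

Formats: FASTA for sequences (headers may carry an ``|miRNA`` / ``|lncRNA``
suffix), ``id<TAB>dot-bracket`` text for secondary structures, and a
three-column TSV (``id_a  id_b  label``) for labeled pairs.  All readers
tolerate CRLF line endings and ``#`` comment lines.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO

__all__ = [
    "RNARecord",
    "RNAGraph",
    "AdjacencyView",
    "canonical_pair",
    "validate_structure",
    "read_fasta",
    "read_structures",
    "attach_structures",
    "read_pairs",
    "write_pairs",
    "build_graph",
]

KINDS = ("miRNA", "lncRNA", "unknown")
RNA_ALPHABET = frozenset("ACGU")


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered pair in canonical (lexicographic) order; self-pairs rejected."""
    if a == b:
        raise ValueError(f"self-pair ({a!r}, {b!r}) is not a valid RNA-RNA pair")
    return (a, b) if a < b else (b, a)


def validate_structure(structure: str) -> None:
    """Check a dot-bracket string: only ``.()`` characters, balanced brackets."""
    depth = 0
    for i, ch in enumerate(structure):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced ')' at position {i} in structure")
        elif ch != ".":
            raise ValueError(f"invalid character {ch!r} at position {i} in structure")
    if depth != 0:
        raise ValueError(f"unbalanced structure: {depth} unclosed '('")


@dataclass
class RNARecord:
    """One RNA molecule: id, kind, sequence over ACGU, optional structure."""

    id: str
    sequence: str
    kind: str = "unknown"
    structure: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid sequence characters {sorted(bad)}"
            )
        if self.structure is not None:
            if len(self.structure) != len(self.sequence):
                raise ValueError(
                    f"record {self.id!r}: structure length {len(self.structure)} "
                    f"!= sequence length {len(self.sequence)}"
                )
            validate_structure(self.structure)


@dataclass
class AdjacencyView:
    """Dense adjacency matrices of a graph: A, self-looped A_hat, degrees D_hat.

    Graphs in this package are small (hundreds of nodes), so dense arrays are
    the simplest faithful representation.
    """

    A: np.ndarray
    A_hat: np.ndarray
    D_hat: np.ndarray

    @property
    def propagation_matrix(self) -> np.ndarray:
        """Symmetric-normalized operator ``D_hat^{-1/2} A_hat D_hat^{-1/2}``."""
        d = np.diag(self.D_hat)
        inv_sqrt = 1.0 / np.sqrt(d)
        return self.A_hat * inv_sqrt[:, None] * inv_sqrt[None, :]


@dataclass
class RNAGraph:
    """Undirected RNA interaction graph with per-node features.

    ``labels`` retains *both* classes of labeled pairs; ``edges`` holds only
    the positive (known-interaction) pairs.
    """

    ids: list[str]
    edges: set[tuple[str, str]]
    X: np.ndarray
    labels: dict[tuple[str, str], int] = field(default_factory=dict)
    records: list[RNARecord] | None = None

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate node ids in graph")
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.ids):
            raise ValueError(
                f"feature matrix has {self.X.shape[0]} rows for {len(self.ids)} nodes"
            )
        known = set(self.ids)
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            if (a, b) != canonical_pair(a, b):
                raise ValueError(f"edge ({a!r}, {b!r}) is not in canonical order")
            if a not in known or b not in known:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown node")

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def index(self) -> dict[str, int]:
        return {rid: i for i, rid in enumerate(self.ids)}

    def neighbor_map(self) -> dict[str, set[str]]:
        nbrs: dict[str, set[str]] = {rid: set() for rid in self.ids}
        for a, b in self.edges:
            nbrs[a].add(b)
            nbrs[b].add(a)
        return nbrs

    def degree(self, rid: str) -> int:
        return sum(1 for a, b in self.edges if rid in (a, b))

    def replace_edges(self, edges: set[tuple[str, str]]) -> "RNAGraph":
        """A copy of the graph with a different edge set (same nodes/X/labels)."""
        return RNAGraph(
            ids=self.ids,
            edges=set(edges),
            X=self.X,
            labels=self.labels,
            records=self.records,
        )

    def adjacency(self) -> AdjacencyView:
        idx = self.index
        n = self.n_nodes
        A = np.zeros((n, n), dtype=float)
        for a, b in self.edges:
            A[idx[a], idx[b]] = 1.0
            A[idx[b], idx[a]] = 1.0
        A_hat = A + np.eye(n)
        D_hat = np.diag(A_hat.sum(axis=1))
        return AdjacencyView(A=A, A_hat=A_hat, D_hat=D_hat)


# ----------------------------------------------------------------------
# readers / writers
def _read_text(path) -> str:
    text = Path(path).read_text()
    return text.replace("\r\n", "\n").replace("\r", "\n")


def read_fasta(path) -> list[RNARecord]:
    """Read RNA records from FASTA, normalizing T to U.

    Header form ``>id|miRNA`` or ``>id|lncRNA`` sets the record kind;
    otherwise the kind is ``unknown``.  Duplicate ids and non-ACGU/T
    characters are errors.
    """
    text = "\n".join(
        line for line in _read_text(path).split("\n") if not line.startswith("#")
    )
    records: list[RNARecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        token = rec.id
        kind = "unknown"
        rid = token
        if "|" in token:
            head, tail = token.rsplit("|", 1)
            if tail in ("miRNA", "lncRNA"):
                rid, kind = head, tail
        if rid in seen:
            raise ValueError(f"duplicate record id {rid!r} in {path}")
        seen.add(rid)
        seq = str(rec.seq).upper().replace("T", "U")
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"record {rid!r}: invalid sequence characters {sorted(bad)}"
            )
        records.append(RNARecord(id=rid, sequence=seq, kind=kind))
    return records


def read_structures(path) -> dict[str, str]:
    """Read ``id<TAB>dot-bracket`` lines into a mapping."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(_read_text(path).split("\n"), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'id<TAB>structure'")
        rid, structure = parts
        if rid in out:
            raise ValueError(f"{path}:{lineno}: duplicate structure for {rid!r}")
        validate_structure(structure)
        out[rid] = structure
    return out


def attach_structures(
    records: list[RNARecord], structures: dict[str, str]
) -> list[RNARecord]:
    """Return records with structures attached (validated against lengths)."""
    out = []
    for rec in records:
        s = structures.get(rec.id)
        out.append(replace(rec, structure=s) if s is not None else rec)
    return out


def read_pairs(path, known_ids: set[str] | None = None) -> list[tuple[str, str, int]]:
    """Read labeled pairs from a 3-column TSV; collapse duplicates.

    Pairs are unordered; re-stated duplicates with the same label collapse to
    one entry, conflicting labels raise.  If ``known_ids`` is given, every id
    must resolve against it.
    """
    seen: dict[tuple[str, str], int] = {}
    order: list[tuple[str, str]] = []
    for lineno, line in enumerate(_read_text(path).split("\n"), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
        a, b, raw = parts
        if raw not in ("0", "1"):
            raise ValueError(f"{path}:{lineno}: label must be 0 or 1, got {raw!r}")
        label = int(raw)
        if known_ids is not None:
            for rid in (a, b):
                if rid not in known_ids:
                    raise ValueError(f"{path}:{lineno}: unknown id {rid!r}")
        pair = canonical_pair(a, b)
        if pair in seen:
            if seen[pair] != label:
                raise ValueError(
                    f"{path}:{lineno}: conflicting labels for pair {pair}"
                )
            continue
        seen[pair] = label
        order.append(pair)
    return [(a, b, seen[(a, b)]) for a, b in order]


def write_pairs(path, pairs: list[tuple[str, str, int]]) -> None:
    """Write pairs as TSV in canonical order, preserving list order."""
    with open(path, "w") as fh:
        for a, b, label in pairs:
            a, b = canonical_pair(a, b)
            fh.write(f"{a}\t{b}\t{int(label)}\n")


def build_graph(
    records: list[RNARecord],
    pairs: list[tuple[str, str, int]],
    X: np.ndarray,
) -> RNAGraph:
    """Assemble the RNA graph: positive pairs become edges, all pairs labels.

    ``X`` rows must follow the record order (the canonical node order).
    """
    ids = [rec.id for rec in records]
    known = set(ids)
    if len(known) != len(ids):
        raise ValueError("duplicate record ids")
    edges: set[tuple[str, str]] = set()
    labels: dict[tuple[str, str], int] = {}
    for a, b, label in pairs:
        if a == b:
            raise ValueError(f"self-pair ({a!r}, {a!r}) is not allowed")
        for rid in (a, b):
            if rid not in known:
                raise ValueError(f"pair references unknown id {rid!r}")
        pair = canonical_pair(a, b)
        if pair in labels and labels[pair] != label:
            raise ValueError(f"conflicting labels for pair {pair}")
        labels[pair] = int(label)
        if label == 1:
            edges.add(pair)
    if not edges:
        warnings.warn("graph has no positive pairs; building an edgeless graph")
    return RNAGraph(ids=ids, edges=edges, X=np.asarray(X, float), labels=labels, records=list(records))
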