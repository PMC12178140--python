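"""Initial node features: weighted multi-scale k-mer composition plus
secondary-structure composition scalars.

Each RNA sequence is summarized by its k-mer frequency vectors for
k = 1..k_max, weighted by a normalized arithmetic progression
(w_k = k / sum(1..k_max)) so that longer, more specific k-mers contribute
more mass, and optionally by four structure-composition scalars derived
from a dot-bracket string.  Structures come from the input when provided
and otherwise from a built-in maximum-base-pairing (Nussinov) fold, so no
external folding binary is required.  Columns are z-scored by default
because the mixed scales feed a normalized graph convolution.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import product

import numpy as np
from numba import njit

from .graph import RNARecord, validate_structure

__all__ = [
    "FeatureConfig",
    "arithmetic_weights",
    "kmer_frequencies",
    "fold_nussinov",
    "structure_features",
    "featurize",
    "feature_names",
    "write_features",
    "read_features",
]

ALPHABET = "ACGU"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
# allowed base pairs: Watson-Crick plus GU wobble
_PAIRABLE = np.zeros((4, 4), dtype=np.bool_)
for _a, _b in ("AU", "UA", "GC", "CG", "GU", "UG"):
    _PAIRABLE[_CODE[_a], _CODE[_b]] = True

STRUCTURE_FEATURE_NAMES = (
    "paired_fraction",
    "hairpins_per_nt",
    "max_stem_run_frac",
    "max_unpaired_run_frac",
)


def arithmetic_weights(k_max: int) -> np.ndarray:
    """Normalized arithmetic-progression weights w_k = k / sum(1..k_max)."""
    if k_max < 1:
        raise ValueError(f"k_max must be >= 1, got {k_max}")
    w = np.arange(1, k_max + 1, dtype=float)
    return w / w.sum()


def kmer_frequencies(sequence: str, k: int) -> np.ndarray:
    """Frequency vector over all 4^k k-mers in fixed lexicographic order."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n = len(sequence)
    if n < k:
        raise ValueError(f"sequence length {n} < k = {k}")
    bad = set(sequence) - set(ALPHABET)
    if bad:
        raise ValueError(f"invalid sequence characters {sorted(bad)}")
    counts = np.zeros(4**k, dtype=float)
    codes = [_CODE[c] for c in sequence]
    idx = 0
    base = 4 ** (k - 1)
    for i in range(k):
        idx = idx * 4 + codes[i]
    counts[idx] += 1
    for i in range(k, n):
        idx = (idx % base) * 4 + codes[i]
        counts[idx] += 1
    return counts / (n - k + 1)


# ----------------------------------------------------------------------
# maximum-base-pairing fold (Nussinov dynamic program)
@njit(cache=False)
def _nussinov_fill(pairable: np.ndarray, min_loop: int) -> np.ndarray:
    n = pairable.shape[0]
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                if pairable[i, k]:
                    v = 1
                    if k - 1 > i:
                        v += dp[i + 1, k - 1]
                    if k < j:
                        v += dp[k + 1, j]
                    if v > best:
                        best = v
            dp[i, j] = best
    return dp


def _traceback(dp, pairable, min_loop, i, j, out):
    while i < j:
        paired = False
        for k in range(i + min_loop + 1, j + 1):
            if pairable[i, k]:
                v = 1
                if k - 1 > i:
                    v += dp[i + 1, k - 1]
                if k < j:
                    v += dp[k + 1, j]
                if v == dp[i, j]:
                    out[i], out[k] = "(", ")"
                    _traceback(dp, pairable, min_loop, i + 1, k - 1, out)
                    i = k + 1
                    paired = True
                    break
        if not paired:
            i += 1


def fold_nussinov(sequence: str, min_loop: int = 3) -> str:
    """Non-crossing pairing maximizing base-pair count, as dot-bracket.

    Allowed pairs are AU/UA, GC/CG and GU/UG; every pair encloses at least
    ``min_loop`` unpaired positions.  Ties are broken toward the 5'-most
    opening pair, making the traceback deterministic.
    """
    bad = set(sequence) - set(ALPHABET)
    if bad:
        raise ValueError(f"invalid sequence characters {sorted(bad)}")
    n = len(sequence)
    if n <= min_loop + 1:
        return "." * n
    codes = np.array([_CODE[c] for c in sequence], dtype=np.int64)
    pairable = _PAIRABLE[codes[:, None], codes[None, :]]
    dp = _nussinov_fill(pairable, min_loop)
    out = ["."] * n
    _traceback(dp, pairable, min_loop, 0, n - 1, out)
    return "".join(out)


def structure_features(structure: str) -> np.ndarray:
    """Four composition scalars of a dot-bracket string, each in [0, 1].

    (paired fraction, hairpin loops per nt, longest same-bracket run / len,
    longest unpaired run / len).  The parser is permissive about loop sizes:
    any balanced string is accepted.
    """
    validate_structure(structure)
    n = len(structure)
    if n == 0:
        raise ValueError("empty structure")
    paired = sum(1 for c in structure if c in "()")
    hairpins = len(re.findall(r"\(\.*\)", structure))

    def _max_run(chars: str) -> int:
        best = run = 0
        prev = None
        for c in structure:
            if c in chars and c == prev:
                run += 1
            elif c in chars:
                run = 1
            else:
                run = 0
            prev = c
            best = max(best, run)
        return best

    max_stem = max(_max_run("("), _max_run(")"))
    max_unpaired = _max_run(".")
    # '.' runs: _max_run treats consecutive '.' correctly since '.' == prev
    return np.array(
        [paired / n, hairpins / n, max_stem / n, max_unpaired / n], dtype=float
    )


# ----------------------------------------------------------------------
@dataclass
class FeatureConfig:
    """Configuration for the initial feature matrix.

    weights defaults to the arithmetic progression over k = 1..k_max.
    """

    k_max: int = 3
    weights: np.ndarray | None = None
    use_structure: bool = True
    standardize: bool = True

    def resolved_weights(self) -> np.ndarray:
        if self.weights is None:
            return arithmetic_weights(self.k_max)
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.k_max,):
            raise ValueError(f"weights must have length k_max={self.k_max}")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be nonnegative and sum to 1")
        return w

    @property
    def width(self) -> int:
        return sum(4**k for k in range(1, self.k_max + 1)) + (
            len(STRUCTURE_FEATURE_NAMES) if self.use_structure else 0
        )


def feature_names(cfg: FeatureConfig) -> list[str]:
    names: list[str] = []
    for k in range(1, cfg.k_max + 1):
        names.extend("kmer_" + "".join(p) for p in product(ALPHABET, repeat=k))
    if cfg.use_structure:
        names.extend(STRUCTURE_FEATURE_NAMES)
    return names


def featurize(records: list[RNARecord], cfg: FeatureConfig | None = None) -> np.ndarray:
    """Build the node feature matrix X, one row per record in input order."""
    if not records:
        raise ValueError("no records to featurize")
    cfg = cfg or FeatureConfig()
    too_short = [r.id for r in records if len(r.sequence) < cfg.k_max]
    if too_short:
        raise ValueError(
            f"records shorter than k_max={cfg.k_max}: {sorted(too_short)}"
        )
    w = cfg.resolved_weights()
    rows = []
    for rec in records:
        blocks = [
            w[k - 1] * kmer_frequencies(rec.sequence, k)
            for k in range(1, cfg.k_max + 1)
        ]
        if cfg.use_structure:
            structure = rec.structure or fold_nussinov(rec.sequence)
            blocks.append(structure_features(structure))
        rows.append(np.concatenate(blocks))
    X = np.asarray(rows, dtype=float)
    if cfg.standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        X = (X - mu) / np.maximum(sd, 1e-8)
    return X


def write_features(path, ids: list[str], X: np.ndarray, names: list[str]) -> None:
    X = np.asarray(X)
    if X.shape != (len(ids), len(names)):
        raise ValueError("feature matrix shape does not match ids/names")
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(names) + "\n")
        for rid, row in zip(ids, X):
            fh.write(rid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_features(path) -> tuple[list[str], np.ndarray, list[str]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if header[0] != "id":
            raise ValueError("feature TSV must start with an 'id' column")
        names = header[1:]
        ids, rows = [], []
        for line in fh:
            parts = line.rstrip("\r\n").split("\t")
            if len(parts) != len(names) + 1:
                raise ValueError("ragged feature TSV row")
            ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return ids, np.asarray(rows, dtype=float), names
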