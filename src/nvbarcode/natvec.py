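"""Covariance-augmented natural vectors for alignment-free sequence comparison.

A DNA sequence S = (s_1, ..., s_N) is summarized per nucleotide k by

* n_k    — count of k,
* mu_k   — mean 1-based position of k,
* D2_k   — normalized positional variation, sum_i (i - mu_k)^2 w_k(i) / (n_k N),

and per unordered nucleotide pair (k1, k2) by a subset-averaged positional
covariance. For position sets A (size n) and B (size m >= n), Cov(A, B) is the
average, over all C(m, n) ascending size-n subsets of B, of
sum_i (a_i - mu_A)(b_i - mu_subset) / n; the pair feature is Cov(A, B) / N.
When k1 = k2 this reduces exactly to D2_k. The 18 features (4 counts, 4 means,
4 variations, 6 covariances) map each sequence to a point in R^18; Euclidean
distance between these points is the similarity metric used downstream.

The combinatorial average has an O(n m) closed form: each subset's own mean
contributes nothing because sum_i (a_i - mu_A) = 0, so the average equals
(1/n) sum_j b_j sum_i (a_i - mu_A) P(rank of b_j in the subset = i), with
hypergeometric rank weights P = C(j-1, i-1) C(m-j, n-i) / C(m, n).
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator, TransformerMixin

from .sequences import SequenceRecord

NUCLEOTIDES = ("A", "C", "G", "T")
PAIRS = (("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T"))

NV18_COLUMNS = (
    "n_A", "n_C", "n_G", "n_T",
    "mu_A", "mu_C", "mu_G", "mu_T",
    "d2_A", "d2_C", "d2_G", "d2_T",
    "cov_AC", "cov_AG", "cov_AT", "cov_CG", "cov_CT", "cov_GT",
)

_BLOCKS = {
    "number": slice(0, 4),
    "mean_position": slice(4, 8),
    "normalized_variation": slice(8, 12),
    "covariance": slice(12, 18),
}

_MAX_BRUTE_SUBSETS = 10**6


def positions_of(seq: str, k: str) -> np.ndarray:
    """Ascending 1-based positions of nucleotide ``k`` in ``seq``."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return np.flatnonzero(arr == ord(k)) + 1


def count_mean_var(seq: str) -> dict[str, tuple[int, float, float]]:
    """(n_k, mu_k, D2_k) per nucleotide; (0, 0, 0) when k is absent."""
    N = len(seq)
    out = {}
    for k in NUCLEOTIDES:
        pos = positions_of(seq, k)
        n = pos.size
        if n == 0:
            out[k] = (0, 0.0, 0.0)
            continue
        mu = pos.mean()
        d2 = float(((pos - mu) ** 2).sum() / (n * N))
        out[k] = (n, float(mu), d2)
    return out


def brute_force_cov(A: Sequence[float], B: Sequence[float]) -> float:
    """Subset-averaged covariance by literal enumeration (test-scale oracle).

    Enumerates every ascending size-n subset of the larger set and averages
    sum_i (a_i - mu_A)(b_i - mu_subset) / n, each set centered on its own mean.
    """
    a = np.sort(np.asarray(A, dtype=float))
    b = np.sort(np.asarray(B, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("position sets must be nonempty")
    if a.size > b.size:
        a, b = b, a
    n, m = a.size, b.size
    if comb(m, n) > _MAX_BRUTE_SUBSETS:
        raise ValueError(
            f"C({m},{n}) subsets exceed enumeration guard; use subset_avg_cov"
        )
    mu_a = a.mean()
    total = 0.0
    count = 0
    for sub in combinations(b, n):
        t = np.asarray(sub)
        total += float(((a - mu_a) * (t - t.mean())).sum() / n)
        count += 1
    return total / count


def subset_avg_cov(A: Sequence[float], B: Sequence[float]) -> float:
    """Closed-form subset-averaged covariance, O(n m).

    Equals :func:`brute_force_cov` exactly (to floating-point roundoff)
    without enumerating subsets, via hypergeometric rank weights.
    """
    a = np.sort(np.asarray(A, dtype=float))
    b = np.sort(np.asarray(B, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("position sets must be nonempty")
    if a.size > b.size:
        a, b = b, a
    n, m = a.size, b.size
    dev = a - a.mean()
    if n == 1:
        return 0.0
    if n == m:
        return float((dev * (b - b.mean())).sum() / n)
    # log-binomial rank weights: P[i, j] = C(j-1, i-1) C(m-j, n-i) / C(m, n)
    lg = gammaln(np.arange(m + 2, dtype=float) + 1.0)  # lg[x] = ln(x!)

    def lcomb(N_: np.ndarray, K_: np.ndarray) -> np.ndarray:
        out = np.where((K_ < 0) | (K_ > N_), -np.inf, 0.0)
        ok = out == 0.0
        Nv, Kv = np.where(ok, N_, 0), np.where(ok, K_, 0)
        out = out + lg[Nv] - lg[Kv] - lg[Nv - Kv]
        return out

    i = np.arange(1, n + 1)[:, None]
    j = np.arange(1, m + 1)[None, :]
    logp = lcomb(j - 1, i - 1) + lcomb(m - j, n - i) - lcomb(
        np.array([[m]]), np.array([[n]])
    )
    P = np.exp(logp)
    return float(dev @ P @ b / n)


def cov_pair(seq: str, k1: str, k2: str) -> float:
    """Pair covariance feature Cov(k1, k2) = Cov(A, B) / N.

    Returns 0 when either nucleotide is absent. For k1 = k2 this equals D2_k.
    """
    A = positions_of(seq, k1)
    B = positions_of(seq, k2)
    if A.size == 0 or B.size == 0:
        return 0.0
    if k1 == k2:
        mu = A.mean()
        return float(((A - mu) ** 2).sum() / (A.size * len(seq)))
    return subset_avg_cov(A, B) / len(seq)


def natural_vector18(seq: str) -> np.ndarray:
    """The 18-dimensional covariance-augmented natural vector of ``seq``.

    Order: (n_A..n_T, mu_A..mu_T, D2_A..D2_T, cov_AC, cov_AG, cov_AT,
    cov_CG, cov_CT, cov_GT). Pair entries are Cov(A,B)/N, i.e. divided by the
    sequence length exactly once.
    """
    cmv = count_mean_var(seq)
    v = np.empty(18)
    for idx, k in enumerate(NUCLEOTIDES):
        n, mu, d2 = cmv[k]
        v[idx], v[4 + idx], v[8 + idx] = n, mu, d2
    for idx, (k1, k2) in enumerate(PAIRS):
        v[12 + idx] = cov_pair(seq, k1, k2)
    return v


def natural_vector12(seq: str) -> np.ndarray:
    """The original 12-dimensional natural vector (counts, means, variations)."""
    return natural_vector18(seq)[:12]


def ablated_vector(seq: str, drop: str) -> np.ndarray:
    """18-dim vector with one feature block removed (14- or 12-dim result).

    ``drop`` is one of {"number", "mean_position", "normalized_variation",
    "covariance"}; the remaining blocks keep their order.
    """
    if drop not in _BLOCKS:
        raise ValueError(f"unknown feature block {drop!r}; choose from {sorted(_BLOCKS)}")
    v = natural_vector18(seq)
    keep = np.ones(18, dtype=bool)
    keep[_BLOCKS[drop]] = False
    return v[keep]


def kmer_vector(seq: str, k: int = 5) -> np.ndarray:
    """Overlapping k-mer counts in lexicographic order over {A,C,G,T} (4^k dims)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    N = len(seq)
    if N < k:
        raise ValueError(f"sequence of length {N} shorter than k={k}")
    code = {c: i for i, c in enumerate(NUCLEOTIDES)}
    digits = np.array([code[c] for c in seq], dtype=np.int64)
    idx = np.zeros(N - k + 1, dtype=np.int64)
    for off in range(k):
        idx = idx * 4 + digits[off:off + N - k + 1]
    return np.bincount(idx, minlength=4**k).astype(float)


def _vectorizer(method: str):
    """Resolve a method string to (callable, column names)."""
    if method == "nv18":
        return natural_vector18, list(NV18_COLUMNS)
    if method == "nv12":
        return natural_vector12, list(NV18_COLUMNS[:12])
    if method.startswith("ablated:"):
        drop = method.split(":", 1)[1]
        if drop not in _BLOCKS:
            raise ValueError(f"unknown feature block {drop!r}")
        keep = np.ones(18, dtype=bool)
        keep[_BLOCKS[drop]] = False
        cols = [c for c, kkeep in zip(NV18_COLUMNS, keep) if kkeep]
        return (lambda s: ablated_vector(s, drop)), cols
    if method.startswith("kmer:"):
        k = int(method.split(":", 1)[1])
        cols = ["".join(p) for p in _lex_kmers(k)]
        return (lambda s: kmer_vector(s, k)), cols
    raise ValueError(f"unknown featurization method {method!r}")


def _lex_kmers(k: int) -> Iterable[tuple[str, ...]]:
    from itertools import product
    return product(NUCLEOTIDES, repeat=k)


class NaturalVectorEncoder(BaseEstimator, TransformerMixin):
    """Sequence featurizer with the sklearn transformer interface.

    Parameters
    ----------
    method : str, default "nv18"
        One of ``nv18``, ``nv12``, ``ablated:<block>`` with block in
        {number, mean_position, normalized_variation, covariance}, or
        ``kmer:<k>``.

    The encoder is stateless; ``fit`` only validates the method string.
    ``transform`` accepts SequenceRecords or plain strings and returns an
    (n_sequences, n_features) array. Deterministic: identical sequences map
    to identical rows.
    """

    def __init__(self, method: str = "nv18"):
        self.method = method

    def fit(self, X, y=None):
        fn, cols = _vectorizer(self.method)
        self.feature_names_ = cols
        self.n_features_out_ = len(cols)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "feature_names_"):
            self.fit(X)
        fn, _ = _vectorizer(self.method)
        rows = []
        for item in X:
            seq = item.seq if isinstance(item, SequenceRecord) else str(item)
            rec_id = item.id if isinstance(item, SequenceRecord) else None
            try:
                rows.append(fn(seq))
            except ValueError as exc:
                ctx = f" (record {rec_id!r})" if rec_id else ""
                raise ValueError(f"featurization failed{ctx}: {exc}") from exc
        if not rows:
            return np.empty((0, self.n_features_out_))
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)


def featurize(records: Sequence[SequenceRecord], method: str = "nv18") -> pd.DataFrame:
    """Feature matrix (rows = record ids, columns = named features)."""
    enc = NaturalVectorEncoder(method).fit(records)
    X = enc.transform(records)
    ids = [r.id if isinstance(r, SequenceRecord) else f"seq{i}"
           for i, r in enumerate(records)]
    return pd.DataFrame(X, index=pd.Index(ids, name="id"), columns=enc.feature_names_)
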