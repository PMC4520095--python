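"""Physico-chemical encoding and consensus clustering of discriminative
n-grams.

Each 21-position window is re-expressed as binary indicator vectors for a
small set of residue properties (hydrophobic, negative, positive, proline
by default); the windows mapping to each discriminative n-gram are averaged
position-wise (mask-aware for truncated windows) into a per-property
profile. One k-means (k = 10) partition is fitted per property, and the
per-property partitions are reconciled by a soft least-squares Euclidean
consensus: alternating optimal label matching (linear assignment) and
membership averaging minimizes

    sum_b || M - M_b Pi_b ||_F^2

over soft memberships M with rows on the simplex.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .errors import UsageError, ValidationError
from .model import AA_SET, DEFAULT_WIDTH, PhosphopeptideWindow, Signature
from .ngrams import NGramCountTable

#: Default binary residue property sets; overridable via a property table file.
DEFAULT_PROPERTIES: dict[str, frozenset[str]] = {
    "hydrophobic": frozenset("ACFILMV"),
    "negative": frozenset("DE"),
    "positive": frozenset("KRH"),
    "proline": frozenset("P"),
}

CENTER = (DEFAULT_WIDTH - 1) // 2  # 0-based column of the phosphosite


def validate_properties(props: Mapping[str, Iterable[str]]
                        ) -> dict[str, frozenset[str]]:
    out: dict[str, frozenset[str]] = {}
    for name, residues in props.items():
        rs = frozenset(residues)
        if not rs <= AA_SET:
            raise ValidationError(
                f"property {name!r} contains non-amino-acid residues "
                f"{sorted(rs - AA_SET)}")
        if name in out:
            raise ValidationError(f"duplicate property {name!r}")
        out[name] = rs
    return out


def encode_window(window: PhosphopeptideWindow,
                  props: Mapping[str, frozenset[str]] = DEFAULT_PROPERTIES
                  ) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-property 0/1 vectors aligned to the 21 canonical positions.

    Returns (values, mask): ``values[p][j]`` is 1.0 iff the residue at
    aligned position j belongs to property p; ``mask[j]`` is True where the
    (possibly truncated) window defines a residue other than 'X'.
    """
    start = CENTER - window.offset_of_site
    if start < 0 or start + len(window.window) > DEFAULT_WIDTH:
        raise ValidationError(
            f"window {window.window!r} (offset {window.offset_of_site}) does "
            f"not fit the {DEFAULT_WIDTH}-position frame")
    mask = np.zeros(DEFAULT_WIDTH, dtype=bool)
    values = {p: np.zeros(DEFAULT_WIDTH) for p in props}
    for j, res in enumerate(window.window):
        if res == "X":
            continue
        col = start + j
        mask[col] = True
        for p, residues in props.items():
            if res in residues:
                values[p][col] = 1.0
    return values, mask


@dataclass
class PhyschemProfile:
    """Mask-aware positional property means over an n-gram's source windows."""

    ngram: str
    means: dict[str, np.ndarray]  # property -> (21,) in [0, 1]
    support: np.ndarray           # (21,) number of windows defining each position
    n_windows: int


def profile_ngram(ngram: str,
                  tables: NGramCountTable | Sequence[NGramCountTable],
                  props: Mapping[str, frozenset[str]] = DEFAULT_PROPERTIES
                  ) -> PhyschemProfile:
    """Average the encodings of every window containing ``ngram``."""
    if isinstance(tables, NGramCountTable):
        tables = [tables]
    windows: list[PhosphopeptideWindow] = []
    for t in tables:
        windows.extend(t.source_windows.get(ngram, []))
    if not windows:
        raise KeyError(f"n-gram {ngram!r} has no source windows")
    sums = {p: np.zeros(DEFAULT_WIDTH) for p in props}
    support = np.zeros(DEFAULT_WIDTH)
    for w in windows:
        values, mask = encode_window(w, props)
        support += mask
        for p in props:
            sums[p] += values[p]
    means = {p: np.divide(sums[p], support, out=np.zeros(DEFAULT_WIDTH),
                          where=support > 0) for p in props}
    return PhyschemProfile(ngram=ngram, means=means, support=support,
                           n_windows=len(windows))


def profile_matrix(ngrams: Sequence[str],
                   tables: NGramCountTable | Sequence[NGramCountTable],
                   props: Mapping[str, frozenset[str]] = DEFAULT_PROPERTIES
                   ) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Stack profiles into per-property (n x 21) matrices plus a concatenation.

    Masked positions are imputed with the property's global mean over all
    observed positions so every vector has a fixed length. Returns
    (per_property, concatenated) where ``concatenated`` is (n, 21*P).
    """
    profiles = [profile_ngram(g, tables, props) for g in ngrams]
    per_property: dict[str, np.ndarray] = {}
    for p in props:
        mat = np.stack([pr.means[p] for pr in profiles])
        observed = np.stack([pr.support > 0 for pr in profiles])
        if observed.any():
            global_mean = mat[observed].mean()
        else:
            global_mean = 0.0
        mat = np.where(observed, mat, global_mean)
        per_property[p] = mat
    concatenated = np.hstack([per_property[p] for p in props])
    return per_property, concatenated


def kmeans_partition(profiles: np.ndarray, k: int = 10, seed: int = 0,
                     restarts: int = 10) -> np.ndarray:
    """Hard k-means partition (Lloyd, squared Euclidean, k-means++ restarts)."""
    profiles = np.asarray(profiles, dtype=np.float64)
    if profiles.ndim != 2:
        raise UsageError("profiles must be a 2-d array")
    if profiles.shape[0] < k:
        raise UsageError(f"{profiles.shape[0]} items < k={k}")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed,
                algorithm="lloyd")
    return km.fit_predict(profiles)


@dataclass
class ConsensusClustering:
    """Soft consensus over several hard partitions of the same items."""

    items: list[str]
    membership: np.ndarray        # (n, k), rows on the simplex
    labels: np.ndarray            # (n,) argmax-hardened consensus
    objective: float
    objective_history: list[float]
    input_partitions: list[np.ndarray] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.membership.shape[1]


def _one_hot(labels: np.ndarray, k: int) -> np.ndarray:
    m = np.zeros((len(labels), k))
    m[np.arange(len(labels)), labels] = 1.0
    return m


def consensus_partition(partitions: Sequence[np.ndarray], k: int,
                        items: Sequence[str] | None = None,
                        max_iter: int = 100, tol: float = 1e-10,
                        seed: int = 0) -> ConsensusClustering:
    """Soft least-squares Euclidean consensus of hard partitions.

    Alternates (i) per-input optimal column matching of M_b to the current
    consensus M by linear assignment maximizing trace(M^T M_b Pi), and
    (ii) M = mean of the matched one-hot memberships (automatically on the
    simplex). The objective sum_b ||M - M_b Pi_b||^2 is non-increasing and
    reaches 0 for inputs identical up to label permutation. Initialization
    is the first partition's membership, so the result is deterministic;
    ``seed`` is accepted for interface symmetry.
    """
    if len(partitions) < 2:
        raise UsageError("need at least 2 input partitions")
    n = len(partitions[0])
    for p in partitions:
        if len(p) != n:
            raise UsageError("partitions cover different item sets")
        if np.any(np.asarray(p) >= k) or np.any(np.asarray(p) < 0):
            raise UsageError(f"partition labels must lie in [0, {k})")
    mats = [_one_hot(np.asarray(p, dtype=int), k) for p in partitions]
    m = mats[0].copy()
    history: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        matched = []
        for mb in mats:
            gain = m.T @ mb  # (k, k): overlap of consensus col i with input col j
            rows, cols = linear_sum_assignment(-gain)
            perm = np.empty(k, dtype=int)
            perm[cols] = rows  # input column j -> consensus column perm[j]
            matched.append(mb @ _perm_matrix(perm, k))
        m = np.mean(matched, axis=0)
        obj = float(sum(np.sum((m - mb) ** 2) for mb in matched))
        history.append(obj)
        if prev - obj < tol:
            break
        prev = obj
    labels = m.argmax(axis=1)
    return ConsensusClustering(
        items=list(items) if items is not None else [str(i) for i in range(n)],
        membership=m, labels=labels, objective=history[-1],
        objective_history=history,
        input_partitions=[np.asarray(p, dtype=int) for p in partitions])


def _perm_matrix(perm: np.ndarray, k: int) -> np.ndarray:
    """Column-permutation matrix sending input column j to column perm[j]."""
    pi = np.zeros((k, k))
    pi[np.arange(k), perm] = 1.0
    return pi


def cluster_distribution(consensus: ConsensusClustering, sig: Signature,
                         species_tables: Mapping[str, NGramCountTable]
                         ) -> pd.DataFrame:
    """Per species, the fraction of its present signature n-grams in each
    consensus cluster (rows sum to 1 for species with any present n-gram)."""
    missing = [g for g in sig.ngrams if g not in set(consensus.items)]
    if missing:
        raise UsageError(f"consensus does not cover signature n-grams "
                         f"{missing[:5]}...")
    label_of = dict(zip(consensus.items, consensus.labels))
    k = consensus.k
    rows = {}
    for sp, table in species_tables.items():
        hist = np.zeros(k)
        for g in sig.ngrams:
            if table.counts.get(g, 0) > 0:
                hist[label_of[g]] += 1
        total = hist.sum()
        rows[sp] = hist / total if total else hist
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"cluster_{i}" for i in range(k)])
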