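"""Signature evaluation: supervised SVM classification and hierarchical
clustering with multiscale-bootstrap BP/AU support values.

Classification follows the species-level design: each species contributes
one feature vector (its signature-restricted dampened normalized
frequencies), a support vector machine with the normalized polynomial
kernel

    K~(x, y) = K(x, y) / sqrt(K(x, x) K(y, y)),   K(x, y) = (x . y + 1)^d

is trained on the training species (one-vs-one for multiclass) and each
test species is assigned to one training class.

Cluster uncertainty is assessed pvclust-style: the n-gram rows are
bootstrap-resampled at several relative sample sizes r (default 0.5..1.4),
the species tree is rebuilt per replicate, and each observed edge's
per-scale bootstrap probability BP_r is probit-fitted as

    Phi^-1(1 - BP_r) = v sqrt(r) + c / sqrt(r)

by weighted least squares; the approximately unbiased p-value is
AU = 1 - Phi(v - c) and BP is the raw bootstrap probability at r = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm
from sklearn.svm import SVC

from .errors import UsageError
from .frequencies import FrequencyMatrix

logger = logging.getLogger(__name__)

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 1))

DISTANCES = ("correlation", "euclidean")
LINKAGES = ("average", "complete", "ward")


def normalized_polynomial_kernel(a: np.ndarray, b: np.ndarray,
                                 degree: int = 2) -> np.ndarray:
    """Cosine-normalized polynomial kernel between row vectors of a and b.

    K~(x, x) = 1 for every x (including the zero vector, since K(0,0)=1).
    """
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    k = (a @ b.T + 1.0) ** degree
    ka = (np.einsum("ij,ij->i", a, a) + 1.0) ** degree
    kb = (np.einsum("ij,ij->i", b, b) + 1.0) ** degree
    return k / np.sqrt(np.outer(ka, kb))


@dataclass
class ClassificationResult:
    """0/1 confusion matrix (test species x training species) and accuracy."""

    confusion: pd.DataFrame
    assigned: dict[str, str]  # test species -> predicted training species
    accuracy: float


def train_and_classify(train_fm: FrequencyMatrix, labels: Mapping[str, str],
                       test_fm: FrequencyMatrix, degree: int = 2,
                       c: float = 1.0,
                       pairing: Mapping[str, str] | None = None
                       ) -> ClassificationResult:
    """Train an SVM on training-species columns and classify test columns.

    ``labels`` maps each training species to its class (normally itself).
    ``pairing`` (test species -> expected training species) defines accuracy;
    it defaults to identity of class labels being unavailable, in which case
    accuracy is computed against ``labels`` applied to the pairing — if no
    pairing is given, accuracy is NaN.
    """
    if train_fm.ngrams != test_fm.ngrams:
        raise UsageError("train and test matrices must share an identical "
                         "n-gram ordering")
    classes = {labels[sp] for sp in train_fm.species}
    if len(classes) < 2:
        raise UsageError("need at least 2 training classes")

    x_train = train_fm.normfreq.T  # species are rows
    x_test = test_fm.normfreq.T
    for j, sp in enumerate(test_fm.species):
        if not x_test[j].any():
            logger.warning("test species %r has an all-zero feature vector; "
                           "its assignment is arbitrary", sp)

    y = np.array([labels[sp] for sp in train_fm.species])
    svm = SVC(C=c, kernel="precomputed")
    svm.fit(normalized_polynomial_kernel(x_train, x_train, degree), y)
    pred = svm.predict(normalized_polynomial_kernel(x_test, x_train, degree))

    train_order = list(dict.fromkeys(labels[sp] for sp in train_fm.species))
    confusion = pd.DataFrame(0, index=list(test_fm.species),
                             columns=train_order, dtype=int)
    assigned: dict[str, str] = {}
    for sp, cls in zip(test_fm.species, pred):
        assigned[sp] = str(cls)
        confusion.loc[sp, str(cls)] = 1
    if pairing is not None:
        hits = sum(assigned[sp] == labels.get(pairing[sp], pairing[sp])
                   for sp in test_fm.species if sp in pairing)
        accuracy = hits / len(test_fm.species)
    else:
        accuracy = float("nan")
    return ClassificationResult(confusion=confusion, assigned=assigned,
                                accuracy=accuracy)


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Agglomerative tree over species columns (scipy linkage encoding)."""

    labels: list[str]
    merge: np.ndarray  # scipy linkage matrix, shape (n-1, 4)
    distance: str
    linkage: str

    def clades(self) -> list[frozenset[str]]:
        """Member sets of the n-1 internal nodes, in merge order."""
        return _merge_clades(self.merge, self.labels)

    def to_newick(self, support: Mapping[frozenset[str], str] | None = None
                  ) -> str:
        """Newick string; optional per-clade comment strings (e.g. AU/BP)."""
        n = len(self.labels)
        names: dict[int, str] = {i: self.labels[i] for i in range(n)}
        members: dict[int, frozenset[str]] = {
            i: frozenset([self.labels[i]]) for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.merge):
            a, b = int(a), int(b)
            node = n + k
            members[node] = members[a] | members[b]
            comment = ""
            if support and members[node] in support:
                comment = f"[&{support[members[node]]}]"
            names[node] = f"({names[a]},{names[b]}){comment}:{h:.6g}"
        root = n + len(self.merge) - 1
        # strip the root's branch length
        s = names[root]
        return s[: s.rfind(":")] + ";"


def _merge_clades(merge: np.ndarray, labels: Sequence[str]
                  ) -> list[frozenset[str]]:
    n = len(labels)
    members: list[frozenset[str]] = [frozenset([x]) for x in labels]
    out: list[frozenset[str]] = []
    for a, b, _, _ in merge:
        clade = members[int(a)] | members[int(b)]
        members.append(clade)
        out.append(clade)
    return out


def _column_distance(x: np.ndarray, distance: str, species: Sequence[str],
                     strict: bool = True) -> np.ndarray:
    """Condensed distance between columns of x."""
    if distance == "euclidean":
        return pdist(x.T, metric="euclidean")
    # correlation distance 1 - r, with a guard for constant columns
    xt = x.T.astype(np.float64)
    sd = xt.std(axis=1)
    # relative tolerance: a numerically constant column is degenerate too
    degenerate = sd <= 1e-12 * np.maximum(np.abs(xt).max(axis=1), 1.0)
    if degenerate.any():
        if strict:
            bad = [species[j] for j in np.flatnonzero(degenerate)]
            raise UsageError("constant column(s) under correlation distance: "
                             f"{bad}")
        # bootstrap replicates: treat a constant column as uncorrelated
        xt = xt.copy()
        sd = sd.copy()
        sd[degenerate] = 1.0
    centered = xt - xt.mean(axis=1, keepdims=True)
    denom = sd * np.sqrt(xt.shape[1])
    z = centered / denom[:, None]
    corr = np.clip(z @ z.T, -1.0, 1.0)
    if degenerate.any():
        corr[degenerate, :] = 0.0
        corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    return squareform(1.0 - corr, checks=False)


def hierarchical_cluster(fm: FrequencyMatrix, distance: str = "correlation",
                         linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of species columns (defaults: 1-correlation,
    average linkage, matching pvclust defaults)."""
    if distance not in DISTANCES:
        raise UsageError(f"unknown distance {distance!r}")
    if linkage not in LINKAGES:
        raise UsageError(f"unknown linkage {linkage!r}")
    if len(fm.species) < 2:
        raise UsageError("need at least 2 species columns")
    d = _column_distance(fm.normfreq, distance, fm.species, strict=True)
    merge = scipy_linkage(d, method=linkage)
    return Dendrogram(labels=list(fm.species), merge=merge,
                      distance=distance, linkage=linkage)


# ---------------------------------------------------------------------------
# multiscale bootstrap
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class EdgeSupport:
    members: frozenset[str]
    bp: float   # bootstrap probability at r = 1
    au: float   # approximately unbiased p-value
    bp_per_scale: tuple[float, ...]
    v: float    # fitted signed distance
    c: float    # fitted curvature


@dataclass
class BootstrapDendrogram:
    tree: Dendrogram
    edges: list[EdgeSupport]
    scales: tuple[float, ...]
    n_boot: int
    seed: int
    _by_members: dict[frozenset[str], EdgeSupport] = field(
        init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self._by_members = {e.members: e for e in self.edges}

    def edge(self, members: frozenset[str] | set[str] | Sequence[str]
             ) -> EdgeSupport:
        return self._by_members[frozenset(members)]

    def to_newick(self) -> str:
        support = {e.members: f"AU={100 * e.au:.0f},BP={100 * e.bp:.0f}"
                   for e in self.edges}
        return self.tree.to_newick(support)


def _probit_fit(bp: np.ndarray, scales: np.ndarray, n_boot: int
                ) -> tuple[float, float, float]:
    """Fit Phi^-1(1-BP_r) = v sqrt(r) + c / sqrt(r); return (au, v, c).

    BP identically 1 (or 0) across every scale short-circuits to AU = 1
    (or 0): the probit fit cannot represent the constant profile of an
    always-present (never-present) edge, so the limit value is reported
    directly, as pvclust does. Otherwise degenerate per-scale values are
    clamped to [1/(B+1), B/(B+1)] before the probit transform.
    """
    if np.all(bp >= 1.0):
        return 1.0, 0.0, 0.0
    if np.all(bp <= 0.0):
        return 0.0, 0.0, 0.0
    lo, hi = 1.0 / (n_boot + 1), n_boot / (n_boot + 1)
    if np.any((bp <= 0.0) | (bp >= 1.0)):
        logger.debug("clamping degenerate per-scale BP values before probit")
    bpc = np.clip(bp, lo, hi)
    x = norm.ppf(1.0 - bpc)
    # inverse variance of the probit-transformed binomial proportion
    w = n_boot * norm.pdf(x) ** 2 / (bpc * (1.0 - bpc))
    a = np.column_stack([np.sqrt(scales), 1.0 / np.sqrt(scales)])
    aw = a * w[:, None]
    beta, *_ = np.linalg.lstsq(aw.T @ a, aw.T @ x, rcond=None)
    v, c = float(beta[0]), float(beta[1])
    au = float(np.clip(1.0 - norm.cdf(v - c), 0.0, 1.0))
    return au, v, c


def multiscale_bootstrap(fm: FrequencyMatrix,
                         scales: Sequence[float] = DEFAULT_SCALES,
                         n_boot: int = 1000, seed: int = 0,
                         distance: str = "correlation",
                         linkage: str = "average") -> BootstrapDendrogram:
    """pvclust-style multiscale bootstrap over n-gram rows.

    For each relative sample size r the round(r*G) rows are resampled with
    replacement ``n_boot`` times and the species tree rebuilt; each full-data
    edge's presence frequency per scale feeds the probit fit for AU, and BP
    is reported at the scale closest to r = 1. Edges never observed get
    BP = AU = 0.
    """
    scales = np.asarray(sorted(scales), dtype=np.float64)
    if np.any(scales <= 0):
        raise UsageError("scales must be positive")
    if n_boot < 100:
        raise UsageError("n_boot must be at least 100")
    full = hierarchical_cluster(fm, distance=distance, linkage=linkage)
    target_edges = full.clades()
    labels = full.labels
    x = fm.normfreq
    g = x.shape[0]
    rng = np.random.default_rng(seed)

    counts = {clade: np.zeros(len(scales)) for clade in target_edges}
    for si, r in enumerate(scales):
        m = max(1, int(round(r * g)))
        for _ in range(n_boot):
            idx = rng.integers(0, g, size=m)
            sub = x[idx]
            d = _column_distance(sub, distance, labels, strict=False)
            merge = scipy_linkage(d, method=linkage)
            for clade in _merge_clades(merge, labels):
                hit = counts.get(clade)
                if hit is not None:
                    hit[si] += 1.0

    r1 = int(np.argmin(np.abs(scales - 1.0)))
    edges: list[EdgeSupport] = []
    for clade in target_edges:
        bp_r = counts[clade] / n_boot
        if not bp_r.any():
            edges.append(EdgeSupport(members=clade, bp=0.0, au=0.0,
                                     bp_per_scale=tuple(bp_r), v=0.0, c=0.0))
            continue
        au, v, c = _probit_fit(bp_r, scales, n_boot)
        edges.append(EdgeSupport(members=clade, bp=float(bp_r[r1]), au=au,
                                 bp_per_scale=tuple(bp_r), v=v, c=c))
    return BootstrapDendrogram(tree=full, edges=edges,
                               scales=tuple(float(s) for s in scales),
                               n_boot=n_boot, seed=seed)
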