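"""Enriched counts, dampened normalized frequencies, discriminative scores,
and signature assembly.

For each training species the replicate datasets' n-gram counts are summed
("enriched counts"). Relative frequencies are computed per species over the
union vocabulary, then multiplied by an IDF-style dampening weight

    w(g) = log2(N / s(g)) + 1

where N is the number of training species and s(g) the number of species in
which n-gram g occurs: n-grams present in fewer species get more weight,
ubiquitous ones weight 1. Per n-gram the species are ranked by dampened
normalized frequency f1 >= f2 >= f3 >= ... and a discriminative score is
computed either as a ratio f1 / ((f2 + f3) / 2) (flagged infinite when the
denominator is zero, i.e. species-exclusive n-grams) or as a difference
f1 - (f2 + f3) / 2. N-grams scoring above a threshold T are discriminative
for their top species; the signature keeps those also observed in the paired
same-kingdom test species, with weights frozen at their training values.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .errors import UsageError, ValidationError, ConfigError
from .model import Signature, SignatureEntry, SignatureParams, StudyDesign
from .ngrams import ENRICHED, NGramCountTable

logger = logging.getLogger(__name__)

RATIO = "ratio"
DIFFERENCE = "difference"


def enriched_counts(tables: Sequence[NGramCountTable]) -> NGramCountTable:
    """Sum one species' per-dataset counts into its enriched table."""
    if not tables:
        raise UsageError("no tables given")
    species = {t.species for t in tables}
    if len(species) != 1:
        raise UsageError(f"tables span multiple species: {sorted(species)}")
    nspans = {(t.n_min, t.n_max) for t in tables}
    if len(nspans) != 1:
        raise UsageError("tables disagree on (n_min, n_max)")
    out = NGramCountTable(species=species.pop(), dataset_id=ENRICHED,
                          n_min=tables[0].n_min, n_max=tables[0].n_max)
    for t in tables:
        out.counts.update(t.counts)
        for g, ws in t.source_windows.items():
            out.source_windows.setdefault(g, []).extend(ws)
    return out


def dampening_weight(s_g: int, n_species: int) -> float:
    """IDF-style weight log2(N/s)+1; strictly decreasing in s, 1 at s=N."""
    if s_g == 0:
        raise ValueError("n-gram absent from every species cannot be weighted")
    if not 1 <= s_g <= n_species:
        raise ValueError(f"require 1 <= s_g <= N, got s_g={s_g}, N={n_species}")
    return math.log2(n_species / s_g) + 1.0


@dataclass
class FrequencyMatrix:
    """N-gram x species matrix of dampened normalized frequencies.

    ``raw`` holds enriched counts; ``relfreq`` the per-species (column)
    relative frequencies over the vocabulary; ``normfreq = relfreq * w(g)``.
    """

    ngrams: list[str]
    species: list[str]
    raw: np.ndarray          # (G, S) int64
    relfreq: np.ndarray      # (G, S) float64, columns sum to 1 where nonzero
    weights: np.ndarray      # (G,) dampening weights
    normfreq: np.ndarray     # (G, S)
    n_species_present: np.ndarray  # (G,) s(g)
    n_min: int
    n_max: int
    _index: dict[str, int] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.ngrams)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.raw.shape

    def row(self, ngram: str) -> int:
        return self._index[ngram]

    def column(self, species: str) -> np.ndarray:
        return self.normfreq[:, self.species.index(species)]


def build_frequency_matrix(
    per_species_enriched: Mapping[str, NGramCountTable]
) -> FrequencyMatrix:
    """Column-normalize enriched counts over the union vocabulary and dampen.

    Species order follows the mapping's insertion order (it is the
    deterministic tie-break for top-species assignment downstream); the
    vocabulary is sorted lexicographically.
    """
    species = list(per_species_enriched)
    if len(species) < 2:
        raise UsageError("need at least 2 species")
    nspans = {(t.n_min, t.n_max) for t in per_species_enriched.values()}
    if len(nspans) != 1:
        raise UsageError("species tables disagree on (n_min, n_max)")
    n_min, n_max = nspans.pop()

    vocab: set[str] = set()
    for t in per_species_enriched.values():
        vocab.update(t.counts)
    if not vocab:
        raise UsageError("union n-gram vocabulary is empty")
    ngrams = sorted(vocab)
    index = {g: i for i, g in enumerate(ngrams)}

    raw = np.zeros((len(ngrams), len(species)), dtype=np.int64)
    for j, sp in enumerate(species):
        col = raw[:, j]
        for g, c in per_species_enriched[sp].counts.items():
            col[index[g]] = c

    totals = raw.sum(axis=0)
    for j, sp in enumerate(species):
        if totals[j] == 0:
            raise UsageError(f"species {sp!r} has zero total n-gram count")
    relfreq = raw / totals.astype(np.float64)

    s_g = (raw > 0).sum(axis=1)
    weights = np.log2(len(species) / s_g) + 1.0
    normfreq = relfreq * weights[:, None]
    return FrequencyMatrix(ngrams=ngrams, species=species, raw=raw,
                           relfreq=relfreq, weights=weights, normfreq=normfreq,
                           n_species_present=s_g, n_min=n_min, n_max=n_max)


@dataclass(frozen=True, slots=True)
class DiscriminativeScore:
    ngram: str
    top_species: str
    f1: float
    f2: float
    f3: float
    score: float  # math.inf flags a zero ratio denominator
    mode: str
    tied: bool  # top rank shared; broken by species order


class ScoreTable(Sequence):
    """Vectorized discriminative scores; behaves as a sequence of
    :class:`DiscriminativeScore` records."""

    def __init__(self, ngrams: list[str], species: list[str], mode: str,
                 top_index: np.ndarray, f1: np.ndarray, f2: np.ndarray,
                 f3: np.ndarray, score: np.ndarray, tied: np.ndarray):
        self.ngrams = ngrams
        self.species = species
        self.mode = mode
        self.top_index = top_index
        self.f1, self.f2, self.f3 = f1, f2, f3
        self.score = score
        self.tied = tied
        self._index = {g: i for i, g in enumerate(ngrams)}

    def __len__(self) -> int:
        return len(self.ngrams)

    def __getitem__(self, i):
        if isinstance(i, str):
            i = self._index[i]
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(len(self)))]
        return DiscriminativeScore(
            ngram=self.ngrams[i], top_species=self.species[self.top_index[i]],
            f1=float(self.f1[i]), f2=float(self.f2[i]), f3=float(self.f3[i]),
            score=float(self.score[i]), mode=self.mode, tied=bool(self.tied[i]),
        )

    def score_of(self, ngram: str) -> float:
        return float(self.score[self._index[ngram]])


def discriminative_scores(fm: FrequencyMatrix, mode: str = RATIO) -> ScoreTable:
    """Score every n-gram's top species against the mean of ranks 2 and 3.

    Ties for the top are broken by species order in ``fm`` and flagged.
    """
    if mode not in (RATIO, DIFFERENCE):
        raise UsageError(f"unknown score mode {mode!r}")
    if len(fm.species) < 3:
        raise UsageError("discriminative scoring needs at least 3 species")
    nf = fm.normfreq
    ranked = -np.sort(-nf, axis=1)  # descending
    f1, f2, f3 = ranked[:, 0], ranked[:, 1], ranked[:, 2]
    top_index = nf.argmax(axis=1)  # first index on ties == species order
    tied = (nf == f1[:, None]).sum(axis=1) > 1
    denom = (f2 + f3) / 2.0
    if mode == DIFFERENCE:
        score = f1 - denom
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(denom > 0, f1 / np.where(denom > 0, denom, 1.0),
                             np.inf)
    return ScoreTable(ngrams=list(fm.ngrams), species=list(fm.species),
                      mode=mode, top_index=top_index, f1=f1, f2=f2, f3=f3,
                      score=score, tied=tied)


def select_discriminative(scores: ScoreTable, threshold: float
                          ) -> dict[str, set[str]]:
    """Group n-grams with score strictly above ``threshold`` by top species.

    Infinite (flagged) ratio scores are always kept. Every species present in
    the score table gets a key, possibly with an empty set.
    """
    if not threshold > 0:
        raise UsageError("threshold must be positive")
    keep = scores.score > threshold  # inf > T is True
    out: dict[str, set[str]] = {sp: set() for sp in scores.species}
    for i in np.flatnonzero(keep):
        out[scores.species[scores.top_index[i]]].add(scores.ngrams[i])
    return out


def build_signature(train_discr: Mapping[str, set[str]],
                    test_tables: Mapping[str, NGramCountTable],
                    design: StudyDesign, fm: FrequencyMatrix,
                    scores: ScoreTable, threshold: float) -> Signature:
    """Keep each training species' discriminative n-grams that also occur in
    its paired test species; freeze training weights into the entries."""
    test_of = design.test_of
    entries: list[SignatureEntry] = []
    for train_sp in design.train_species:
        if train_sp not in test_of:
            raise ConfigError(f"training species {train_sp!r} has no paired "
                              "test species")
        test_sp = test_of[train_sp]
        if test_sp not in test_tables:
            raise ConfigError(f"no count table for test species {test_sp!r}")
        test_counts = test_tables[test_sp].counts
        kingdom = design.kingdom_of[train_sp]
        for g in sorted(train_discr.get(train_sp, ())):
            if test_counts.get(g, 0) > 0:
                entries.append(SignatureEntry(
                    ngram=g, top_species=train_sp, kingdom=kingdom,
                    score=scores.score_of(g),
                    weight=float(fm.weights[fm.row(g)]),
                ))
    params = SignatureParams(n_min=fm.n_min, n_max=fm.n_max,
                             threshold=threshold, score_mode=scores.mode)
    return Signature(entries=entries, parameters=params)


def project_frequencies(sig: Signature,
                        species_tables: Mapping[str, NGramCountTable]
                        ) -> FrequencyMatrix:
    """Normalized frequencies over the signature vocabulary with FROZEN weights.

    Relative frequencies are renormalized per species over the signature
    n-grams only; the dampening weights are the signature's training-time
    weights, never recomputed from the projected species' presence pattern.
    A species containing none of the signature n-grams gets an all-zero
    column (with a warning), not an error.
    """
    if not sig.entries:
        raise UsageError("cannot project an empty signature")
    ngrams = sig.ngrams
    index = {g: i for i, g in enumerate(ngrams)}
    species = list(species_tables)
    raw = np.zeros((len(ngrams), len(species)), dtype=np.int64)
    for j, sp in enumerate(species):
        counts = species_tables[sp].counts
        col = raw[:, j]
        for g, i in index.items():
            c = counts.get(g, 0)
            if c:
                col[i] = c
    totals = raw.sum(axis=0).astype(np.float64)
    for j, sp in enumerate(species):
        if totals[j] == 0:
            logger.warning("species %r contains no signature n-gram; "
                           "projected column is all zeros", sp)
            totals[j] = 1.0  # keeps the column at exact zeros
    relfreq = raw / totals
    weights = np.array([e.weight for e in sig.entries])
    normfreq = relfreq * weights[:, None]
    s_g = (raw > 0).sum(axis=1)
    return FrequencyMatrix(ngrams=list(ngrams), species=species, raw=raw,
                           relfreq=relfreq, weights=weights, normfreq=normfreq,
                           n_species_present=s_g, n_min=sig.parameters.n_min,
                           n_max=sig.parameters.n_max)
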