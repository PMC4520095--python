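"""N-gram enumeration and counting over phosphopeptide windows.

An n-gram is any contiguous substring of a window; by default all lengths
6..21 are enumerated with multiplicity, so a full 21-mer yields
sum(22 - L for L in 6..21) = 136 instances. Substrings containing the
unknown-residue character 'X' are dropped so the n-gram alphabet stays
exactly the 20 amino acids. N-grams are not required to cover the central
phosphoserine.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

from .errors import UsageError
from .model import PhosphopeptideWindow

DEFAULT_N_MIN = 6
DEFAULT_N_MAX = 21

#: Scope marker for tables aggregated over a species' replicate datasets.
ENRICHED = "enriched"


def enumerate_ngrams(window: str, n_min: int = DEFAULT_N_MIN,
                     n_max: int = DEFAULT_N_MAX) -> list[str]:
    """Every contiguous substring of ``window`` with length in [n_min, n_max].

    Returns instances with multiplicity, ordered by length then start
    position. Substrings containing 'X' are omitted. An empty window (or one
    shorter than ``n_min``) yields an empty list.
    """
    if n_min < 1 or n_min > n_max:
        raise UsageError(f"require 1 <= n_min <= n_max, got ({n_min}, {n_max})")
    length = len(window)
    out: list[str] = []
    has_x = "X" in window
    for n in range(n_min, min(n_max, length) + 1):
        for i in range(length - n + 1):
            sub = window[i:i + n]
            if has_x and "X" in sub:
                continue
            out.append(sub)
    return out


@dataclass
class NGramCountTable:
    """N-gram counts for one (species, dataset) scope, or a species' enriched sum.

    ``source_windows`` maps each distinct n-gram to the windows containing it
    (each window listed once regardless of within-window multiplicity); it
    supports mapping discriminative n-grams back to their phosphopeptides for
    logos and physico-chemical profiles.
    """

    species: str
    dataset_id: str  # a dataset label, or ENRICHED for aggregated tables
    counts: Counter[str] = field(default_factory=Counter)
    n_min: int = DEFAULT_N_MIN
    n_max: int = DEFAULT_N_MAX
    source_windows: dict[str, list[PhosphopeptideWindow]] = field(
        default_factory=dict, repr=False
    )

    @property
    def scope(self) -> tuple[str, str]:
        return (self.species, self.dataset_id)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def windows_of(self, ngram: str) -> list[PhosphopeptideWindow]:
        if ngram not in self.counts:
            raise KeyError(f"n-gram {ngram!r} not in table {self.scope}")
        return self.source_windows.get(ngram, [])


def count_dataset(windows: Sequence[PhosphopeptideWindow],
                  n_min: int = DEFAULT_N_MIN, n_max: int = DEFAULT_N_MAX,
                  track_sources: bool = True) -> NGramCountTable:
    """Count n-grams, summing multiplicities, over one dataset's windows.

    All windows must share a single (species, dataset) scope; an empty window
    list yields an empty table with scope ("", "").
    """
    scopes = {(w.species, w.dataset_id) for w in windows}
    if len(scopes) > 1:
        raise UsageError(f"windows span multiple scopes: {sorted(scopes)}")
    species, dataset_id = scopes.pop() if scopes else ("", "")
    table = NGramCountTable(species=species, dataset_id=dataset_id,
                            n_min=n_min, n_max=n_max)
    counts = table.counts
    sources = table.source_windows
    for w in windows:
        instances = enumerate_ngrams(w.window, n_min, n_max)
        counts.update(instances)
        if track_sources:
            for g in set(instances):
                sources.setdefault(g, []).append(w)
    return table


def merge_counts(tables: Iterable[NGramCountTable]) -> NGramCountTable:
    """Element-wise sum of count tables regardless of species (utility)."""
    tables = list(tables)
    if not tables:
        raise UsageError("no tables to merge")
    out = NGramCountTable(species=tables[0].species, dataset_id=ENRICHED,
                          n_min=tables[0].n_min, n_max=tables[0].n_max)
    for t in tables:
        if (t.n_min, t.n_max) != (out.n_min, out.n_max):
            raise UsageError("tables disagree on (n_min, n_max)")
        out.counts.update(t.counts)
        for g, ws in t.source_windows.items():
            out.source_windows.setdefault(g, []).extend(ws)
    return out
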