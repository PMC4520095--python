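"""Top discriminative n-gram selection and sequence-logo matrices.

For a species, the signature entries with the greatest discriminative ratio
are selected (species-exclusive n-grams carry an infinite flagged ratio and
are always kept); the serine-centered phosphopeptides containing those
n-grams are stacked into a position frequency matrix, and per-position
information content is computed in bits against the uniform 20-residue
background with the standard small-sample correction:

    ic_p = log2(20) - (H_p + 19 / (2 ln 2 n_p))     (clamped to [0, log2 20])

where H_p is the Shannon entropy of the column over its n_p unmasked
sequences. Output is numeric matrices; graphical rendering is left to
external logo tools.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UsageError
from .model import AMINO_ACIDS, DEFAULT_WIDTH, PhosphopeptideWindow, Signature
from .physchem import CENTER

LOG2_20 = math.log2(20)


def select_top_ngrams(sig: Signature, species: str, cutoff: float
                      ) -> set[str]:
    """Signature n-grams of ``species`` with ratio score >= cutoff.

    Infinite flagged scores are always included. Requires ratio-mode scores.
    """
    if sig.parameters.score_mode != "ratio":
        raise UsageError("top n-gram selection needs ratio-mode scores")
    if not cutoff > 0:
        raise UsageError("cutoff must be positive")
    entries = sig.entries_for(species)
    if not entries:
        raise KeyError(f"no signature entries for species {species!r}")
    return {e.ngram for e in entries
            if math.isinf(e.score) or e.score >= cutoff}


def ratio_percentile_cutoff(sig: Signature, species: str,
                            q: float = 95.0) -> float:
    """Default per-species cutoff: the q-th percentile of its ratio scores
    (infinite if more than (100-q)% of the scores are flagged infinite)."""
    entries = sig.entries_for(species)
    if not entries:
        raise KeyError(f"no signature entries for species {species!r}")
    # order statistic, not interpolation: infinite flagged scores are common
    # and interpolating between a finite score and infinity is undefined
    return float(np.percentile([e.score for e in entries], q,
                               method="lower"))


@dataclass
class LogoMatrix:
    """Position frequency matrix plus per-position information content."""

    pfm: np.ndarray          # (21, 20), unmasked rows sum to 1
    ic: np.ndarray           # (21,) bits in [0, log2 20]
    support: np.ndarray      # (21,) unmasked sequence count n_p
    n_sequences: int
    species: str | None = None
    cutoff: float | None = None

    @property
    def alphabet(self) -> str:
        return AMINO_ACIDS

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.pfm, columns=list(AMINO_ACIDS))
        df.insert(0, "position", np.arange(1, DEFAULT_WIDTH + 1))
        df["n"] = self.support.astype(int)
        df["ic"] = self.ic
        return df


def build_logo(windows: Sequence[PhosphopeptideWindow],
               small_sample_correction: bool = True,
               species: str | None = None,
               cutoff: float | None = None) -> LogoMatrix:
    """Stack windows aligned on the central serine into a PFM + IC vector.

    Truncated windows contribute only to the positions they define; 'X'
    residues are masked. Positions with no unmasked sequence get a zero PFM
    row and ic = 0.
    """
    if not windows:
        raise UsageError("cannot build a logo from zero windows")
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    counts = np.zeros((DEFAULT_WIDTH, len(AMINO_ACIDS)))
    for w in windows:
        start = CENTER - w.offset_of_site
        for j, res in enumerate(w.window):
            if res == "X":
                continue
            counts[start + j, aa_index[res]] += 1
    support = counts.sum(axis=1)
    pfm = np.divide(counts, support[:, None],
                    out=np.zeros_like(counts), where=support[:, None] > 0)
    ic = np.zeros(DEFAULT_WIDTH)
    for p in range(DEFAULT_WIDTH):
        n_p = support[p]
        if n_p == 0:
            continue
        f = pfm[p][pfm[p] > 0]
        entropy = float(-(f * np.log2(f)).sum())
        correction = 19.0 / (2.0 * math.log(2) * n_p) if small_sample_correction else 0.0
        ic[p] = min(max(LOG2_20 - (entropy + correction), 0.0), LOG2_20)
    return LogoMatrix(pfm=pfm, ic=ic, support=support,
                      n_sequences=len(windows), species=species, cutoff=cutoff)
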