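"""Shared data model: phosphopeptide windows, study designs, and signatures.

A *phosphopeptide window* is a short peptide centered on a measured
phospho-serine, extracted from its source protein with a fixed nominal
width (21 by default, the phosphosite at the 11th position) and truncated
— never padded — at protein termini. A *study design* fixes the training
species (two replicate datasets each), the test species, and the
test-to-train pairing within each kingdom/phylum. A *signature* is the set
of training-species discriminative n-grams that were also observed in the
paired same-kingdom test species, together with their scores and frozen
dampening weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError, ValidationError

#: The 20 standard amino acids, in the conventional alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)
#: Windows may carry 'X' for unknown residues; n-grams never do.
WINDOW_ALPHABET = AA_SET | {"X"}

#: Nominal window width used throughout (phosphosite at 0-based offset 10).
DEFAULT_WIDTH = 21


@dataclass(frozen=True, slots=True)
class PhosphopeptideWindow:
    """One serine-centered sequence window with its provenance.

    ``site_pos`` is the 1-based residue index of the phosphosite in the
    source protein; ``offset_of_site`` is the 0-based index of that residue
    within ``window``.
    """

    species: str
    dataset_id: str
    protein_id: str
    site_pos: int
    window: str
    offset_of_site: int

    def __post_init__(self) -> None:
        if not self.window:
            raise ValidationError("empty window")
        if len(self.window) > DEFAULT_WIDTH:
            raise ValidationError(
                f"window longer than {DEFAULT_WIDTH}: {self.window!r}"
            )
        bad = set(self.window) - WINDOW_ALPHABET
        if bad:
            raise ValidationError(
                f"window {self.window!r} contains non-amino-acid characters {sorted(bad)}"
            )
        if not 0 <= self.offset_of_site < len(self.window):
            raise ValidationError(
                f"offset_of_site {self.offset_of_site} outside window of length "
                f"{len(self.window)}"
            )

    @property
    def central_residue(self) -> str:
        return self.window[self.offset_of_site]

    def check_central(self, allowed: str = "S") -> None:
        """Raise unless the phospho-residue is one of ``allowed`` (strict mode: 'S')."""
        if self.central_residue not in allowed:
            raise ValidationError(
                f"central residue {self.central_residue!r} of window "
                f"{self.window!r} not in {allowed!r}"
            )

    @property
    def window_id(self) -> str:
        return f"{self.species}:{self.dataset_id}:{self.protein_id}:{self.site_pos}"


@dataclass(frozen=True)
class StudyDesign:
    """Training/test species layout with kingdom/phylum pairing.

    ``pairing`` maps each test species to its same-kingdom training species
    and must be a bijection between the two lists.
    """

    train_species: tuple[str, ...]
    test_species: tuple[str, ...]
    pairing: dict[str, str]
    kingdom_of: dict[str, str]
    datasets_of: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "train_species", tuple(self.train_species))
        object.__setattr__(self, "test_species", tuple(self.test_species))
        object.__setattr__(
            self, "datasets_of", {k: tuple(v) for k, v in self.datasets_of.items()}
        )
        if set(self.pairing) != set(self.test_species):
            raise ConfigError("pairing keys must be exactly the test species")
        if sorted(self.pairing.values()) != sorted(self.train_species):
            raise ConfigError(
                "pairing must be a bijection onto the training species"
            )
        for sp in (*self.train_species, *self.test_species):
            if sp not in self.kingdom_of:
                raise ConfigError(f"species {sp!r} missing from kingdom_of")
            if self.kingdom_of[self.pairing.get(sp, sp)] != self.kingdom_of[sp]:
                raise ConfigError(
                    f"paired species {sp!r} and {self.pairing[sp]!r} are in "
                    "different kingdoms"
                )

    @property
    def train_of(self) -> dict[str, str]:
        """Alias of ``pairing``: test species -> training species."""
        return dict(self.pairing)

    @property
    def test_of(self) -> dict[str, str]:
        """Inverse pairing: training species -> its paired test species."""
        return {v: k for k, v in self.pairing.items()}

    @property
    def all_species(self) -> tuple[str, ...]:
        return self.train_species + self.test_species


@dataclass(frozen=True, slots=True)
class SignatureEntry:
    ngram: str
    top_species: str
    kingdom: str
    score: float  # may be math.inf for ratio-mode species-exclusive n-grams
    weight: float  # frozen dampening weight from training


@dataclass(frozen=True, slots=True)
class SignatureParams:
    n_min: int
    n_max: int
    threshold: float
    score_mode: str  # "ratio" or "difference"


@dataclass
class Signature:
    """Kingdom/phylum-specific discriminative n-grams with frozen weights."""

    entries: list[SignatureEntry]
    parameters: SignatureParams
    _by_ngram: dict[str, SignatureEntry] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        seen: dict[str, SignatureEntry] = {}
        for e in self.entries:
            if e.ngram in seen:
                raise ValidationError(f"duplicate signature n-gram {e.ngram!r}")
            if not e.weight > 0:
                raise ValidationError(f"non-positive weight for {e.ngram!r}")
            if e.score < 0:
                raise ValidationError(f"negative score for {e.ngram!r}")
            seen[e.ngram] = e
        self._by_ngram = seen

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, ngram: str) -> bool:
        return ngram in self._by_ngram

    def __getitem__(self, ngram: str) -> SignatureEntry:
        return self._by_ngram[ngram]

    @property
    def ngrams(self) -> list[str]:
        return [e.ngram for e in self.entries]

    def entries_for(self, species: str) -> list[SignatureEntry]:
        return [e for e in self.entries if e.top_species == species]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Signature):
            return NotImplemented
        return self.entries == other.entries and self.parameters == other.parameters
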