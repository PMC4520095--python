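"""Seeded synthetic multi-species phosphopeptide studies with planted
kingdom-specific motifs.

The generator emulates the comparative study design: five training species
from five kingdom/phylum groups with two replicate datasets each, five
paired test species with one dataset each, hundreds of 21-mer
serine-centered windows per dataset. Windows are drawn i.i.d. from a
background residue distribution (uniform by default) with 'S' forced at the
central position; with a configured probability one of the kingdom's motif
patterns is stamped at its anchor, wildcard positions ('x') left as
background. Default motifs follow the qualitative kingdom patterns of real
phosphoproteomes: basic/arginine flanks in animals (distinct Chordata and
Arthropoda variants), C-terminal acidic runs in plants, C-terminal prolines
in fungi, and an asparagine-rich block for the apicomplexan group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError
from .model import AMINO_ACIDS, DEFAULT_WIDTH, PhosphopeptideWindow, StudyDesign
from .physchem import CENTER


@dataclass(frozen=True, slots=True)
class Motif:
    """A planted pattern anchored on the central phosphoserine.

    ``pattern`` is a residue string with 'x' wildcards; ``anchor`` is the
    index within the pattern aligned to the window center (defaults to the
    pattern's first 'S'). ``insertion_prob`` is the per-window stamping
    probability of this motif.
    """

    pattern: str
    insertion_prob: float
    anchor: int = -1

    def __post_init__(self) -> None:
        anchor = self.anchor
        if anchor < 0:
            anchor = self.pattern.find("S")
            if anchor < 0:
                raise ConfigError(f"pattern {self.pattern!r} has no 'S' and "
                                  "no explicit anchor")
            object.__setattr__(self, "anchor", anchor)
        if not 0.0 <= self.insertion_prob <= 1.0:
            raise ConfigError("insertion_prob must be in [0, 1]")
        bad = set(self.pattern) - set(AMINO_ACIDS) - {"x"}
        if bad:
            raise ConfigError(f"pattern {self.pattern!r} has invalid "
                              f"characters {sorted(bad)}")
        start = CENTER - self.anchor
        if start < 0 or start + len(self.pattern) > DEFAULT_WIDTH:
            raise ConfigError(f"pattern {self.pattern!r} (anchor "
                              f"{self.anchor}) overruns the "
                              f"{DEFAULT_WIDTH}-mer window")

    def fixed_ngrams(self, n_min: int = 6) -> set[str]:
        """Contiguous wildcard-free substrings of length >= n_min: the
        n-grams this motif plants verbatim in every stamped window."""
        out: set[str] = set()
        for block in self.pattern.split("x"):
            for n in range(n_min, len(block) + 1):
                for i in range(len(block) - n + 1):
                    out.add(block[i:i + n])
        return out


#: Default kingdom/phylum motif sets (insertion probability 0.3 each).
DEFAULT_MOTIFS: dict[str, tuple[Motif, ...]] = {
    "Plantae": (Motif("SDDEDEEDE", 0.3),),
    "Chordata": (Motif("RKRRSRRKR", 0.3),),
    "Arthropoda": (Motif("KKRKSKRKK", 0.3),),
    "Ascomycota": (Motif("SPPPPPPPP", 0.3),),
    "Apicomplexa": (Motif("NNNNSNNNN", 0.3),),
}

_TRAIN = ("Ath", "Hsa", "Dme", "Sce", "Pfa")
_TEST = ("Osa", "Mmu", "Cel", "Spo", "Tgo")
_KINGDOMS = ("Plantae", "Chordata", "Arthropoda", "Ascomycota", "Apicomplexa")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of a synthetic study; defaults mirror the real design."""

    seed: int = 1
    n_train_species: int = 5
    datasets_per_train: int = 2
    n_test_species: int = 5
    windows_per_dataset: int = 500
    background: tuple[float, ...] = field(
        default_factory=lambda: (1.0 / 20,) * 20)
    motifs: dict[str, tuple[Motif, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MOTIFS))
    train_species: tuple[str, ...] = _TRAIN
    test_species: tuple[str, ...] = _TEST
    kingdoms: tuple[str, ...] = _KINGDOMS

    def __post_init__(self) -> None:
        if len(self.background) != 20 or abs(sum(self.background) - 1) > 1e-9:
            raise ConfigError("background must be 20 probabilities summing to 1")
        if not (len(self.train_species) == len(self.test_species)
                == len(self.kingdoms) == self.n_train_species
                == self.n_test_species):
            raise ConfigError("species/kingdom lists must all have length "
                              f"{self.n_train_species}")
        for kingdom, motifs in self.motifs.items():
            if sum(m.insertion_prob for m in motifs) > 1.0 + 1e-12:
                raise ConfigError(f"kingdom {kingdom!r} motif insertion "
                                  "probabilities exceed 1")

    def design(self) -> StudyDesign:
        kingdom_of = dict(zip(self.train_species, self.kingdoms))
        kingdom_of.update(zip(self.test_species, self.kingdoms))
        datasets_of = {sp: tuple(f"d{i + 1}" for i in
                                 range(self.datasets_per_train))
                       for sp in self.train_species}
        datasets_of.update({sp: ("d1",) for sp in self.test_species})
        return StudyDesign(
            train_species=self.train_species, test_species=self.test_species,
            pairing=dict(zip(self.test_species, self.train_species)),
            kingdom_of=kingdom_of, datasets_of=datasets_of)


def generate_window(cfg: SimulationConfig, kingdom: str,
                    rng: np.random.Generator, species: str = "sim",
                    dataset_id: str = "d1", index: int = 0
                    ) -> PhosphopeptideWindow:
    """One 21-mer background window with central 'S', maybe one stamped motif."""
    if kingdom not in cfg.motifs:
        raise ConfigError(f"kingdom {kingdom!r} has no motif list")
    residues = list(rng.choice(list(AMINO_ACIDS), size=DEFAULT_WIDTH,
                               p=cfg.background))
    residues[CENTER] = "S"
    u = rng.random()
    acc = 0.0
    for motif in cfg.motifs[kingdom]:
        acc += motif.insertion_prob
        if u < acc:
            start = CENTER - motif.anchor
            for j, res in enumerate(motif.pattern):
                if res != "x":
                    residues[start + j] = res
            break
    return PhosphopeptideWindow(
        species=species, dataset_id=dataset_id,
        protein_id=f"{species}_{dataset_id}_p{index}", site_pos=CENTER + 1,
        window="".join(residues), offset_of_site=CENTER)


def generate_study(cfg: SimulationConfig) -> tuple[
        dict[tuple[str, str], list[PhosphopeptideWindow]],
        dict[str, list[PhosphopeptideWindow]],
        StudyDesign,
        dict[str, tuple[Motif, ...]]]:
    """Full synthetic study: training datasets, test datasets, design, truth.

    All randomness flows from one generator seeded with ``cfg.seed``; the
    returned ground truth maps each kingdom to its planted motifs.
    """
    design = cfg.design()
    kingdoms_missing = set(design.kingdom_of.values()) - set(cfg.motifs)
    if kingdoms_missing:
        raise ConfigError(f"kingdoms without motif lists: "
                          f"{sorted(kingdoms_missing)}")
    rng = np.random.default_rng(cfg.seed)
    train: dict[tuple[str, str], list[PhosphopeptideWindow]] = {}
    for sp in design.train_species:
        kingdom = design.kingdom_of[sp]
        for ds in design.datasets_of[sp]:
            train[(sp, ds)] = [
                generate_window(cfg, kingdom, rng, species=sp, dataset_id=ds,
                                index=i)
                for i in range(cfg.windows_per_dataset)]
    test: dict[str, list[PhosphopeptideWindow]] = {}
    for sp in design.test_species:
        kingdom = design.kingdom_of[sp]
        (ds,) = design.datasets_of[sp]
        test[sp] = [
            generate_window(cfg, kingdom, rng, species=sp, dataset_id=ds,
                            index=i)
            for i in range(cfg.windows_per_dataset)]
    truth = {k: tuple(v) for k, v in cfg.motifs.items()}
    return train, test, design, truth


def scaled_config(cfg: SimulationConfig, windows_per_dataset: int
                  ) -> SimulationConfig:
    """The same study conditions at a smaller per-dataset size (for quick
    desk-scale runs); motif content and design are unchanged."""
    return replace(cfg, windows_per_dataset=windows_per_dataset)
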