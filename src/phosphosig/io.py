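"""On-disk formats: window tables, FASTA + site tables, signatures,
frequency matrices, study designs, property tables.

All tabular artifacts are plain TSV with '#'-prefixed comment/parameter
lines; site positions are 1-based inclusive (UniProt convention) in files,
offsets are 0-based internally. Writers and readers round-trip exactly.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO

from .errors import (ConfigError, CoordinateError, FormatError, UsageError,
                     ValidationError)
from .frequencies import FrequencyMatrix
from .model import (DEFAULT_WIDTH, PhosphopeptideWindow, Signature,
                    SignatureEntry, SignatureParams, StudyDesign)
from .ngrams import NGramCountTable

WINDOW_COLUMNS = ("species", "dataset", "protein", "site", "window")
SIGNATURE_COLUMNS = ("ngram", "top_species", "kingdom", "score", "weight")


# ---------------------------------------------------------------------------
# window tables
# ---------------------------------------------------------------------------

def read_window_table(path: str | Path, expected_width: int = DEFAULT_WIDTH,
                      strict: bool = True, center_residues: str = "S"
                      ) -> list[PhosphopeptideWindow]:
    """Read a TSV of pre-extracted windows (species, dataset, protein, site,
    window), rejecting rows that violate the window invariants.

    The phosphosite offset is inferred from the site position and the
    nominal width: a window truncated at the protein N-terminus starts at
    residue 1, so its offset is min(site - 1, (width - 1) // 2).
    """
    if expected_width < 1 or expected_width % 2 == 0:
        raise UsageError("expected_width must be a positive odd integer")
    center = (expected_width - 1) // 2
    path = Path(path)
    windows: list[PhosphopeptideWindow] = []
    with path.open() as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = set(WINDOW_COLUMNS) - set(header)
                if missing:
                    raise FormatError(
                        f"{path}: missing column(s) {sorted(missing)}")
                continue
            row = dict(zip(header, fields))
            try:
                site = int(row["site"])
                if site < 1:
                    raise ValueError
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad site {row['site']!r}")
            seq = row["window"]
            if len(seq) > expected_width:
                raise ValidationError(
                    f"{path}:{lineno}: window longer than {expected_width}")
            offset = min(site - 1, center)
            try:
                w = PhosphopeptideWindow(
                    species=row["species"], dataset_id=row["dataset"],
                    protein_id=row["protein"], site_pos=site, window=seq,
                    offset_of_site=offset)
                if strict:
                    w.check_central(center_residues)
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            windows.append(w)
    if header is None:
        raise FormatError(f"{path}: empty file")
    return windows


def write_window_table(windows: Sequence[PhosphopeptideWindow],
                       path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# serine-centered phosphopeptide windows; "
                 "site positions are 1-based\n")
        fh.write("\t".join(WINDOW_COLUMNS) + "\n")
        for w in windows:
            fh.write(f"{w.species}\t{w.dataset_id}\t{w.protein_id}\t"
                     f"{w.site_pos}\t{w.window}\n")


# ---------------------------------------------------------------------------
# FASTA + site table extraction
# ---------------------------------------------------------------------------

def read_site_table(path: str | Path) -> list[tuple[str, str, str, int]]:
    """Rows of (species, dataset, protein, site) from a TSV site table."""
    path = Path(path)
    rows: list[tuple[str, str, str, int]] = []
    with path.open() as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = {"species", "dataset", "protein", "site"} - set(header)
                if missing:
                    raise FormatError(
                        f"{path}: missing column(s) {sorted(missing)}")
                continue
            row = dict(zip(header, fields))
            try:
                site = int(row["site"])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad site {row['site']!r}")
            rows.append((row["species"], row["dataset"], row["protein"], site))
    return rows


def extract_window(sequence: str, site_pos: int, width: int = DEFAULT_WIDTH
                   ) -> tuple[str, int]:
    """(window, offset) spanning site_pos +/- (width-1)/2, truncated at the
    protein termini; never padded."""
    if width < 1 or width % 2 == 0:
        raise UsageError("width must be a positive odd integer")
    if not 1 <= site_pos <= len(sequence):
        raise CoordinateError(
            f"site {site_pos} outside protein of length {len(sequence)}")
    half = (width - 1) // 2
    start = max(1, site_pos - half)
    end = min(len(sequence), site_pos + half)
    return sequence[start - 1:end], site_pos - start


def extract_windows_from_fasta(fasta: str | Path, sites: str | Path,
                               width: int = DEFAULT_WIDTH,
                               strict: bool = True,
                               center_residues: str = "S"
                               ) -> list[PhosphopeptideWindow]:
    """Extract serine-centered windows from protein FASTA + TSV site table."""
    proteins = {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(str(fasta), "fasta")}
    windows: list[PhosphopeptideWindow] = []
    for species, dataset, protein, site in read_site_table(sites):
        if protein not in proteins:
            raise KeyError(f"protein {protein!r} absent from {fasta}")
        seq = proteins[protein]
        window, offset = extract_window(seq, site, width)
        w = PhosphopeptideWindow(species=species, dataset_id=dataset,
                                 protein_id=protein, site_pos=site,
                                 window=window, offset_of_site=offset)
        if strict:
            w.check_central(center_residues)
        windows.append(w)
    return windows


# ---------------------------------------------------------------------------
# signatures
# ---------------------------------------------------------------------------

def write_signature(sig: Signature, path: str | Path) -> None:
    path = Path(path)
    p = sig.parameters
    with path.open("w") as fh:
        fh.write(f"#n_min={p.n_min}\n#n_max={p.n_max}\n")
        fh.write(f"#threshold={p.threshold!r}\n#score_mode={p.score_mode}\n")
        fh.write("\t".join(SIGNATURE_COLUMNS) + "\n")
        for e in sig.entries:
            fh.write(f"{e.ngram}\t{e.top_species}\t{e.kingdom}\t"
                     f"{e.score!r}\t{e.weight!r}\n")


def read_signature(path: str | Path) -> Signature:
    path = Path(path)
    params: dict[str, str] = {}
    entries: list[SignatureEntry] = []
    seen: set[str] = set()
    with path.open() as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" not in line:
                    raise FormatError(f"{path}:{lineno}: malformed parameter "
                                      f"header {line!r}")
                key, value = line[1:].split("=", 1)
                params[key.strip()] = value.strip()
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if tuple(header) != SIGNATURE_COLUMNS:
                    raise FormatError(f"{path}: unexpected columns {header}")
                continue
            row = dict(zip(header, fields))
            if row["ngram"] in seen:
                raise FormatError(f"{path}:{lineno}: duplicate n-gram "
                                  f"{row['ngram']!r}")
            seen.add(row["ngram"])
            entries.append(SignatureEntry(
                ngram=row["ngram"], top_species=row["top_species"],
                kingdom=row["kingdom"], score=float(row["score"]),
                weight=float(row["weight"])))
    try:
        parameters = SignatureParams(
            n_min=int(params["n_min"]), n_max=int(params["n_max"]),
            threshold=float(params["threshold"]),
            score_mode=params["score_mode"])
    except KeyError as exc:
        raise FormatError(f"{path}: missing parameter header {exc}") from exc
    return Signature(entries=entries, parameters=parameters)


# ---------------------------------------------------------------------------
# frequency matrices and count tables
# ---------------------------------------------------------------------------

def write_frequency_matrix(fm: FrequencyMatrix, path: str | Path) -> None:
    """TSV with raw enriched counts plus per-row weight and s(g); relative
    and dampened frequencies are recomputed on read (deterministically)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#n_min={fm.n_min}\n#n_max={fm.n_max}\n")
        fh.write("#columns: ngram, dampening weight, s(g), then raw enriched "
                 "counts per species\n")
        fh.write("ngram\tweight\ts\t" + "\t".join(fm.species) + "\n")
        for i, g in enumerate(fm.ngrams):
            row = "\t".join(str(int(c)) for c in fm.raw[i])
            fh.write(f"{g}\t{float(fm.weights[i])!r}\t"
                     f"{int(fm.n_species_present[i])}\t{row}\n")


def read_frequency_matrix(path: str | Path) -> FrequencyMatrix:
    path = Path(path)
    params: dict[str, str] = {}
    ngrams: list[str] = []
    weights: list[float] = []
    s_g: list[int] = []
    raw_rows: list[list[int]] = []
    species: list[str] | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, value = line[1:].split("=", 1)
                    params[key.strip()] = value.strip()
                continue
            fields = line.split("\t")
            if species is None:
                if fields[:3] != ["ngram", "weight", "s"]:
                    raise FormatError(f"{path}: unexpected columns {fields}")
                species = fields[3:]
                continue
            ngrams.append(fields[0])
            weights.append(float(fields[1]))
            s_g.append(int(fields[2]))
            raw_rows.append([int(x) for x in fields[3:]])
    if species is None:
        raise FormatError(f"{path}: no header row")
    raw = np.array(raw_rows, dtype=np.int64)
    totals = raw.sum(axis=0).astype(np.float64)
    totals[totals == 0] = 1.0
    relfreq = raw / totals
    w = np.array(weights)
    return FrequencyMatrix(
        ngrams=ngrams, species=species, raw=raw, relfreq=relfreq, weights=w,
        normfreq=relfreq * w[:, None], n_species_present=np.array(s_g),
        n_min=int(params.get("n_min", 6)), n_max=int(params.get("n_max", 21)))


def write_count_table(table: NGramCountTable, path: str | Path) -> None:
    """Deterministic lexicographic TSV dump of an n-gram count table."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#species={table.species}\n#dataset={table.dataset_id}\n")
        fh.write(f"#n_min={table.n_min}\n#n_max={table.n_max}\n")
        fh.write("ngram\tcount\n")
        for g in sorted(table.counts):
            fh.write(f"{g}\t{table.counts[g]}\n")


def read_count_table(path: str | Path) -> NGramCountTable:
    path = Path(path)
    params: dict[str, str] = {}
    counts: Counter[str] = Counter()
    with path.open() as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, value = line[1:].split("=", 1)
                params[key.strip()] = value.strip()
                continue
            if not header_seen:
                header_seen = True
                continue
            g, c = line.split("\t")
            counts[g] = int(c)
    return NGramCountTable(
        species=params.get("species", ""), dataset_id=params.get("dataset", ""),
        counts=counts, n_min=int(params.get("n_min", 6)),
        n_max=int(params.get("n_max", 21)))


# ---------------------------------------------------------------------------
# study design and property tables
# ---------------------------------------------------------------------------

def read_study_design(path: str | Path) -> StudyDesign:
    with Path(path).open() as fh:
        data = yaml.safe_load(fh)
    try:
        return StudyDesign(
            train_species=tuple(data["train_species"]),
            test_species=tuple(data["test_species"]),
            pairing=dict(data["pairing"]),
            kingdom_of=dict(data["kingdom_of"]),
            datasets_of={k: tuple(v) for k, v in data["datasets_of"].items()})
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"{path}: malformed study design ({exc})") from exc


def write_study_design(design: StudyDesign, path: str | Path) -> None:
    data = {
        "train_species": list(design.train_species),
        "test_species": list(design.test_species),
        "pairing": dict(design.pairing),
        "kingdom_of": dict(design.kingdom_of),
        "datasets_of": {k: list(v) for k, v in design.datasets_of.items()},
    }
    with Path(path).open("w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_property_table(path: str | Path) -> dict[str, frozenset[str]]:
    """TSV: property name <tab> comma-separated residues."""
    from .physchem import validate_properties

    props: dict[str, list[str]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                name, residues = line.split("\t")
            except ValueError:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            if name in props:
                raise FormatError(f"{path}:{lineno}: duplicate property "
                                  f"{name!r}")
            props[name] = [r.strip() for r in residues.split(",") if r.strip()]
    return validate_properties(props)
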