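"""End-to-end orchestration of the discriminative n-gram analysis.

``run_study`` takes per-dataset window lists and a study design and carries
out the whole comparative analysis: per-dataset n-gram counting, enriched
per-species counts, the dampened training frequency matrix, discriminative
scoring and selection, signature assembly against the paired test species,
signature-restricted projections, SVM classification of the test species,
and (optionally) the multiscale-bootstrap dendrogram over all species.
Downstream physico-chemical clustering and logo construction consume the
returned bundle.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .classify import (BootstrapDendrogram, ClassificationResult,
                       DEFAULT_SCALES, multiscale_bootstrap,
                       train_and_classify)
from .errors import UsageError
from .frequencies import (FrequencyMatrix, RATIO, ScoreTable,
                          build_frequency_matrix, build_signature,
                          discriminative_scores, enriched_counts,
                          project_frequencies, select_discriminative)
from .logos import LogoMatrix, build_logo, ratio_percentile_cutoff, \
    select_top_ngrams
from .model import PhosphopeptideWindow, Signature, StudyDesign
from .ngrams import NGramCountTable, count_dataset
from .physchem import (ConsensusClustering, DEFAULT_PROPERTIES,
                       cluster_distribution, consensus_partition,
                       kmeans_partition, profile_matrix)


@dataclass(frozen=True)
class PipelineParams:
    """Defaults of the analysis; see docs/methods.md for rationale."""

    n_min: int = 6
    n_max: int = 21
    score_mode: str = RATIO
    threshold: float = 0.05
    svm_degree: int = 2
    svm_c: float = 1.0
    distance: str = "correlation"
    linkage: str = "average"
    scales: tuple[float, ...] = DEFAULT_SCALES
    n_boot: int = 1000
    seed: int = 1


@dataclass
class StudyResult:
    design: StudyDesign
    params: PipelineParams
    train_enriched: dict[str, NGramCountTable]
    test_tables: dict[str, NGramCountTable]
    fm_train: FrequencyMatrix
    scores: ScoreTable
    discriminative: dict[str, set[str]]
    signature: Signature
    train_projection: FrequencyMatrix
    test_projection: FrequencyMatrix
    combined_projection: FrequencyMatrix
    classification: ClassificationResult
    bootstrap: BootstrapDendrogram | None = None
    _tables_by_species: dict[str, NGramCountTable] = field(
        init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self._tables_by_species = {**self.train_enriched, **self.test_tables}

    @property
    def species_tables(self) -> dict[str, NGramCountTable]:
        """Enriched tables for training species, dataset tables for test."""
        return self._tables_by_species


def run_study(train_windows: Mapping[tuple[str, str],
                                     Sequence[PhosphopeptideWindow]],
              test_windows: Mapping[str, Sequence[PhosphopeptideWindow]],
              design: StudyDesign,
              params: PipelineParams = PipelineParams(),
              with_bootstrap: bool = True) -> StudyResult:
    """Run the full comparative analysis on one study's window lists."""
    per_dataset: dict[str, list[NGramCountTable]] = {}
    for (sp, ds), windows in train_windows.items():
        if sp not in design.train_species:
            raise UsageError(f"unknown training species {sp!r}")
        per_dataset.setdefault(sp, []).append(
            count_dataset(windows, params.n_min, params.n_max))
    train_enriched = {sp: enriched_counts(per_dataset[sp])
                      for sp in design.train_species}
    test_tables = {sp: count_dataset(test_windows[sp], params.n_min,
                                     params.n_max)
                   for sp in design.test_species}

    fm_train = build_frequency_matrix(train_enriched)
    scores = discriminative_scores(fm_train, mode=params.score_mode)
    discr = select_discriminative(scores, params.threshold)
    signature = build_signature(discr, test_tables, design, fm_train, scores,
                                params.threshold)
    if not signature.entries:
        raise UsageError("signature is empty: no discriminative n-gram was "
                         "observed in its paired test species")

    train_projection = project_frequencies(signature, train_enriched)
    test_projection = project_frequencies(signature, test_tables)
    combined_projection = project_frequencies(
        signature, {**train_enriched, **test_tables})

    labels = {sp: sp for sp in design.train_species}
    classification = train_and_classify(
        train_projection, labels, test_projection, degree=params.svm_degree,
        c=params.svm_c, pairing=design.pairing)

    bootstrap = None
    if with_bootstrap:
        bootstrap = multiscale_bootstrap(
            combined_projection, scales=params.scales, n_boot=params.n_boot,
            seed=params.seed, distance=params.distance,
            linkage=params.linkage)
    return StudyResult(
        design=design, params=params, train_enriched=train_enriched,
        test_tables=test_tables, fm_train=fm_train, scores=scores,
        discriminative=discr, signature=signature,
        train_projection=train_projection, test_projection=test_projection,
        combined_projection=combined_projection,
        classification=classification, bootstrap=bootstrap)


@dataclass
class PhyschemResult:
    ngrams: list[str]
    per_property_labels: dict[str, np.ndarray]
    consensus: ConsensusClustering
    distribution: "object"  # pandas DataFrame species x cluster


def physchem_analysis(result: StudyResult,
                      props: Mapping[str, frozenset[str]] = DEFAULT_PROPERTIES,
                      k: int = 10, seed: int = 0, restarts: int = 10
                      ) -> PhyschemResult:
    """Per-property k-means on signature n-gram profiles, consensus partition,
    and the species x cluster distribution."""
    ngrams = result.signature.ngrams
    tables = list(result.species_tables.values())
    per_property, _ = profile_matrix(ngrams, tables, props)
    labels = {p: kmeans_partition(mat, k=k, seed=seed, restarts=restarts)
              for p, mat in per_property.items()}
    consensus = consensus_partition(list(labels.values()), k=k, items=ngrams,
                                    seed=seed)
    distribution = cluster_distribution(consensus, result.signature,
                                        result.species_tables)
    return PhyschemResult(ngrams=list(ngrams), per_property_labels=labels,
                          consensus=consensus, distribution=distribution)


def species_logo(result: StudyResult, species: str,
                 cutoff: float | None = None) -> LogoMatrix:
    """Logo matrix of the windows (in ``species``) matching the top
    discriminative n-grams of that species' kingdom.

    For a test species the top n-grams are those of its paired training
    species; the windows are always the species' own. ``cutoff`` defaults to
    the 95th percentile of the relevant ratio scores.
    """
    train_sp = result.design.pairing.get(species, species)
    if train_sp not in result.design.train_species:
        raise KeyError(f"unknown species {species!r}")
    if cutoff is None:
        cutoff = ratio_percentile_cutoff(result.signature, train_sp)
    top = select_top_ngrams(result.signature, train_sp, cutoff)
    table = result.species_tables[species]
    windows: list[PhosphopeptideWindow] = []
    seen: set[str] = set()
    for g in sorted(top):
        for w in table.source_windows.get(g, []):
            if w.window_id not in seen:
                seen.add(w.window_id)
                windows.append(w)
    if not windows:
        raise UsageError(f"no windows of {species!r} match the top n-grams")
    return build_logo(windows, species=species, cutoff=cutoff)
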