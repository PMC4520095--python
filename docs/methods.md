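# Methods

This note documents the models and procedures implemented in `phosphosig`,
the parameters that matter, and the choices made where the design was
genuinely open.

## Phosphopeptide windows

The unit of analysis is a serine-centered peptide window: 21 residues with
the measured phospho-serine at the 11th position (0-based offset 10).
Windows near protein termini are **truncated, never padded** — a padding
character would pollute the n-gram alphabet, and truncation keeps every
window an exact substring of its protein. Site positions are 1-based in
all files (UniProt convention) and 0-based internally. Strict mode accepts
only 'S' as the central residue; a switch admits T/Y for reuse, off by
default. Residues outside the 20-letter alphabet are carried in windows as
'X' but never enter an n-gram.

## N-gram layer

Every contiguous substring of length 6..21 of each window is an n-gram,
counted with multiplicity (a full 21-mer yields Σ_{L=6..21}(22−L) = 136
instances). N-grams are not required to cover the central serine.
Substrings containing 'X' are dropped rather than wildcarded so the
alphabet stays exact. Per species, the replicate datasets' counts are
summed element-wise into *enriched counts*; the source windows of each
n-gram are tracked so discriminative n-grams can later be mapped back to
their phosphopeptides.

## Dampened normalized frequencies

With N training species, each species' enriched counts are normalized to
relative frequencies over the union vocabulary, then multiplied by an
IDF-style dampening weight

    w(g) = log2(N / s(g)) + 1,

where s(g) is the number of species containing g. The weight is 1 for
ubiquitous n-grams and strictly increases as g becomes rarer, which is the
qualitative contract a dampening factor must satisfy when comparing
unbalanced datasets; the exact functional form is this package's choice
and is pluggable.

## Discriminative scores and the signature

Per n-gram the species are ranked by dampened normalized frequency
f1 ≥ f2 ≥ f3 ≥ …; the top species is the argmax (ties broken
deterministically by training-species order and flagged). Two score modes
exist:

* **ratio** (default): f1 / ((f2 + f3)/2), flagged infinite when
  f2 = f3 = 0 (species-exclusive n-grams), threshold T = 0.05;
* **difference**: f1 − (f2 + f3)/2, same threshold scale as the
  frequencies themselves.

The ratio is the method's native scale. Note that a finite ratio is ≥ 1 by
construction, so T = 0.05 excludes nothing finite — the selective pressure
in ratio mode comes from the infinite-flag ordering and, decisively, from
the validation filter below. The difference mode is provided for
sensitivity analysis; on realistic vocabularies (10^5–10^6 n-grams) the
normalized frequencies are ~10^-3, so a difference threshold of 0.05 is
far above any attainable score and selects nothing — it is only meaningful
on small vocabularies.

The **signature** keeps each training species' discriminative n-grams that
also occur (raw count > 0) in the paired same-kingdom/phylum test species,
recording the kingdom label, the score, and the **frozen** training
weight. Projection onto any species renormalizes relative frequencies over
the signature vocabulary only and reuses the frozen weights, so the
signature acts as a fixed model applied to new data. A projected species
containing no signature n-gram gets an all-zero column and a warning, not
an error.

## Classification

One feature vector per species (its signature-restricted dampened
normalized frequencies). The SVM uses the normalized polynomial kernel

    K~(x,y) = K(x,y) / sqrt(K(x,x) K(y,y)),  K(x,y) = (x·y + 1)^d,

d = 2 and C = 1 by default (both configurable); the kernel normalization
is implemented and unit-tested here, the max-margin optimization is
delegated to scikit-learn's SVC with a precomputed Gram matrix (one-vs-one
for multiclass). The result is a 0/1 confusion matrix of test species
against training species and the fraction assigned to their paired
training species.

## Hierarchical clustering and multiscale bootstrap

Species columns are clustered agglomeratively; defaults are correlation
distance (1 − Pearson) with average linkage, the conventional defaults of
multiscale-bootstrap cluster analysis, since the analysis is about
frequency *profiles* rather than magnitudes. A constant column under
correlation distance is an error on the full data; inside bootstrap
replicates it is treated as uncorrelated with everything (distance 1) so
replicates never fail.

Cluster uncertainty: for each relative sample size r in {0.5, 0.6, …,
1.4}, round(r·G) n-gram rows are resampled with replacement n_boot times
(default 1000) and the tree rebuilt; each full-data edge's per-scale
presence frequency BP_r is fitted by weighted least squares as

    Φ⁻¹(1 − BP_r) = v·√r + c/√r,

with weights given by the inverse variance of the probit-transformed
binomial proportion, and the approximately unbiased p-value is
AU = 1 − Φ(v − c); BP is reported at r = 1. Degenerate cases: per-scale
BP_r ∈ {0, 1} is clamped to [1/(B+1), B/(B+1)] before the probit; an edge
whose BP_r is identically 1 (or 0) at *every* scale short-circuits to
AU = 1 (resp. 0), because the two-term basis cannot represent a constant
profile and the limit value is the only faithful report (this mirrors
pvclust's handling). Edges never observed get BP = AU = 0. A constant
BP_r = 0.5 profile is a fixed point: v = c = 0, AU = 0.5.

## Physico-chemical consensus clustering

Windows are re-encoded as binary indicator vectors for four residue
properties — hydrophobic {A,C,F,I,L,M,V}, negative {D,E}, positive
{K,R,H}, proline {P}. These default sets are this package's choice and can
be replaced via a property-table file. For each signature n-gram the
indicator vectors of its source windows are averaged position-wise
(mask-aware: truncated or 'X' positions are excluded from the mean),
giving one 21-vector per property. For k-means and the consensus the
masked positions are imputed with the property's global mean so all
vectors have fixed length.

Per property, a k-means partition (k = 10, Lloyd, squared Euclidean, 10
k-means++ restarts, empty clusters repaired by the library) clusters the
n-grams. The per-property partitions are reconciled by a **soft
least-squares Euclidean consensus**: minimize Σ_b ‖M − M_b Π_b‖²_F over a
soft membership M (rows on the simplex) and per-input column permutations
Π_b, alternating optimal label matching (linear assignment maximizing
trace(MᵀM_bΠ)) with M = mean of matched memberships. Both steps are exact
minimizations of the objective in their block, so it is non-increasing;
initialization is the first input's membership, making the result
deterministic. Inputs identical up to label permutation reach objective 0.

The species × cluster distribution reports, per species, the fraction of
signature n-grams *present* in that species (raw count > 0) falling in
each consensus cluster — the denominator is presence, not ownership, so
every species is described over all clusters.

## Logos

Per species, the top discriminative n-grams are the signature entries of
its kingdom with ratio score ≥ a cutoff; infinite flagged scores are
always included. The cutoff is an explicit per-species choice, defaulting
to the 95th percentile (as an order statistic — interpolation is undefined
with infinite scores) of that species' ratio scores. The windows of the
species containing any top n-gram form the logo: a 21 × 20 position
frequency matrix (mask-aware counts; unmasked columns sum to 1) and
per-position information content

    ic_p = log2(20) − (H_p + 19/(2·ln2·n_p)),

clamped to [0, log2 20], with Shannon entropy H_p in bits over the n_p
unmasked sequences at position p and the standard small-sample correction
(switchable off). In strict serine mode the central column is degenerate:
frequency of S is 1.

## Synthetic studies

The generator emulates the comparative design: 5 training species from 5
kingdom/phylum groups × 2 replicate datasets, 5 paired test species × 1
dataset, 500 windows per dataset by default. Windows are i.i.d. background
draws (uniform over the 20 residues by default, a composition table can be
supplied) with 'S' forced at the center; with probability 0.3 one of the
kingdom's motifs is stamped at its anchor. At most one motif is stamped
per window. All randomness flows through one seeded generator.

Default motifs, one fully-fixed 9-mer block per group, chosen to reflect
the qualitative kingdom patterns of real phosphoproteomes: Plantae
`SDDEDEEDE` (C-terminal acidic), Chordata `RKRRSRRKR` and Arthropoda
`KKRKSKRKK` (basic/arginine flanks, distinct per phylum), Ascomycota
`SPPPPPPPP` (C-terminal prolines), Apicomplexa `NNNNSNNNN`
(asparagine-rich low-complexity, as in *P. falciparum*). A pattern must
contain a contiguous wildcard-free block of ≥ 6 residues to plant any
recurring n-gram at all; 9-mer blocks plant Σ_{L=6..9}(10−L) = 10
recurring n-grams each, enough that bootstrap resampling essentially never
loses a species' whole planted set.

What the generator does **not** emulate: species-specific residue
composition, mass-spectrometry detection bias, missed cleavages,
dataset-size imbalance, phosphosite localization uncertainty, homology
between species beyond the shared motifs. Passing tests therefore show
that the pipeline recovers planted, species-exclusive enrichment under
clean conditions — they do not certify performance on real data, where
discriminative frequencies are weaker and backgrounds differ per species.

## Numerical choices and degenerate inputs

* Vocabulary order is lexicographic; species order follows the study
  design — both fixed so every result is deterministic given inputs.
* Top-rank ties broken by training-species order and flagged.
* Ratio scores with zero denominator are flagged infinite and sort above
  all finite scores; no arbitrary cap.
* Constant columns: error on full-data correlation clustering, distance 1
  inside bootstrap replicates (see above).
* Relative-frequency denominators: full vocabulary at training, signature
  vocabulary at projection.
* Empty signature aborts the pipeline with an explicit error.

## Problem sizes used in the shipped analyses

The default synthetic study (7,500 windows, vocabulary ≈ 6.4 × 10^5
n-grams, signature ≈ 5.7 × 10^3 entries) with 1000 bootstrap replicates
per scale runs the full pipeline in about a minute on one CPU; the test
suite uses a 150-window-per-dataset variant of the same conditions for the
module-level checks and the full default study for the end-to-end
acceptance properties.

## Known limitations

* The dampening formula and the binary property sets are package choices
  satisfying the stated qualitative contracts, not reproductions of any
  specific published table; both are pluggable.
* The difference score mode is scale-dependent (see above) and is not
  meaningful with the default threshold on realistic vocabularies.
* AU p-values from 10 scales and 1000 replicates carry Monte-Carlo noise
  of a few percent; they are support diagnostics, not calibrated tests.
* Logo cutoffs are subjective by nature; the 95th-percentile default is a
  convention, and per-species cutoffs should be chosen by inspection for
  publication-grade figures.
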