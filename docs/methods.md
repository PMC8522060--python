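# Methods

## Identification model

`glycomet` treats CAZyme detection in unassembled short reads as a translated
homology-search classification problem. A read is a ~100-nt DNA fragment of
unknown strand and frame; it is translated in all six frames and each frame
peptide (≈33 aa for a 100-nt read) is aligned locally against a reference set
of family-annotated CAZyme proteins. The classifier is a pair of strict
thresholds on the best hit: identity > 0.90 and alignment length > 25 aa.
The strictness matters at the boundary — a hit at exactly 90% identity or
exactly 25 columns is negative.

Assumptions baked into this model:

* a 33-aa peptide carries enough signal to separate true CAZyme fragments
  from non-CAZyme sequence when the identity bar is high; the grid evaluation
  exists precisely to check this on truth-labelled data;
* one gene call per read (the best hit); a read is never counted toward two
  subjects, but a multi-family top subject contributes to each of its
  families in downstream family-presence statistics;
* raw read counts are the abundance unit — no normalisation by gene length or
  genome size.

## Alignment conventions

* Scoring: BLOSUM62 with affine gaps, open 11 / extend 1. A gap of length L
  costs `open + L·extend`, matching the gap-existence convention of
  translated-search tools.
* Identity = identical residue columns / all aligned columns (gaps count in
  the denominator, never as identities) — the BLAST/GhostX tabular
  convention. The hit table is 12-column BLAST outfmt-6; the internal aligner
  writes `NA` for the e-value, which it does not compute.
* Stop codons: frame peptides are aligned whole, with `*` given a large
  negative substitution score (−1000) so that no optimal local alignment
  crosses a stop and a `*` column can never count as an identity. This
  preserves one alignment per frame rather than splitting peptides at stops.
* Seeding: candidate subjects share at least one exact amino-acid 4-mer with
  the query peptide; each candidate is then aligned by full Smith–Waterman
  dynamic programming. `exhaustive=True` (CLI `--exhaustive`) skips seeding
  and aligns against every subject; the test suite uses this mode when
  comparing against the independent full-DP oracle, and also checks that the
  seeded and exhaustive paths agree on homologous reads.
* Determinism: the traceback starts at the highest-scoring cell (first in
  row-major order on ties) and prefers substitution > gap-in-subject >
  gap-in-query, closing a gap over extending it. Two independent
  implementations of this rule (the numba kernel and the plain-Python test
  oracle) therefore produce identical score, identity and alignment length.
* Report floor: hits scoring below 20 are suppressed. This is pre-threshold
  noise control only; a 33-aa peptide passing even the loosest grid corner
  (60% identity over >5 aa with plausible composition) scores well above it.
* Best-hit order: score, then identity, then alignment length, then the
  lexicographically smallest subject accession — a total order, so the result
  is independent of hit-list order.

## Benchmark construction and grid evaluation

Virtual shotgun benchmarks are built from annotated genomes whose genes carry
boolean CAZyme truth labels: each CDS is cut into non-overlapping 100-nt
windows from the 5' end (a trailing partial window is discarded) and up to
three windows per gene are sampled uniformly without replacement. Genes
shorter than 300 nt contribute all their windows rather than being dropped.
Fragments inherit their gene's label, and read ids encode genome, gene and
offset so any call can be audited.

The grid spans identity 0.60–0.90 in steps of 0.05 and alignment length
5–25 aa in steps of 5 (both configurable). Precision, recall and FDR are
computed per genome; a metric whose denominator is zero is undefined (NaN),
never silently zero. The operating point is the cell maximising mean
precision across genomes, ties broken by lower mean FDR and then by larger
thresholds; per-genome surfaces are always retained because aggregation
choices can hide per-genome failures. Recall on these synthetic benchmarks is
near 1.0 by construction (every true fragment is an exact copy of a reference
protein region) and is reported descriptively, not used for selection.

## Synthetic data: what it emulates and what it does not

The generator provides the standard study conditions used throughout the
tests and the acceptance script:

* **Reference DB**: 200 random proteins of 150–400 aa, single family code
  drawn uniformly from a 23-family pool spanning all six CAZy classes.
* **Benchmark genomes** (5 per run): 30 true genes (exact back-translations
  of sampled reference proteins), 50 random-DNA decoys and 20 homolog decoys
  — back-translations of reference proteins mutated at the amino-acid level
  to a target identity drawn uniformly from 0.60–0.85, labelled False. The
  homolog band sits below the 0.90 identity bar so the strict grid corner is
  the precision-optimal cell, but local 33-aa windows of an 85%-identity
  homolog occasionally exceed 90% identity by chance, which is what keeps the
  corner's FDR realistically non-zero (a few percent) instead of exactly 0.
* **Metagenomes**: per environment, a family list, sample count, reads per
  sample and a background fraction. Planted reads are 100-nt windows cut at
  random offsets from back-translated reference CDS, allocated across the
  environment's families in a balanced round-robin so every listed family is
  present in every sample; background reads are uniform random DNA drawn at a
  binomial rate. Defaults in the acceptance run: 3 environments × 3 samples ×
  80 reads, background 0.25.

Back-translation uses one fixed codon per amino acid (the most used E. coli
codon), so planted reads align at exactly 100% amino-acid identity. This
makes expected outcomes analytic — identified fraction 1.0, exact-match
fraction 1.0, I_ms equal to the planted design — at the cost of realism: real
metagenome reads carry sequencing errors, codon variation, strain-level
divergence, intergenic sequence and uneven coverage, none of which the
generator models (an optional uniform substitution noise is the only
concession). Passing tests on these fixtures therefore demonstrates the
correctness of the machinery (translation, alignment, thresholding,
bookkeeping), not field performance on real data; the precision/FDR achieved
against near-homolog decoys is the closest proxy for the hard part of the
real problem.

Problem sizes (1500 benchmark reads, 720 metagenome reads, 200-protein
reference) were chosen as the smallest scale at which the homolog-decoy
precision estimate is stable to a few percent across seeds.

## Exact matches

An identified read is flagged *exact* when its aligned region is 100%
identical with no gaps — alignment-region identity, not full-protein
identity, since a 33-aa read can never cover a whole protein. Exact matches
are interpreted as fragments of genes already present in the reference
database, and the per-sample exact fraction separates "known" from candidate
novel glycan genes.

## Environment statistics

* Glycan-gene ratio = identified reads / total reads per sample; environment
  aggregates use the unweighted mean and the n−1 sample SD (undefined for a
  single sample).
* Class composition: each identified read adds one count to the CAZy class of
  each family of its top hit; proportions are over the class-count total and
  sum to 1 whenever any read was identified.
* I_ms detection means ≥1 identified read of the family in the sample; a
  `min_reads` option raises this floor but defaults to 1. I_ms depends only on
  presence/absence, so duplicate reads of a family in one sample do not move
  it.
* Environment vocabulary is free-form, taken from the user-supplied
  sample→environment table; no ontology mapping is attempted.

## Family grouping and enrichment

The heatmap-style classification of families into general / moderate /
specific is formalised with three explicit parameters: a prevalence cutoff
τ (family "present" in an environment iff I_ms ≥ τ, default 0.5), a minimum
environment count for *general* (default 11, anchored to a twelve-environment
survey design) and a maximum for *specific* (default 3). Smaller designs pass
bounds matching their column count; the pipeline command derives defaults
from the matrix width. An explicit rule was chosen over reproducing a visual
dendrogram cut because only the former is reproducible.

Clustering is agglomerative with Euclidean distance and Ward linkage
(scipy); leaf order is made deterministic by always placing the child
subtree containing the smallest original row index first, and the tree is
exportable as Newick with merge-height branch lengths. Substrate enrichment
compares the fraction of polysaccharide+oligosaccharide families between
groups with 2×2 chi-squared tests without continuity correction (the plain
chi-squared statistic); a degenerate table with an empty margin is reported
as statistic 0, p = 1, and a group with no families is skipped. Pathway
coverage is the fraction of a user-supplied pathway EC list intersected by
the general families' EC numbers; family→EC mappings are user tables, with
no remote database access.

## Degenerate inputs and numerical choices

* Zero identified reads: ratio 0, class proportions and exact fraction NaN.
* Empty alignments, empty hit lists and absent best hits are all valid
  negatives, never errors.
* Metrics and I_ms are exact rational arithmetic on counts; the only
  tolerances in the tests are 1e−9 for cross-implementation float agreement
  (Ward heights, chi-squared p-values) and ±0.02 for the realised identity of
  mutated homologs (rounding of the mutation count).
* All randomness flows through `numpy.random.default_rng` seeded explicitly;
  every generator is bit-reproducible given (parameters, seed).

## Known limitations

* The internal aligner computes no e-value; statistical significance is
  delegated to the identity/length thresholds that the benchmark calibrates.
* No HMM-based detection: the method is sequence alignment only, so remote
  homologs below the identity bar are invisible by design.
* No paired-end handling, no quality-aware error model, no taxonomic
  attribution of identified reads.
* The external-tool adapter infers no reading frame from tabular output and
  trusts the tool's identity/length conventions to be BLAST-compatible.
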