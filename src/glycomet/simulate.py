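"""Virtual shotgun benchmarks and fully synthetic fixtures.

Two jobs live here:

* building truth-labelled read sets from annotated genomes — each gene CDS is
  cut into non-overlapping 100-nt windows from the 5' end and a fixed number
  of windows is sampled per gene, carrying the gene's glycan-related label;
* generating synthetic inputs for every pipeline stage: a family-annotated
  reference protein set, genomes mixing exact back-translated CAZyme genes
  with random and near-homolog decoy genes, and multi-environment metagenome
  read sets with a controlled family composition.

Back-translation uses one fixed codon per amino acid, so a read cut from a
"True" gene aligns to its source protein at 100% amino-acid identity. All
generators are deterministic given their parameters and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .refdb import FamilyCode, ReferenceDB, ReferenceProtein

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# One deterministic codon per amino acid (the most used E. coli codon), so
# back-translation followed by translation is the identity on protein space.
BACK_TABLE = {
    "A": "GCG", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGC", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAT",
}

DEFAULT_FAMILY_POOL = tuple(
    [f"GH{i}" for i in (1, 2, 3, 5, 13, 43, 47)]
    + [f"GT{i}" for i in (2, 4, 21, 23, 80)]
    + ["PL1", "PL9", "CE1", "CE4", "CBM5", "CBM48", "AA3", "AA10"]
)


def back_translate(protein: str) -> str:
    """Deterministic reverse translation (one fixed codon per residue)."""
    return "".join(BACK_TABLE[aa] for aa in protein.upper())


@dataclass
class GeneRecord:
    gene_id: str
    cds: str
    label: bool
    family: FamilyCode | None = None

    def __post_init__(self) -> None:
        if self.label and self.family is None:
            raise ValueError(f"glycan-related gene {self.gene_id} needs a family")


@dataclass
class GenomeModel:
    genome_id: str
    genes: list[GeneRecord]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate gene ids in genome {self.genome_id}")


@dataclass
class ReadFragment:
    read_id: str
    dna: str
    source_gene: str
    truth_label: bool
    family: FamilyCode | None = None


@dataclass
class BenchmarkSet:
    genome_id: str
    fragments: list[ReadFragment]
    rng_seed: int


def fragment_gene(cds: str, read_len: int = 100) -> list[str]:
    """Cut a CDS into non-overlapping windows of ``read_len`` from the 5' end.

    A trailing partial window shorter than ``read_len`` is discarded; an empty
    CDS yields an empty list.
    """
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    n = len(cds) // read_len
    return [cds[i * read_len:(i + 1) * read_len] for i in range(n)]


def _sample_indices(n: int, k: int, rng: np.random.Generator) -> list[int]:
    if n <= k:
        return list(range(n))
    return sorted(int(i) for i in rng.choice(n, size=k, replace=False))


def sample_fragments(windows: list, k: int = 3,
                     seed: int | np.random.Generator = 0) -> list:
    """Sample ``k`` windows uniformly without replacement (all if fewer).

    The selection preserves 5'->3' order and is deterministic per seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    return [windows[i] for i in _sample_indices(len(windows), k, rng)]


def build_benchmark(genome: GenomeModel, read_len: int = 100, k: int = 3,
                    seed: int = 0) -> BenchmarkSet:
    """Fragment every gene and sample up to ``k`` truth-labelled reads each.

    Read ids encode genome, gene and 5' offset so the source of any read can
    be recovered: ``<genome>|<gene>|<offset>``.
    """
    rng = np.random.default_rng(seed)
    fragments: list[ReadFragment] = []
    if not genome.genes:
        logger.warning("genome %s has no genes; empty benchmark",
                       genome.genome_id)
    for gene in genome.genes:
        windows = fragment_gene(gene.cds, read_len)
        for widx in _sample_indices(len(windows), k, rng):
            win = windows[widx]
            offset = widx * read_len
            fragments.append(ReadFragment(
                read_id=f"{genome.genome_id}|{gene.gene_id}|{offset}",
                dna=win,
                source_gene=gene.gene_id,
                truth_label=gene.label,
                family=gene.family,
            ))
    return BenchmarkSet(genome.genome_id, fragments, rng_seed=seed)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def synth_reference_db(n_proteins: int = 200,
                       length_range: tuple[int, int] = (150, 400),
                       family_pool=DEFAULT_FAMILY_POOL,
                       seed: int = 0) -> ReferenceDB:
    """Generate a random family-annotated reference protein set."""
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    pool = [FamilyCode.parse(f) if isinstance(f, str) else f
            for f in family_pool]
    proteins = []
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        fam = pool[int(rng.integers(len(pool)))]
        proteins.append(ReferenceProtein(
            accession=f"REF{i:05d}",
            families=[fam],
            sequence=_random_protein(rng, length),
        ))
    return ReferenceDB(proteins, source_note=f"synthetic(seed={seed})")


def _mutate_protein(seq: str, target_identity: float,
                    rng: np.random.Generator) -> str:
    """Substitute residues at random positions to hit a target identity."""
    n_mut = int(round((1.0 - target_identity) * len(seq)))
    if n_mut == 0:
        return seq
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    chars = list(seq)
    for pos in positions:
        alternatives = [a for a in AMINO_ACIDS if a != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(chars)


def synth_genome(refdb: ReferenceDB, n_true: int = 30,
                 n_decoy_random: int = 50, n_decoy_homolog: int = 20,
                 homolog_identity_range: tuple[float, float] = (0.60, 0.85),
                 seed: int = 0, genome_id: str = "synthG") -> GenomeModel:
    """Build a genome of true CAZyme genes plus random and homolog decoys.

    True genes are exact back-translations of sampled reference proteins
    (label True, family from the source protein). Homolog decoys are
    back-translations of proteins mutated at the amino-acid level to a target
    identity drawn uniformly from ``homolog_identity_range``; together with
    uniform-DNA random decoys they are labelled False.
    """
    if n_true > len(refdb):
        raise ValueError(
            f"n_true={n_true} exceeds reference size {len(refdb)}")
    lo, hi = homolog_identity_range
    if not (0 <= lo <= hi < 1):
        raise ValueError("homolog_identity_range must lie within [0, 1)")
    rng = np.random.default_rng(seed)
    proteins = refdb.proteins
    genes: list[GeneRecord] = []

    true_idx = rng.choice(len(proteins), size=n_true, replace=False)
    for j, idx in enumerate(true_idx):
        prot = proteins[idx]
        genes.append(GeneRecord(
            gene_id=f"{genome_id}_true{j:04d}",
            cds=back_translate(prot.sequence),
            label=True,
            family=prot.families[0],
        ))
    for j in range(n_decoy_random):
        length = int(rng.integers(150, 401)) * 3
        cds = "".join(rng.choice(list("ACGT"), size=length))
        genes.append(GeneRecord(f"{genome_id}_rand{j:04d}", cds, False))
    for j in range(n_decoy_homolog):
        prot = proteins[int(rng.integers(len(proteins)))]
        target = float(rng.uniform(lo, hi))
        mutated = _mutate_protein(prot.sequence, target, rng)
        genes.append(GeneRecord(
            f"{genome_id}_homo{j:04d}", back_translate(mutated), False))
    return GenomeModel(genome_id, genes)


@dataclass
class EnvironmentSpec:
    """Per-environment composition for the metagenome generator."""

    families: list[str]
    n_samples: int
    reads_per_sample: int
    background_fraction: float = 0.2


@dataclass
class SyntheticMetagenome:
    reads: dict[str, list[tuple[str, str]]]   # sample_id -> [(read_id, dna)]
    sample_table: pd.DataFrame                # sample_id, environment
    truth: pd.DataFrame                       # read_id, sample_id, family


def synth_metagenome(env_spec: dict[str, EnvironmentSpec],
                     refdb: ReferenceDB, seed: int = 0,
                     read_len: int = 100) -> SyntheticMetagenome:
    """Generate multi-environment read sets with planted family composition.

    Non-background reads are 100-nt windows cut at random offsets from the
    back-translated CDS of reference proteins belonging to the environment's
    families; the windows are balanced across families so that every listed
    family is present in every sample (provided enough reads). Background
    reads are uniform random DNA at the stated fraction.
    """
    if not env_spec:
        raise ValueError("empty environment specification")
    rng = np.random.default_rng(seed)
    by_family: dict[str, list[ReferenceProtein]] = {}
    for prot in refdb:
        for fam in prot.families:
            by_family.setdefault(str(fam), []).append(prot)

    reads: dict[str, list[tuple[str, str]]] = {}
    table_rows = []
    truth_rows = []
    for env, spec in env_spec.items():
        if not spec.families:
            raise ValueError(f"environment {env} lists no families")
        for fam in spec.families:
            if fam not in by_family:
                raise ValueError(f"family {fam} absent from reference DB")
        for s in range(spec.n_samples):
            sample_id = f"{env}_s{s:02d}"
            table_rows.append((sample_id, env))
            sample_reads: list[tuple[str, str]] = []
            n_bg = int(rng.binomial(spec.reads_per_sample,
                                    spec.background_fraction))
            n_fg = spec.reads_per_sample - n_bg
            # balanced allocation so every family is covered when n_fg is
            # at least the number of families
            base, extra = divmod(n_fg, len(spec.families))
            counter = 0
            for fi, fam in enumerate(spec.families):
                n_reads = base + (1 if fi < extra else 0)
                pool = by_family[fam]
                for _ in range(n_reads):
                    prot = pool[int(rng.integers(len(pool)))]
                    cds = back_translate(prot.sequence)
                    offset = int(rng.integers(0, len(cds) - read_len + 1))
                    rid = f"{sample_id}_r{counter:06d}"
                    sample_reads.append((rid, cds[offset:offset + read_len]))
                    truth_rows.append((rid, sample_id, fam))
                    counter += 1
            for _ in range(n_bg):
                rid = f"{sample_id}_r{counter:06d}"
                dna = "".join(rng.choice(list("ACGT"), size=read_len))
                sample_reads.append((rid, dna))
                truth_rows.append((rid, sample_id, ""))
                counter += 1
            reads[sample_id] = sample_reads
    return SyntheticMetagenome(
        reads=reads,
        sample_table=pd.DataFrame(table_rows,
                                  columns=["sample_id", "environment"]),
        truth=pd.DataFrame(truth_rows,
                           columns=["read_id", "sample_id", "family"]),
    )


# ---------------------------------------------------------------------------
# plain-text writers

def write_reads_fasta(reads: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, dna in reads:
            fh.write(f">{rid}\n{dna}\n")


def write_benchmark(bench: BenchmarkSet, fasta_path: str | Path,
                    truth_path: str | Path) -> None:
    """Write benchmark reads (FASTA) and truth labels (TSV)."""
    write_reads_fasta([(f.read_id, f.dna) for f in bench.fragments],
                      fasta_path)
    rows = [(f.read_id, f.source_gene, f.truth_label,
             str(f.family) if f.family else "")
            for f in bench.fragments]
    pd.DataFrame(rows, columns=["read_id", "source_gene", "label", "family"]
                 ).to_csv(truth_path, sep="\t", index=False)
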