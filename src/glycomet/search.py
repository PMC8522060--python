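"""Six-frame translation and translated local alignment against the reference.

Reads are translated in all six frames (three offsets on each strand, standard
genetic code, stops rendered ``*``) and each frame peptide is aligned locally
against reference proteins. Candidate subjects are found by shared exact
k-mer seeding (default k=4) and refined by full affine-gap Smith-Waterman
dynamic programming; an ``exhaustive`` mode aligns against every subject with
no seeding. Identity and alignment length follow the BLAST tabular
convention: alignment length counts all aligned columns including gaps, and
identity is identical residue columns divided by alignment length.

Determinism. The dynamic program is fully deterministic: the traceback starts
at the highest-scoring cell (first in row-major order on ties) and at each
step prefers a substitution column over a gap in the subject (consuming a
query residue) over a gap in the query; within a gap state, closing the gap
is preferred over extending it. A gap of length L costs open + L * extend.
Stop codons are unmatchable: any column pairing a ``*`` receives a large
negative score, so optimal local alignments never cross a stop.
"""

from __future__ import annotations

import logging
import shlex
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .refdb import FamilyCode, ReferenceDB

logger = logging.getLogger(__name__)

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]

ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
_X_INDEX = _AA_INDEX["X"]
_STOP_INDEX = _AA_INDEX["*"]
STOP_SCORE = -1000

FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")


@dataclass(frozen=True)
class PeptideFragment:
    read_id: str
    frame: str
    peptide: str


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring; defaults mirror translated-BLAST (BLOSUM62, 11/1)."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")

    def matrix(self) -> np.ndarray:
        return build_score_matrix(self.matrix_name)


_MATRIX_CACHE: dict[str, np.ndarray] = {}


def build_score_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """Integer substitution matrix over ALPHABET with unmatchable stops."""
    if name not in _MATRIX_CACHE:
        base = substitution_matrices.load(name)
        mat = np.zeros((len(ALPHABET), len(ALPHABET)), dtype=np.int32)
        for i, a in enumerate(ALPHABET):
            for j, b in enumerate(ALPHABET):
                mat[i, j] = int(base[a, b])
        mat[_STOP_INDEX, :] = STOP_SCORE
        mat[:, _STOP_INDEX] = STOP_SCORE
        _MATRIX_CACHE[name] = mat
    return _MATRIX_CACHE[name]


def encode_peptide(peptide: str) -> np.ndarray:
    """Encode an amino-acid string as indices into ALPHABET (unknown -> X)."""
    return np.array([_AA_INDEX.get(aa, _X_INDEX) for aa in peptide.upper()],
                    dtype=np.uint8)


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    subject: str
    frame: str
    identity: float
    alignment_length: int
    score: float
    mismatches: int = 0
    gap_opens: int = 0
    gaps: int = 0
    qstart: int = 0
    qend: int = 0
    sstart: int = 0
    send: int = 0
    families: tuple = ()


# ---------------------------------------------------------------------------
# six-frame translation

def _translate_frame(dna: str, offset: int) -> str:
    sub = dna[offset:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    return str(Seq(sub).translate())


def six_frame_translate(dna: str, read_id: str = "") -> list[PeptideFragment]:
    """Translate a DNA read in frames +1/+2/+3 and -1/-2/-3.

    Reverse frames are read from the reverse complement at offsets 0/1/2.
    IUPAC ambiguity codes translate to X; reads shorter than one codon yield
    six empty peptides with a warning.
    """
    dna = dna.upper()
    if len(dna) < 3:
        logger.warning("read %s shorter than one codon", read_id)
        return [PeptideFragment(read_id, f, "") for f in FRAMES]
    rc = str(Seq(dna).reverse_complement())
    out = []
    for strand_seq, sign in ((dna, "+"), (rc, "-")):
        for offset in range(3):
            out.append(PeptideFragment(
                read_id, f"{sign}{offset + 1}",
                _translate_frame(strand_seq, offset)))
    return out


# ---------------------------------------------------------------------------
# Smith-Waterman kernel

@njit(cache=True)
def _sw_kernel(q, s, sub, gap_open, gap_extend):  # pragma: no cover - jitted
    n = q.shape[0]
    m = s.shape[0]
    NEG = -(10 ** 9)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in query (horiz)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in subject (vert)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i, j - 1] - gap_open - gap_extend
            if E[i, j - 1] - gap_extend > e:
                e = E[i, j - 1] - gap_extend
            E[i, j] = e
            f = H[i - 1, j] - gap_open - gap_extend
            if F[i - 1, j] - gap_extend > f:
                f = F[i - 1, j] - gap_extend
            F[i, j] = f
            h = H[i - 1, j - 1] + sub[q[i - 1], s[j - 1]]
            if f > h:
                h = f
            if e > h:
                h = e
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    if best <= 0:
        return (0, 0, 0, 0, 0, 0, 0, 0, 0, 0)
    # traceback: prefer diagonal, then vertical (F), then horizontal (E);
    # inside a gap state prefer closing the gap over extending it
    i = bi
    j = bj
    identities = 0
    mismatches = 0
    gaps = 0
    gap_opens = 0
    length = 0
    state = 0  # 0 = H, 1 = E (horizontal), 2 = F (vertical)
    qend = bi
    send = bj
    while True:
        if state == 0:
            if H[i, j] == 0:
                break
            diag = H[i - 1, j - 1] + sub[q[i - 1], s[j - 1]]
            if H[i, j] == diag:
                length += 1
                if q[i - 1] == s[j - 1] and q[i - 1] != 23:
                    identities += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = 2
            else:
                state = 1
        elif state == 1:  # E: gap in query, consume s[j-1]
            length += 1
            gaps += 1
            closing = H[i, j - 1] - gap_open - gap_extend
            if E[i, j] == closing:
                gap_opens += 1
                state = 0
            # else stay in E (extend)
            j -= 1
        else:  # F: gap in subject, consume q[i-1]
            length += 1
            gaps += 1
            closing = H[i - 1, j] - gap_open - gap_extend
            if F[i, j] == closing:
                gap_opens += 1
                state = 0
            i -= 1
    qstart = i + 1
    sstart = j + 1
    return (best, identities, length, mismatches, gap_opens, gaps,
            qstart, qend, sstart, send)


def smith_waterman(query: str | np.ndarray, subject: str | np.ndarray,
                   scoring: ScoringScheme = ScoringScheme()) -> dict:
    """Locally align two peptides; returns score/identity/length and coords.

    Returns a dict with keys score, identities, length, identity, mismatches,
    gap_opens, gaps, qstart, qend, sstart, send (1-based inclusive aligned
    region); score 0 means no positive-scoring local alignment exists.
    """
    q = encode_peptide(query) if isinstance(query, str) else query
    s = encode_peptide(subject) if isinstance(subject, str) else subject
    if len(q) == 0 or len(s) == 0:
        return dict(score=0, identities=0, length=0, identity=0.0,
                    mismatches=0, gap_opens=0, gaps=0,
                    qstart=0, qend=0, sstart=0, send=0)
    res = _sw_kernel(q, s, scoring.matrix(),
                     np.int64(scoring.gap_open), np.int64(scoring.gap_extend))
    (score, identities, length, mismatches, gap_opens, gaps,
     qstart, qend, sstart, send) = (int(x) for x in res)
    identity = identities / length if length else 0.0
    return dict(score=score, identities=identities, length=length,
                identity=identity, mismatches=mismatches,
                gap_opens=gap_opens, gaps=gaps,
                qstart=qstart, qend=qend, sstart=sstart, send=send)


# ---------------------------------------------------------------------------
# seeded database search

class KmerIndex:
    """Exact k-mer index over the reference proteins for candidate seeding."""

    def __init__(self, refdb: ReferenceDB, k: int = 4):
        self.k = k
        self.refdb = refdb
        self.encoded = [encode_peptide(p.sequence) for p in refdb.proteins]
        self._index: dict[str, set[int]] = {}
        for pi, prot in enumerate(refdb.proteins):
            seq = prot.sequence
            for pos in range(len(seq) - k + 1):
                self._index.setdefault(seq[pos:pos + k], set()).add(pi)

    def candidates(self, peptide: str) -> list[int]:
        k = self.k
        found: set[int] = set()
        for pos in range(len(peptide) - k + 1):
            hit = self._index.get(peptide[pos:pos + k])
            if hit:
                found |= hit
        return sorted(found)


def align_translated(peptides: Iterable[PeptideFragment], refdb: ReferenceDB,
                     scoring: ScoringScheme = ScoringScheme(),
                     min_report: int = 20, exhaustive: bool = False,
                     index: KmerIndex | None = None,
                     seed_k: int = 4) -> list[AlignmentHit]:
    """Align frame peptides against the reference database.

    Candidates come from the shared-k-mer index unless ``exhaustive`` is set,
    in which case every subject is aligned (the oracle-verifiable path).
    Hits scoring below ``min_report`` are suppressed.
    """
    if len(refdb) == 0:
        raise ValueError("empty reference database")
    if index is None:
        index = KmerIndex(refdb, k=seed_k)
    hits: list[AlignmentHit] = []
    all_candidates = list(range(len(refdb)))
    for frag in peptides:
        if not frag.peptide:
            continue
        cand = (all_candidates if exhaustive
                else index.candidates(frag.peptide))
        if not cand:
            continue
        q = encode_peptide(frag.peptide)
        for pi in cand:
            prot = refdb.proteins[pi]
            res = smith_waterman(q, index.encoded[pi], scoring)
            if res["score"] < min_report or res["length"] == 0:
                continue
            hits.append(AlignmentHit(
                read_id=frag.read_id, subject=prot.accession,
                frame=frag.frame, identity=res["identity"],
                alignment_length=res["length"], score=res["score"],
                mismatches=res["mismatches"], gap_opens=res["gap_opens"],
                gaps=res["gaps"], qstart=res["qstart"], qend=res["qend"],
                sstart=res["sstart"], send=res["send"],
                families=tuple(prot.families)))
    return hits


def best_hit(hits: Sequence[AlignmentHit]) -> AlignmentHit | None:
    """The top hit for one read across all frames and subjects.

    Maximum by score, then identity, then alignment length; remaining ties go
    to the lexicographically smallest subject accession. Returns None for an
    empty input; the result is independent of input order.
    """
    if not hits:
        return None
    ids = {h.read_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"best_hit called on multiple reads: {sorted(ids)}")
    best = hits[0]
    for h in hits[1:]:
        key_h = (h.score, h.identity, h.alignment_length)
        key_b = (best.score, best.identity, best.alignment_length)
        if key_h > key_b or (key_h == key_b and h.subject < best.subject):
            best = h
    return best


def best_hits_per_read(hits: Iterable[AlignmentHit]) -> dict[str, AlignmentHit]:
    """Group hits by read and keep the best one per read."""
    grouped: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        grouped.setdefault(h.read_id, []).append(h)
    return {rid: best_hit(hs) for rid, hs in grouped.items()}


def search_reads(reads: Iterable[tuple[str, str]], refdb: ReferenceDB,
                 scoring: ScoringScheme = ScoringScheme(),
                 min_report: int = 20, exhaustive: bool = False,
                 seed_k: int = 4) -> dict[str, AlignmentHit]:
    """Six-frame translate DNA reads and return the best hit per read.

    ``reads`` are (read_id, dna) pairs; reads with no reportable hit are
    absent from the result.
    """
    index = KmerIndex(refdb, k=seed_k)
    result: dict[str, AlignmentHit] = {}
    for rid, dna in reads:
        frags = six_frame_translate(dna, rid)
        hits = align_translated(frags, refdb, scoring, min_report,
                                exhaustive, index=index)
        top = best_hit(hits) if hits else None
        if top is not None:
            result[rid] = top
    return result


# ---------------------------------------------------------------------------
# BLAST outfmt-6 compatible hit tables and the external-tool adapter

OUTFMT6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                   "gapopen", "qstart", "qend", "sstart", "send",
                   "evalue", "bitscore"]


def write_hits_tsv(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits in 12-column BLAST tabular order (evalue rendered NA)."""
    rows = [(h.read_id, h.subject, round(h.identity * 100, 2),
             h.alignment_length, h.mismatches, h.gap_opens, h.qstart,
             h.qend, h.sstart, h.send, "NA", h.score) for h in hits]
    pd.DataFrame(rows, columns=OUTFMT6_COLUMNS).to_csv(
        path, sep="\t", index=False, header=False)


def _hit_from_fields(fields: list[str],
                     refdb: ReferenceDB | None) -> AlignmentHit:
    families: tuple = ()
    subject = fields[1]
    if refdb is not None:
        try:
            families = tuple(refdb.families_of(subject))
        except KeyError:
            pass
    return AlignmentHit(
        read_id=fields[0], subject=subject, frame="?",
        identity=float(fields[2]) / 100.0, alignment_length=int(fields[3]),
        score=float(fields[11]), mismatches=int(fields[4]),
        gap_opens=int(fields[5]), qstart=int(fields[6]), qend=int(fields[7]),
        sstart=int(fields[8]), send=int(fields[9]), families=families)


def read_hits_tsv(path: str | Path,
                  refdb: ReferenceDB | None = None) -> list[AlignmentHit]:
    """Parse a 12-column BLAST tabular file; malformed rows are skipped."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                if len(fields) < 12:
                    raise ValueError("fewer than 12 columns")
                hits.append(_hit_from_fields(fields, refdb))
            except ValueError as exc:
                logger.warning("%s line %d unparsable (%s); skipped",
                               path, lineno, exc)
    return hits


def external_search_adapter(command_template: str, reads_fasta: str | Path,
                            db_fasta: str | Path, out_path: str | Path,
                            refdb: ReferenceDB | None = None
                            ) -> list[AlignmentHit]:
    """Run an external translated-search tool and parse its tabular output.

    ``command_template`` uses ``{reads}``, ``{db}`` and ``{out}`` placeholders
    and must produce 12-column BLAST-tabular output at ``{out}``. A nonzero
    exit status is fatal with the captured stderr.
    """
    cmd = command_template.format(reads=reads_fasta, db=db_fasta,
                                  out=out_path)
    proc = subprocess.run(shlex.split(cmd), capture_output=True, text=True)
    if proc.returncode != 0:
        raise RuntimeError(
            f"external search failed (exit {proc.returncode}): {proc.stderr}")
    return read_hits_tsv(out_path, refdb)


def read_fasta_reads(path: str | Path) -> list[tuple[str, str]]:
    """Load reads from FASTA or FASTQ as (read_id, dna) pairs."""
    fmt = "fastq" if str(path).endswith(("fastq", "fq")) else "fasta"
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), fmt)]
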