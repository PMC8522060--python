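"""Apply the calibrated scheme to metagenome reads.

Each read is six-frame translated, searched against the reference database,
and called glycan-related when its best hit clears the operating point
(default identity > 0.90 and alignment length > 25 aa). Identified reads are
annotated with the top hit's families and CAZy classes, and flagged as exact
matches when the aligned region is gapless and 100% identical — such reads
correspond to genes already present in the reference database.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .benchmark import classify_read
from .refdb import FamilyCode, ReferenceDB
from .search import (AlignmentHit, ScoringScheme, read_fasta_reads,
                     search_reads)

logger = logging.getLogger(__name__)

DEFAULT_ID_THR = 0.90
DEFAULT_LEN_THR = 25


@dataclass(frozen=True)
class IdentifiedRead:
    read_id: str
    subject: str
    families: tuple
    classes: tuple
    identity: float
    alignment_length: int
    exact_match: bool


@dataclass
class SampleResult:
    sample_id: str
    total_reads: int
    identified: list[IdentifiedRead]

    def __post_init__(self) -> None:
        if len(self.identified) > self.total_reads:
            raise ValueError("more identified reads than total reads")

    @property
    def ratio(self) -> float:
        return len(self.identified) / self.total_reads if self.total_reads else 0.0


def flag_exact(hit: AlignmentHit) -> bool:
    """True iff the aligned region is 100% identical with no gaps."""
    return hit.identity == 1.0 and hit.gaps == 0


def _to_identified(hit: AlignmentHit) -> IdentifiedRead:
    classes = tuple(dict.fromkeys(f.cazy_class for f in hit.families))
    return IdentifiedRead(
        read_id=hit.read_id, subject=hit.subject,
        families=tuple(str(f) for f in hit.families), classes=classes,
        identity=hit.identity, alignment_length=hit.alignment_length,
        exact_match=flag_exact(hit))


def identify_sample(reads: Iterable[tuple[str, str]] | str | Path,
                    refdb: ReferenceDB, id_thr: float = DEFAULT_ID_THR,
                    len_thr: int = DEFAULT_LEN_THR,
                    scoring: ScoringScheme = ScoringScheme(),
                    sample_id: str = "sample",
                    best_hits: dict[str, AlignmentHit] | None = None,
                    **search_kwargs) -> SampleResult:
    """Identify glycan-related reads in one sample.

    ``reads`` is a list of (read_id, dna) pairs or a FASTA/FASTQ path. Each
    read contributes at most one identification: its best hit across all six
    frames, kept only when it clears both thresholds strictly.
    Pre-computed ``best_hits`` (e.g. from an external search tool) skip the
    internal alignment.
    """
    if isinstance(reads, (str, Path)):
        reads = read_fasta_reads(reads)
    else:
        reads = list(reads)
    if not reads:
        raise ValueError(f"sample {sample_id}: no reads")
    if best_hits is None:
        best_hits = search_reads(reads, refdb, scoring, **search_kwargs)
    identified = [
        _to_identified(hit)
        for rid, _ in reads
        if (hit := best_hits.get(rid)) is not None
        and classify_read(hit, id_thr, len_thr)
    ]
    return SampleResult(sample_id, total_reads=len(reads),
                        identified=identified)


def write_sample_result(result: SampleResult, path: str | Path) -> None:
    """Per-sample TSV: read_id, subject, families, classes, identity,
    length, exact."""
    rows = [(r.read_id, r.subject, ";".join(r.families), ";".join(r.classes),
             round(r.identity, 6), r.alignment_length, r.exact_match)
            for r in result.identified]
    df = pd.DataFrame(rows, columns=["read_id", "subject", "families",
                                     "classes", "identity", "length",
                                     "exact"])
    with open(path, "w") as fh:
        fh.write(f"# sample_id={result.sample_id} "
                 f"total_reads={result.total_reads}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_sample_result(path: str | Path) -> SampleResult:
    """Round-trip reader for :func:`write_sample_result` output."""
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(tok.split("=") for tok in header.lstrip("# ").split())
        df = pd.read_csv(fh, sep="\t")
    identified = [
        IdentifiedRead(
            read_id=str(row.read_id), subject=str(row.subject),
            families=tuple(str(row.families).split(";")) if pd.notna(row.families) else (),
            classes=tuple(str(row.classes).split(";")) if pd.notna(row.classes) else (),
            identity=float(row.identity),
            alignment_length=int(row.length),
            exact_match=bool(row.exact))
        for row in df.itertuples()
    ]
    return SampleResult(meta["sample_id"], int(meta["total_reads"]),
                        identified)
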