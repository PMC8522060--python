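"""CAZyme reference database: parsing, deduplication, family/substrate lookup.

The reference database is a protein FASTA in which each record header carries
one or more CAZy family codes (dbCAN-style, e.g. ``>AAB12345|GH13|CBM48``).
Families belong to one of six CAZy classes: glycoside hydrolases (GH),
glycosyltransferases (GT), polysaccharide lyases (PL), carbohydrate esterases
(CE), carbohydrate-binding modules (CBM) and auxiliary activities (AA).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The six CAZy classes, in conventional display order.
CAZY_CLASSES = ("GH", "GT", "PL", "CE", "CBM", "AA")

#: Valid substrate categories for the family -> substrate table.
SUBSTRATE_CLASSES = (
    "monosaccharide",
    "disaccharide",
    "oligosaccharide",
    "polysaccharide",
    "peptidoglycan-related",
    "other",
)

_FAMILY_RE = re.compile(r"^(GH|GT|PL|CE|CBM|AA)(\d+)(?:_(\w+))?$")


@dataclass(frozen=True, order=True)
class FamilyCode:
    """A CAZy family code such as GH13, GT2 or GH5_4 (with subfamily)."""

    class_prefix: str
    number: int
    subfamily: str | None = None

    def __post_init__(self) -> None:
        if self.class_prefix not in CAZY_CLASSES:
            raise ValueError(f"unknown CAZy class prefix in family code: "
                             f"{self.class_prefix}{self.number}")
        if self.number <= 0:
            raise ValueError(f"family number must be positive: {self.number}")

    @classmethod
    def parse(cls, text: str) -> "FamilyCode":
        m = _FAMILY_RE.match(text.strip())
        if m is None:
            raise ValueError(f"not a valid CAZy family code: {text!r}")
        prefix, number, sub = m.groups()
        return cls(prefix, int(number), sub)

    @property
    def cazy_class(self) -> str:
        """The CAZy class this family belongs to (equals the prefix)."""
        return self.class_prefix

    def __str__(self) -> str:
        base = f"{self.class_prefix}{self.number}"
        return f"{base}_{self.subfamily}" if self.subfamily else base


def family_class(code: FamilyCode | str) -> str:
    """Resolve a family code to its CAZy class; raises on unknown prefixes."""
    if isinstance(code, str):
        code = FamilyCode.parse(code)
    return code.cazy_class


@dataclass
class ReferenceProtein:
    accession: str
    families: list[FamilyCode]
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.accession}")
        if not self.families:
            raise ValueError(f"no family codes for {self.accession}")
        self.sequence = self.sequence.upper()


@dataclass
class ReferenceDB:
    """A collection of family-annotated reference proteins.

    Accession lookup is exact; after :func:`deduplicate` no two proteins share
    an identical amino-acid sequence.
    """

    proteins: list[ReferenceProtein]
    source_note: str = ""
    dedup_count: int = 0
    skipped_records: int = 0
    _by_accession: dict[str, ReferenceProtein] = field(
        default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._by_accession = {p.accession: p for p in self.proteins}
        if len(self._by_accession) != len(self.proteins):
            raise ValueError("duplicate accessions in reference database")

    def __len__(self) -> int:
        return len(self.proteins)

    def __iter__(self):
        return iter(self.proteins)

    def get(self, accession: str) -> ReferenceProtein:
        return self._by_accession[accession]

    def families_of(self, accession: str) -> list[FamilyCode]:
        return self.get(accession).families


def _default_header_rule(header: str) -> tuple[str, list[FamilyCode]]:
    """Parse ``accession|FAM1|FAM2...`` headers.

    The first ``|``-separated token is the accession; every remaining token
    that parses as a family code is kept. Raises ValueError when no token
    yields a family code.
    """
    tokens = header.split()[0].split("|")
    accession = tokens[0]
    families = []
    for tok in tokens[1:]:
        try:
            families.append(FamilyCode.parse(tok))
        except ValueError:
            continue
    if not accession or not families:
        raise ValueError(f"header yields no accession/family: {header!r}")
    return accession, families


def parse_reference_fasta(path: str | Path, header_rule=None) -> ReferenceDB:
    """Read a reference protein FASTA into a :class:`ReferenceDB`.

    ``header_rule`` is a callable ``header -> (accession, [FamilyCode])``;
    records for which it raises ValueError are skipped (and counted in
    ``skipped_records``). An unreadable file or a file with zero parsable
    records is fatal.
    """
    rule = header_rule or _default_header_rule
    proteins: list[ReferenceProtein] = []
    skipped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        try:
            accession, families = rule(header)
            proteins.append(
                ReferenceProtein(accession, families, str(rec.seq)))
        except ValueError as exc:
            skipped += 1
            logger.warning("skipping record: %s", exc)
    if not proteins:
        raise ValueError(f"no parsable reference records in {path}")
    return ReferenceDB(proteins, source_note=str(path),
                       skipped_records=skipped)


def deduplicate(db: ReferenceDB) -> ReferenceDB:
    """Collapse exact duplicate sequences (case-normalised to upper).

    The first occurrence in input order is kept; family codes of dropped
    duplicates are merged into the keeper (order-preserving, unique).
    Idempotent.
    """
    keepers: dict[str, ReferenceProtein] = {}
    order: list[str] = []
    removed = 0
    for prot in db.proteins:
        seq = prot.sequence.upper()
        if seq in keepers:
            removed += 1
            keeper = keepers[seq]
            merged = list(keeper.families)
            for fam in prot.families:
                if fam not in merged:
                    merged.append(fam)
            keeper.families = merged
        else:
            keeper = ReferenceProtein(prot.accession, list(prot.families), seq)
            keepers[seq] = keeper
            order.append(seq)
    return ReferenceDB([keepers[s] for s in order],
                       source_note=db.source_note,
                       dedup_count=db.dedup_count + removed,
                       skipped_records=db.skipped_records)


def write_reference_fasta(db: ReferenceDB, fasta_path: str | Path,
                          index_path: str | Path | None = None) -> None:
    """Write a normalised reference FASTA plus an optional TSV index."""
    records = [
        SeqRecord(Seq(p.sequence),
                  id="|".join([p.accession] + [str(f) for f in p.families]),
                  description="")
        for p in db.proteins
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if index_path is not None:
        rows = [(p.accession, ";".join(str(f) for f in p.families),
                 len(p.sequence)) for p in db.proteins]
        pd.DataFrame(rows, columns=["accession", "families", "length"]).to_csv(
            index_path, sep="\t", index=False)


class SubstrateTable:
    """Family -> substrate category mapping with an ``other`` fallback.

    Lookups of families absent from the table resolve to ``"other"`` with a
    logged warning, so downstream enrichment statistics never fail on an
    unannotated family.
    """

    def __init__(self, mapping: dict[FamilyCode, str]):
        for fam, cls in mapping.items():
            if cls not in SUBSTRATE_CLASSES:
                raise ValueError(
                    f"invalid substrate class {cls!r} for family {fam}")
        self._mapping = dict(mapping)
        self.fallback_warnings: list[str] = []

    def __len__(self) -> int:
        return len(self._mapping)

    def __contains__(self, family) -> bool:
        return self._coerce(family) in self._mapping

    @staticmethod
    def _coerce(family) -> FamilyCode:
        return FamilyCode.parse(family) if isinstance(family, str) else family

    def lookup(self, family: FamilyCode | str) -> str:
        fam = self._coerce(family)
        if fam not in self._mapping:
            msg = f"family {fam} has no substrate entry; using 'other'"
            logger.warning(msg)
            self.fallback_warnings.append(msg)
            return "other"
        return self._mapping[fam]


def load_substrate_table(path: str | Path) -> SubstrateTable:
    """Load a two-column ``family<TAB>substrate_class`` TSV (with header)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"substrate table {path} needs two columns")
    mapping: dict[FamilyCode, str] = {}
    for lineno, (fam_text, cls) in enumerate(
            zip(df.iloc[:, 0], df.iloc[:, 1]), start=2):
        cls = str(cls).strip()
        if cls not in SUBSTRATE_CLASSES:
            raise ValueError(
                f"{path} line {lineno}: invalid substrate class {cls!r}")
        mapping[FamilyCode.parse(str(fam_text))] = cls
    return SubstrateTable(mapping)
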