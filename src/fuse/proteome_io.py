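"""Protein catalog construction from Ensembl-style peptide FASTA files.

The catalog is the registry every later stage keys off: it resolves BLAST
accessions to transcripts, supplies the sequence lengths used by the coverage
term of the confidence scores, and records the biotype-based kept/excluded
partition. Excluded transcripts (nonsense-mediated decay, polymorphic
pseudogenes, T-cell receptor and immunoglobulin gene biotypes by default) are
withheld from pairing and grouping but carried forward so the expression stage
can pass them through with their original values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "ProteinCatalog",
    "PairOrigin",
    "DEFAULT_BIOTYPE_EXCLUSIONS",
    "parse_protein_fasta",
    "filter_by_biotype",
    "categorize_pair",
]

#: Transcript biotypes removed before pair formation. ``TR_*`` and ``IG_*``
#: prefixes cover the T-cell receptor and immunoglobulin gene biotypes.
DEFAULT_BIOTYPE_EXCLUSIONS = frozenset(
    {
        "nonsense_mediated_decay",
        "non_sense_mediated_decay",
        "polymorphic_pseudogene",
        "TR_*",
        "IG_*",
    }
)


class PairOrigin(str, Enum):
    """Origin category of a protein pair, judged from gene symbols alone."""

    SAME_GENE = "same_gene"
    SAME_GENE_FAMILY = "same_gene_family"
    DIFFERENT_GENE_FAMILY = "different_gene_family"
    UNDEFINED = "undefined"


@dataclass(frozen=True)
class ProteinRecord:
    """One peptide entry: identifiers, biotype and residue count."""

    protein_id: str
    transcript_id: str
    gene_id: str
    gene_symbol: str | None
    transcript_biotype: str
    seq_length: int

    def __post_init__(self) -> None:
        if self.seq_length < 1:
            raise ValueError(
                f"seq_length must be >= 1 for {self.protein_id}, got {self.seq_length}"
            )


@dataclass
class ProteinCatalog:
    """Kept/excluded partition of the parsed proteome."""

    records: list[ProteinRecord] = field(default_factory=list)
    excluded: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_protein: dict[str, ProteinRecord] = {}
        self._by_transcript: dict[str, ProteinRecord] = {}
        for rec in [*self.records, *self.excluded]:
            if rec.protein_id in self._by_protein:
                raise ValueError(f"duplicate protein accession: {rec.protein_id}")
            if rec.transcript_id in self._by_transcript:
                raise ValueError(f"duplicate transcript accession: {rec.transcript_id}")
            self._by_protein[rec.protein_id] = rec
            self._by_transcript[rec.transcript_id] = rec

    def by_protein_id(self, protein_id: str) -> ProteinRecord:
        return self._by_protein[protein_id]

    def by_transcript_id(self, transcript_id: str) -> ProteinRecord:
        return self._by_transcript[transcript_id]

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._by_protein

    def __len__(self) -> int:
        return len(self.records) + len(self.excluded)

    @property
    def kept_transcript_ids(self) -> list[str]:
        return [r.transcript_id for r in self.records]

    @property
    def excluded_transcript_ids(self) -> list[str]:
        return [r.transcript_id for r in self.excluded]

    def to_table(self):
        """Catalog metadata as a DataFrame (kept|excluded status column)."""
        import pandas as pd

        rows = []
        for status, recs in (("kept", self.records), ("excluded", self.excluded)):
            for r in recs:
                rows.append(
                    {
                        "protein_id": r.protein_id,
                        "transcript_id": r.transcript_id,
                        "gene_id": r.gene_id,
                        "gene_symbol": r.gene_symbol or "",
                        "transcript_biotype": r.transcript_biotype,
                        "seq_length": r.seq_length,
                        "status": status,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "protein_id",
                "transcript_id",
                "gene_id",
                "gene_symbol",
                "transcript_biotype",
                "seq_length",
                "status",
            ],
        )


_ATTR_RE = re.compile(r"(\w+):(\S+)")


def _parse_header(description: str) -> dict[str, str]:
    return {m.group(1): m.group(2) for m in _ATTR_RE.finditer(description)}


def parse_protein_fasta(path: str | Path) -> ProteinCatalog:
    """Parse an Ensembl-dialect peptide FASTA into an (unfiltered) catalog.

    Headers must carry ``transcript:`` and ``transcript_biotype:`` attributes;
    ``gene:`` and ``gene_symbol:`` are picked up when present. A trailing stop
    codon ``*`` is stripped before the residue count; an internal ``*`` is an
    error since such a length would corrupt the coverage term downstream.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    n = 0
    for entry in SeqIO.parse(str(path), "fasta"):
        n += 1
        attrs = _parse_header(entry.description)
        protein_id = entry.id
        for required in ("transcript", "transcript_biotype"):
            if required not in attrs:
                raise ValueError(
                    f"missing '{required}:' attribute in header: >{entry.description}"
                )
        seq = str(entry.seq)
        if seq.endswith("*"):
            seq = seq[:-1]
        if "*" in seq:
            raise ValueError(
                f"internal stop codon in sequence of {protein_id}: >{entry.description}"
            )
        if not seq:
            raise ValueError(f"empty sequence for {protein_id}")
        records.append(
            ProteinRecord(
                protein_id=protein_id,
                transcript_id=attrs["transcript"],
                gene_id=attrs.get("gene", ""),
                gene_symbol=attrs.get("gene_symbol"),
                transcript_biotype=attrs["transcript_biotype"],
                seq_length=len(seq),
            )
        )
    if n == 0:
        raise ValueError(f"no FASTA entries found in {path}")
    return ProteinCatalog(records=records)


def _biotype_excluded(biotype: str, exclusions: Iterable[str]) -> bool:
    b = biotype.lower()
    for pattern in exclusions:
        p = pattern.lower()
        if p.endswith("*"):
            if b.startswith(p[:-1]):
                return True
        elif b == p:
            return True
    return False


def filter_by_biotype(
    catalog: ProteinCatalog,
    exclusions: Iterable[str] = DEFAULT_BIOTYPE_EXCLUSIONS,
) -> ProteinCatalog:
    """Partition the catalog by transcript biotype (case-insensitive, ``*`` glob).

    Excluded records stay in the catalog object so the expression stage can
    emit them as passthrough rows with their original values.
    """
    exclusions = list(exclusions)
    kept: list[ProteinRecord] = []
    dropped: list[ProteinRecord] = []
    for rec in [*catalog.records, *catalog.excluded]:
        if _biotype_excluded(rec.transcript_biotype, exclusions):
            dropped.append(rec)
        else:
            kept.append(rec)
    return ProteinCatalog(records=kept, excluded=dropped)


# Clone-style accessions (e.g. AC012345.1) and bare numbers carry no family
# information, so pairs touching them are uncategorizable.
_CLONE_RE = re.compile(r"^[A-Za-z]+\d+\.\d+$")
_NUMERIC_RE = re.compile(r"^\d+$")
# Trailing "-digits" is an Ensembl transcript-name suffix, not family structure.
_TRANSCRIPT_SUFFIX_RE = re.compile(r"-\d+$")
# Family stem: strip trailing digits plus one optional member letter
# (UBE2D1 -> UBE2D; HIST1H1A -> HIST1H, matching HIST1H1E).
_FAMILY_TAIL_RE = re.compile(r"\d+[A-Z]?$")


def _is_undefined_symbol(symbol: str | None) -> bool:
    if not symbol:
        return True
    return bool(_CLONE_RE.match(symbol) or _NUMERIC_RE.match(symbol))


def family_stem(symbol: str) -> str:
    """Family stem of a gene symbol: upper-cased, transcript suffix and the
    trailing member designation (optional letter + digits) removed."""
    s = _TRANSCRIPT_SUFFIX_RE.sub("", symbol.upper())
    return _FAMILY_TAIL_RE.sub("", s)


def categorize_pair(symbol_a: str | None, symbol_b: str | None) -> PairOrigin:
    """Classify a protein pair's origin from the two gene symbols.

    Symmetric in its arguments. Pairs with an absent or bare clone/numeric
    symbol are ``undefined``; equal symbols are ``same_gene``; equal non-empty
    family stems are ``same_gene_family``; anything else is
    ``different_gene_family``.
    """
    if _is_undefined_symbol(symbol_a) or _is_undefined_symbol(symbol_b):
        return PairOrigin.UNDEFINED
    a, b = symbol_a.upper(), symbol_b.upper()  # type: ignore[union-attr]
    if a == b:
        return PairOrigin.SAME_GENE
    stem_a, stem_b = family_stem(a), family_stem(b)
    if stem_a and stem_a == stem_b:
        return PairOrigin.SAME_GENE_FAMILY
    return PairOrigin.DIFFERENT_GENE_FAMILY
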