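"""Reduce all-vs-all BLAST+ tabular hits to one feature record per pair.

Standard ``outfmt 6`` carries twelve columns; only percent identity, alignment
length and the gap-opening count feed the confidence scores. Sequence lengths
come from the protein catalog rather than from BLAST, since plain format 6
does not include qlen/slen. Reciprocal hits and multiple HSPs are collapsed to
the single best-scoring hit per unordered pair so the pair table is
orientation-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .proteome_io import ProteinCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "BlastHit",
    "AlignmentFeatures",
    "read_blast_tab",
    "best_hit_per_pair",
    "to_features",
    "features_table",
]

OUTFMT6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_id: str
    pident: float
    aln_length: int
    gap_count: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.aln_length < 1:
            raise ValueError(f"alignment length must be >= 1, got {self.aln_length}")
        if not 0.0 <= self.pident <= 100.0:
            raise ValueError(f"pident out of [0, 100]: {self.pident}")


@dataclass(frozen=True)
class AlignmentFeatures:
    """Symmetric per-pair alignment features; lengths are catalog lengths."""

    id_a: str
    id_b: str
    pident: float
    aln_length: int
    gap_count: int
    len_a: int
    len_b: int

    @property
    def pair(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def read_blast_tab(
    path: str | Path,
    catalog: ProteinCatalog,
    gap_column: str = "gapopen",
) -> list[BlastHit]:
    """Parse BLAST+ ``outfmt 6`` output, dropping self-hits.

    Extra trailing columns are tolerated. Hits whose query or subject is not
    in the catalog are skipped (count logged). ``gap_column`` selects which
    column provides the gap count; the default is the gap-opening column that
    plain format 6 always carries, but an extended ``gaps`` column (13th) can
    be named instead.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 12:
        raise ValueError(
            f"{path}: expected >= 12 tab-separated columns, found {df.shape[1]}"
        )
    names = list(OUTFMT6_COLUMNS)
    if df.shape[1] > 12:
        names += ["gaps"] + [f"extra{i}" for i in range(df.shape[1] - 13)]
    df.columns = names[: df.shape[1]]
    if gap_column not in df.columns:
        raise ValueError(f"gap column {gap_column!r} not present in {path}")

    hits: list[BlastHit] = []
    n_unresolved = 0
    n_self = 0
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        q, s = d["qseqid"], d["sseqid"]
        if q == s:
            n_self += 1
            continue
        if q not in catalog or s not in catalog:
            n_unresolved += 1
            continue
        try:
            hit = BlastHit(
                query_id=q,
                subject_id=s,
                pident=float(d["pident"]),
                aln_length=int(d["length"]),
                gap_count=int(d[gap_column]),
                evalue=float(d["evalue"]),
                bitscore=float(d["bitscore"]),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {i}: {exc}") from exc
        hits.append(hit)
    if n_unresolved:
        logger.info("%s: skipped %d hits with IDs not in catalog", path, n_unresolved)
    if n_self:
        logger.debug("%s: dropped %d self-hits", path, n_self)
    return hits


def best_hit_per_pair(hits: list[BlastHit]) -> dict[tuple[str, str], BlastHit]:
    """One hit per unordered pair: max bitscore, then min evalue, then max
    pident, then first occurrence."""
    best: dict[tuple[str, str], tuple[tuple[float, float, float, int], BlastHit]] = {}
    for i, hit in enumerate(hits):
        key = _canonical(hit.query_id, hit.subject_id)
        # Sort key: larger is better; -evalue and -i invert the minima.
        rank = (hit.bitscore, -hit.evalue, hit.pident, -i)
        if key not in best or rank > best[key][0]:
            best[key] = (rank, hit)
    return {key: hit for key, (rank, hit) in best.items()}


def to_features(hit: BlastHit, catalog: ProteinCatalog) -> AlignmentFeatures:
    """Attach catalog sequence lengths to a hit, canonicalizing pair order."""
    a, b = _canonical(hit.query_id, hit.subject_id)
    return AlignmentFeatures(
        id_a=a,
        id_b=b,
        pident=hit.pident,
        aln_length=hit.aln_length,
        gap_count=hit.gap_count,
        len_a=catalog.by_protein_id(a).seq_length,
        len_b=catalog.by_protein_id(b).seq_length,
    )


def features_table(
    path: str | Path, catalog: ProteinCatalog, gap_column: str = "gapopen"
) -> pd.DataFrame:
    """Full reduction: BLAST file -> one-row-per-pair feature DataFrame."""
    hits = read_blast_tab(path, catalog, gap_column=gap_column)
    per_pair = best_hit_per_pair(hits)
    feats = [to_features(hit, catalog) for hit in per_pair.values()]
    df = pd.DataFrame(
        [
            {
                "id_a": f.id_a,
                "id_b": f.id_b,
                "pident": f.pident,
                "aln_length": f.aln_length,
                "gap_count": f.gap_count,
                "len_a": f.len_a,
                "len_b": f.len_b,
            }
            for f in feats
        ],
        columns=["id_a", "id_b", "pident", "aln_length", "gap_count", "len_a", "len_b"],
    )
    return df.sort_values(["id_a", "id_b"], ignore_index=True)
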