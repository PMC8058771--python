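"""Ordered domain-architecture profiles from InterProScan TSV output.

Each InterPro member-database analysis ("tool") predicts signatures with
residue coordinates. Per protein and per tool, signatures are ordered along
the sequence; two proteins' ordered lists are then compared per tool and
labeled with one of five levels:

- ``STONM`` — same type, order and number of motifs (lists identical);
- ``STNM``  — same type and number (equal as multisets, order lost);
- ``STM``   — same type only (equal distinct-signature sets);
- ``NM``    — no match;
- ``NP``    — not present: no prediction by that tool for at least one
  protein of the pair (covers the both-empty case too).

The labels form a strict hierarchy: exactly one applies to any pair of lists.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_TOOLS",
    "ComparisonLabel",
    "DomainAnnotation",
    "DomainProfile",
    "PairDomainComparison",
    "read_interpro_tsv",
    "build_profiles",
    "compare_tool_profiles",
    "compare_pair",
]

#: The 14 member-database analyses of InterProScan 5.31-70.0. Sequence-feature
#: analyses (Coils, MobiDBLite, ...) are not part of the roster.
DEFAULT_TOOLS: tuple[str, ...] = (
    "CDD",
    "Gene3D",
    "Hamap",
    "PANTHER",
    "Pfam",
    "PIRSF",
    "PRINTS",
    "ProDom",
    "ProSitePatterns",
    "ProSiteProfiles",
    "SFLD",
    "SMART",
    "SUPERFAMILY",
    "TIGRFAM",
)


class ComparisonLabel(str, Enum):
    STONM = "STONM"
    STNM = "STNM"
    STM = "STM"
    NM = "NM"
    NP = "NP"


@dataclass(frozen=True)
class DomainAnnotation:
    """One signature match: 1-based inclusive residue coordinates."""

    protein_id: str
    tool: str
    signature_id: str
    start: int
    stop: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.stop:
            raise ValueError(
                f"bad coordinates for {self.protein_id}/{self.signature_id}: "
                f"{self.start}-{self.stop}"
            )


@dataclass
class DomainProfile:
    """Per-tool ordered signature lists for one protein."""

    protein_id: str
    per_tool: dict[str, list[str]] = field(default_factory=dict)

    def signatures(self, tool: str) -> list[str]:
        return self.per_tool.get(tool, [])


@dataclass(frozen=True)
class PairDomainComparison:
    """One comparison label per configured tool for an unordered pair."""

    id_a: str
    id_b: str
    labels: tuple[ComparisonLabel, ...]
    tools: tuple[str, ...]

    def label_for(self, tool: str) -> ComparisonLabel:
        return self.labels[self.tools.index(tool)]

    @property
    def all_np(self) -> bool:
        return all(lab is ComparisonLabel.NP for lab in self.labels)


def read_interpro_tsv(
    path: str | Path,
    tools: tuple[str, ...] = DEFAULT_TOOLS,
) -> list[DomainAnnotation]:
    """Parse InterProScan TSV rows into annotations.

    Columns used (1-based): 1 protein accession, 4 analysis, 5 signature
    accession, 7 start, 8 stop. Rows from analyses outside ``tools`` are
    ignored with a logged count; exact duplicates are collapsed.
    """
    path = Path(path)
    tool_set = set(tools)
    seen: set[DomainAnnotation] = set()
    out: list[DomainAnnotation] = []
    n_ignored = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise ValueError(f"{path}: line {lineno}: fewer than 8 columns")
            tool = cols[3]
            if tool not in tool_set:
                n_ignored += 1
                continue
            try:
                start, stop = int(cols[6]), int(cols[7])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start > stop:
                raise ValueError(f"{path}: line {lineno}: start > stop")
            ann = DomainAnnotation(
                protein_id=cols[0],
                tool=tool,
                signature_id=cols[4],
                start=start,
                stop=stop,
            )
            if ann not in seen:
                seen.add(ann)
                out.append(ann)
    if n_ignored:
        logger.info("%s: ignored %d rows from unconfigured analyses", path, n_ignored)
    return out


def build_profiles(
    annotations: list[DomainAnnotation],
    proteins: set[str] | list[str],
    tools: tuple[str, ...] = DEFAULT_TOOLS,
) -> dict[str, DomainProfile]:
    """Ordered profiles per protein: signatures sorted by (start, stop, id).

    Every protein in ``proteins`` gets a profile, empty lists included, so
    unannotated proteins compare as NP everywhere.
    """
    buckets: dict[tuple[str, str], list[DomainAnnotation]] = {}
    for ann in annotations:
        buckets.setdefault((ann.protein_id, ann.tool), []).append(ann)
    profiles: dict[str, DomainProfile] = {}
    for pid in proteins:
        per_tool: dict[str, list[str]] = {}
        for tool in tools:
            anns = buckets.get((pid, tool), [])
            anns.sort(key=lambda a: (a.start, a.stop, a.signature_id))
            per_tool[tool] = [a.signature_id for a in anns]
        profiles[pid] = DomainProfile(protein_id=pid, per_tool=per_tool)
    return profiles


def compare_tool_profiles(list_a: list[str], list_b: list[str]) -> ComparisonLabel:
    """Label two ordered signature lists; NP if either is empty."""
    if not list_a or not list_b:
        return ComparisonLabel.NP
    if list_a == list_b:
        return ComparisonLabel.STONM
    if Counter(list_a) == Counter(list_b):
        return ComparisonLabel.STNM
    if set(list_a) == set(list_b):
        return ComparisonLabel.STM
    return ComparisonLabel.NM


def compare_pair(
    profile_a: DomainProfile,
    profile_b: DomainProfile,
    tools: tuple[str, ...] = DEFAULT_TOOLS,
) -> PairDomainComparison:
    """Per-tool comparison of two profiles built over the same tool list."""
    for p in (profile_a, profile_b):
        missing = [t for t in tools if t not in p.per_tool]
        if missing:
            raise ValueError(
                f"profile for {p.protein_id} lacks tools {missing}; "
                "profiles must be built over the comparison tool list"
            )
    id_a, id_b = sorted((profile_a.protein_id, profile_b.protein_id))
    labels = tuple(
        compare_tool_profiles(profile_a.signatures(t), profile_b.signatures(t))
        for t in tools
    )
    return PairDomainComparison(id_a=id_a, id_b=id_b, labels=labels, tools=tuple(tools))


def comparisons_table(comparisons: list[PairDomainComparison]) -> pd.DataFrame:
    """Pair-labels DataFrame: pair ids plus one column per tool."""
    if not comparisons:
        return pd.DataFrame(columns=["id_a", "id_b"])
    tools = comparisons[0].tools
    rows = []
    for c in comparisons:
        row = {"id_a": c.id_a, "id_b": c.id_b}
        row.update({t: lab.value for t, lab in zip(c.tools, c.labels)})
        rows.append(row)
    return pd.DataFrame(rows, columns=["id_a", "id_b", *tools]).sort_values(
        ["id_a", "id_b"], ignore_index=True
    )
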