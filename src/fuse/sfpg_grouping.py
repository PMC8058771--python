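"""Similar Function Protein Group (SFPG) formation from scored pairs.

One SFPG is seeded per transcript: its members are the seed plus every
transcript whose pair score with the seed meets the confidence-score cutoff
(CSC). Groups are deliberately per-seed neighborhoods, not connected
components — merging overlapping neighborhoods would pool transcripts that
are each similar to the seed but not to one another, creating false-positive
groups and erasing specialized functions. A transcript can therefore belong
to several (possibly identical) groups; the member -> groups index drives the
downstream expression redistribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .proteome_io import PairOrigin, ProteinCatalog, categorize_pair

__all__ = [
    "SFPG",
    "SFPGSet",
    "build_groups",
    "group_stats",
    "categorize_pairs_report",
]


@dataclass(frozen=True)
class SFPG:
    """A seed transcript and all transcripts scoring >= CSC against it."""

    group_id: str  # the seed transcript id
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.group_id not in self.members:
            raise ValueError(f"seed {self.group_id} must be one of its own members")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class SFPGSet:
    """All groups at one cutoff plus the inverse member -> group-ids index."""

    groups: list[SFPG]
    cutoff_used: int
    score_type: str
    membership: dict[str, list[str]] = field(init=False)

    def __post_init__(self) -> None:
        index: dict[str, list[str]] = {}
        for g in self.groups:
            for m in g.members:
                index.setdefault(m, []).append(g.group_id)
        for ids in index.values():
            ids.sort()
        self.membership = index
        self._by_id = {g.group_id: g for g in self.groups}

    def group(self, group_id: str) -> SFPG:
        return self._by_id[group_id]

    def n_groups_of(self, member: str) -> int:
        return len(self.membership[member])

    def groups_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group_id": g.group_id,
                    "size": g.size,
                    "members": ",".join(sorted(g.members)),
                }
                for g in self.groups
            ],
            columns=["group_id", "size", "members"],
        ).sort_values("group_id", ignore_index=True)

    def membership_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "transcript_id": t,
                    "n_groups": len(ids),
                    "group_ids": ",".join(ids),
                }
                for t, ids in sorted(self.membership.items())
            ],
            columns=["transcript_id", "n_groups", "group_ids"],
        )


def _qualifying_pairs(
    scores: pd.DataFrame, csc: int, score_type: str
) -> pd.DataFrame:
    if score_type not in ("DS", "KS"):
        raise ValueError(f"score_type must be 'DS' or 'KS', got {score_type!r}")
    return scores[scores[score_type] >= csc]


def build_groups(
    scores: pd.DataFrame,
    csc: int,
    score_type: str = "KS",
    universe: Iterable[str] | None = None,
    id_map: Mapping[str, str] | None = None,
    dedup: bool = False,
) -> SFPGSet:
    """Form per-seed SFPGs at cutoff ``csc`` over ``universe`` transcripts.

    ``scores`` is the pair-score table (id_a, id_b, DS, KS). ``id_map``
    optionally translates the score table's protein ids to transcript ids.
    Every universe transcript seeds a group; transcripts with no qualifying
    partner yield singletons, so redistribution later covers the whole
    universe. With ``dedup``, groups with identical member sets collapse to
    one, keeping the lexicographically smallest seed as id.
    """
    if not 1 <= csc <= 100:
        raise ValueError(f"CSC must be a positive integer <= 100, got {csc}")
    qual = _qualifying_pairs(scores, csc, score_type)

    def translate(x: str) -> str:
        return id_map[x] if id_map is not None else x

    neighbors: dict[str, set[str]] = {}
    for a, b in zip(qual["id_a"], qual["id_b"]):
        ta, tb = translate(a), translate(b)
        neighbors.setdefault(ta, set()).add(tb)
        neighbors.setdefault(tb, set()).add(ta)

    if universe is None:
        seeds = sorted(neighbors)
    else:
        seeds = sorted(set(universe))
        unknown = set(neighbors) - set(seeds)
        if unknown:
            raise ValueError(
                f"scored transcripts outside the universe: {sorted(unknown)[:5]}..."
                if len(unknown) > 5
                else f"scored transcripts outside the universe: {sorted(unknown)}"
            )

    groups = [
        SFPG(group_id=t, members=frozenset({t} | neighbors.get(t, set())))
        for t in seeds
    ]
    if dedup:
        by_members: dict[frozenset[str], SFPG] = {}
        for g in sorted(groups, key=lambda g: g.group_id):
            by_members.setdefault(g.members, g)
        groups = sorted(by_members.values(), key=lambda g: g.group_id)
    return SFPGSet(groups=groups, cutoff_used=csc, score_type=score_type)


def group_stats(sfpgs: SFPGSet) -> dict[str, float]:
    """Summary of the group-size distribution at the set's cutoff."""
    sizes = [g.size for g in sfpgs.groups]
    non_singleton = [s for s in sizes if s > 1]
    sizes_series = pd.Series(sizes, dtype=float)
    return {
        "n_groups": len(sizes),
        "n_non_singleton": len(non_singleton),
        "size_mean": float(sizes_series.mean()) if sizes else 0.0,
        "size_median": float(sizes_series.median()) if sizes else 0.0,
        "size_max": max(sizes) if sizes else 0,
        "size_total": sum(sizes),
    }


def categorize_pairs_report(
    scores: pd.DataFrame,
    catalog: ProteinCatalog,
    csc: int,
    score_type: str = "KS",
) -> dict[PairOrigin, int]:
    """Count qualifying pairs per gene-name origin category.

    Score-table ids are protein accessions; symbols come from the catalog.
    """
    qual = _qualifying_pairs(scores, csc, score_type)
    counts = {origin: 0 for origin in PairOrigin}
    for a, b in zip(qual["id_a"], qual["id_b"]):
        sym_a = catalog.by_protein_id(a).gene_symbol
        sym_b = catalog.by_protein_id(b).gene_symbol
        counts[categorize_pair(sym_a, sym_b)] += 1
    return counts
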