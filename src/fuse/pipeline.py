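"""End-to-end orchestration: FASTA + BLAST + InterPro + counts -> group expression.

Chains the stage modules in their natural order — catalog parsing and biotype
filtering, pair-feature reduction, domain-profile comparison, DS/KS scoring,
SFPG formation at the cutoff, normalization and redistribution — and bundles
every intermediate table in a results object so each stage remains
inspectable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import expression_recalc as er
from .alignment_features import features_table
from .confidence_scoring import ScoringScheme, load_scheme, score_all_pairs
from .domain_profiles import (
    build_profiles,
    compare_pair,
    comparisons_table,
    read_interpro_tsv,
)
from .proteome_io import (
    DEFAULT_BIOTYPE_EXCLUSIONS,
    ProteinCatalog,
    filter_by_biotype,
    parse_protein_fasta,
)
from .sfpg_grouping import SFPGSet, build_groups, group_stats

__all__ = ["PipelineResult", "run_pipeline", "read_counts", "read_lengths"]


@dataclass
class PipelineResult:
    catalog: ProteinCatalog
    features: pd.DataFrame
    comparisons: pd.DataFrame
    scores: pd.DataFrame
    sfpgs: SFPGSet
    size_factors: pd.Series
    fpkm: pd.DataFrame
    group_expression: pd.DataFrame
    method: str

    def summary(self) -> dict:
        stats = group_stats(self.sfpgs)
        stats.update(
            {
                "n_kept": len(self.catalog.records),
                "n_excluded": len(self.catalog.excluded),
                "n_scored_pairs": len(self.scores),
                "csc": self.sfpgs.cutoff_used,
                "score_type": self.sfpgs.score_type,
                "method": self.method,
            }
        )
        return stats


def read_counts(path: str | Path) -> pd.DataFrame:
    """Transcript x sample raw-count TSV (first column transcript_id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_lengths(path: str | Path) -> pd.Series:
    """Effective lengths from a two-column TSV or an RSEM isoforms table."""
    df = pd.read_csv(path, sep="\t")
    if "effective_length" in df.columns:
        id_col = "transcript_id"
    elif "effective_length" in (c.lower() for c in df.columns):  # RSEM dialect
        df.columns = [c.lower() for c in df.columns]
        id_col = "transcript_id"
    else:
        raise ValueError(f"{path}: no effective_length column found")
    return df.set_index(id_col)["effective_length"].astype(float)


def run_pipeline(
    fasta: str | Path,
    blast: str | Path,
    interpro: str | Path | None,
    counts: str | Path | pd.DataFrame,
    lengths: str | Path | pd.Series,
    csc: int = 95,
    score_type: str = "KS",
    method: str = "GD",
    scheme: ScoringScheme | str | Path | Mapping | None = None,
    exclusions: Iterable[str] = DEFAULT_BIOTYPE_EXCLUSIONS,
) -> PipelineResult:
    """Run the full method and return every intermediate product.

    ``method`` selects the redistribution rule: ``"GD"`` (group-size
    distribution, the default) or ``"ED"`` (equal distribution).
    """
    method = method.upper()
    if method not in ("ED", "GD"):
        raise ValueError(f"method must be 'ED' or 'GD', got {method!r}")
    if not isinstance(scheme, ScoringScheme):
        scheme = load_scheme(scheme)

    catalog = filter_by_biotype(parse_protein_fasta(fasta), exclusions)
    kept_catalog = ProteinCatalog(records=list(catalog.records))
    feats = features_table(blast, kept_catalog)

    if interpro is not None:
        annotations = read_interpro_tsv(interpro, tools=scheme.tools)
    else:
        annotations = []
    pair_ids = set(feats["id_a"]) | set(feats["id_b"])
    profiles = build_profiles(annotations, pair_ids, tools=scheme.tools)
    comps = [
        compare_pair(profiles[a], profiles[b], tools=scheme.tools)
        for a, b in zip(feats["id_a"], feats["id_b"])
    ]
    comp_table = comparisons_table(comps)

    scores = score_all_pairs(feats, comp_table, scheme)

    protein_to_transcript = {
        r.protein_id: r.transcript_id for r in catalog.records
    }
    counts_df = read_counts(counts) if isinstance(counts, (str, Path)) else counts
    efflen = read_lengths(lengths) if isinstance(lengths, (str, Path)) else lengths

    kept_ids = [
        t for t in catalog.kept_transcript_ids if t in counts_df.index
    ]
    sfpgs = build_groups(
        scores,
        csc=csc,
        score_type=score_type,
        universe=kept_ids,
        id_map=protein_to_transcript,
    )

    catalog_transcripts = [
        t
        for t in counts_df.index
        if t in set(catalog.kept_transcript_ids) | set(catalog.excluded_transcript_ids)
    ]
    counts_df = counts_df.loc[catalog_transcripts]
    size_factors = er.size_factors_median_of_ratios(counts_df)
    fpkm = er.to_fpkm(counts_df, efflen, size_factors)

    redistribute = er.recalc_gd if method == "GD" else er.recalc_ed
    group_expr = redistribute(fpkm, sfpgs)
    final = er.assemble_output(
        group_expr, fpkm, catalog.excluded_transcript_ids
    )
    return PipelineResult(
        catalog=catalog,
        features=feats,
        comparisons=comp_table,
        scores=scores,
        sfpgs=sfpgs,
        size_factors=size_factors,
        fpkm=fpkm,
        group_expression=final,
        method=method,
    )
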