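"""Discovery (DS) and Knowledge (KS) confidence scores for protein pairs.

Both scores start from three alignment components computed under a
configurable scoring scheme:

    AIS = %identity * identity_weight / 100
    ACS = (coverage_weight / 100) * sum over the two sequences of
          (100 - 100 * seq_length_i / alignment_length)
    AGS = gap_count * gap_weight / 100        (gap_weight <= 0)

DS uses the alignment alone, normalized by the maximum attainable identity
score and clamped to [0, 100]:

    DS = clamp((AIS + ACS + AGS) * 100 / identity_weight, 0, 100)

KS adds the summed per-tool domain-comparison score ITCS. Tools labeled NP
(no prediction for at least one protein) are skipped in both the sum and its
maximum, so missing predictions neither reward nor penalize a pair:

    ITCS      = sum over non-NP tools of weight(label)
    max_ITCS  = sum over non-NP tools of weight(STONM)
    KS        = clamp((AIS + ACS + AGS + ITCS) * 100
                      / (identity_weight + max_ITCS), 0, 100)

The KS denominator includes identity_weight so that identical sequences with
identical annotations score exactly 100 and KS stays on the same 0-100 scale
as DS. When every tool is NP, KS falls back to DS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .alignment_features import AlignmentFeatures
from .domain_profiles import DEFAULT_TOOLS, ComparisonLabel, PairDomainComparison

logger = logging.getLogger(__name__)

__all__ = [
    "ScoringScheme",
    "PairScore",
    "DEFAULT_LABEL_WEIGHTS",
    "load_scheme",
    "alignment_components",
    "discovery_score",
    "knowledge_score",
    "score_all_pairs",
]

#: Implementation-default per-tool label weights (config-overridable).
DEFAULT_LABEL_WEIGHTS: dict[str, float] = {
    "STONM": 10.0,
    "STNM": 6.0,
    "STM": 3.0,
    "NM": 0.0,
}

_ORDER = ("STONM", "STNM", "STM", "NM")


@dataclass(frozen=True)
class ScoringScheme:
    """Weights of the confidence-score components.

    Invariants: identity_weight > 0, gap_weight <= 0, and for every tool the
    label weights are monotone STONM >= STNM >= STM >= NM.
    """

    identity_weight: float = 100.0
    coverage_weight: float = 50.0
    gap_weight: float = -50.0
    tool_label_weights: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {t: dict(DEFAULT_LABEL_WEIGHTS) for t in DEFAULT_TOOLS}
    )

    def __post_init__(self) -> None:
        if self.identity_weight <= 0:
            raise ValueError("identity_weight must be positive")
        if self.gap_weight > 0:
            raise ValueError("gap_weight must be <= 0 (gaps measure dissimilarity)")
        for tool, weights in self.tool_label_weights.items():
            missing = [lab for lab in _ORDER if lab not in weights]
            if missing:
                raise ValueError(f"tool {tool}: missing label weights {missing}")
            vals = [weights[lab] for lab in _ORDER]
            if any(a < b for a, b in zip(vals, vals[1:])):
                raise ValueError(
                    f"tool {tool}: label weights must satisfy "
                    "STONM >= STNM >= STM >= NM"
                )

    @property
    def tools(self) -> tuple[str, ...]:
        return tuple(self.tool_label_weights)

    def weight(self, tool: str, label: ComparisonLabel) -> float:
        return float(self.tool_label_weights[tool][label.value])


@dataclass(frozen=True)
class PairScore:
    id_a: str
    id_b: str
    AIS: float
    ACS: float
    AGS: float
    ITCS: float
    max_ais: float
    max_itcs_non_np: float
    DS: float
    KS: float


def load_scheme(
    config: str | Path | Mapping | None = None,
    tools: tuple[str, ...] = DEFAULT_TOOLS,
) -> ScoringScheme:
    """Build a ScoringScheme from a flat key-value document (YAML path or
    mapping); missing keys take the documented defaults.

    Recognized keys: ``identity_weight``, ``coverage_weight``, ``gap_weight``
    and ``tool_label_weights`` (tool -> {STONM, STNM, STM, NM} -> weight;
    tools absent from the mapping get the default label weights).
    """
    if config is None:
        doc: Mapping = {}
    elif isinstance(config, (str, Path)):
        with open(config) as fh:
            doc = yaml.safe_load(fh) or {}
    else:
        doc = config
    per_tool_cfg = doc.get("tool_label_weights", {})
    tool_weights = {}
    for tool in tools:
        weights = dict(DEFAULT_LABEL_WEIGHTS)
        weights.update(per_tool_cfg.get(tool, {}))
        tool_weights[tool] = weights
    return ScoringScheme(
        identity_weight=float(doc.get("identity_weight", 100.0)),
        coverage_weight=float(doc.get("coverage_weight", 50.0)),
        gap_weight=float(doc.get("gap_weight", -50.0)),
        tool_label_weights=tool_weights,
    )


def alignment_components(
    f: AlignmentFeatures, s: ScoringScheme
) -> tuple[float, float, float]:
    """(AIS, ACS, AGS) for one pair.

    The coverage term sums over the pair's two sequences; an alignment shorter
    than a sequence yields a negative contribution for that sequence.
    """
    # (pident / 100) * weight is exactly the weight at pident == 100, which
    # keeps the identity bound (self-alignment scores 100) exact.
    ais = (f.pident / 100.0) * s.identity_weight
    acs = (s.coverage_weight / 100.0) * sum(
        100.0 - 100.0 * length / f.aln_length for length in (f.len_a, f.len_b)
    )
    ags = f.gap_count * s.gap_weight / 100.0
    return ais, acs, ags


def _clamp(x: float) -> float:
    return min(100.0, max(0.0, x))


def discovery_score(f: AlignmentFeatures, s: ScoringScheme) -> float:
    ais, acs, ags = alignment_components(f, s)
    return _clamp(100.0 * ((ais + acs + ags) / s.identity_weight))


def knowledge_score(
    f: AlignmentFeatures, c: PairDomainComparison, s: ScoringScheme
) -> float:
    ais, acs, ags = alignment_components(f, s)
    itcs = 0.0
    max_itcs = 0.0
    for tool, label in zip(c.tools, c.labels):
        if label is ComparisonLabel.NP:
            continue
        itcs += s.weight(tool, label)
        max_itcs += s.weight(tool, ComparisonLabel.STONM)
    if max_itcs == 0.0:  # every tool NP: fall back to the discovery score
        return _clamp(100.0 * ((ais + acs + ags) / s.identity_weight))
    return _clamp(
        100.0 * ((ais + acs + ags + itcs) / (s.identity_weight + max_itcs))
    )


def score_all_pairs(
    features: pd.DataFrame,
    comparisons: pd.DataFrame | None,
    scheme: ScoringScheme,
) -> pd.DataFrame:
    """Vectorized scoring of every aligned pair.

    ``features`` is the pair-features table (id_a, id_b, pident, aln_length,
    gap_count, len_a, len_b); ``comparisons`` the pair-labels table (id_a,
    id_b, one column per tool) or None. Pairs with no comparison row are
    treated as all-NP. Pairs absent from ``features`` are not scored:
    unaligned means unscored.
    """
    tools = list(scheme.tools)
    df = features.copy()
    if comparisons is not None and len(comparisons):
        df = df.merge(comparisons, on=["id_a", "id_b"], how="left")
    for tool in tools:
        if tool not in df.columns:
            df[tool] = ComparisonLabel.NP.value
        df[tool] = df[tool].fillna(ComparisonLabel.NP.value)

    ais = (df["pident"].to_numpy(float) / 100.0) * scheme.identity_weight
    aln = df["aln_length"].to_numpy(float)
    acs = (scheme.coverage_weight / 100.0) * (
        (100.0 - 100.0 * df["len_a"].to_numpy(float) / aln)
        + (100.0 - 100.0 * df["len_b"].to_numpy(float) / aln)
    )
    ags = df["gap_count"].to_numpy(float) * scheme.gap_weight / 100.0
    base = ais + acs + ags

    itcs = np.zeros(len(df))
    max_itcs = np.zeros(len(df))
    for tool in tools:
        labels = df[tool].to_numpy(str)
        non_np = labels != ComparisonLabel.NP.value
        weights = scheme.tool_label_weights[tool]
        lw = np.zeros(len(df))
        for lab in _ORDER:
            lw[labels == lab] = weights[lab]
        itcs += np.where(non_np, lw, 0.0)
        max_itcs += np.where(non_np, weights["STONM"], 0.0)

    ds_raw = 100.0 * (base / scheme.identity_weight)
    ds = np.clip(ds_raw, 0.0, 100.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ks_raw = 100.0 * ((base + itcs) / (scheme.identity_weight + max_itcs))
    ks = np.where(max_itcs > 0.0, np.clip(ks_raw, 0.0, 100.0), ds)

    n_clamped = int(np.sum((ds_raw < 0.0) | (ds_raw > 100.0)))
    if n_clamped:
        logger.info("clamped DS for %d pairs to [0, 100]", n_clamped)

    out = pd.DataFrame(
        {
            "id_a": df["id_a"],
            "id_b": df["id_b"],
            "AIS": ais,
            "ACS": acs,
            "AGS": ags,
            "ITCS": itcs,
            "max_ais": scheme.identity_weight,
            "max_itcs_non_np": max_itcs,
            "DS": ds,
            "KS": ks,
        }
    )
    return out.sort_values(["id_a", "id_b"], ignore_index=True)
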