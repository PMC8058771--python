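"""Normalization and SFPG-level expression recalculation.

Raw transcript counts are first made comparable across samples with the
median-of-ratios size-factor estimator (the default normalization of count-
based differential-expression tools): the reference for each transcript is
its geometric mean across samples, computed over transcripts with strictly
positive counts everywhere; each sample's factor is the median ratio of its
counts to that reference. Normalized counts are then length-corrected to
FPKM using RSEM-style effective lengths:

    FPKM_tj = normcount_tj * 1e9 / (efflen_t * sum_t normcount_tj)

with transcripts of zero effective length dropped from the library-size sum
and assigned FPKM 0.

Group expression then redistributes each member transcript's FPKM over the
groups it belongs to, either equally (ED):

    expr(g) = sum over members m of fpkm(m) / n_groups(m)

or proportionally to group size (GD), encoding genetic redundancy — bigger
groups retain more of a shared member's expression:

    expr(g) = sum over members m of fpkm(m) * |g| / sum over groups h of m |h|

Both rules conserve total expression per sample exactly; excluded-biotype
transcripts are appended as passthrough rows with their own FPKM.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .sfpg_grouping import SFPGSet

logger = logging.getLogger(__name__)

__all__ = [
    "size_factors_median_of_ratios",
    "to_fpkm",
    "recalc_ed",
    "recalc_gd",
    "assemble_output",
]


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Per-sample size factors (transcripts in rows, samples in columns).

    Requires at least two samples and at least one transcript counted in
    every sample; the geometric-mean reference is computed in log space.
    """
    if counts.shape[1] < 2:
        raise ValueError("size factors need at least 2 samples")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts are not allowed")
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no transcript has nonzero counts in every sample; the "
            "pseudo-reference fallback is not implemented"
        )
    sub = counts.loc[all_positive]
    log_ref = np.log(sub).mean(axis=1)
    ratios = np.log(sub).sub(log_ref, axis=0)
    return pd.Series(np.exp(ratios.median(axis=0)), index=counts.columns, name="size_factor")


def to_fpkm(
    counts: pd.DataFrame,
    effective_lengths: pd.Series,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Normalized FPKM matrix.

    ``counts`` are raw counts; if ``size_factors`` is given each sample is
    divided by its factor first. Effective lengths are aligned on the
    transcript index; transcripts with effective length 0 (shorter than the
    fragment length) get FPKM 0 and do not enter the per-sample library size.
    An all-zero sample yields an all-zero column.
    """
    efflen = effective_lengths.reindex(counts.index)
    if efflen.isna().any():
        missing = efflen.index[efflen.isna()].tolist()
        raise ValueError(f"missing effective lengths for transcripts: {missing[:5]}")
    norm = counts / size_factors if size_factors is not None else counts.astype(float)
    usable = efflen > 0
    n_zero_len = int((~usable).sum())
    if n_zero_len:
        logger.info("%d transcripts with effective length 0 set to FPKM 0", n_zero_len)
    lib_size = norm.loc[usable].sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fpkm = norm.mul(1e9).div(efflen, axis=0).div(lib_size, axis=1)
    fpkm = fpkm.where(usable, 0.0, axis=0)
    fpkm = fpkm.fillna(0.0)  # all-zero samples: 0/0 -> 0
    return fpkm


def _member_group_frame(fpkm: pd.DataFrame, sfpgs: SFPGSet) -> pd.DataFrame:
    """Long frame of (group_id, member, group size, member's total group size)."""
    rows = []
    for g in sfpgs.groups:
        for m in g.members:
            if m not in sfpgs.membership or not sfpgs.membership[m]:
                raise ValueError(f"member {m} has empty membership")
            rows.append((g.group_id, m, g.size))
    df = pd.DataFrame(rows, columns=["group_id", "member", "group_size"])
    total_size = df.groupby("member")["group_size"].transform("sum")
    n_groups = df.groupby("member")["group_size"].transform("size")
    df["total_group_size"] = total_size
    df["n_groups"] = n_groups
    return df


def _redistribute(fpkm: pd.DataFrame, sfpgs: SFPGSet, method: str) -> pd.DataFrame:
    df = _member_group_frame(fpkm, sfpgs)
    if method == "ED":
        weight = 1.0 / df["n_groups"].to_numpy()
    else:
        weight = df["group_size"].to_numpy() / df["total_group_size"].to_numpy()
    member_fpkm = fpkm.reindex(df["member"]).fillna(0.0).to_numpy()
    contrib = member_fpkm * weight[:, None]
    out = pd.DataFrame(contrib, columns=fpkm.columns)
    out["group_id"] = df["group_id"].to_numpy()
    return out.groupby("group_id").sum().sort_index()


def recalc_ed(fpkm: pd.DataFrame, sfpgs: SFPGSet) -> pd.DataFrame:
    """Equal distribution: each member's FPKM split evenly over its groups."""
    return _redistribute(fpkm, sfpgs, "ED")


def recalc_gd(fpkm: pd.DataFrame, sfpgs: SFPGSet) -> pd.DataFrame:
    """Group-size distribution: split proportional to each group's size."""
    return _redistribute(fpkm, sfpgs, "GD")


def assemble_output(
    group_expr: pd.DataFrame,
    fpkm: pd.DataFrame,
    excluded_transcripts: Iterable[str],
) -> pd.DataFrame:
    """Final matrix: group rows plus one passthrough row per excluded
    transcript carrying its own FPKM; row ids must not collide."""
    excluded = [t for t in excluded_transcripts if t in fpkm.index]
    passthrough = fpkm.loc[excluded]
    overlap = set(group_expr.index) & set(passthrough.index)
    if overlap:
        raise ValueError(
            f"row id collision between groups and passthrough: {sorted(overlap)[:5]}"
        )
    return pd.concat([group_expr, passthrough], axis=0)
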