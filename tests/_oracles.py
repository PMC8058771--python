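"""Independent straight-line oracles used by the tests.

These deliberately re-derive the scores and labels from their definitions in
plain scalar Python, without touching the package's vectorized or optimized
code paths, so agreement between the two routes is informative.
"""

from __future__ import annotations

import numpy as np


def naive_label(list_a: list[str], list_b: list[str]) -> str:
    """Classify two ordered motif lists by the five-level definitions."""
    if len(list_a) == 0 or len(list_b) == 0:
        return "NP"  # no prediction for at least one protein
    same_type = set(list_a) == set(list_b)
    same_number = sorted(list_a) == sorted(list_b)
    same_order = list_a == list_b
    if same_type and same_number and same_order:
        return "STONM"
    if same_type and same_number:
        return "STNM"
    if same_type:
        return "STM"
    return "NM"


def naive_scores(
    pident: float,
    aln_length: int,
    gap_count: int,
    len_a: int,
    len_b: int,
    labels: dict[str, str],
    identity_weight: float,
    coverage_weight: float,
    gap_weight: float,
    tool_label_weights: dict[str, dict[str, float]],
) -> tuple[float, float]:
    """(DS, KS) evaluated term by term from the score definitions."""
    tool_weights = tool_label_weights
    ais = pident * identity_weight / 100.0
    acs = 0.0
    for length in (len_a, len_b):
        acs += (100.0 - length / aln_length * 100.0) * coverage_weight / 100.0
    ags = gap_count * gap_weight / 100.0
    ds = (ais + acs + ags) * 100.0 / identity_weight
    ds = min(100.0, max(0.0, ds))

    itcs = 0.0
    max_itcs = 0.0
    for tool, label in labels.items():
        if label == "NP":
            continue
        itcs += tool_weights[tool][label]
        max_itcs += tool_weights[tool]["STONM"]
    if max_itcs == 0.0:
        return ds, ds
    ks = (ais + acs + ags + itcs) * 100.0 / (identity_weight + max_itcs)
    return ds, min(100.0, max(0.0, ks))


def random_scheme_params(rng: np.random.Generator, tools: tuple[str, ...]) -> dict:
    """A random valid scheme: positive identity weight, non-positive gap
    weight, per-tool monotone label weights."""
    tool_weights = {}
    for tool in tools:
        vals = np.sort(rng.uniform(0.0, 20.0, size=4))[::-1]
        tool_weights[tool] = {
            "STONM": float(vals[0]),
            "STNM": float(vals[1]),
            "STM": float(vals[2]),
            "NM": float(vals[3]),
        }
    return {
        "identity_weight": float(rng.uniform(10.0, 200.0)),
        "coverage_weight": float(rng.uniform(0.0, 100.0)),
        "gap_weight": float(-rng.uniform(0.0, 100.0)),
        "tool_label_weights": tool_weights,
    }


def random_features_params(rng: np.random.Generator) -> dict:
    aln = int(rng.integers(50, 500))
    return {
        "pident": float(rng.uniform(0.0, 100.0)),
        "aln_length": aln,
        "gap_count": int(rng.integers(0, 10)),
        "len_a": int(rng.integers(30, 600)),
        "len_b": int(rng.integers(30, 600)),
    }


def random_labels(rng: np.random.Generator, tools: tuple[str, ...]) -> dict[str, str]:
    choices = ["STONM", "STNM", "STM", "NM", "NP"]
    return {t: choices[rng.integers(0, 5)] for t in tools}
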