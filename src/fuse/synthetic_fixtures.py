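"""Seeded synthetic input bundles with planted ground truth.

Generates everything the pipeline consumes — an Ensembl-dialect protein
FASTA, BLAST-like tabular hits, InterPro-like TSV annotations and a raw
count matrix with effective lengths — from a compact specification, so the
whole method is testable without external tools or downloads.

Protein families are planted by mutating a family root sequence at disjoint
position sets per member, which pins pairwise within-family identity near the
requested target. BLAST-like rows carry the *realized* pairwise identity
(recomputed from the emitted sequences), the root length as alignment length
and a planted gap count (0 by default: the mutation plan is substitution-
only). Each family carries a per-tool two-domain architecture shared by all
members; optional perturbations (swap the domain order, or drop a tool's
annotations) on a family's last member plant STNM/NP labels. Counts are
negative-binomial with per-sample planted size factors, making size-factor
recovery a quantitative test. Excluded-biotype (nonsense-mediated decay)
transcripts can be planted to exercise the passthrough path.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .domain_profiles import DEFAULT_TOOLS

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "make_fixture",
    "simulate_counts",
    "verify_against_truth",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic bundle.

    ``architecture_perturbations`` maps family index -> {tool: 'swap'|'drop'};
    the perturbation is applied to that family's last member.
    """

    n_families: int = 2
    family_sizes: tuple[int, ...] = (5, 5)
    within_identity: float = 98.0
    between_identity: float = 0.0
    n_tools_annotated: int = 4
    architecture_perturbations: dict = field(default_factory=dict)
    n_samples: int = 3
    planted_size_factors: tuple[float, ...] | None = None
    nb_dispersion: float = 0.1
    n_excluded: int = 0
    root_length: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.family_sizes) != self.n_families:
            raise ValueError("family_sizes must have n_families entries")
        if any(s < 1 for s in self.family_sizes):
            raise ValueError("family sizes must be >= 1")
        if not self.within_identity > self.between_identity:
            raise ValueError("within_identity must exceed between_identity")
        if self.within_identity > 100 or self.between_identity < 0:
            raise ValueError("identity targets must lie in [0, 100]")
        if self.planted_size_factors is not None and len(
            self.planted_size_factors
        ) != self.n_samples:
            raise ValueError("planted_size_factors must have n_samples entries")
        if not 0 <= self.n_tools_annotated <= len(DEFAULT_TOOLS):
            raise ValueError("n_tools_annotated out of range")


@dataclass
class GroundTruth:
    """What was planted: family membership, per-pair tool labels, factors."""

    families: dict[str, list[str]]  # family id -> member transcript ids
    transcript_family: dict[str, str]
    pair_labels: dict[tuple[str, str], dict[str, str]]  # protein-id pairs
    realized_identities: dict[tuple[str, str], float]
    size_factors: tuple[float, ...]
    excluded_transcripts: list[str]
    protein_to_transcript: dict[str, str]


def _mutate(
    seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Substitute each position with a uniformly drawn *different* residue."""
    out = seq.copy()
    for pos in positions:
        choices = AMINO_ACIDS[AMINO_ACIDS != out[pos]]
        out[pos] = rng.choice(choices)
    return out


def _identity(a: np.ndarray, b: np.ndarray) -> float:
    return 100.0 * float(np.mean(a == b))


def simulate_counts(
    n_transcripts: int,
    size_factors: tuple[float, ...],
    dispersion: float,
    rng: np.random.Generator,
    mean_log: float = 5.0,
    sd_log: float = 1.0,
) -> np.ndarray:
    """Negative-binomial count matrix (transcripts x samples) with planted
    per-sample scale factors and a log-normal baseline mean."""
    mu0 = rng.lognormal(mean=mean_log, sigma=sd_log, size=n_transcripts)
    n_nb = 1.0 / dispersion
    counts = np.empty((n_transcripts, len(size_factors)), dtype=int)
    for j, sf in enumerate(size_factors):
        mu = mu0 * sf
        p = n_nb / (n_nb + mu)
        counts[:, j] = rng.negative_binomial(n_nb, p)
    return counts


def make_fixture(
    spec: FixtureSpec, out_dir: str | Path
) -> tuple[dict[str, Path], GroundTruth]:
    """Write a deterministic bundle to ``out_dir``; return file paths + truth.

    Bundle layout: proteins.fa, blast.tsv, interpro.tsv, counts.tsv,
    lengths.tsv, truth.json.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    L = spec.root_length

    d_within = int(round(L * (1.0 - spec.within_identity / 100.0) / 2.0))
    for size in spec.family_sizes:
        if size * d_within > L:
            raise ValueError("family too large for the requested within-identity")

    # Family roots: independent unless a between-identity is requested, in
    # which case they descend from a shared ancestor by disjoint mutations.
    if spec.between_identity > 0:
        d_between = int(round(L * (1.0 - spec.between_identity / 100.0) / 2.0))
        if spec.n_families * d_between > L:
            raise ValueError("too many families for the requested between-identity")
        ancestor = rng.choice(AMINO_ACIDS, size=L)
        perm = rng.permutation(L)
        roots = [
            _mutate(ancestor, perm[f * d_between : (f + 1) * d_between], rng)
            for f in range(spec.n_families)
        ]
    else:
        roots = [rng.choice(AMINO_ACIDS, size=L) for _ in range(spec.n_families)]

    fam_letters = string.ascii_uppercase
    sequences: dict[str, np.ndarray] = {}
    families: dict[str, list[str]] = {}
    transcript_family: dict[str, str] = {}
    protein_to_transcript: dict[str, str] = {}
    fasta_entries: list[tuple[str, str]] = []  # (header, sequence)
    member_proteins: dict[str, list[str]] = {}

    for f, size in enumerate(spec.family_sizes):
        fam_id = f"FAM{f}"
        base_symbol = f"GEN{fam_letters[f % 26]}"
        perm = rng.permutation(L)
        families[fam_id] = []
        member_proteins[fam_id] = []
        for k in range(size):
            pid, tid, gid = f"P{f}_{k}", f"T{f}_{k}", f"G{f}_{k}"
            seq = _mutate(roots[f], perm[k * d_within : (k + 1) * d_within], rng)
            sequences[pid] = seq
            families[fam_id].append(tid)
            transcript_family[tid] = fam_id
            protein_to_transcript[pid] = tid
            member_proteins[fam_id].append(pid)
            header = (
                f"{pid} pep gene:{gid} transcript:{tid} "
                f"gene_biotype:protein_coding transcript_biotype:protein_coding "
                f"gene_symbol:{base_symbol}{k + 1}"
            )
            fasta_entries.append((header, "".join(seq) + "*"))

    excluded_transcripts: list[str] = []
    for k in range(spec.n_excluded):
        pid, tid, gid = f"PX{k}", f"TX{k}", f"GX{k}"
        seq = rng.choice(AMINO_ACIDS, size=L)
        excluded_transcripts.append(tid)
        protein_to_transcript[pid] = tid
        header = (
            f"{pid} pep gene:{gid} transcript:{tid} "
            f"gene_biotype:protein_coding "
            f"transcript_biotype:nonsense_mediated_decay gene_symbol:NMD{k + 1}"
        )
        fasta_entries.append((header, "".join(seq) + "*"))

    # BLAST-like rows: all within-family unordered pairs; between-family
    # pairs only when a between-identity was planted.
    blast_rows: list[str] = []
    realized: dict[tuple[str, str], float] = {}

    def emit_hit(pa: str, pb: str) -> None:
        ident = _identity(sequences[pa], sequences[pb])
        realized[(pa, pb)] = ident
        bitscore = round(2.0 * L * ident / 100.0, 1)
        mismatches = int(round(L * (1 - ident / 100.0)))
        blast_rows.append(
            f"{pa}\t{pb}\t{ident:.2f}\t{L}\t{mismatches}\t0"
            f"\t1\t{L}\t1\t{L}\t1e-50\t{bitscore}"
        )

    all_fams = list(families)
    for fam_id in all_fams:
        prots = member_proteins[fam_id]
        for i in range(len(prots)):
            for j in range(i + 1, len(prots)):
                emit_hit(prots[i], prots[j])
    if spec.between_identity > 0:
        for fi in range(len(all_fams)):
            for fj in range(fi + 1, len(all_fams)):
                for pa in member_proteins[all_fams[fi]]:
                    for pb in member_proteins[all_fams[fj]]:
                        emit_hit(pa, pb)

    # InterPro-like rows: per family, a two-domain architecture per annotated
    # tool, shared by every member; perturbations hit the last member.
    tools = DEFAULT_TOOLS[: spec.n_tools_annotated]
    interpro_rows: list[str] = []
    pair_labels: dict[tuple[str, str], dict[str, str]] = {}

    def ip_row(pid: str, tool: str, sig: str, start: int, stop: int) -> str:
        return (
            f"{pid}\tmd5\t{L}\t{tool}\t{sig}\tdescription\t{start}\t{stop}"
            f"\t1e-20\tT\t01-01-2020"
        )

    for f, fam_id in enumerate(all_fams):
        prots = member_proteins[fam_id]
        perturb = spec.architecture_perturbations.get(f, {})
        for idx, pid in enumerate(prots):
            is_last = idx == len(prots) - 1
            for tool in tools:
                action = perturb.get(tool) if is_last else None
                sig_a, sig_b = f"SIG{f}_{tool}a", f"SIG{f}_{tool}b"
                if action == "drop":
                    continue
                if action == "swap":
                    interpro_rows.append(ip_row(pid, tool, sig_b, 10, 50))
                    interpro_rows.append(ip_row(pid, tool, sig_a, 60, 120))
                else:
                    interpro_rows.append(ip_row(pid, tool, sig_a, 10, 50))
                    interpro_rows.append(ip_row(pid, tool, sig_b, 60, 120))
        # expected per-tool labels for within-family pairs
        for i in range(len(prots)):
            for j in range(i + 1, len(prots)):
                labels: dict[str, str] = {}
                touches_last = j == len(prots) - 1
                for tool in DEFAULT_TOOLS:
                    if tool not in tools:
                        labels[tool] = "NP"
                        continue
                    action = perturb.get(tool)
                    if action == "drop" and touches_last:
                        labels[tool] = "NP"
                    elif action == "swap" and touches_last:
                        labels[tool] = "STNM"
                    else:
                        labels[tool] = "STONM"
                pair_labels[(prots[i], prots[j])] = labels

    # Counts and effective lengths for every transcript, excluded included.
    transcripts = [
        protein_to_transcript[header.split()[0]] for header, _ in fasta_entries
    ]
    size_factors = spec.planted_size_factors or tuple([1.0] * spec.n_samples)
    counts = simulate_counts(len(transcripts), size_factors, spec.nb_dispersion, rng)
    efflen = np.round(rng.uniform(500.0, 3000.0, size=len(transcripts)), 2)
    samples = [f"sample{j + 1}" for j in range(spec.n_samples)]
    counts_df = pd.DataFrame(counts, index=transcripts, columns=samples)
    counts_df.index.name = "transcript_id"
    lengths_df = pd.DataFrame(
        {"transcript_id": transcripts, "effective_length": efflen}
    )

    paths = {
        "proteins": out_dir / "proteins.fa",
        "blast": out_dir / "blast.tsv",
        "interpro": out_dir / "interpro.tsv",
        "counts": out_dir / "counts.tsv",
        "lengths": out_dir / "lengths.tsv",
        "truth": out_dir / "truth.json",
    }
    with open(paths["proteins"], "w") as fh:
        for header, seq in fasta_entries:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    paths["blast"].write_text("\n".join(blast_rows) + ("\n" if blast_rows else ""))
    paths["interpro"].write_text(
        "\n".join(interpro_rows) + ("\n" if interpro_rows else "")
    )
    counts_df.to_csv(paths["counts"], sep="\t")
    lengths_df.to_csv(paths["lengths"], sep="\t", index=False)

    truth = GroundTruth(
        families=families,
        transcript_family=transcript_family,
        pair_labels=pair_labels,
        realized_identities=realized,
        size_factors=size_factors,
        excluded_transcripts=excluded_transcripts,
        protein_to_transcript=protein_to_transcript,
    )
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "families": families,
                "excluded_transcripts": excluded_transcripts,
                "size_factors": list(size_factors),
                "pair_labels": {
                    f"{a}|{b}": labels for (a, b), labels in pair_labels.items()
                },
                "realized_identities": {
                    f"{a}|{b}": ident for (a, b), ident in realized.items()
                },
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return paths, truth


def verify_against_truth(sfpgs, truth: GroundTruth, csc: int) -> dict:
    """Compare recovered groups with the planted families.

    Passes iff every non-singleton group's member set equals exactly the
    planted family of its seed. Also flags under-grouping (all singletons
    while multi-member families exist) and merged neighborhoods (a group
    spanning more than one family).
    """
    family_sets = {fid: frozenset(m) for fid, m in truth.families.items()}
    non_singleton = [g for g in sfpgs.groups if g.size > 1]
    exact = True
    merged = False
    for g in non_singleton:
        fams = {truth.transcript_family.get(m) for m in g.members}
        if len(fams) > 1:
            merged = True
        seed_family = truth.transcript_family.get(g.group_id)
        if seed_family is None or g.members != family_sets[seed_family]:
            exact = False
    multi_member_families = [f for f, m in truth.families.items() if len(m) > 1]
    under_grouped = not non_singleton and bool(multi_member_families)
    if under_grouped:
        exact = False
    return {
        "csc": csc,
        "n_non_singleton_groups": len(non_singleton),
        "exact_recovery": exact and not merged,
        "under_grouped": under_grouped,
        "merged_neighborhoods": merged,
    }
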