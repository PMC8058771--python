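# Methods

## Model and assumptions

`fuse` treats "function" operationally: two proteins are assigned similar
function when their sequences align with high identity and coverage and,
where domain predictions exist, their domain architectures agree per InterPro
analysis tool. The method makes no claim about activity or localization; it
assumes that (i) proteins whose full-length alignments are nearly identical
and (ii) whose ordered domain compositions match tool-by-tool are functionally
interchangeable for the purpose of expression aggregation. Grouping is
deliberately local (per-seed neighborhoods, never transitive closure):
similarity at a cutoff is not transitive, and merging overlapping
neighborhoods would create groups whose extreme members share little.

## Scoring

Per pair, the alignment contributes AIS (identity), ACS (coverage) and AGS
(gap) components; the domain comparison contributes one label per tool from
{STONM, STNM, STM, NM, NP}, converted to a weight. Two details are design
choices of this implementation:

- **Knowledge-score denominator.** The score is normalized by
  `identity_weight + max_itcs_nonNP` rather than the maximum tool score
  alone. The alternative puts identical proteins above 100 and breaks the
  stated 0–100 range of the cutoff; the chosen form gives DS = KS = 100 for
  identical, identically annotated proteins under *every* valid scheme (a
  property the test suite asserts with randomized schemes).
- **Coverage index.** The coverage sum runs over the pair's two sequences
  (query and subject). Reading the index as an exponent produces
  dimensionally absurd values and is rejected. An alignment longer than both
  sequences yields a *positive* ACS; this is evaluated literally and counted
  in logs rather than clipped, since heavily gapped alignments are already
  penalized through AGS.

Numeric weight defaults (identity 100, coverage 50, gap −50; per tool
STONM/STNM/STM/NM = 10/6/3/0 over the 14 member-database analyses of
InterProScan 5.31-70.0) are implementation defaults, config-overridable; any
scheme satisfying identity > 0, gap ≤ 0 and per-tool monotone label weights
preserves every invariant above. Because the published weight table for this
scheme family is not available, exact third-party score values are out of
scope; all guarantees are structural (bounds, monotonicity, symmetry, oracle
equivalence).

Floating-point note: AIS is computed as `(pident / 100) * identity_weight`
and the final scores as `100 * (numerator / denominator)`. This ordering
makes the identity bound exact in IEEE arithmetic (at `pident == 100` the
ratio is bitwise 1.0); the naive orderings can land 1 ulp below 100.

## Domain-architecture labels

Signatures are ordered by (start, stop, accession) per protein per tool;
"type" means the signature accession of the emitting tool, not the integrated
InterPro entry. The five labels form a strict hierarchy checked exhaustively
against a brute-force classifier in the tests. Both-unannotated pairs are NP,
not STONM: absence of prediction is treated as missing information, never as
agreement. STM requires the *distinct-signature sets* to be equal; sets that
merely overlap are NM, the stricter of the plausible readings. Duplicate
identical annotation rows collapse; overlapping duplicates at different
coordinates are kept distinct.

## Grouping

`build_groups` forms one group per universe transcript: the seed plus all
transcripts scoring at or above the CSC (an integer in [1, 100]; default
KS ≥ 95). Singletons are materialized so the downstream redistribution covers
the whole kept universe — this is what makes the conservation identity hold
globally. Duplicated member sets under different seeds are retained by
default (one group per transcript preserves specialized functions in the
output naming); `--dedup-groups` collapses them keeping the smallest seed.

## Normalization and redistribution

Size factors are classical median-of-ratios: the per-transcript reference is
the geometric mean across samples (computed in log space) over transcripts
with all counts positive; each sample's factor is the median count/reference
ratio. No pseudo-reference fallback is implemented — an input with no
all-positive transcript is rejected with an explicit error. The estimator is
cross-checked in the tests against the pydeseq2 reference implementation.

FPKM uses the per-sample sum of *normalized* counts over transcripts with
positive effective length as the library size. The upstream quantifier fixes
neither convention; taking the post-normalization sum keeps the FPKM matrix
self-consistent with the size-factor step and makes FPKM invariant to
rescaling any single sample's raw counts. Transcripts with effective length 0
(shorter than the fragment length; real quantifiers emit such rows) get FPKM
0 and leave the library-size sum.

For a member *m* with FPKM *x* belonging to groups with sizes *s₁…s_k*:
ED contributes *x/k* to each group; GD contributes *x·sⱼ/Σs* to group *j*.
Both rules distribute each member's expression with weights summing to one,
so per sample Σ(group rows) = Σ(kept FPKM) exactly; passthrough rows add the
excluded-biotype FPKM on both sides. Group expression is computed per sample
independently; no cross-sample smoothing. Group-level values should be read
comparatively (one SFPG across conditions), not as absolute abundances
across SFPGs, since members are shared between rows.

## Synthetic data generator

`synthetic_fixtures` emulates the input stack end to end: families planted by
substitution-only mutation of a 300-aa root (uniform 20-letter alphabet) at
disjoint position sets per member, which pins pairwise within-family identity
to the target (±1 point for sequences ≥ 200 aa); alignment rows carrying the
realized identity, full-length alignment and planted gap counts;
architecture rows realizing a two-domain-per-tool family architecture with
optional order-swap/drop perturbations; negative-binomial counts (dispersion
0.1, log-normal baseline) with planted per-sample factors. Defaults — two
families of five at 98% within-identity, no between-family hits, four
annotated tools, three samples — describe the well-separated regime the
grouping is designed for.

What the generator does *not* emulate, and what passing tests therefore do
not show about real data: partial and multi-HSP alignments (coverage and gap
terms are exercised only through hand-built feature tables), indels,
realistic BLAST e-value/bitscore statistics, tool-specific annotation biases,
and genuinely ambiguous boundary pairs whose correct grouping is unknown.
The end-to-end recovery results demonstrate correctness of the machinery, not
field performance on a real proteome.

## Problem sizes and numerics

Test and acceptance runs use deliberately small problems: 1,000 random
triples for score-oracle agreement (tolerance 1e-9 absolute), exhaustive
label comparison over all list pairs up to length 3 on a 3-signature
alphabet (1,600 pairs), 20 fixtures × 4 cutoffs for monotonicity, 100
fixtures with excluded transcripts for conservation (tolerance 1e-9
relative), 2,000 transcripts for size-factor recovery (tolerance 2% after
geometric-mean-1 rescaling) and ten 2×5-member bundles for end-to-end
recovery. These sizes give stable verdicts for structural properties;
scaling behaviour on ~100k-protein proteomes is linear in pairs for scoring
and grouping but has not been benchmarked here.

Tie-breaks and degenerate inputs: best hit per unordered pair by (bitscore,
−evalue, pident, first occurrence); signature order ties by stop then
accession; all-zero samples produce all-zero FPKM columns; empty exclusion
sets, empty InterPro files and absent gene symbols are all legal inputs.

## Known limitations

- Single best HSP per pair; composite coverage across HSPs is not merged.
- The gene-family classifier is a symbol-stem heuristic (strip trailing
  digits plus one member letter), adequate for reporting pair origins, not a
  curated family database.
- Biotype exclusion matches transcript biotype strings/prefixes; genomes
  with other annotation dialects may need a custom exclusion set.
- No differential-expression testing, PCA or clustering; the output matrix
  is meant to feed standard downstream tools.
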