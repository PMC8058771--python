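# fuse

Function-based regrouping of RNA-Seq expression. Standard transcript-level
quantification treats every isoform as its own unit, yet many distinct
transcripts — alternative isoforms of one gene, or paralogs across a gene
family — encode proteins with essentially the same function. `fuse` scores
every aligned protein pair for functional similarity, collects highly similar
proteins into **Similar Function Protein Groups (SFPGs)**, and recomputes the
expression matrix per functional group instead of per transcript locus, so
downstream analyses measure what the cell can *do* rather than which locus
happened to be transcribed.

Intended users: transcriptomics analysts with an Ensembl-style protein FASTA,
all-vs-all protein BLAST hits (tabular format 6), InterProScan `.tsv`
annotations and an RSEM-style transcript count table.

## Method

For an aligned pair of proteins with percent identity *p*, alignment length
*l*, gap count *g* and sequence lengths *L₁*, *L₂*, three components are
computed under a configurable scoring scheme (identity weight *wᵢ* > 0,
coverage weight *w_c*, gap weight *w_g* ≤ 0):

- AIS = *p* · *wᵢ* / 100 (alignment identity score)
- ACS = (*w_c* / 100) · Σ_{k=1,2} (100 − 100 · *L_k* / *l*) (coverage)
- AGS = *g* · *w_g* / 100 (gap penalty)

The **Discovery score** uses alignment evidence alone:

    DS = clamp₀¹⁰⁰( (AIS + ACS + AGS) · 100 / wᵢ )

The **Knowledge score** adds ordered domain-architecture evidence. Per
InterPro analysis tool, the two proteins' position-ordered signature lists
are labeled STONM (same type, order and number of motifs) ≻ STNM (same type
and number) ≻ STM (same type) ≻ NM (no match), or NP when at least one
protein has no prediction from that tool. With ITCS the sum of the per-tool
label weights over non-NP tools and maxITCS the corresponding sum of STONM
weights (NP tools are skipped on both sides, so missing predictions are
neutral):

    KS = clamp₀¹⁰⁰( (AIS + ACS + AGS + ITCS) · 100 / (wᵢ + maxITCS) )

with KS = DS when every tool is NP. Identical proteins with identical
annotations score exactly DS = KS = 100.

An SFPG is seeded per transcript: the seed plus every transcript whose pair
score meets the confidence score cutoff (CSC, default KS ≥ 95). Groups are
per-seed neighborhoods, deliberately *not* merged into connected components —
merging would pool proteins similar to the seed but not to each other.

Expression is recomputed from normalized FPKM (median-of-ratios size factors,
then length correction with RSEM effective lengths). A transcript shared by
several groups splits its FPKM either equally (**ED**) or proportionally to
group size (**GD**, the default — bigger groups model genetic redundancy).
Both rules conserve the per-sample expression total exactly; excluded-biotype
transcripts (nonsense-mediated decay, polymorphic pseudogenes, TR/IG genes)
never enter groups and pass through with their original FPKM.

## Worked example

Generate a synthetic bundle with two planted five-member protein families at
98% within-family identity (plus counts with planted size factors), then run
the full pipeline:

```
fuse fixtures --seed 5 --out bundle/
fuse run --fasta bundle/proteins.fa --blast bundle/blast.tsv \
         --interpro bundle/interpro.tsv --counts bundle/counts.tsv \
         --lengths bundle/lengths.tsv --csc 95 --method gd --out out/
```

The run prints the stage summary:

```
csc: 95
method: GD
n_excluded: 0
n_groups: 10
n_kept: 10
n_non_singleton: 10
n_scored_pairs: 20
pair_origins:
  different_gene_family: 0
  same_gene: 0
  same_gene_family: 20
  undefined: 0
score_type: KS
size_max: 5
size_mean: 5.0
size_median: 5.0
size_total: 50
```

Ten proteins form 20 within-family pairs, all categorized as same-gene-family
from their symbols; each of the ten transcripts seeds a group equal to its
planted family (size 5). `out/pair_scores.tsv` holds the score components —
for a within-family pair at 98% identity with full coverage and four tools
agreeing (STONM weight 10 each):

```
id_a   id_b   AIS   ACS  AGS  ITCS  DS    KS
P0_0   P0_1   98.0  0.0  -0.0 40.0  98.0  98.571428…
```

i.e. KS = (98 + 40)·100/(100 + 40). `out/group_expression.tsv` is the final
SFPG × sample matrix whose per-sample totals equal the FPKM totals in
`out/normalized_fpkm.tsv`.

The per-tool label weights and the three alignment weights are defaults of
this implementation and can be overridden with `--scheme scheme.yaml`.

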