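# orthocascade

Comparative-transcriptomics pipeline for species without a reference
genome: reciprocal-best-hit orthology against multiple reference species,
priority-cascade assignment into a non-redundant ortholog set,
cross-species sequence-identity statistics, and Fisher-exact annotation
enrichment — plus a fully seeded synthetic benchmark generator so every
stage can be validated against planted ground truth.

## The problem

A de-novo-assembled transcriptome (for instance from an emesis model
organism such as the least shrew) arrives as thousands of anonymous
transcript sequences. To attach biology to them, each transcript must be
tied to a known gene in well-annotated species. `orthocascade`
implements the standard desk workflow around precomputed BLAST tabular
alignments:

1. **Best hits.** For each query, keep the subject with the highest
   bitscore among hits with e-value ≤ cutoff (default 1e-5). Ties break
   deterministically by e-value, percent identity, then subject id;
   multiple HSPs of one query–subject pair are collapsed to the best HSP.
2. **Reciprocal best hits ("blast-back").** Transcript *f* and reference
   gene *r* are one-to-one orthologs iff *f*'s best hit is *r* **and**
   *r*'s best hit is *f*.
3. **Priority cascade.** With several reference species ordered by
   priority (default human → mouse → dog → ferret), each focal transcript
   is assigned to the *first* species in which it has a reciprocal pair,
   yielding a non-redundant ortholog set; transcripts with a pair in
   *every* species form the shared one-to-one ortholog set.
4. **Identity statistics.** Per-species mean percent identity (each
   ortholog one observation), compared between species pairs with a pooled
   two-proportion z-test: with p̂ = (p₁n₁ + p₂n₂)/(n₁ + n₂),

   z = (p₁ − p₂) / √( p̂(1 − p̂)(1/n₁ + 1/n₂) ).

   Genes ranked by identity to a chosen species are split into k-tiles
   (deciles by default; the remainder joins the most-conserved partition).
5. **Enrichment.** For gene set S, background B and term T, the one-sided
   Fisher exact p-value is the hypergeometric upper tail P(X ≥ a) with
   a = |S ∩ T|, evaluated in log space; Bonferroni (m·p) and
   Benjamini–Hochberg step-up adjustments are reported per table. An
   optional EASE variant (a − 1) reproduces DAVID's conservative score.

The synthetic generator plants everything this workflow must survive:
per-species divergence with a synonymous bias (so protein identity
exceeds nucleotide identity), paralogous duplicates, fragmented focal
transcripts (≥ 201 bp), per-species ortholog dropout, spurious alignment
noise, and annotation terms enriched in chosen subsets.

## Worked example

`examples/` holds one short script per capability. From
`examples/02_identity_statistics.py` (300 simulated genes, seed 42):

```
human  : nucleotide  88.56%  protein  90.72%  (n=290)
mouse  : nucleotide  85.88%  protein  88.18%  (n=277)
dog    : nucleotide  88.90%  protein  91.22%  (n=287)
ferret : nucleotide  88.66%  protein  90.88%  (n=289)
human vs mouse nucleotide identity (n~290): z = 0.956, one-tailed p = 0.17
same means at n=6,999 each: z = 4.746, one-tailed p = 1.04e-06
```

Each row is the unweighted mean identity over that species' reciprocal
pairs; protein exceeds nucleotide identity because most accepted
substitutions are synonymous. The z-test shows a ~2.7-point identity gap
is insignificant at a few hundred orthologs but decisive at
transcriptome scale. `examples/01_simulate_and_recover.py` shows perfect
cascade recovery (precision = recall = 1.0) on clean data, and
`examples/03_conservation_deciles_enrichment.py` shows a planted term
dominating its conservation decile at p ≈ 3e-28.

## Command line

```bash
orthocascade run-all --config examples/pipeline.yaml
orthocascade simulate|orthology|cascade|shared|stats|enrich --config <yaml> \
    [--seed N] [--evalue 1e-5] [--k 10] [--ease]
```

Stages communicate through TSV files under `outdir`; `run-all` finishes
with a manifest (seed, config, input checksums, row counts) and is
byte-for-byte idempotent. Point `hits_dir`, `focal_fasta`, `annotation`
and `gene_sets` at real BLAST tabular output, FASTA and annotation files
to run on real data; the annotated `examples/pipeline.yaml` documents
every field.

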