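# Methods

This note documents the models, statistical procedures and numerical
choices behind `orthocascade`, and what the synthetic benchmark does and
does not demonstrate about real data.

## Orthology model

Orthology is operationalised as the reciprocal best hit (RBH): focal
transcript *f* and reference gene *r* are called one-to-one orthologs
exactly when each is the other's top-scoring alignment hit across the
species boundary. RBH is deliberately conservative — members of large
gene families (recently duplicated paralogs) often fail the reciprocity
requirement and are excluded rather than mis-assigned. The pipeline makes
no attempt at many-to-many resolution, tree reconciliation or synteny;
reference identifiers are opaque strings, so whether the reference side
is transcripts or genes is the caller's choice.

**Best-hit determinism.** BLAST tabular output carries no tie-breaking
guarantee, so best hits are selected by an explicit total order:
bitscore (desc), e-value (asc), percent identity (desc), subject
identifier (asc). Multiple HSPs of one query–subject pair are collapsed
to the single highest-scoring HSP *before* subjects compete — scores are
never summed across HSPs, the simplest defensible reading of best-hit
logic over multi-HSP output. Hits failing the e-value cutoff (default
1e-5, a conventional transcript-orthology threshold, configurable) are
removed before any selection.

**Cascade.** Given reference species in priority order (default human,
mouse, dog, ferret — most-annotated first), each focal transcript is
assigned to the first species with a reciprocal pair. The result is
non-redundant by construction (each transcript appears once), covers the
union of the per-species pair sets, and is monotone: adding pairs to a
lower-priority species never changes an assignment already made at
higher priority. Transcripts with a pair in every species form the
shared set — the intersection of the per-species focal-id sets, bounded
above by the smallest per-species pair count.

**Identity bookkeeping.** The identity attached to a pair is the percent
identity of the focal→reference direction's best HSP; protein-level
identity is attached from a separate protein-level search when the same
pair is that search's best hit.

## Identity statistics

Mean identity is the unweighted arithmetic mean over pairs — each
ortholog is one observation regardless of alignment length — matching
how the per-species means feed the z-test with n = ortholog count.

The species comparison uses the pooled two-proportion z-test (no
continuity correction), treating a mean percent identity as a proportion
with n = number of orthologs. This is statistically loose — identities
are bounded means, not Bernoulli outcomes — and is implemented
deliberately to replicate the widely used online two-proportion
calculator workflow, not to endorse it; the implementation documents
this and callers wanting a defensible test should compare per-gene
identity distributions directly. The one-tailed alternative is p₁ > p₂
with the caller ordering arguments; the two-tailed p is
2·min(one-tailed, 1 − one-tailed). A pooled proportion of exactly 0 or 1
has zero variance and is a hard error.

Conservation partitioning takes genes pre-sorted by decreasing identity
(ties by identifier, stable) and fills k contiguous partitions: the
first takes ⌊N/k⌋ + (N mod k) genes — the remainder goes entirely to the
most-conserved partition — and the rest take ⌊N/k⌋ each, so
concatenation restores the input order and, e.g., 6,952 genes split
10 ways as 697 + 9×695.

Length summaries report exact integer min/max/total, mean, and sample
(n−1) standard deviation by default (population form behind a flag,
since conventions differ); histograms use fixed-width left-closed bins
anchored at 0, default 500 bp.

## Enrichment engine

For gene set S (harmonised to the annotation background B; genes outside
B are dropped and logged) and term T, the 2×2 table is a = |S∩T|,
b = |S|−a, c = |T|−a, d = |B|−|S|−c, and the one-sided p-value is the
hypergeometric upper tail P(X ≥ a), computed by summing the log-space
pmf (cached cumulative log-factorials, max-shifted logsumexp) — stable
out to backgrounds of tens of thousands of genes, and verified
cell-exactly against independent enumeration. The EASE flag substitutes
max(a−1, 0), DAVID's conservative variant; the default is the plain
Fisher tail.

Terms with a < min_count (default 2, DAVID's behaviour) are not tested
and do not count toward the adjustment universe m, which is therefore
per-run. Bonferroni is min(1, m·p); the "Benjamini" column is the
Benjamini–Hochberg step-up q-value (q₍ᵢ₎ = min_{j≥i} p₍ⱼ₎·m/j, capped at
1, returned in input order). Partition mode runs each conservation
k-tile against the annotation table's own background — the "rest of the
genome" — not the union of partitions; backgrounds are always explicit,
never implicit.

Annotation terms are flat labels: no ontology-graph propagation or
hierarchy handling. A caveat inherent to exact tests: Fisher p-values
are discrete and conservative (super-uniform under the null), so
calibration statements only hold where counts are large; see the
benchmark section.

## Synthetic benchmark

The generator emulates the data regime of a de-novo focal transcriptome
mapped against four mammalian reference gene sets.

* **Ancestral genes.** Random CDS (ATG + sense codons + stop; no
  premature stop in frame), internal codon count ~ Normal(440, 300)
  floored at 67 codons, flanked by 90 bp untranslated ends — mean
  transcript ≈ 1.5 kb, minimum compatible with the 201 bp fragment
  floor. Protein identity is computed on the CDS; nucleotide identity on
  the whole transcript.
* **Divergence.** Per-site substitution applied to the *reference* copy
  only, so each species' divergence parameter is the pairwise
  focal↔reference rate and expected nucleotide identity is exactly
  100·(1 − d). Defaults d = 0.114 (human), 0.1406 (mouse), 0.111 (dog),
  0.113 (ferret) emulate observed mammalian cDNA identities of ~85.9–88.9%.
* **Synonymous bias.** A fraction (default 0.75) of CDS substitutions is
  made silent by placing the change at a position of the codon with a
  synonymous alternative (usually the wobble position) — modelling
  purifying selection redirecting accepted substitutions to silent
  sites. Exactly one base changes per hit either way, so the nucleotide
  expectation is unaffected while amino-acid identity lands ~2.5 points
  above nucleotide identity, reproducing the protein > nucleotide
  pattern of real cross-mammal comparisons. This is a per-site model
  with a bias knob, not a full codon model (GY94 etc.): transparent
  expectations were preferred over mechanistic realism. Note the
  inequality direction requires the effective silent fraction to exceed
  2/3; at bias 0.5 a per-site model necessarily yields protein identity
  *below* nucleotide identity.
* **Confounders.** Paralogs (per-gene, per-species, default 5%) are
  duplicated into the reference sets only and diverge a further 0.08 —
  modelling reference gene families; the ortholog then outranks the
  paralog in bitscore. Fragmentation truncates focal transcripts to
  uniform windows ≥ 201 bp (default 10%), emulating incomplete
  assemblies. Dropout (default 5%, per species or global) removes the
  ortholog copy. Spurious hits (default 1% of true hits per direction)
  carry low identity and bitscore.
* **Hit tables.** One alignment row per true homolog pair, both
  directions, with percent identity computed exactly positionwise over
  the aligned window (no indels, so windows are coordinate-exact).
  Bitscore is the surrogate max(0, 2·matches − 3·mismatches) and the
  e-value K·L·2^(−bitscore) with fixed constants — monotone in alignment
  quality, which is all downstream logic consumes; neither is
  BLAST-calibrated.
* **Annotations.** Background terms annotate each gene independently
  (default probability 0.1); an enriched term raises that to
  min(1, fold·baseline) inside its target subset. Terms are expressed
  over focal transcript identifiers so gene sets, partitions and
  annotation share one identifier space.
* **Determinism.** One top-level seed; each stage draws from a
  `SeedSequence`-derived generator, so identical configs produce
  byte-identical FASTA, hit tables, annotation, truth files and pipeline
  outputs.

**What passing tests show — and don't.** Perfect recovery on the clean
fixture validates the *logic* (selection, reciprocity, cascade
accounting), not robustness to real BLAST behaviour: the generator has
no indels, no local-alignment ambiguity, no assembly chimeras, no
isoforms sharing exons, and its score surrogates are noiseless. Identity
calibration shows the statistics recover planted parameters, not that
real divergences follow this substitution model. The dropout expectation
(1−d)^k for the shared-set fraction holds because dropout is independent
across species; correlated gene loss would break it.

**Benchmark problem sizes** (chosen to keep the default suite and the
acceptance script in seconds-to-minutes on one CPU): 500 genes for
recovery and identity-calibration checks; 300 genes × 20 seeds for the
dropout expectation; enrichment power at a 1,000-gene background with a
50-gene target at 10-fold enrichment (100 replicates); null calibration
at a 7,000-gene background with a 700-gene set (200 replicates) — the
decile-versus-genome proportions of the motivating analysis, and the
regime where counts are large enough that the discreteness of exact-test
p-values is negligible and a uniformity (KS) check is meaningful; at toy
scale (hundreds of genes) the same check fails for any correct Fisher
implementation because the null p-value distribution is genuinely
sub-uniform.

## Formats and interfaces

FASTA is read via Biopython (identifiers = first whitespace token;
sequences uppercased; U→T in nucleotide mode; N/X allowed; duplicate ids
and illegal characters are hard errors naming the offender). BLAST
tabular is the standard 12-column `outfmt 6`; rows with any other column
count are hard errors naming the row. Writers emit canonical formatting
so read→write round-trips are byte-identical on generator output.
Annotation TSVs are 2–3 columns (term, gene[, name]); gene lists are one
identifier per line with `#` comments. Whether assembler isoform
suffixes (e.g. `_i1`) should be collapsed is left to upstream
preprocessing: the full first token is the identifier.

## Known limitations

* RBH under-calls orthologs in large gene families by design.
* The two-proportion z-test on mean identities is a faithful replication
  of a common but questionable practice (see above).
* The substitution model has no indels, rate heterogeneity or codon-level
  selection coefficients; fragment windows are uniform rather than
  coverage-driven.
* Enrichment treats terms as independent flat labels; no
  hierarchy-aware correction.
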