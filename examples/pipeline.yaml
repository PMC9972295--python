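# Annotated orthocascade pipeline configuration.
# Run with:  orthocascade run-all --config examples/pipeline.yaml

outdir: runs/demo          # all stage outputs land here
seed: 42                   # single top-level seed; every stage derives from it

# Reference species in cascade priority order (rank 1 first).  Each focal
# transcript is assigned to the first species in this list for which a
# reciprocal best hit exists.
species_priority: [human, mouse, dog, ferret]
focal_species: shrew

evalue_cutoff: 1.0e-5      # hits above this e-value never become best hits
partitions: 10             # conservation k-tiles (10 = deciles)
order_by: human            # species whose identity ranks genes and sorts the matrix

# Enrichment options
min_count: 2               # terms need >= this many set genes to be tested
ease: false                # true = DAVID-style EASE score (a-1 in the tail)

# Where to find alignment tables ({focal}_vs_{species}.nt.tsv and the
# reverse direction, 12-column BLAST tabular).  Defaults to
# <outdir>/simulated, i.e. the synthetic dataset written by the simulate
# stage.  Point it at real BLAST output to run on real data.
# hits_dir: /path/to/blast/tables
# focal_fasta: /path/to/focal_transcripts.fasta
# annotation: /path/to/annotation.tsv     # term <TAB> gene [<TAB> term name]
# gene_sets: [/path/to/candidates.txt]    # one identifier per line

# Synthetic dataset knobs (only used by the simulate stage); anything not
# set here keeps the generator defaults, which emulate four mammalian
# references at 11-14% nucleotide divergence.
simulate:
  n_genes: 300
  dropout_rate: 0.05       # per-species chance a gene has no ortholog copy
  paralog_rate: 0.05       # per-gene chance of a diverged duplicate per species
  fragment_rate: 0.10      # share of focal transcripts truncated (>= 201 bp kept)
  spurious_hit_rate: 0.01  # noise alignments as a fraction of true hits
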