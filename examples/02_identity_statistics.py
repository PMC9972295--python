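"""Cross-species identity means and the two-proportion z-test.

Simulates the default study conditions (four reference species at
realistic divergences, synonymous-biased substitution), computes
per-species mean nucleotide and protein identity over the reciprocal
pairs, and tests whether the focal-to-human identity significantly
exceeds the focal-to-mouse identity.
"""

from orthocascade import (
    SimulationConfig,
    annotate_protein_identity,
    best_hits,
    mean_identity,
    reciprocal_best_hits,
    simulate_dataset,
    two_proportion_ztest,
)

config = SimulationConfig(n_genes=300, seed=42)
sim = simulate_dataset(config)

means = {}
for species in config.reference_species:
    fwd_hits, rev_hits = sim.nt_hits[species]
    pairs = reciprocal_best_hits(best_hits(fwd_hits), best_hits(rev_hits))
    pairs = annotate_protein_identity(pairs, best_hits(sim.aa_hits[species][0]))
    nt = mean_identity(pairs, level="nucleotide")
    with_protein = [p for p in pairs if p.protein_identity is not None]
    aa = mean_identity(with_protein, level="protein")
    means[species] = (nt, len(pairs))
    print(f"{species:7s}: nucleotide {nt:6.2f}%  protein {aa:6.2f}%  (n={len(pairs)})")

print("Protein identity exceeds nucleotide identity in every species —")
print("the synonymous substitution bias leaves amino acids more conserved.")

(nt_h, n_h), (nt_m, n_m) = means["human"], means["mouse"]
result = two_proportion_ztest(nt_h / 100, nt_m / 100, n_h, n_m, tail="one")
print(f"human vs mouse nucleotide identity (n~{n_h}): z = {result.z:.3f}, "
      f"one-tailed p = {result.p_value:.3g}")
print("At a few hundred orthologs a ~2.7-point identity gap is not yet")
print("significant under this test; at transcriptome scale it is:")
at_scale = two_proportion_ztest(nt_h / 100, nt_m / 100, 6999, 6999, tail="one")
print(f"same means at n=6,999 each: z = {at_scale.z:.3f}, "
      f"one-tailed p = {at_scale.p_value:.3g}")
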