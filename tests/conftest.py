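import numpy as np
import pytest

from orthocascade import (
    SimulationConfig,
    annotate_protein_identity,
    best_hits,
    reciprocal_best_hits,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def zero_noise_sim():
    """Small synthetic dataset with no paralogs, fragments, dropout or noise."""
    config = SimulationConfig(
        n_genes=60,
        seed=5,
        paralog_rate=0.0,
        fragment_rate=0.0,
        dropout_rate=0.0,
        spurious_hit_rate=0.0,
        cds_length_distribution=(200.0, 80.0),
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def default_sim():
    """Small dataset at the default (noisy) study conditions."""
    config = SimulationConfig(n_genes=80, seed=7, cds_length_distribution=(200.0, 80.0))
    return simulate_dataset(config)


def rbh_pairs_for(sim, species, evalue_cutoff=1e-5, with_protein=False):
    """Reciprocal-best-hit pairs for one reference species of a simulation."""
    focal = sim.config.focal_species
    fwd_hits, rev_hits = sim.nt_hits[species]
    fwd = best_hits(fwd_hits, evalue_cutoff, focal, species)
    rev = best_hits(rev_hits, evalue_cutoff, species, focal)
    pairs = reciprocal_best_hits(fwd, rev)
    if with_protein:
        fwd_aa = best_hits(sim.aa_hits[species][0], evalue_cutoff, focal, species)
        pairs = annotate_protein_identity(pairs, fwd_aa)
    return pairs


def all_rbh_pairs(sim, evalue_cutoff=1e-5, with_protein=False):
    return {
        sp: rbh_pairs_for(sim, sp, evalue_cutoff, with_protein)
        for sp in sim.config.reference_species
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
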