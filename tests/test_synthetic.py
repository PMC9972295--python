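"""Synthetic-data generator: determinism, planted structure, calibration."""

import numpy as np
import pytest

from orthocascade.formats_io import read_blast_tab, write_blast_tab
from orthocascade.simulate import (
    SimulationConfig,
    SyntheticTruth,
    _CODON_AA,
    build_hit_tables,
    evolve_species,
    fragment_focal,
    generate_ancestral_genes,
    mutate_sequence,
    plant_annotations,
    simulate_dataset,
)
from conftest import all_rbh_pairs, rbh_pairs_for

SMALL = dict(cds_length_distribution=(150.0, 50.0), n_genes=40)


class TestGenerateAncestralGenes:
    def test_deterministic_from_seed(self):
        config = SimulationConfig(seed=3, **SMALL)
        a = generate_ancestral_genes(config)
        b = generate_ancestral_genes(config)
        assert [(r.transcript_id, r.sequence) for r in a] == [
            (r.transcript_id, r.sequence) for r in b
        ]

    def test_zero_genes(self):
        assert generate_ancestral_genes(SimulationConfig(n_genes=0)) == []

    def test_cds_structure_no_internal_stops(self):
        config = SimulationConfig(seed=9, n_genes=300, cds_length_distribution=(150.0, 50.0))
        for rec in generate_ancestral_genes(config):
            start, end = config.cds_bounds(len(rec))
            cds = rec.sequence[start:end]
            assert cds.startswith("ATG")
            assert _CODON_AA[cds[-3:]] == "*"
            internal = [cds[i : i + 3] for i in range(0, len(cds) - 3, 3)]
            assert all(_CODON_AA[c] != "*" for c in internal)

    def test_invalid_config_errors(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=-1)
        with pytest.raises(ValueError):
            SimulationConfig(dropout_rate=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(divergence={"human": 0.1})  # missing species


class TestEvolveSpecies:
    def test_zero_divergence_identical_sequences(self):
        config = SimulationConfig(
            seed=4, divergence={sp: 0.0 for sp in ("human", "mouse", "dog", "ferret")},
            dropout_rate=0.0, paralog_rate=0.0, **SMALL,
        )
        ancestral = generate_ancestral_genes(config)
        sets, truth = evolve_species(ancestral, config)
        by_gene = {r.transcript_id: r.sequence for r in ancestral}
        for sp in config.reference_species:
            for rec in sets[sp]:
                gene, _ = truth.gene_of(rec.transcript_id)
                assert rec.sequence == by_gene[gene]

    def test_full_dropout_removes_species(self):
        config = SimulationConfig(
            seed=4, dropout_rate={"human": 0.0, "mouse": 1.0, "dog": 0.0, "ferret": 0.0},
            paralog_rate=0.0, **SMALL,
        )
        sets, truth = evolve_species(generate_ancestral_genes(config), config)
        assert sets["mouse"] == []
        assert all(truth.ref_ids[g]["mouse"] is None for g in truth.genes)

    def test_nucleotide_identity_matches_model_expectation(self):
        """At divergence d the realized mean identity is 100(1-d) within 3 SE."""
        d = 0.14
        config = SimulationConfig(
            seed=12, n_genes=500, divergence={sp: d for sp in ("human", "mouse", "dog", "ferret")},
            synonymous_bias=0.5, dropout_rate=0.0, paralog_rate=0.0,
            fragment_rate=0.0, spurious_hit_rate=0.0,
            cds_length_distribution=(200.0, 60.0),
        )
        sim = simulate_dataset(config)
        identities = np.array([h.pct_identity for h in sim.nt_hits["human"][0]])
        lengths = np.array([h.aln_length for h in sim.nt_hits["human"][0]])
        expected = 100.0 * (1 - d)
        # binomial per-site variance aggregated over transcripts
        se = 100.0 * np.sqrt(np.mean(d * (1 - d) / lengths) / len(lengths))
        assert abs(identities.mean() - expected) < 3 * se

    def test_protein_identity_exceeds_nucleotide_at_default_bias(self, default_sim):
        pairs = rbh_pairs_for(default_sim, "human", with_protein=True)
        withp = [p for p in pairs if p.protein_identity is not None]
        nt = np.mean([p.nucleotide_identity for p in withp])
        aa = np.mean([p.protein_identity for p in withp])
        assert aa > nt

    def test_paralogs_recorded_in_truth(self):
        config = SimulationConfig(seed=8, paralog_rate=0.5, **SMALL)
        sets, truth = evolve_species(generate_ancestral_genes(config), config)
        n_paralogs = sum(len(v) for v in truth.paralogs.values())
        assert n_paralogs > 0
        for sp, per in truth.paralogs.items():
            ids = {r.transcript_id for r in sets[sp]}
            assert set(per) <= ids


class TestFragmentFocal:
    def _focal(self, config):
        sets, truth = evolve_species(generate_ancestral_genes(config), config)
        return sets[config.focal_species], truth

    def test_zero_rate_is_identity(self):
        config = SimulationConfig(seed=2, fragment_rate=0.0, **SMALL)
        focal, _ = self._focal(config)
        out, fmap = fragment_focal(focal, config)
        assert [(r.transcript_id, r.sequence) for r in out] == [
            (r.transcript_id, r.sequence) for r in focal
        ]
        assert all(ws == 0 and we == full for full, ws, we in fmap.values())

    def test_minimum_fragment_length_respected(self):
        config = SimulationConfig(seed=2, fragment_rate=1.0, min_fragment_bp=201, **SMALL)
        focal, _ = self._focal(config)
        out, _ = fragment_focal(focal, config)
        assert all(len(r) >= 201 for r in out)
        assert any(len(out[i]) < len(focal[i]) for i in range(len(out)))

    def test_fragments_are_exact_substrings_of_parent(self):
        config = SimulationConfig(seed=6, fragment_rate=1.0, **SMALL)
        focal, _ = self._focal(config)
        parents = {r.transcript_id: r.sequence for r in focal}
        out, fmap = fragment_focal(focal, config)
        for rec in out:
            full, ws, we = fmap[rec.transcript_id]
            assert rec.sequence == parents[rec.transcript_id][ws:we]
            assert full == len(parents[rec.transcript_id])


class TestHitTables:
    def test_pct_identity_matches_positionwise_oracle(self, default_sim):
        """Emitted true-pair identities equal an independent per-character
        comparison over the aligned window."""
        sim = default_sim
        focal = {r.transcript_id: r.sequence for r in sim.transcripts["shrew"]}
        refs = {r.transcript_id: r.sequence for r in sim.transcripts["human"]}
        checked = 0
        for h in sim.nt_hits["human"][0]:
            if h.subject_id not in refs or h.query_id not in focal:
                continue
            gene, _ = sim.truth.gene_of(h.subject_id)
            qgene, _ = sim.truth.gene_of(h.query_id)
            if gene is None or gene != qgene:
                continue  # spurious hit: identity is synthetic noise
            window = refs[h.subject_id][h.sstart - 1 : h.send]
            query = focal[h.query_id]
            matches = sum(1 for x, y in zip(query, window) if x == y)
            assert h.pct_identity == pytest.approx(100.0 * matches / len(window), abs=1e-9)
            checked += 1
        assert checked > 0

    def test_ortholog_outranks_paralog_in_bitscore(self):
        config = SimulationConfig(
            seed=21, n_genes=60, paralog_rate=0.6, fragment_rate=0.0,
            dropout_rate=0.0, spurious_hit_rate=0.0,
            cds_length_distribution=(150.0, 50.0),
        )
        sim = simulate_dataset(config)
        for sp in config.reference_species:
            by_query = {}
            for h in sim.nt_hits[sp][0]:
                by_query.setdefault(h.query_id, []).append(h)
            compared = 0
            for fid, hits in by_query.items():
                ortho = [h for h in hits if not sim.truth.gene_of(h.subject_id)[1]]
                para = [h for h in hits if sim.truth.gene_of(h.subject_id)[1]]
                if ortho and para:
                    assert max(h.bitscore for h in ortho) > max(h.bitscore for h in para)
                    compared += 1
            assert compared > 0
            break  # one species suffices; generation is shared

    def test_emitted_files_parse_losslessly(self, tmp_path, default_sim):
        fwd = default_sim.nt_hits["dog"][0]
        path = tmp_path / "hits.tsv"
        write_blast_tab(fwd, path)
        back = read_blast_tab(path)
        assert len(back) == len(fwd)
        assert [(h.query_id, h.subject_id, h.aln_length) for h in back] == [
            (h.query_id, h.subject_id, h.aln_length) for h in fwd
        ]

    def test_zero_noise_hit_count_equals_surviving_orthologs(self, zero_noise_sim):
        sim = zero_noise_sim
        for sp in sim.config.reference_species:
            survivors = sum(
                1 for g in sim.truth.genes if sim.truth.ref_ids[g][sp] is not None
            )
            assert len(sim.nt_hits[sp][0]) == survivors


class TestPlantAnnotations:
    def _truth(self, n=200):
        genes = tuple(f"g{i:04d}" for i in range(n))
        return SyntheticTruth(
            genes=genes,
            focal_ids={g: f"shrew_{g}" for g in genes},
            ref_ids={g: {} for g in genes},
            paralogs={},
            fragment_map={},
            cds={},
        )

    def test_fold_below_one_errors(self):
        truth = self._truth()
        with pytest.raises(ValueError):
            plant_annotations(truth, 5, {"T": (truth.genes[:10], 0.5)}, seed=1)

    def test_zero_terms_empty_table(self):
        table = plant_annotations(self._truth(), 0, seed=1)
        assert len(table) == 0

    def test_enriched_term_overrepresented_in_target(self):
        truth = self._truth(1000)
        subset = truth.genes[:100]
        table = plant_annotations(
            truth, 0, {"PLANTED": (subset, 8.0)}, baseline=0.05, seed=3
        )
        members = table.genes_for("PLANTED")
        target_ids = {truth.focal_ids[g] for g in subset}
        inside = len(members & target_ids) / len(target_ids)
        outside = len(members - target_ids) / (1000 - 100)
        assert inside > 4 * outside

    def test_unknown_subset_gene_errors(self):
        with pytest.raises(ValueError):
            plant_annotations(self._truth(), 0, {"T": (("nope",), 2.0)}, seed=1)


class TestDeterminismAndRecovery:
    def test_identical_seed_byte_identical_outputs(self, tmp_path):
        config = SimulationConfig(seed=13, **SMALL)
        dir_a, dir_b = tmp_path / "a", tmp_path / "b"
        simulate_dataset(config, out_dir=dir_a)
        simulate_dataset(config, out_dir=dir_b)
        files_a = sorted(p.name for p in dir_a.iterdir())
        assert files_a == sorted(p.name for p in dir_b.iterdir())
        for name in files_a:
            assert (dir_a / name).read_bytes() == (dir_b / name).read_bytes(), name

    def test_zero_noise_cascade_recovers_truth_exactly(self, zero_noise_sim):
        from orthocascade import cascade_assign, score_cascade

        sim = zero_noise_sim
        pairs = all_rbh_pairs(sim)
        assignments = cascade_assign(pairs, list(sim.config.reference_species))
        precision, recall = score_cascade(
            assignments, sim.truth, sim.config.reference_species
        )
        assert precision == 1.0 and recall == 1.0

    def test_dropout_scales_shared_set(self):
        from orthocascade import shared_orthologs

        config = SimulationConfig(
            seed=17, n_genes=300, dropout_rate=0.25, paralog_rate=0.0,
            fragment_rate=0.0, spurious_hit_rate=0.0,
            cds_length_distribution=(150.0, 50.0),
        )
        sim = simulate_dataset(config)
        shared = shared_orthologs(all_rbh_pairs(sim))
        assert set(shared.focal_ids()) == sim.truth.expected_shared()
        expected = 0.75 ** 4
        se = np.sqrt(expected * (1 - expected) / config.n_genes)
        assert abs(len(shared) / config.n_genes - expected) < 4 * se
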