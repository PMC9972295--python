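"""Stage orchestration: simulate, orthology, cascade, shared, stats, enrich.

Each stage is a plain function over a :class:`PipelineConfig`; the CLI in
:mod:`orthocascade.cli` is a thin wrapper.  Stages communicate through
TSV files under the configured output directory, so any stage can be
re-run in isolation, and a full run is idempotent: the same inputs,
config and seed produce byte-identical outputs (the manifest records
versions, seed and input checksums and contains no timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .formats_io import (
    FormatError,
    GeneSet,
    read_blast_tab,
    read_fasta,
    read_annotation_table,
    read_gene_set,
    read_pair_table,
    write_enrichment_table,
    write_ortholog_map,
    write_pair_table,
)
from .orthology import (
    annotate_protein_identity,
    best_hits,
    cascade_assign,
    reciprocal_best_hits,
    shared_orthologs,
)
from .identity_stats import (
    Partition,
    length_summary,
    mean_identity,
    partition_by_conservation,
    rank_by_identity,
    identity_matrix,
    two_proportion_ztest,
)
from .enrichment import enrich, enrich_partitions
from .simulate import SimulationConfig, simulate_dataset

__all__ = [
    "PipelineConfig",
    "cmd_simulate",
    "cmd_orthology",
    "cmd_cascade",
    "cmd_shared",
    "cmd_stats",
    "cmd_enrich",
    "cmd_run_all",
]

logger = logging.getLogger(__name__)

_CONFIG_FIELDS = {
    "outdir",
    "seed",
    "focal_species",
    "species_priority",
    "evalue_cutoff",
    "partitions",
    "min_count",
    "ease",
    "bin_width",
    "order_by",
    "ztest_tail",
    "hits_dir",
    "focal_fasta",
    "annotation",
    "gene_sets",
    "simulate",
}


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    focal_species: str = "shrew"
    species_priority: list[str] = field(
        default_factory=lambda: ["human", "mouse", "dog", "ferret"]
    )
    evalue_cutoff: float = 1e-5
    partitions: int = 10
    min_count: int = 2
    ease: bool = False
    bin_width: int = 500
    order_by: str = "human"
    ztest_tail: str = "one"
    hits_dir: str | None = None
    focal_fasta: str | None = None
    annotation: str | None = None
    gene_sets: list[str] = field(default_factory=list)
    simulate: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.species_priority:
            raise ValueError("species_priority must be non-empty")
        if len(set(self.species_priority)) != len(self.species_priority):
            raise ValueError(f"species_priority has duplicates: {self.species_priority}")
        if self.partitions < 1:
            raise ValueError("partitions must be >= 1")
        if self.order_by not in self.species_priority:
            raise ValueError(
                f"order_by {self.order_by!r} is not in species_priority {self.species_priority}"
            )

    @classmethod
    def from_dict(cls, data: Mapping[str, Any], **overrides: Any) -> "PipelineConfig":
        merged = {**data, **{k: v for k, v in overrides.items() if v is not None}}
        unknown = set(merged) - _CONFIG_FIELDS
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        if "outdir" not in merged:
            raise ValueError("config is missing required field 'outdir'")
        return cls(**merged)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must be a YAML mapping")
        return cls.from_dict(data, **overrides)

    # --- derived paths -----------------------------------------------------

    @property
    def out(self) -> Path:
        return Path(self.outdir)

    @property
    def simulated_dir(self) -> Path:
        return self.out / "simulated"

    @property
    def hits_path(self) -> Path:
        return Path(self.hits_dir) if self.hits_dir else self.simulated_dir

    def simulation_config(self) -> SimulationConfig:
        params = dict(self.simulate)
        params.setdefault("seed", self.seed)
        params.setdefault("focal_species", self.focal_species)
        params.setdefault("reference_species", tuple(self.species_priority))
        if isinstance(params.get("reference_species"), list):
            params["reference_species"] = tuple(params["reference_species"])
        if isinstance(params.get("cds_length_distribution"), list):
            params["cds_length_distribution"] = tuple(params["cds_length_distribution"])
        return SimulationConfig(**params)


def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing {what}: {path}")
    return path


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def cmd_simulate(config: PipelineConfig):
    """Generate the synthetic dataset on disk under ``<outdir>/simulated``."""
    sim = simulate_dataset(config.simulation_config(), out_dir=config.simulated_dir)
    n_seqs = sum(len(v) for v in sim.transcripts.values())
    logger.info("simulate: wrote %d sequences for %d species to %s",
                n_seqs, len(sim.transcripts), config.simulated_dir)
    return sim


def _load_pairs(config: PipelineConfig) -> dict[str, list]:
    pairs_dir = config.out / "pairs"
    return {
        sp: read_pair_table(_require(pairs_dir / f"{sp}.tsv", f"{sp} pair table"), sp)
        for sp in config.species_priority
    }


def cmd_orthology(config: PipelineConfig) -> dict[str, set]:
    """Compute per-species reciprocal-best-hit pair tables from hit files."""
    hits_dir = config.hits_path
    focal = config.focal_species
    pairs_dir = config.out / "pairs"
    pairs_dir.mkdir(parents=True, exist_ok=True)
    pairs_by_species: dict[str, set] = {}
    for sp in config.species_priority:
        fwd_hits = read_blast_tab(
            _require(hits_dir / f"{focal}_vs_{sp}.nt.tsv", "forward hit table")
        )
        rev_hits = read_blast_tab(
            _require(hits_dir / f"{sp}_vs_{focal}.nt.tsv", "reverse hit table")
        )
        fwd = best_hits(fwd_hits, config.evalue_cutoff, focal, sp)
        rev = best_hits(rev_hits, config.evalue_cutoff, sp, focal)
        pairs = reciprocal_best_hits(fwd, rev)
        aa_path = hits_dir / f"{focal}_vs_{sp}.aa.tsv"
        if aa_path.exists():
            fwd_aa = best_hits(read_blast_tab(aa_path), config.evalue_cutoff, focal, sp)
            pairs = annotate_protein_identity(pairs, fwd_aa)
        write_pair_table(pairs, pairs_dir / f"{sp}.tsv")
        logger.info("orthology[%s]: %d reciprocal pairs", sp, len(pairs))
        pairs_by_species[sp] = pairs
    return pairs_by_species


def cmd_cascade(config: PipelineConfig):
    """Non-redundant priority-cascade assignment plus a per-species count summary."""
    pairs = _load_pairs(config)
    assignments = cascade_assign(pairs, config.species_priority)
    write_ortholog_map(assignments, config.out / "cascade_assignments.tsv")
    counts = {sp: 0 for sp in config.species_priority}
    for a in assignments:
        counts[a.reference_species] += 1
    with open(config.out / "cascade_summary.tsv", "w") as handle:
        handle.write("species\trank\tcount\n")
        for rank, sp in enumerate(config.species_priority, start=1):
            handle.write(f"{sp}\t{rank}\t{counts[sp]}\n")
    logger.info("cascade: %d non-redundant assignments (%s)", len(assignments),
                ", ".join(f"{sp}={counts[sp]}" for sp in config.species_priority))
    return assignments


def cmd_shared(config: PipelineConfig):
    """Focal transcripts with a reciprocal pair in every species."""
    pairs = _load_pairs(config)
    shared = shared_orthologs(pairs)
    with open(config.out / "shared_orthologs.tsv", "w") as handle:
        handle.write("focal_id\t" + "\t".join(shared.species) + "\n")
        for focal_id in shared.focal_ids():
            row = shared.rows[focal_id]
            handle.write(
                focal_id + "\t" + "\t".join(row[sp].reference_id for sp in shared.species) + "\n"
            )
    logger.info("shared: %d transcripts shared across %d species",
                len(shared), len(shared.species))
    return shared


def cmd_stats(config: PipelineConfig) -> dict[str, Any]:
    """Length summary, identity means, z-test report, identity matrix, partitions."""
    stats_dir = config.out / "stats"
    stats_dir.mkdir(parents=True, exist_ok=True)
    focal_fasta = Path(config.focal_fasta) if config.focal_fasta else (
        config.simulated_dir / f"{config.focal_species}.fasta"
    )
    transcripts = read_fasta(_require(focal_fasta, "focal transcript FASTA"),
                             species=config.focal_species)
    summary = length_summary(transcripts, bin_width=config.bin_width)
    with open(stats_dir / "length_summary.tsv", "w") as handle:
        handle.write("n\tmin_bp\tmax_bp\tmean_bp\tsd_bp\ttotal_bp\n")
        handle.write(
            f"{summary.n}\t{summary.min_bp}\t{summary.max_bp}\t"
            f"{summary.mean_bp:.3f}\t{summary.sd_bp:.3f}\t{summary.total_bp}\n"
        )
    with open(stats_dir / "length_histogram.tsv", "w") as handle:
        handle.write("bin_left\tbin_right\tcount\n")
        for left, right, count in summary.histogram:
            handle.write(f"{left}\t{right}\t{count}\n")
    logger.info("stats: %d transcripts, mean length %.1f bp", summary.n, summary.mean_bp)

    pairs = _load_pairs(config)
    means: dict[tuple[str, str], tuple[float, int]] = {}
    with open(stats_dir / "identity_means.tsv", "w") as handle:
        handle.write("species\tlevel\tn\tmean_identity\n")
        for sp in config.species_priority:
            for level in ("nucleotide", "protein"):
                usable = [
                    p for p in pairs[sp]
                    if (p.nucleotide_identity if level == "nucleotide" else p.protein_identity)
                    is not None
                ]
                if not usable:
                    continue
                mean = mean_identity(usable, level=level)
                means[(sp, level)] = (mean, len(usable))
                handle.write(f"{sp}\t{level}\t{len(usable)}\t{mean:.3f}\n")

    with open(stats_dir / "ztest_report.tsv", "w") as handle:
        handle.write("level\tspecies_high\tspecies_low\tp1\tp2\tn1\tn2\tz\tp_value\ttail\n")
        for level in ("nucleotide", "protein"):
            sps = [sp for sp in config.species_priority if (sp, level) in means]
            for i, sp_a in enumerate(sps):
                for sp_b in sps[i + 1 :]:
                    (m_a, n_a), (m_b, n_b) = means[(sp_a, level)], means[(sp_b, level)]
                    hi, lo = ((sp_a, m_a, n_a), (sp_b, m_b, n_b)) if m_a >= m_b else (
                        (sp_b, m_b, n_b), (sp_a, m_a, n_a))
                    res = two_proportion_ztest(
                        hi[1] / 100.0, lo[1] / 100.0, hi[2], lo[2], tail=config.ztest_tail
                    )
                    handle.write(
                        f"{level}\t{hi[0]}\t{lo[0]}\t{res.p1:.6f}\t{res.p2:.6f}\t"
                        f"{res.n1}\t{res.n2}\t{res.z:.4f}\t{res.p_value:.6g}\t{res.tail}\n"
                    )

    ranked = rank_by_identity(pairs, config.order_by)
    if config.gene_sets:
        gene_set = read_gene_set(config.gene_sets[0])
    else:
        gene_set = GeneSet("all_ranked", frozenset(g for g, _ in ranked))
    matrix = identity_matrix(gene_set, pairs, order_by=config.order_by)
    matrix.to_tsv(stats_dir / "identity_matrix.tsv")

    parts = partition_by_conservation(ranked, config.partitions)
    rank_lookup = dict(ranked)
    with open(stats_dir / "partitions.tsv", "w") as handle:
        handle.write("partition\tgene\tidentity\n")
        for part in parts:
            for gene in part.members:
                handle.write(f"{part.index}\t{gene}\t{rank_lookup[gene]:.3f}\n")
    logger.info("stats: %d partitions over %d ranked genes", len(parts), len(ranked))
    return {"length": summary, "means": means, "partitions": parts, "matrix": matrix}


def _read_partitions(path: Path) -> list[Partition]:
    groups: dict[int, list[tuple[str, float]]] = {}
    with open(path) as handle:
        header = handle.readline()
        for line in handle:
            idx_s, gene, identity = line.rstrip("\n").split("\t")
            groups.setdefault(int(idx_s), []).append((gene, float(identity)))
    parts = []
    for idx in sorted(groups):
        members = tuple(g for g, _ in groups[idx])
        values = [v for _, v in groups[idx]]
        parts.append(Partition(index=idx, members=members,
                               identity_range=(max(values), min(values))))
    return parts


def cmd_enrich(config: PipelineConfig) -> dict[str, Any]:
    """Enrichment tables for each conservation partition and configured gene set."""
    annotation_path = Path(config.annotation) if config.annotation else (
        config.simulated_dir / "annotation.tsv"
    )
    annotation = read_annotation_table(_require(annotation_path, "annotation table"))
    enrich_dir = config.out / "enrichment"
    enrich_dir.mkdir(parents=True, exist_ok=True)
    results: dict[str, Any] = {}
    partitions_path = config.out / "stats" / "partitions.tsv"
    if partitions_path.exists():
        parts = _read_partitions(partitions_path)
        per_partition = enrich_partitions(
            parts, annotation, min_count=config.min_count, ease=config.ease
        )
        for idx, rows in per_partition.items():
            write_enrichment_table(rows, enrich_dir / f"partition_{idx:02d}.tsv")
            logger.info("enrich[partition %d]: %d terms tested", idx, len(rows))
        results["partitions"] = per_partition
    for path in config.gene_sets:
        gene_set = read_gene_set(path)
        rows = enrich(gene_set, annotation, min_count=config.min_count, ease=config.ease)
        write_enrichment_table(rows, enrich_dir / f"{gene_set.name}.tsv")
        logger.info("enrich[%s]: %d terms tested", gene_set.name, len(rows))
        results[gene_set.name] = rows
    return results


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for block in iter(lambda: handle.read(65536), b""):
            digest.update(block)
    return digest.hexdigest()


def _row_count(path: Path) -> int:
    with open(path) as handle:
        return sum(1 for _ in handle)


def cmd_run_all(config: PipelineConfig) -> Path:
    """All stages in dependency order, finishing with a reproducibility manifest."""
    config.out.mkdir(parents=True, exist_ok=True)
    if config.simulate or not config.hits_dir:
        cmd_simulate(config)
    cmd_orthology(config)
    cmd_cascade(config)
    cmd_shared(config)
    cmd_stats(config)
    cmd_enrich(config)
    inputs = sorted(
        p for p in config.hits_path.glob("*") if p.is_file()
    )
    outputs = sorted(
        p
        for pattern in ("pairs/*.tsv", "cascade_*.tsv", "shared_orthologs.tsv",
                        "stats/*.tsv", "enrichment/*.tsv")
        for p in config.out.glob(pattern)
    )
    manifest = {
        "package": "orthocascade",
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "inputs": {str(p.relative_to(config.out)) if p.is_relative_to(config.out) else str(p): _sha256(p) for p in inputs},
        "outputs": {str(p.relative_to(config.out)): _row_count(p) for p in outputs},
    }
    manifest_path = config.out / "manifest.json"
    with open(manifest_path, "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    logger.info("run-all: manifest written to %s", manifest_path)
    return manifest_path
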