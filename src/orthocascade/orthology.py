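"""Reciprocal-best-hit orthology and priority-cascade assignment.

The orthology model: a focal-species transcript and a reference-species
gene are called one-to-one orthologs when each is the other's top-scoring
alignment hit ("blast-back").  With several reference species, every focal
transcript is then assigned to the highest-priority species in which it
has a reciprocal pair, producing a non-redundant ortholog set; transcripts
with a reciprocal pair in *every* species form the shared ortholog set.

Best-hit selection is deterministic: hits are filtered by e-value, HSPs of
one query-subject pair are collapsed to the highest-scoring HSP, and ties
break by bitscore, then e-value, then percent identity, then lexicographic
subject id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from .formats_io import HitRecord

__all__ = [
    "BestHit",
    "BestHitMap",
    "OrthologPair",
    "OrthologAssignment",
    "SharedOrthologSet",
    "best_hits",
    "reciprocal_best_hits",
    "annotate_protein_identity",
    "cascade_assign",
    "shared_orthologs",
]

DEFAULT_EVALUE_CUTOFF = 1e-5


class BestHit(NamedTuple):
    subject_id: str
    bitscore: float
    evalue: float
    pct_identity: float


@dataclass(frozen=True)
class BestHitMap:
    """Per-query single best subject for one (query species, subject species) direction."""

    query_species: str
    subject_species: str
    entries: Mapping[str, BestHit]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class OrthologPair:
    """A reciprocal best-hit pair between a focal transcript and a reference gene.

    Identity values are taken from the focal-to-reference direction's best
    HSP; protein identity is absent until attached from a protein-level
    search.
    """

    focal_id: str
    reference_id: str
    reference_species: str
    nucleotide_identity: float | None = None
    protein_identity: float | None = None


@dataclass(frozen=True)
class OrthologAssignment:
    """A focal transcript bound to exactly one reference species' ortholog.

    ``priority_rank`` is 1 for the highest-priority species in the
    configured order.
    """

    focal_id: str
    reference_species: str
    reference_id: str
    priority_rank: int
    nucleotide_identity: float | None = None


@dataclass(frozen=True)
class SharedOrthologSet:
    """Focal transcripts having a reciprocal pair in every configured species."""

    species: tuple[str, ...]
    rows: Mapping[str, Mapping[str, OrthologPair]]  # focal_id -> species -> pair

    def __len__(self) -> int:
        return len(self.rows)

    def focal_ids(self) -> list[str]:
        return sorted(self.rows)


def _hsp_sort_key(hit: HitRecord):
    return (-hit.bitscore, hit.evalue, -hit.pct_identity)


def _best_hit_sort_key(hit: HitRecord):
    # bitscore desc, e-value asc, identity desc, subject id asc
    return (-hit.bitscore, hit.evalue, -hit.pct_identity, hit.subject_id)


def best_hits(
    hits: Iterable[HitRecord],
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    query_species: str = "",
    subject_species: str = "",
) -> BestHitMap:
    """Select, per query, the single best subject among e-value-passing hits.

    Multiple HSPs of one query-subject pair are first collapsed to the
    highest-bitscore HSP; the surviving candidates then compete by the
    deterministic tie-break order (bitscore, e-value, identity, subject id).
    Empty input yields an empty map.
    """
    per_pair: dict[tuple[str, str], HitRecord] = {}
    for hit in hits:
        if hit.evalue > evalue_cutoff:
            continue
        key = (hit.query_id, hit.subject_id)
        cur = per_pair.get(key)
        if cur is None or _hsp_sort_key(hit) < _hsp_sort_key(cur):
            per_pair[key] = hit
    per_query: dict[str, HitRecord] = {}
    for hit in per_pair.values():
        cur = per_query.get(hit.query_id)
        if cur is None or _best_hit_sort_key(hit) < _best_hit_sort_key(cur):
            per_query[hit.query_id] = hit
    entries = {
        q: BestHit(h.subject_id, h.bitscore, h.evalue, h.pct_identity)
        for q, h in per_query.items()
    }
    return BestHitMap(query_species, subject_species, entries)


def reciprocal_best_hits(fwd: BestHitMap, rev: BestHitMap) -> set[OrthologPair]:
    """Pairs (f, r) with fwd[f] = r and rev[r] = f; one-to-one by construction.

    ``fwd`` is the focal-to-reference direction and supplies the pair's
    nucleotide identity.
    """
    species = fwd.subject_species or rev.query_species
    pairs: set[OrthologPair] = set()
    for focal_id, fwd_hit in fwd.entries.items():
        back = rev.entries.get(fwd_hit.subject_id)
        if back is not None and back.subject_id == focal_id:
            pairs.add(
                OrthologPair(
                    focal_id=focal_id,
                    reference_id=fwd_hit.subject_id,
                    reference_species=species,
                    nucleotide_identity=fwd_hit.pct_identity,
                )
            )
    return pairs


def annotate_protein_identity(
    pairs: Iterable[OrthologPair], protein_fwd: BestHitMap
) -> set[OrthologPair]:
    """Attach protein-level identity where the protein search found the same pair."""
    out: set[OrthologPair] = set()
    for pair in pairs:
        hit = protein_fwd.entries.get(pair.focal_id)
        identity = hit.pct_identity if hit is not None and hit.subject_id == pair.reference_id else None
        out.add(
            OrthologPair(
                focal_id=pair.focal_id,
                reference_id=pair.reference_id,
                reference_species=pair.reference_species,
                nucleotide_identity=pair.nucleotide_identity,
                protein_identity=identity,
            )
        )
    return out


def _index_pairs(pairs: Iterable[OrthologPair], species: str) -> dict[str, OrthologPair]:
    indexed: dict[str, OrthologPair] = {}
    for pair in pairs:
        if pair.focal_id in indexed:
            raise ValueError(
                f"duplicate focal id {pair.focal_id!r} in {species!r} pair set "
                "(violates the one-to-one input contract)"
            )
        indexed[pair.focal_id] = pair
    return indexed


def cascade_assign(
    pairs_by_species: Mapping[str, Iterable[OrthologPair]],
    priority: Sequence[str],
) -> list[OrthologAssignment]:
    """Assign each focal transcript to its highest-priority reciprocal partner.

    ``priority`` must list every species of ``pairs_by_species`` exactly
    once (rank 1 = first).  The result covers the union of per-species
    focal ids, each focal transcript appearing exactly once; transcripts
    with no reciprocal pair anywhere are absent.
    """
    if sorted(priority) != sorted(pairs_by_species):
        raise ValueError(
            f"priority {list(priority)!r} must list every species of "
            f"{sorted(pairs_by_species)!r} exactly once"
        )
    indexed = {
        sp: _index_pairs(pairs_by_species[sp], sp) for sp in priority
    }
    all_focal = sorted(set().union(*(set(idx) for idx in indexed.values())) if indexed else set())
    assignments: list[OrthologAssignment] = []
    for focal_id in all_focal:
        for rank, sp in enumerate(priority, start=1):
            pair = indexed[sp].get(focal_id)
            if pair is not None:
                assignments.append(
                    OrthologAssignment(
                        focal_id=focal_id,
                        reference_species=sp,
                        reference_id=pair.reference_id,
                        priority_rank=rank,
                        nucleotide_identity=pair.nucleotide_identity,
                    )
                )
                break
    return assignments


def shared_orthologs(
    pairs_by_species: Mapping[str, Iterable[OrthologPair]],
) -> SharedOrthologSet:
    """Focal transcripts with a reciprocal pair in every configured species."""
    species = tuple(pairs_by_species)
    indexed = {sp: _index_pairs(pairs_by_species[sp], sp) for sp in species}
    if not indexed:
        return SharedOrthologSet(species=(), rows={})
    common = set.intersection(*(set(idx) for idx in indexed.values()))
    rows = {
        focal_id: {sp: indexed[sp][focal_id] for sp in species}
        for focal_id in sorted(common)
    }
    return SharedOrthologSet(species=species, rows=rows)
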