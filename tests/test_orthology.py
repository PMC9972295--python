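"""Best-hit selection, reciprocal best hits, cascade and shared-set logic.

The randomized checks compare the implementation against brute-force
oracles: an exhaustive per-query argmax with an explicit sort key for
best hits, a set comprehension over all (focal, reference) combinations
for reciprocity, and a first-match scan per transcript for the cascade.
"""

import numpy as np
import pytest

from orthocascade.formats_io import HitRecord
from orthocascade.orthology import (
    BestHit,
    BestHitMap,
    OrthologPair,
    best_hits,
    cascade_assign,
    reciprocal_best_hits,
    shared_orthologs,
)

SPECIES_ORDER = ["human", "mouse", "dog", "ferret"]


def _hit(q, s, bitscore, evalue=1e-50, pident=90.0, length=100):
    return HitRecord(q, s, pident, length, 5, 0, 1, length, 1, length, evalue, float(bitscore))


def _oracle_best_hits(hits, cutoff):
    """Brute force: filter, collapse HSPs per pair, then per-query argmax."""
    passing = [h for h in hits if h.evalue <= cutoff]
    per_pair = {}
    for h in passing:
        key = (h.query_id, h.subject_id)
        per_pair.setdefault(key, []).append(h)
    collapsed = [
        sorted(group, key=lambda h: (-h.bitscore, h.evalue, -h.pct_identity))[0]
        for group in per_pair.values()
    ]
    result = {}
    for q in {h.query_id for h in collapsed}:
        candidates = [h for h in collapsed if h.query_id == q]
        best = sorted(
            candidates,
            key=lambda h: (-h.bitscore, h.evalue, -h.pct_identity, h.subject_id),
        )[0]
        result[q] = best.subject_id
    return result


class TestBestHits:
    def test_dominant_bitscore_wins(self):
        bh = best_hits([_hit("q1", "s1", 370), _hit("q1", "s2", 200)])
        assert bh.entries["q1"].subject_id == "s1"

    def test_tie_broken_by_lower_evalue(self):
        bh = best_hits(
            [_hit("q1", "s1", 370, evalue=1e-50), _hit("q1", "s2", 370, evalue=1e-60)]
        )
        assert bh.entries["q1"].subject_id == "s2"

    def test_tie_broken_by_identity_then_subject_id(self):
        bh = best_hits(
            [
                _hit("q1", "s2", 370, evalue=1e-50, pident=95.0),
                _hit("q1", "s1", 370, evalue=1e-50, pident=90.0),
            ]
        )
        assert bh.entries["q1"].subject_id == "s2"
        bh = best_hits(
            [_hit("q1", "s2", 370), _hit("q1", "s1", 370)]
        )
        assert bh.entries["q1"].subject_id == "s1"

    def test_evalue_cutoff_filters_before_selection(self):
        bh = best_hits(
            [_hit("q1", "s1", 500, evalue=1.0), _hit("q1", "s2", 100, evalue=1e-30)],
            evalue_cutoff=1e-5,
        )
        assert bh.entries["q1"].subject_id == "s2"

    def test_multiple_hsps_collapse_to_best_single_hsp(self):
        # pair (q1,s1) has two HSPs (300+250); best single HSP (300) loses
        # to s2's 320 — HSPs must not be summed
        bh = best_hits(
            [
                _hit("q1", "s1", 300),
                _hit("q1", "s1", 250),
                _hit("q1", "s2", 320),
            ]
        )
        assert bh.entries["q1"].subject_id == "s2"

    def test_empty_input_empty_map(self):
        assert len(best_hits([])) == 0

    def test_matches_bruteforce_oracle_on_random_instances(self, rng):
        for _ in range(200):
            hits = [
                _hit(
                    f"q{int(rng.integers(0, 20))}",
                    f"s{int(rng.integers(0, 15))}",
                    bitscore=float(rng.choice([100, 200, 300, 370])),
                    evalue=float(10.0 ** -rng.integers(3, 80)),
                    pident=float(rng.choice([80.0, 90.0, 95.0])),
                )
                for _ in range(int(rng.integers(1, 40)))
            ]
            got = {q: e.subject_id for q, e in best_hits(hits).entries.items()}
            assert got == _oracle_best_hits(hits, 1e-5)


def _random_map(rng, q_prefix, s_prefix, n=30):
    return BestHitMap(
        "", "",
        {
            f"{q_prefix}{i}": BestHit(
                f"{s_prefix}{int(rng.integers(0, n))}", 100.0, 1e-20, 90.0
            )
            for i in range(n)
        },
    )


class TestReciprocalBestHits:
    def test_perfect_reciprocity(self):
        fwd = BestHitMap("shrew", "human", {"q1": BestHit("s1", 370.0, 1e-50, 95.0)})
        rev = BestHitMap("human", "shrew", {"s1": BestHit("q1", 370.0, 1e-50, 95.0)})
        pairs = reciprocal_best_hits(fwd, rev)
        assert {(p.focal_id, p.reference_id) for p in pairs} == {("q1", "s1")}
        assert next(iter(pairs)).nucleotide_identity == 95.0

    def test_broken_reciprocity_yields_nothing(self):
        fwd = BestHitMap("shrew", "human", {"q1": BestHit("s1", 370.0, 1e-50, 95.0)})
        rev = BestHitMap("human", "shrew", {"s1": BestHit("q2", 370.0, 1e-50, 95.0)})
        assert reciprocal_best_hits(fwd, rev) == set()

    def test_matches_set_comprehension_oracle_and_is_one_to_one(self, rng):
        for _ in range(200):
            fwd = _random_map(rng, "q", "s")
            rev = _random_map(rng, "s", "q")
            pairs = reciprocal_best_hits(fwd, rev)
            oracle = {
                (f, fwd.entries[f].subject_id)
                for f in fwd.entries
                if fwd.entries[f].subject_id in rev.entries
                and rev.entries[fwd.entries[f].subject_id].subject_id == f
            }
            assert {(p.focal_id, p.reference_id) for p in pairs} == oracle
            focals = [p.focal_id for p in pairs]
            refs = [p.reference_id for p in pairs]
            assert len(set(focals)) == len(focals)
            assert len(set(refs)) == len(refs)

    def test_symmetry_under_argument_swap(self, rng):
        fwd = _random_map(rng, "q", "s")
        rev = _random_map(rng, "s", "q")
        direct = {(p.focal_id, p.reference_id) for p in reciprocal_best_hits(fwd, rev)}
        swapped = {(p.reference_id, p.focal_id) for p in reciprocal_best_hits(rev, fwd)}
        assert direct == swapped


def _pair(focal, ref, species, identity=90.0):
    return OrthologPair(focal, ref, species, identity)


class TestCascadeAssign:
    def test_highest_priority_species_wins(self):
        pairs = {
            "human": {_pair("t1", "h1", "human")},
            "mouse": set(),
            "dog": set(),
            "ferret": {_pair("t1", "f1", "ferret")},
        }
        (assignment,) = cascade_assign(pairs, SPECIES_ORDER)
        assert assignment.reference_species == "human"
        assert assignment.priority_rank == 1

    def test_unmatched_transcript_absent(self):
        pairs = {sp: set() for sp in SPECIES_ORDER}
        pairs["human"] = {_pair("t1", "h1", "human")}
        assignments = cascade_assign(pairs, SPECIES_ORDER)
        assert {a.focal_id for a in assignments} == {"t1"}

    def test_duplicate_focal_in_one_species_errors(self):
        pairs = {
            "human": [_pair("t1", "h1", "human"), _pair("t1", "h2", "human")],
            "mouse": set(),
            "dog": set(),
            "ferret": set(),
        }
        with pytest.raises(ValueError, match="t1"):
            cascade_assign(pairs, SPECIES_ORDER)

    def test_priority_must_cover_species(self):
        with pytest.raises(ValueError):
            cascade_assign({"human": set()}, ["human", "mouse"])

    def test_matches_first_match_scan_and_union_size(self, rng):
        for _ in range(100):
            pairs = {
                sp: {
                    _pair(f"t{i}", f"{sp}_{i}", sp)
                    for i in rng.choice(50, size=int(rng.integers(0, 30)), replace=False)
                }
                for sp in SPECIES_ORDER
            }
            assignments = cascade_assign(pairs, SPECIES_ORDER)
            union = set().union(*({p.focal_id for p in pairs[sp]} for sp in SPECIES_ORDER))
            assert len(assignments) == len(union)
            by_focal = {a.focal_id: a for a in assignments}
            for focal in union:
                expected_sp = next(
                    sp for sp in SPECIES_ORDER
                    if focal in {p.focal_id for p in pairs[sp]}
                )
                assert by_focal[focal].reference_species == expected_sp
                assert by_focal[focal].priority_rank == SPECIES_ORDER.index(expected_sp) + 1

    def test_monotonicity_lower_priority_additions_do_not_reassign(self):
        pairs = {
            "human": {_pair("t1", "h1", "human")},
            "mouse": set(),
            "dog": set(),
            "ferret": set(),
        }
        before = {a.focal_id: a for a in cascade_assign(pairs, SPECIES_ORDER)}
        pairs["ferret"] = {_pair("t1", "f1", "ferret"), _pair("t2", "f2", "ferret")}
        after = {a.focal_id: a for a in cascade_assign(pairs, SPECIES_ORDER)}
        assert after["t1"] == before["t1"]
        assert after["t2"].reference_species == "ferret"


class TestSharedOrthologs:
    def test_present_in_all_species(self):
        pairs = {sp: {_pair("t1", f"{sp}_1", sp)} for sp in SPECIES_ORDER}
        shared = shared_orthologs(pairs)
        assert shared.focal_ids() == ["t1"]
        assert set(shared.rows["t1"]) == set(SPECIES_ORDER)

    def test_missing_one_species_excluded(self):
        pairs = {sp: {_pair("t1", f"{sp}_1", sp)} for sp in SPECIES_ORDER[:-1]}
        pairs["ferret"] = set()
        assert len(shared_orthologs(pairs)) == 0

    def test_matches_intersection_oracle_and_bounds(self, rng):
        for _ in range(100):
            pairs = {
                sp: {
                    _pair(f"t{i}", f"{sp}_{i}", sp)
                    for i in rng.choice(40, size=int(rng.integers(0, 30)), replace=False)
                }
                for sp in SPECIES_ORDER
            }
            shared = shared_orthologs(pairs)
            oracle = set.intersection(
                *({p.focal_id for p in pairs[sp]} for sp in SPECIES_ORDER)
            )
            assert set(shared.focal_ids()) == oracle
            assert len(shared) <= min(len(pairs[sp]) for sp in SPECIES_ORDER)
            # shared focal ids are a subset of cascade focal ids
            cascade_ids = {a.focal_id for a in cascade_assign(pairs, SPECIES_ORDER)}
            assert oracle <= cascade_ids
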