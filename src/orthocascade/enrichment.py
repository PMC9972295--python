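"""Fisher-exact annotation enrichment with Bonferroni and Benjamini-Hochberg.

For a gene set S tested against a background B and a term with gene set T,
the 2x2 table is

    a = |S & T|        b = |S| - a
    c = |T| - a        d = |B| - |S| - c

and the one-sided enrichment p-value is the hypergeometric upper tail
P(X >= a) with N = |B|, K = |T| draws of n = |S|, evaluated in log space.
The optional EASE variant substitutes a-1 for a (never below 0), the more
conservative score DAVID reports.  Terms are tested only when a >= a
minimum count (default 2); the multiple-testing universe m is the number
of terms actually tested in the run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats_io import AnnotationTable, GeneSet
from .identity_stats import Partition

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "fisher_exact_greater",
    "hypergeom_sf",
    "adjust_bonferroni",
    "adjust_benjamini_hochberg",
    "enrich",
    "enrich_partitions",
]

logger = logging.getLogger(__name__)

# cumulative log-factorial table, grown on demand
_LOGFACT = np.zeros(1)


def _logfact(n: int) -> np.ndarray:
    global _LOGFACT
    if n >= _LOGFACT.size:
        size = max(n + 1, 2 * _LOGFACT.size, 1024)
        _LOGFACT = np.concatenate(([0.0], np.cumsum(np.log(np.arange(1, size)))))
    return _LOGFACT


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: (a, b) = in-set with/without term, (c, d) = rest of background."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"contingency cells must be non-negative: {self}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    count: int
    percent: float
    p_value: float
    bonferroni: float
    benjamini: float


def hypergeom_sf(a: int, total: int, successes: int, draws: int) -> float:
    """P(X >= a) for X ~ Hypergeometric(N=total, K=successes, n=draws), log-space."""
    lo = max(0, draws - (total - successes))
    hi = min(successes, draws)
    if a <= lo:
        return 1.0
    if a > hi:
        return 0.0
    lf = _logfact(total)
    x = np.arange(a, hi + 1)
    log_pmf = (
        (lf[successes] - lf[x] - lf[successes - x])
        + (lf[total - successes] - lf[draws - x] - lf[total - successes - draws + x])
        - (lf[total] - lf[draws] - lf[total - draws])
    )
    peak = float(log_pmf.max())
    return float(min(1.0, math.exp(peak) * float(np.exp(log_pmf - peak).sum())))


def fisher_exact_greater(table: ContingencyTable) -> float:
    """One-sided Fisher exact p-value for over-representation (upper tail)."""
    return hypergeom_sf(table.a, table.total, table.a + table.c, table.a + table.b)


def adjust_bonferroni(pvals: Sequence[float]) -> list[float]:
    """Elementwise min(1, m * p)."""
    m = len(pvals)
    return [min(1.0, m * p) for p in pvals]


def adjust_benjamini_hochberg(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, returned in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending-sorted p-values,
    capped at 1.
    """
    m = len(pvals)
    if m == 0:
        return []
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adjusted[i] = min(1.0, running)
    return adjusted


def enrich(
    gene_set: GeneSet,
    annotation: AnnotationTable,
    min_count: int = 2,
    ease: bool = False,
) -> list[EnrichmentResult]:
    """Test every annotation term for over-representation in a gene set.

    Genes outside the annotation background are dropped (logged); the
    harmonized set must be non-empty.  Terms with fewer than ``min_count``
    set genes are not tested and do not enter the adjustment universe.
    Results are sorted by ascending p-value, ties by term id.
    """
    genes = set(gene_set.genes) & set(annotation.background)
    dropped = len(gene_set.genes) - len(genes)
    if dropped:
        logger.info(
            "enrich(%s): dropped %d genes outside the annotation background",
            gene_set.name,
            dropped,
        )
    if not genes:
        raise ValueError(
            f"gene set {gene_set.name!r} has no genes in the annotation background"
        )
    n_set = len(genes)
    n_background = len(annotation.background)
    tested: list[tuple[str, str, int, float]] = []
    for term_id in sorted(annotation.terms):
        name, term_genes = annotation.terms[term_id]
        a = len(genes & term_genes)
        if a < min_count:
            continue
        a_eff = max(a - 1, 0) if ease else a
        p = hypergeom_sf(a_eff, n_background, len(term_genes), n_set)
        tested.append((term_id, name, a, p))
    pvals = [t[3] for t in tested]
    bonf = adjust_bonferroni(pvals)
    bh = adjust_benjamini_hochberg(pvals)
    results = [
        EnrichmentResult(
            term_id=term_id,
            term_name=name,
            count=a,
            percent=100.0 * a / n_set,
            p_value=p,
            bonferroni=bonf[i],
            benjamini=bh[i],
        )
        for i, (term_id, name, a, p) in enumerate(tested)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def enrich_partitions(
    partitions: Iterable[Partition],
    annotation: AnnotationTable,
    min_count: int = 2,
    ease: bool = False,
) -> dict[int, list[EnrichmentResult]]:
    """Run :func:`enrich` for each conservation partition against the full background.

    Each partition's members form the gene set; the background is the
    annotation table's own background (the "rest of the genome"), not the
    union of partitions.
    """
    out: dict[int, list[EnrichmentResult]] = {}
    for partition in partitions:
        gene_set = GeneSet(
            name=f"partition_{partition.index:02d}", genes=frozenset(partition.members)
        )
        out[partition.index] = enrich(gene_set, annotation, min_count=min_count, ease=ease)
    return out
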