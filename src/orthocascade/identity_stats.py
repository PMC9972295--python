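"""Length and sequence-identity statistics across ortholog sets.

Covers transcript-length summaries with fixed-width histograms, unweighted
mean percent identity over ortholog pairs, the pooled two-proportion
z-test used to compare mean identities between species pairs, decile (or
k-tile) partitioning of conservation-ranked genes, and gene-by-species
identity matrices exported as TSV.

A statistical caveat carried over deliberately: the z-test treats a mean
percent identity as if it were a proportion of successes over n ortholog
observations.  That is loose — identities are not Bernoulli outcomes — but
it replicates the standard online two-proportion calculator workflow this
pipeline mirrors; see the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .formats_io import GeneSet, TranscriptRecord
from .orthology import OrthologPair

__all__ = [
    "LengthSummary",
    "ZTestResult",
    "Partition",
    "IdentityMatrix",
    "length_summary",
    "mean_identity",
    "two_proportion_ztest",
    "partition_by_conservation",
    "rank_by_identity",
    "identity_matrix",
]


@dataclass(frozen=True)
class LengthSummary:
    """Minimum/maximum/mean/total transcript length plus a fixed-width histogram.

    Histogram bins are left-closed right-open ``[left, right)`` of equal
    width anchored at 0, covering the observed min..max range; counts sum
    to ``n``.
    """

    n: int
    min_bp: int
    max_bp: int
    mean_bp: float
    sd_bp: float
    total_bp: int
    bin_width: int
    histogram: tuple[tuple[int, int, int], ...]  # (left, right, count)


@dataclass(frozen=True)
class ZTestResult:
    p1: float
    p2: float
    n1: int
    n2: int
    z: float
    p_value: float
    tail: str
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class Partition:
    """One conservation k-tile: 1-based index, ordered members, identity range."""

    index: int
    members: tuple[str, ...]
    identity_range: tuple[float, float] | None  # (max, min) within partition

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class IdentityMatrix:
    """Genes x species percent-identity matrix, rows sorted by one species' column."""

    frame: pd.DataFrame
    order_by: str

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="gene", float_format="%.3f")


def length_summary(
    transcripts: Sequence[TranscriptRecord],
    bin_width: int = 500,
    sample_sd: bool = True,
) -> LengthSummary:
    """Summarize transcript lengths; histogram bins are ``bin_width`` bp wide.

    ``sample_sd`` selects the n-1 denominator (default); the population
    form is available for comparability with tools that use it.
    """
    if not transcripts:
        raise ValueError("length_summary requires at least one transcript")
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    lengths = np.array([len(t) for t in transcripts], dtype=np.int64)
    n = int(lengths.size)
    ddof = 1 if sample_sd else 0
    sd = float(lengths.std(ddof=ddof)) if n > ddof else 0.0
    lo_bin = int(lengths.min()) // bin_width
    hi_bin = int(lengths.max()) // bin_width
    counts = np.bincount(lengths // bin_width, minlength=hi_bin + 1)
    histogram = tuple(
        (b * bin_width, (b + 1) * bin_width, int(counts[b]))
        for b in range(lo_bin, hi_bin + 1)
    )
    return LengthSummary(
        n=n,
        min_bp=int(lengths.min()),
        max_bp=int(lengths.max()),
        mean_bp=float(lengths.mean()),
        sd_bp=sd,
        total_bp=int(lengths.sum()),
        bin_width=bin_width,
        histogram=histogram,
    )


def mean_identity(pairs: Iterable[OrthologPair], level: str = "nucleotide") -> float:
    """Unweighted arithmetic mean percent identity over ortholog pairs.

    Each ortholog counts as one observation regardless of alignment
    length.  All pairs must carry identity at the requested level.
    """
    if level not in ("nucleotide", "protein"):
        raise ValueError(f"unknown identity level {level!r}")
    values = []
    for pair in pairs:
        v = pair.nucleotide_identity if level == "nucleotide" else pair.protein_identity
        if v is None:
            raise ValueError(
                f"pair {pair.focal_id!r}/{pair.reference_id!r} lacks {level} identity"
            )
        values.append(v)
    if not values:
        raise ValueError("mean_identity requires at least one pair")
    return float(np.mean(values))


def two_proportion_ztest(
    p1: float, p2: float, n1: int, n2: int, tail: str = "one", alpha: float = 0.05
) -> ZTestResult:
    """Pooled two-proportion z-test.

    z = (p1 - p2) / sqrt(phat (1 - phat) (1/n1 + 1/n2)) with
    phat = (p1 n1 + p2 n2) / (n1 + n2); no continuity correction.  The
    one-tailed p-value tests the alternative p1 > p2 (callers order the
    arguments); the two-tailed value is 2 * min(one-tailed p, 1 - it).
    """
    if tail not in ("one", "two"):
        raise ValueError(f"tail must be 'one' or 'two', got {tail!r}")
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError("proportions must lie in [0, 1]")
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be positive")
    pooled = (p1 * n1 + p2 * n2) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        raise ValueError(f"degenerate pooled proportion {pooled}: variance is zero")
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    one_tailed = float(_sstats.norm.sf(z))
    p_value = one_tailed if tail == "one" else 2.0 * min(one_tailed, 1.0 - one_tailed)
    return ZTestResult(p1=p1, p2=p2, n1=n1, n2=n2, z=z, p_value=p_value, tail=tail, alpha=alpha)


def _as_ranked(ordered_genes: Sequence) -> tuple[list[str], list[float] | None]:
    if not ordered_genes:
        return [], None
    first = ordered_genes[0]
    if isinstance(first, str):
        return list(ordered_genes), None
    genes = [g for g, _ in ordered_genes]
    identities = [float(v) for _, v in ordered_genes]
    return genes, identities


def partition_by_conservation(ordered_genes: Sequence, k: int) -> list[Partition]:
    """Split a conservation-ranked gene list into k contiguous partitions.

    The input must already be sorted by decreasing identity (ties broken
    by identifier).  The first partition takes ``floor(N/k) + N mod k``
    genes — the remainder goes entirely to the most-conserved partition —
    and the remaining k-1 partitions take ``floor(N/k)`` each, so
    concatenating the partitions restores the input order exactly.

    Accepts either bare gene identifiers or ``(gene, identity)`` pairs; in
    the latter case each partition records its (max, min) identity range.
    """
    genes, identities = _as_ranked(ordered_genes)
    n = len(genes)
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"cannot split {n} genes into {k} partitions")
    base = n // k
    sizes = [base + n % k] + [base] * (k - 1)
    partitions: list[Partition] = []
    start = 0
    for index, size in enumerate(sizes, start=1):
        members = tuple(genes[start : start + size])
        id_range = None
        if identities is not None:
            chunk = identities[start : start + size]
            id_range = (max(chunk), min(chunk))
        partitions.append(Partition(index=index, members=members, identity_range=id_range))
        start += size
    return partitions


def rank_by_identity(
    pairs_by_species: Mapping[str, Iterable[OrthologPair]],
    order_by: str,
    level: str = "nucleotide",
) -> list[tuple[str, float]]:
    """Focal genes ranked by decreasing identity to one species, ties by id."""
    if order_by not in pairs_by_species:
        raise ValueError(f"order_by species {order_by!r} not among {sorted(pairs_by_species)}")
    ranked = []
    for pair in pairs_by_species[order_by]:
        v = pair.nucleotide_identity if level == "nucleotide" else pair.protein_identity
        if v is not None:
            ranked.append((pair.focal_id, float(v)))
    ranked.sort(key=lambda gv: (-gv[1], gv[0]))
    return ranked


def identity_matrix(
    gene_set: GeneSet,
    pairs_by_species: Mapping[str, Iterable[OrthologPair]],
    order_by: str,
    level: str = "nucleotide",
) -> IdentityMatrix:
    """Percent-identity matrix (genes x species) for a gene set.

    One row per gene of the set present in at least one species' pair
    set; missing cells are NaN.  Rows sort descending by the ``order_by``
    species' column (missing values last, ties by gene id).
    """
    species = list(pairs_by_species)
    if order_by not in species:
        raise ValueError(f"order_by species {order_by!r} not among {species}")
    lookup: dict[str, dict[str, float]] = {sp: {} for sp in species}
    for sp in species:
        for pair in pairs_by_species[sp]:
            v = pair.nucleotide_identity if level == "nucleotide" else pair.protein_identity
            if v is not None:
                lookup[sp][pair.focal_id] = float(v)
    rows = sorted(g for g in gene_set.genes if any(g in lookup[sp] for sp in species))
    if not rows:
        raise ValueError(
            f"gene set {gene_set.name!r} shares no genes with any species' pair set"
        )
    frame = pd.DataFrame(
        {sp: [lookup[sp].get(g, np.nan) for g in rows] for sp in species},
        index=rows,
    )
    order_col = frame[order_by]
    key = sorted(
        rows,
        key=lambda g: (pd.isna(order_col[g]), -(order_col[g] if not pd.isna(order_col[g]) else 0.0), g),
    )
    return IdentityMatrix(frame=frame.loc[key], order_by=order_by)
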