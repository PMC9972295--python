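"""Readers and writers for every on-disk artifact the pipeline touches.

Formats handled: multi-record FASTA (nucleotide or protein), 12-column
BLAST tabular alignments (``-outfmt 6``), annotation TSVs mapping terms to
gene identifiers, plain-text gene lists, ortholog-assignment maps and
enrichment result tables.  Every reader/writer pair is a lossless round
trip on valid inputs, and malformed input fails loudly with the offending
line or row named in the error.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "FormatError",
    "TranscriptRecord",
    "HitRecord",
    "AnnotationTable",
    "GeneSet",
    "read_fasta",
    "write_fasta",
    "read_blast_tab",
    "write_blast_tab",
    "read_annotation_table",
    "write_annotation_table",
    "read_gene_set",
    "write_gene_set",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_pair_table",
    "write_pair_table",
    "write_enrichment_table",
]

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"

_NT_ALPHABET = frozenset("ACGTN")
_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptRecord:
    """One assembled transcript: identifier, uppercase sequence, species tag.

    The identifier is the first whitespace-delimited token of the FASTA
    header; any remaining header text is kept as ``description`` but is
    ignored by the pipeline.
    """

    transcript_id: str
    sequence: str
    species: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.transcript_id or any(c.isspace() for c in self.transcript_id):
            raise FormatError(
                f"transcript identifier {self.transcript_id!r} is empty or has whitespace"
            )
        if not self.sequence:
            raise FormatError(f"transcript {self.transcript_id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HitRecord:
    """One row of a 12-column BLAST tabular alignment (``-outfmt 6``).

    ``pct_identity`` is a percentage in [0, 100]; query coordinates are
    1-based inclusive with ``qstart <= qend`` (subject coordinates may be
    reversed for minus-strand alignments).
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise FormatError(f"pct_identity {self.pct_identity} outside [0, 100]")
        if self.aln_length <= 0:
            raise FormatError(f"alignment length {self.aln_length} must be positive")
        if self.mismatches < 0 or self.gap_opens < 0:
            raise FormatError("mismatch/gap counts must be non-negative")
        if self.qstart > self.qend:
            raise FormatError(f"qstart {self.qstart} > qend {self.qend}")
        if self.evalue < 0:
            raise FormatError(f"e-value {self.evalue} must be non-negative")


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (duplicates collapsed, never empty)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class AnnotationTable:
    """term -> (term name, gene set) mapping plus an explicit background.

    After harmonization every annotated gene belongs to the background and
    every term's gene set is non-empty; terms emptied by harmonization are
    dropped.  Build instances through :meth:`build`.
    """

    terms: Mapping[str, tuple[str, frozenset[str]]]
    background: frozenset[str]

    @classmethod
    def build(
        cls,
        terms: Mapping[str, tuple[str, Iterable[str]]],
        background: Iterable[str] | None = None,
    ) -> "AnnotationTable":
        if background is None:
            bg = frozenset(g for _, genes in terms.values() for g in genes)
        else:
            bg = frozenset(background)
        harmonized: dict[str, tuple[str, frozenset[str]]] = {}
        for term_id, (name, genes) in terms.items():
            kept = frozenset(genes) & bg
            if kept:
                harmonized[term_id] = (name, kept)
        return cls(terms=harmonized, background=bg)

    def term_name(self, term_id: str) -> str:
        return self.terms[term_id][0]

    def genes_for(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]

    def __len__(self) -> int:
        return len(self.terms)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _locate_illegal_character(path: Path, alphabet: frozenset[str], mode: str) -> tuple[int, str]:
    """Re-scan a FASTA file to report the first illegal sequence character."""
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith(">") or not line.strip():
                continue
            canonical = line.strip().upper()
            if mode == NUCLEOTIDE:
                canonical = canonical.replace("U", "T")
            for char in canonical:
                if char not in alphabet:
                    return lineno, char
    return 0, "?"


def read_fasta(path: str | os.PathLike, mode: str = NUCLEOTIDE, species: str = "") -> list[TranscriptRecord]:
    """Read a FASTA file into :class:`TranscriptRecord` objects in file order.

    Sequences are uppercased; in nucleotide mode U is mapped to T.  Duplicate
    identifiers and characters outside the mode's alphabet are hard errors.
    """
    if mode not in (NUCLEOTIDE, PROTEIN):
        raise ValueError(f"unknown mode {mode!r}")
    path = Path(path)
    alphabet = _NT_ALPHABET if mode == NUCLEOTIDE else _AA_ALPHABET
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate identifier {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if mode == NUCLEOTIDE:
            seq = seq.replace("U", "T")
        illegal = set(seq) - alphabet
        if illegal:
            lineno, char = _locate_illegal_character(path, alphabet, mode)
            raise FormatError(
                f"illegal character {char!r} for {mode} sequence at {path}:{lineno}"
            )
        description = rec.description.partition(" ")[2]
        records.append(
            TranscriptRecord(rec.id, seq, species=species, description=description)
        )
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as handle:
        for rec in records:
            header = rec.transcript_id
            if rec.description:
                header += f" {rec.description}"
            handle.write(f">{header}\n")
            for start in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[start : start + width] + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)
# ---------------------------------------------------------------------------


def _format_evalue(value: float) -> str:
    return f"{value:.3g}" if value else "0.0"


def format_hit(hit: HitRecord) -> str:
    """Canonical tab-separated rendering of one outfmt-6 row (no newline)."""
    return "\t".join(
        (
            hit.query_id,
            hit.subject_id,
            f"{hit.pct_identity:.3f}",
            str(hit.aln_length),
            str(hit.mismatches),
            str(hit.gap_opens),
            str(hit.qstart),
            str(hit.qend),
            str(hit.sstart),
            str(hit.send),
            _format_evalue(hit.evalue),
            f"{hit.bitscore:.1f}",
        )
    )


def read_blast_tab(path: str | os.PathLike) -> list[HitRecord]:
    """Parse a 12-column BLAST tabular file, preserving row order.

    Any row without exactly 12 tab-separated columns is a hard error naming
    the row number.  Multiple HSPs per query-subject pair are preserved;
    resolving them is the job of downstream best-hit logic.
    """
    hits: list[HitRecord] = []
    with open(path) as handle:
        for rowno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}:{rowno}: expected 12 tab-separated columns, found {len(fields)}"
                )
            try:
                hits.append(
                    HitRecord(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pct_identity=float(fields[2]),
                        aln_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        qstart=int(fields[6]),
                        qend=int(fields[7]),
                        sstart=int(fields[8]),
                        send=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{rowno}: {exc}") from exc
    return hits


def write_blast_tab(hits: Iterable[HitRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for hit in hits:
            handle.write(format_hit(hit) + "\n")


# ---------------------------------------------------------------------------
# annotation tables and gene lists
# ---------------------------------------------------------------------------


def read_annotation_table(
    path: str | os.PathLike, background: Iterable[str] | None = None
) -> AnnotationTable:
    """Read a 2- or 3-column TSV of (term, gene[, term name]) rows.

    Lines beginning with ``#`` and blank lines are ignored.  When no
    explicit background is supplied, the union of all annotated genes is
    used.
    """
    terms: dict[str, tuple[str, set[str]]] = {}
    with open(path) as handle:
        for rowno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (2, 3):
                raise FormatError(
                    f"{path}:{rowno}: expected 2 or 3 tab-separated columns, found {len(fields)}"
                )
            term_id, gene = fields[0], fields[1]
            name = fields[2] if len(fields) == 3 else term_id
            if term_id not in terms:
                terms[term_id] = (name, set())
            terms[term_id][1].add(gene)
    if not terms:
        return AnnotationTable.build({}, background=background or ())
    return AnnotationTable.build(
        {t: (name, genes) for t, (name, genes) in terms.items()}, background=background
    )


def write_annotation_table(table: AnnotationTable, path: str | os.PathLike) -> None:
    """Write (term, gene, name) rows sorted by term then gene."""
    with open(path, "w") as handle:
        for term_id in sorted(table.terms):
            name, genes = table.terms[term_id]
            for gene in sorted(genes):
                handle.write(f"{term_id}\t{gene}\t{name}\n")


def read_gene_set(path: str | os.PathLike, name: str | None = None) -> GeneSet:
    """Read a plain-text gene list (one identifier per line, ``#`` comments)."""
    path = Path(path)
    genes: set[str] = set()
    with open(path) as handle:
        for line in handle:
            token = line.strip()
            if not token or token.startswith("#"):
                continue
            genes.add(token)
    if not genes:
        raise FormatError(f"gene list {path} contains no identifiers")
    return GeneSet(name=name or path.stem, genes=frozenset(genes))


def write_gene_set(gene_set: GeneSet, path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for gene in sorted(gene_set.genes):
            handle.write(gene + "\n")


# ---------------------------------------------------------------------------
# ortholog maps, pair tables, enrichment tables
# ---------------------------------------------------------------------------

_ORTHOLOG_MAP_HEADER = "focal_id\tspecies\treference_id\trank\tpct_identity"


def write_ortholog_map(assignments: Iterable, path: str | os.PathLike) -> None:
    """Write cascade assignments as a headered TSV, sorted by focal id."""
    rows = sorted(assignments, key=lambda a: a.focal_id)
    with open(path, "w") as handle:
        handle.write(_ORTHOLOG_MAP_HEADER + "\n")
        for a in rows:
            identity = "" if a.nucleotide_identity is None else f"{a.nucleotide_identity:.3f}"
            handle.write(
                f"{a.focal_id}\t{a.reference_species}\t{a.reference_id}\t{a.priority_rank}\t{identity}\n"
            )


def read_ortholog_map(path: str | os.PathLike) -> list:
    from .orthology import OrthologAssignment

    out = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n")
        if header != _ORTHOLOG_MAP_HEADER:
            raise FormatError(f"{path}: unexpected header {header!r}")
        for rowno, line in enumerate(handle, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise FormatError(f"{path}:{rowno}: expected 5 columns")
            out.append(
                OrthologAssignment(
                    focal_id=fields[0],
                    reference_species=fields[1],
                    reference_id=fields[2],
                    priority_rank=int(fields[3]),
                    nucleotide_identity=float(fields[4]) if fields[4] else None,
                )
            )
    return out


_PAIR_HEADER = "focal_id\treference_id\tnucleotide_identity\tprotein_identity"


def write_pair_table(pairs: Iterable, path: str | os.PathLike) -> None:
    """Write one species' reciprocal-best-hit pairs as a headered TSV."""
    rows = sorted(pairs, key=lambda p: p.focal_id)
    with open(path, "w") as handle:
        handle.write(_PAIR_HEADER + "\n")
        for p in rows:
            nt = "" if p.nucleotide_identity is None else f"{p.nucleotide_identity:.3f}"
            aa = "" if p.protein_identity is None else f"{p.protein_identity:.3f}"
            handle.write(f"{p.focal_id}\t{p.reference_id}\t{nt}\t{aa}\n")


def read_pair_table(path: str | os.PathLike, reference_species: str) -> list:
    from .orthology import OrthologPair

    out = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n")
        if header != _PAIR_HEADER:
            raise FormatError(f"{path}: unexpected header {header!r}")
        for rowno, line in enumerate(handle, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}:{rowno}: expected 4 columns")
            out.append(
                OrthologPair(
                    focal_id=fields[0],
                    reference_id=fields[1],
                    reference_species=reference_species,
                    nucleotide_identity=float(fields[2]) if fields[2] else None,
                    protein_identity=float(fields[3]) if fields[3] else None,
                )
            )
    return out


def write_enrichment_table(results: Sequence, path: str | os.PathLike) -> None:
    """Write enrichment results with columns Term, Count, %, p-value, Bonferroni, Benjamini.

    The Term column carries ``term_id~term_name`` when a distinct name is
    available, mirroring DAVID-style exports.
    """
    with open(path, "w") as handle:
        handle.write("Term\tCount\t%\tp-value\tBonferroni\tBenjamini\n")
        for r in results:
            term = r.term_id if r.term_name in ("", r.term_id) else f"{r.term_id}~{r.term_name}"
            handle.write(
                f"{term}\t{r.count}\t{r.percent:.2f}\t{r.p_value:.6g}\t{r.bonferroni:.6g}\t{r.benjamini:.6g}\n"
            )
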