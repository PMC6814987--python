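"""Genome/annotation I/O and the interval algebra used by every other stage.

Coordinates are 0-based half-open internally.  Emitted report files follow
each format's own convention (1-based inclusive for GFF3 and tabular hit
output, 0-based half-open for BED).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input; message names the offending line."""


def normalize_sequence(raw: str) -> str:
    """Uppercase, map U->T; caller validates the alphabet."""
    return raw.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """A named nucleotide sequence (master chromosome or plastome).

    ``sequence`` is uppercase over {A,C,G,T,N}; ``circular`` marks
    circular-mapping molecules, though analyses treat the sequence as linear
    as deposited.
    """

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        bad = set(self.sequence) - _VALID
        if bad:
            raise FastaFormatError(
                f"genome {self.id!r}: illegal characters {sorted(bad)}"
            )

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int) -> str:
        return self.sequence[start:end]


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open interval; ``strand`` is '+' or '-'."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def overlap_len(self, other: "Interval") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GeneAnnotation:
    """One classified gene copy: ordered exons plus derived introns."""

    gene_name: str
    exons: list[Interval] = field(default_factory=list)
    status: str = "absent"  # {intact, pseudogene, fragment, absent}

    def __post_init__(self) -> None:
        if self.status == "absent" and self.exons:
            raise ValueError("absent gene must have no exons")
        self.exons = sorted(self.exons, key=lambda iv: iv.start)

    @property
    def introns(self) -> list[Interval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(Interval(a.end, b.start, a.strand))
        return out


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[Genome]:
    """Read a (multi-)FASTA file into Genomes, preserving record order.

    Ids are the first whitespace-delimited header token.  Raises
    :class:`FastaFormatError` naming the line number for sequence data before
    any header or for characters outside {A,C,G,T,N} after normalization.
    """
    path = Path(path)
    genomes: list[Genome] = []
    header: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if header is None:
            return
        genomes.append(_build_genome(header, "".join(chunks), header_line))

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FastaFormatError(f"line {lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaFormatError(
                        f"line {lineno}: sequence data before any '>' header"
                    )
                norm = normalize_sequence(line)
                bad = set(norm) - _VALID
                if bad:
                    raise FastaFormatError(
                        f"line {lineno}: illegal characters {sorted(bad)}"
                    )
                chunks.append(norm)
        flush()
    if not genomes:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return genomes


def _build_genome(gid: str, seq: str, lineno: int) -> Genome:
    try:
        return Genome(id=gid, sequence=seq)
    except FastaFormatError as exc:  # pragma: no cover - defensive
        raise FastaFormatError(f"record at line {lineno}: {exc}") from exc


def write_fasta(genomes: Iterable[Genome], path: str | Path, width: int = 70) -> None:
    with Path(path).open("w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    """Union-merge into disjoint, sorted '+'-strand intervals.

    Strand-insensitive: overlapping or abutting intervals coalesce.
    """
    if not intervals:
        return []
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged = [[ivs[0].start, ivs[0].end]]
    for iv in ivs[1:]:
        if iv.start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], iv.end)
        else:
            merged.append([iv.start, iv.end])
    return [Interval(s, e) for s, e in merged]


def interval_union_length(intervals: Sequence[Interval]) -> int:
    """Total bp covered by the set-theoretic union (strand-insensitive)."""
    return sum(iv.length for iv in merge_intervals(intervals))


def subtract_intervals(length: int, covered: Sequence[Interval]) -> list[Interval]:
    """Complement of ``covered`` within [0, length)."""
    gaps: list[Interval] = []
    pos = 0
    for iv in merge_intervals(covered):
        if iv.start > pos:
            gaps.append(Interval(pos, iv.start))
        pos = max(pos, iv.end)
    if pos < length:
        gaps.append(Interval(pos, length))
    return gaps


# ---------------------------------------------------------------------------
# Multipartite concatenation with coordinate map-back
# ---------------------------------------------------------------------------

@dataclass
class ConcatenatedGenome:
    """Concatenation of several records with an offset table for map-back."""

    genome: Genome
    record_ids: list[str]
    offsets: list[int]  # start of each record in concatenated coordinates
    record_lengths: list[int]

    def map_back(self, pos: int) -> tuple[str, int]:
        """Map a concatenated-coordinate position to (record id, local pos).

        Positions inside spacer runs map to the preceding record's id with a
        local position clipped to its length (callers normally only map hit
        endpoints, which never fall in spacers).
        """
        if not 0 <= pos < self.genome.length_bp:
            raise ValueError(f"position {pos} outside concatenated genome")
        idx = 0
        for i, off in enumerate(self.offsets):
            if pos >= off:
                idx = i
        local = min(pos - self.offsets[idx], self.record_lengths[idx] - 1)
        return self.record_ids[idx], local


def concatenate_multipartite(
    genomes: Sequence[Genome], spacer_len: int = 100, out_id: str | None = None
) -> ConcatenatedGenome:
    """Join multipartite records in input order, separated by N-runs."""
    if not genomes:
        raise ValueError("cannot concatenate an empty genome list")
    spacer = "N" * spacer_len
    offsets: list[int] = []
    parts: list[str] = []
    pos = 0
    for i, g in enumerate(genomes):
        if i:
            parts.append(spacer)
            pos += spacer_len
        offsets.append(pos)
        parts.append(g.sequence)
        pos += g.length_bp
    gid = out_id or (genomes[0].id + "_concat" if len(genomes) > 1 else genomes[0].id)
    return ConcatenatedGenome(
        genome=Genome(id=gid, sequence="".join(parts)),
        record_ids=[g.id for g in genomes],
        offsets=offsets,
        record_lengths=[g.length_bp for g in genomes],
    )


# ---------------------------------------------------------------------------
# BED / TSV emission
# ---------------------------------------------------------------------------

def write_bed(
    intervals: Sequence[Interval],
    chrom: str,
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
    header: str | None = None,
) -> None:
    """BED6; scores clipped into [0, 1000] as the format requires."""
    with Path(path).open("w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"feature_{i + 1}"
            score = int(max(0, min(1000, scores[i] if scores else 0)))
            fh.write(f"{chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def write_matrix_tsv(
    ids: Sequence[str],
    values: dict[str, dict[str, float]],
    path: str | Path,
    header: str | None = None,
    fmt: str = "{:.6g}",
) -> None:
    """Square matrix TSV with a leading id column and id header row."""
    with Path(path).open("w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("id\t" + "\t".join(ids) + "\n")
        for q in ids:
            row = [fmt.format(values[q][s]) if s in values.get(q, {}) else "NA" for s in ids]
            fh.write(q + "\t" + "\t".join(row) + "\n")


def read_matrix_tsv(path: str | Path) -> tuple[list[str], dict[str, dict[str, float]]]:
    ids: list[str] = []
    values: dict[str, dict[str, float]] = {}
    with Path(path).open() as fh:
        rows = [l.rstrip("\n") for l in fh if l.strip() and not l.startswith("#")]
    cols = rows[0].split("\t")[1:]
    for row in rows[1:]:
        fields = row.split("\t")
        q = fields[0]
        ids.append(q)
        values[q] = {}
        for s, v in zip(cols, fields[1:]):
            if v != "NA":
                values[q][s] = float(v)
    return ids, values


def write_gff3(
    annotations: Sequence[GeneAnnotation],
    seqid: str,
    path: str | Path,
    source: str = "mitocomp",
) -> None:
    """Minimal GFF3 of gene/exon features (1-based inclusive)."""
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for ann in annotations:
            if not ann.exons:
                continue
            gstart = min(iv.start for iv in ann.exons) + 1
            gend = max(iv.end for iv in ann.exons)
            strand = ann.exons[0].strand
            gid = f"{ann.gene_name}"
            fh.write(
                f"{seqid}\t{source}\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\t"
                f"ID={gid};status={ann.status}\n"
            )
            for i, iv in enumerate(ann.exons, 1):
                fh.write(
                    f"{seqid}\t{source}\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{iv.strand}\t.\tID={gid}.exon{i};Parent={gid}\n"
                )
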