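"""Gene content classification against a reference protein-coding gene set,
intron length measurement, per-gene alignment concatenation, and Kimura
two-parameter distances."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from Bio.Seq import Seq

from .pairalign import HSP, ScoringScheme, find_hsps, global_align
from .repeatscan import RepeatParams
from .seqio import Genome, GeneAnnotation, Interval, interval_union_length, reverse_complement

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
_STANDARD = frozenset("ACGT")


class SaturatedDistance(ValueError):
    """K2P log argument went non-positive: distance undefined."""


@dataclass(frozen=True)
class K2PResult:
    """Transition/transversion proportions and the corrected distance."""

    P: float
    Q: float
    d: float
    sites_used: int


def k2p(aligned_a: str, aligned_b: str) -> K2PResult:
    """Kimura 2-parameter distance on an aligned sequence pair.

    Columns with a gap or non-ACGT symbol in either sequence are excluded
    (pairwise deletion).  d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q); raises
    :class:`SaturatedDistance` when either log argument is <= 0.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    sites = transitions = transversions = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x not in _STANDARD or y not in _STANDARD:
            continue
        sites += 1
        if x == y:
            continue
        if (x in PURINES) == (y in PURINES):
            transitions += 1
        else:
            transversions += 1
    if sites == 0:
        raise ValueError("no comparable sites after pairwise deletion")
    P = transitions / sites
    Q = transversions / sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturatedDistance("distance undefined: saturated")
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PResult(P=P, Q=Q, d=d + 0.0 if d != 0 else 0.0, sites_used=sites)


# ---------------------------------------------------------------------------
# Gene classification
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    gene_name: str
    status: str  # {intact, pseudogene, fragment, absent}
    exons: list[Interval]
    strand: str
    coverage: float  # fraction of reference covered by chained hits
    identity: float

    def annotation(self) -> GeneAnnotation:
        return GeneAnnotation(
            gene_name=self.gene_name,
            exons=self.exons if self.status != "absent" else [],
            status=self.status,
        )


def _chain_colinear(hits: list[HSP]) -> list[HSP]:
    """Greedy best-scoring chain of co-linear same-strand hits.

    Hits must increase in both reference (query) and genome (subject)
    coordinates ('+' strand) or increase in reference while decreasing in
    genome ('-').  Small overlaps are tolerated up to half a hit.
    """
    best_chain: list[HSP] = []
    best_score = 0
    for strand in "+-":
        sh = [h for h in hits if h.strand == strand]
        sh.sort(key=lambda h: h.query.start)
        n = len(sh)
        if not n:
            continue
        score = [h.score for h in sh]
        back: list[int | None] = [None] * n
        for j in range(n):
            for i in range(j):
                a, b = sh[i], sh[j]
                if b.query.start < a.query.start + a.query.length // 2:
                    continue
                if strand == "+":
                    ok = b.subject.start >= a.subject.start + a.subject.length // 2
                else:
                    ok = b.subject.end <= a.subject.end - a.subject.length // 2
                if ok and score[i] + b.score > score[j]:
                    score[j] = score[i] + b.score
                    back[j] = i
        j = max(range(n), key=lambda i: score[i])
        if score[j] > best_score:
            best_score = score[j]
            chain = []
            k: int | None = j
            while k is not None:
                chain.append(sh[k])
                k = back[k]
            best_chain = list(reversed(chain))
    return best_chain


def _has_internal_stop(cds: str) -> bool:
    trimmed = cds[: len(cds) - len(cds) % 3]
    if len(trimmed) < 6:
        return False
    aa = str(Seq(trimmed).translate())
    return "*" in aa[:-1]


def classify_gene(
    genome: Genome,
    gene_name: str,
    reference_cds: str,
    min_fragment: int = 100,
    intact_coverage: float = 0.9,
    pseudo_coverage: float = 0.3,
    params: RepeatParams | None = None,
) -> GeneModel:
    """Classify one reference gene in a genome by chained local alignment.

    intact: co-linear exon chain covering >= ``intact_coverage`` of the
    reference with an undisrupted reading frame; pseudogene: coverage >=
    ``pseudo_coverage`` but a frame-disrupting indel or internal stop;
    fragment: hits exist but every one is < ``min_fragment`` bp or coverage
    < ``pseudo_coverage``; absent: no significant hit at all.
    """
    reference_cds = reference_cds.upper().replace("U", "T")
    if len(reference_cds) % 3 != 0:
        raise ValueError(f"{gene_name}: reference CDS length not divisible by 3")
    params = params or RepeatParams()
    ref = Genome(id=f"{gene_name}_ref", sequence=reference_cds)
    hits = find_hsps(
        ref,
        genome,
        word_size=params.word_size,
        evalue_max=params.evalue_max,
        scheme=params.scheme,
        min_len=min(params.min_repeat_len, len(reference_cds)),
    )
    # sub-min_fragment hits are suppressed outright (not presented); a gene
    # whose every hit is below the fragment floor reads as absent
    hits = [h for h in hits if h.aligned_len >= min_fragment] or []
    if not hits:
        return GeneModel(gene_name, "absent", [], "+", 0.0, 0.0)
    chain = _chain_colinear(hits)
    strand = chain[0].strand
    coverage = interval_union_length([h.query for h in chain]) / len(reference_cds)
    ident = sum(h.matches for h in chain) / max(1, sum(h.aligned_len for h in chain))
    exons = sorted(
        (Interval(h.subject.start, h.subject.end, strand) for h in chain),
        key=lambda iv: iv.start,
    )
    if coverage < pseudo_coverage:
        return GeneModel(gene_name, "fragment", exons, strand, coverage, ident)

    # frame check: each ungapped hit maps reference positions 1:1 onto the
    # genome along one (anti)diagonal; consecutive chain hits whose diagonal
    # offsets differ by a non-multiple of 3 imply a frame-disrupting indel
    def _diag(h: HSP) -> int:
        if h.strand == "+":
            return h.subject.start - h.query.start
        return h.subject.end + h.query.start

    # a large genome-side gap with no reference-side gap is an intron and
    # does not disrupt the reading frame (it splices out); only small
    # diagonal jumps count as indels
    min_intron = 50
    frame_shift = False
    for a, b in zip(chain, chain[1:]):
        if strand == "+":
            genome_gap = b.subject.start - a.subject.end
        else:
            genome_gap = a.subject.start - b.subject.end
        if genome_gap >= min_intron:
            continue
        if (_diag(b) - _diag(a)) % 3 != 0:
            frame_shift = True
            break

    # reconstruct the CDS in the reference frame: start from the reference
    # and overwrite every aligned position with the genome base, so frame
    # and length are preserved and substitutions show through
    virtual = list(reference_cds)
    for h in chain:
        seg = genome.subseq(h.subject.start, h.subject.end)
        if strand == "-":
            seg = reverse_complement(seg)
        virtual[h.query.start : h.query.end] = seg
    recon = "".join(virtual)
    if (
        coverage >= intact_coverage
        and not frame_shift
        and not _has_internal_stop(recon)
    ):
        return GeneModel(gene_name, "intact", exons, strand, coverage, ident)
    return GeneModel(gene_name, "pseudogene", exons, strand, coverage, ident)


def intron_lengths(model: GeneModel) -> list[int]:
    """Gap lengths between consecutive exons on the genome.

    Single-exon genes yield an empty list (intron count 0).
    """
    if model.status in ("absent",):
        raise ValueError("cannot measure introns of an absent gene")
    return [
        b.start - a.end
        for a, b in zip(model.exons, model.exons[1:])
        if b.start > a.end
    ]


# ---------------------------------------------------------------------------
# Concatenated gene alignments
# ---------------------------------------------------------------------------

@dataclass
class ConcatenatedAlignment:
    aligned_a: str
    aligned_b: str
    gene_boundaries: list[tuple[str, int, int]]  # (gene, start col, end col)


def concatenate_genes(
    alignments: dict[str, tuple[str, str]], gene_list: list[str]
) -> ConcatenatedAlignment:
    """Join per-gene pairwise alignments in fixed gene-list order.

    Genes missing from ``alignments`` are skipped with a warning.
    """
    if not gene_list:
        raise ValueError("empty gene list")
    a_parts: list[str] = []
    b_parts: list[str] = []
    bounds: list[tuple[str, int, int]] = []
    pos = 0
    for gene in gene_list:
        if gene not in alignments:
            warnings.warn(f"gene {gene} missing from alignments; skipped")
            continue
        aa, bb = alignments[gene]
        if len(aa) != len(bb):
            raise ValueError(f"gene {gene}: aligned lengths differ")
        a_parts.append(aa)
        b_parts.append(bb)
        bounds.append((gene, pos, pos + len(aa)))
        pos += len(aa)
    if not bounds:
        raise ValueError("no genes left after skipping missing entries")
    return ConcatenatedAlignment(
        aligned_a="".join(a_parts), aligned_b="".join(b_parts), gene_boundaries=bounds
    )


def pairwise_gene_k2p(
    seqs_a: dict[str, str],
    seqs_b: dict[str, str],
    gene_list: list[str],
    scheme: ScoringScheme | None = None,
) -> tuple[K2PResult, ConcatenatedAlignment]:
    """Align shared genes globally, concatenate, and compute K2P."""
    alignments: dict[str, tuple[str, str]] = {}
    for gene in gene_list:
        if gene in seqs_a and gene in seqs_b:
            aa, bb, _, _ = global_align(seqs_a[gene], seqs_b[gene], scheme)
            alignments[gene] = (aa, bb)
    concat = concatenate_genes(alignments, gene_list)
    return k2p(concat.aligned_a, concat.aligned_b), concat


@dataclass
class GeneContentMatrix:
    """Status of every reference gene in every genome, plus intron lengths."""

    genome_ids: list[str]
    gene_names: list[str]
    status: dict[str, dict[str, str]]  # genome -> gene -> status
    intron_lengths: dict[str, dict[str, list[int]]]

    def to_rows(self) -> list[list[str]]:
        rows = [["genome"] + self.gene_names]
        for g in self.genome_ids:
            rows.append([g] + [self.status[g][gene] for gene in self.gene_names])
        return rows


def gene_content_matrix(
    genomes: list[Genome],
    references: dict[str, str],
    min_fragment: int = 100,
    params: RepeatParams | None = None,
) -> GeneContentMatrix:
    ids = [g.id for g in genomes]
    status: dict[str, dict[str, str]] = {}
    introns: dict[str, dict[str, list[int]]] = {}
    for g in genomes:
        status[g.id] = {}
        introns[g.id] = {}
        for gene, ref in references.items():
            model = classify_gene(g, gene, ref, min_fragment, params=params)
            status[g.id][gene] = model.status
            if model.status in ("intact", "pseudogene") and len(model.exons) >= 2:
                introns[g.id][gene] = intron_lengths(model)
    return GeneContentMatrix(
        genome_ids=ids,
        gene_names=sorted(references),
        status=status,
        intron_lengths=introns,
    )
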