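"""Tandem/dispersed repeat detection, repetitive vs single-copy
partitioning, size-class binning, and large-repeat collapsing."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .pairalign import HSP, ScoringScheme, find_hsps
from .seqio import Genome, Interval, interval_union_length, merge_intervals


@dataclass(frozen=True)
class RepeatParams:
    """Alignment and binning parameters for repeat and shared-DNA scans."""

    word_size: int = 7
    evalue_max: float = 1e-6
    min_repeat_len: int = 30
    # (lo, hi) inclusive bp bounds; None hi = open-ended
    size_bins: tuple[tuple[int, int | None], ...] = (
        (30, 100),
        (101, 300),
        (301, 1000),
        (1001, None),
    )
    large_repeat_min: int = 1000
    scheme: ScoringScheme = field(default_factory=ScoringScheme)

    def __post_init__(self) -> None:
        for (lo1, hi1), (lo2, _) in zip(self.size_bins, self.size_bins[1:]):
            if hi1 is None or lo2 != hi1 + 1:
                raise ValueError("size_bins must be contiguous and non-overlapping")
        top_lo = self.size_bins[-1][0]
        if self.large_repeat_min != top_lo - 1:
            raise ValueError(
                "large_repeat_min must equal the top bin's lower bound minus 1"
            )

    def bin_label(self, length: int) -> str | None:
        for lo, hi in self.size_bins:
            if length >= lo and (hi is None or length <= hi):
                return f"{lo}-{hi}" if hi is not None else f">{lo - 1}"
        return None


@dataclass
class TandemArray:
    interval: Interval
    period: int
    copy_number: float
    score: int
    consensus: str


@dataclass
class RepeatCatalog:
    """Per-genome repeat annotation and repetitive/single-copy partition."""

    genome_id: str
    genome_len: int
    dispersed_hits: list[HSP]
    tandem_repeats: list[TandemArray]
    merged_units: list[Interval]
    repetitive_bp: int
    single_copy_bp: int
    bin_counts: dict[str, int]
    hit_bin_counts: dict[str, int]
    families_gt_1kb: list[list[Interval]]

    @property
    def repetitive_pct(self) -> float:
        return 100.0 * self.repetitive_bp / self.genome_len if self.genome_len else 0.0

    @property
    def single_copy_pct(self) -> float:
        return 100.0 * self.single_copy_bp / self.genome_len if self.genome_len else 0.0


@dataclass
class CollapsedGenome:
    """Genome with all but one copy of each >1 kb repeat family removed."""

    genome_id: str
    sequence: str
    deleted_intervals: list[Interval]

    @property
    def collapsed_len_bp(self) -> int:
        return len(self.sequence)

    def as_genome(self) -> Genome:
        return Genome(id=self.genome_id, sequence=self.sequence)


# ---------------------------------------------------------------------------
# Dispersed repeats
# ---------------------------------------------------------------------------

def dispersed_repeats(genome: Genome, params: RepeatParams | None = None) -> list[HSP]:
    """Self-alignment hits with the trivial full-length diagonal hit removed.

    Reciprocal duplicates (A<->B and B<->A) are retained; all hits passing
    the e-value and length thresholds count.
    """
    params = params or RepeatParams()
    hits = find_hsps(
        genome,
        genome,
        word_size=params.word_size,
        evalue_max=params.evalue_max,
        scheme=params.scheme,
        min_len=params.min_repeat_len,
    )
    return [
        h
        for h in hits
        if not (h.strand == "+" and h.query.start == h.subject.start)
    ]


# ---------------------------------------------------------------------------
# Tandem repeats
# ---------------------------------------------------------------------------

def _max_segments(x: np.ndarray, min_score: int) -> list[tuple[int, int, int]]:
    """Disjoint maximal-score segments of x with score >= min_score.

    Recursive best-subarray extraction via the cumulative-sum trick.
    """
    out: list[tuple[int, int, int]] = []

    def best(lo: int, hi: int) -> None:
        if hi - lo <= 0:
            return
        seg = x[lo:hi]
        c = np.concatenate(([0], np.cumsum(seg)))
        run_min = np.minimum.accumulate(c[:-1])
        gains = c[1:] - run_min
        j = int(np.argmax(gains))
        score = int(gains[j])
        if score < min_score:
            return
        i = int(np.argmin(c[: j + 1]))
        out.append((lo + i, lo + j + 1, score))
        best(lo, lo + i)
        best(lo + j + 1, hi)

    best(0, len(x))
    return sorted(out)


def _consensus(seq: str, start: int, end: int, period: int) -> str:
    """Majority base per phase class over the array."""
    cols: list[dict[str, int]] = [dict() for _ in range(period)]
    for i in range(start, end):
        c = seq[i]
        col = cols[(i - start) % period]
        col[c] = col.get(c, 0) + 1
    return "".join(max(col, key=lambda k: (col[k], k)) if col else "A" for col in cols)


def tandem_repeats(
    genome: Genome,
    min_period: int = 1,
    max_period: int = 500,
    min_score: int = 50,
    match: int = 2,
    mismatch: int = -7,
) -> list[TandemArray]:
    """Detect tandem arrays by fixed-lag k-mer recurrence plus consensus check.

    For each candidate period p the per-position self-match score
    (s[i] == s[i+p]) is segmented into maximal runs; candidates are rescored
    against the tiled majority consensus with the classic 2/-7 match/mismatch
    weights, and arrays scoring >= ``min_score`` are reported with fractional
    copy number.  Lowest-period representation wins when harmonics overlap.
    """
    seq = genome.sequence
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    found: list[TandemArray] = []
    for p in range(min_period, min(max_period, n - 1) + 1):
        matches = arr[: n - p] == arr[p:]
        x = np.where(matches, match, mismatch).astype(np.int64)
        for lo, hi, _ in _max_segments(x, min_score):
            start, end = lo, hi + p  # array spans the lagged window too
            cons = _consensus(seq, start, end, p)
            score = 0
            for i in range(start, end):
                score += match if seq[i] == cons[(i - start) % p] else mismatch
            if score < min_score:
                continue
            found.append(
                TandemArray(
                    interval=Interval(start, end),
                    period=p,
                    copy_number=round((end - start) / p, 1),
                    score=score,
                    consensus=cons,
                )
            )
    # suppress harmonics: prefer the smallest period among heavily
    # overlapping arrays
    found.sort(key=lambda t: (t.period, t.interval.start))
    kept: list[TandemArray] = []
    for t in found:
        redundant = False
        for k in kept:
            ov = t.interval.overlap_len(k.interval)
            if ov >= 0.5 * t.interval.length and t.period % k.period == 0:
                redundant = True
                break
        if not redundant:
            kept.append(t)
    kept.sort(key=lambda t: t.interval.start)
    return kept


# ---------------------------------------------------------------------------
# Partition
# ---------------------------------------------------------------------------

def partition(
    genome: Genome,
    dispersed: Sequence[HSP],
    tandem: Sequence[TandemArray],
    params: RepeatParams | None = None,
) -> RepeatCatalog:
    """Merge all repeat intervals and split the genome into repetitive vs
    single-copy DNA.

    Both query- and subject-side intervals of every self-hit count toward
    repetitive coverage (both copies of a repeat are repetitive DNA).
    Partly or wholly overlapping repeats are treated as a single unit;
    ``bin_counts`` bins merged units by length, ``hit_bin_counts`` bins raw
    hits by aligned length.
    """
    params = params or RepeatParams()
    raw: list[Interval] = []
    for h in dispersed:
        raw.append(h.query)
        raw.append(h.subject)
    for t in tandem:
        raw.append(t.interval)
    merged = merge_intervals(raw)
    repetitive_bp = interval_union_length(merged)
    bin_counts = {
        (f"{lo}-{hi}" if hi is not None else f">{lo - 1}"): 0
        for lo, hi in params.size_bins
    }
    hit_bin_counts = dict(bin_counts)
    for iv in merged:
        label = params.bin_label(iv.length)
        if label:
            bin_counts[label] += 1
    for h in dispersed:
        label = params.bin_label(h.aligned_len)
        if label:
            hit_bin_counts[label] += 1
    families = cluster_large_families(dispersed, params.large_repeat_min)
    return RepeatCatalog(
        genome_id=genome.id,
        genome_len=genome.length_bp,
        dispersed_hits=list(dispersed),
        tandem_repeats=list(tandem),
        merged_units=merged,
        repetitive_bp=repetitive_bp,
        single_copy_bp=genome.length_bp - repetitive_bp,
        bin_counts=bin_counts,
        hit_bin_counts=hit_bin_counts,
        families_gt_1kb=families,
    )


def scan_genome(genome: Genome, params: RepeatParams | None = None) -> RepeatCatalog:
    """dispersed + tandem detection + partition in one call."""
    params = params or RepeatParams()
    disp = dispersed_repeats(genome, params)
    tand = tandem_repeats(genome)
    return partition(genome, disp, tand, params)


# ---------------------------------------------------------------------------
# Large-repeat families and collapsing
# ---------------------------------------------------------------------------

def _reciprocal_overlap(a: Interval, b: Interval) -> bool:
    ov = a.overlap_len(b)
    return ov >= 0.5 * a.length and ov >= 0.5 * b.length


def cluster_large_families(
    hits: Sequence[HSP], large_repeat_min: int = 1000
) -> list[list[Interval]]:
    """Single-linkage clustering of >1 kb repeat copies into families.

    Copies are the query- and subject-side intervals of hits longer than
    ``large_repeat_min``.  Two copies belong to one family when a hit links
    them directly (they are copies of the same repeat) or when they overlap
    reciprocally by >= 50% (the same genomic copy reported by different
    hits).  Within a family, overlapping member intervals are union-merged
    into one copy region.  Families are sorted by leftmost copy.
    """
    pairs: list[tuple[Interval, Interval]] = []
    for h in hits:
        if h.aligned_len > large_repeat_min:
            pairs.append((h.query, Interval(h.subject.start, h.subject.end)))
    if not pairs:
        return []
    copies = sorted(
        {iv for pair in pairs for iv in pair}, key=lambda iv: (iv.start, iv.end)
    )
    index = {iv: i for i, iv in enumerate(copies)}
    parent = list(range(len(copies)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for qiv, siv in pairs:
        union(index[qiv], index[siv])
    for i in range(len(copies)):
        for j in range(i + 1, len(copies)):
            if copies[j].start >= copies[i].end:
                break
            if _reciprocal_overlap(copies[i], copies[j]):
                union(i, j)
    fams: dict[int, list[Interval]] = {}
    for i, iv in enumerate(copies):
        fams.setdefault(find(i), []).append(iv)
    out = [merge_intervals(members) for members in fams.values()]
    out.sort(key=lambda members: members[0].start)
    return out


def collapse_large_repeats(
    genome: Genome, catalog: RepeatCatalog
) -> CollapsedGenome:
    """Delete all but the leftmost copy of every repeat family > 1 kb.

    Deletions across families are union-merged first (never delete a base
    twice) and applied right-to-left so coordinates stay valid.  The
    operation is idempotent: a collapsed genome has no residual >1 kb
    family.
    """
    to_delete: list[Interval] = []
    for family in catalog.families_gt_1kb:
        # members are already disjoint (union-merged); keep the leftmost
        to_delete.extend(family[1:])
    merged = merge_intervals(to_delete)
    seq = genome.sequence
    for iv in reversed(merged):
        seq = seq[: iv.start] + seq[iv.end :]
    return CollapsedGenome(
        genome_id=genome.id, sequence=seq, deleted_intervals=merged
    )


def collapse(genome: Genome, params: RepeatParams | None = None) -> CollapsedGenome:
    """Scan + collapse convenience wrapper (tandem scan skipped: tandem
    arrays do not form dispersed >1 kb families)."""
    params = params or RepeatParams()
    disp = dispersed_repeats(genome, params)
    catalog = partition(genome, disp, [], params)
    return collapse_large_repeats(genome, catalog)
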