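"""Pairwise shared-DNA estimation, plastid-insertion (MIPT) detection,
shared-DNA-vs-distance decay statistics, and HGT donor profiling.

Shared DNA is measured as query-side coverage: the union of query intervals
of all retained hits, so the matrix is direction-dependent by design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pairalign import find_hsps
from .repeatscan import CollapsedGenome, RepeatParams
from .seqio import Genome, Interval, interval_union_length, merge_intervals


@dataclass
class SharedDNAResult:
    query_id: str
    subject_id: str
    shared_bp: int
    shared_pct: float
    intervals: list[Interval]


@dataclass
class SharedDNAMatrix:
    """Query-side shared-DNA lengths for all ordered genome pairs."""

    genome_ids: list[str]
    shared_bp: dict[str, dict[str, int]]
    shared_pct: dict[str, dict[str, float]]

    def min_off_diagonal_bp(self) -> int:
        vals = [
            self.shared_bp[q][s]
            for q in self.genome_ids
            for s in self.genome_ids
            if q != s
        ]
        return min(vals)


@dataclass
class MIPTReport:
    """Plastome-derived insertions >= min_len in one mitogenome."""

    genome_id: str
    mipts: list[tuple[Interval, Interval, float]]  # (mito, plastome, identity)
    total_bp: int
    pct_of_genome: float


@dataclass
class HGTProfile:
    """Shared DNA of one query against a panel of subjects, ranked."""

    query_id: str
    shared_bp_by_subject: dict[str, int]

    def ranked(self) -> list[tuple[str, int]]:
        return sorted(
            self.shared_bp_by_subject.items(), key=lambda kv: (-kv[1], kv[0])
        )

    @property
    def putative_donor(self) -> str:
        return self.ranked()[0][0]


@dataclass
class DecayRow:
    subject_id: str
    k2p: float
    shared_bp: int
    shared_pct: float


@dataclass
class DecayTable:
    query_id: str
    rows: list[DecayRow]  # sorted by K2P ascending
    pearson_r: float | None
    spearman_rho: float | None
    half_life: float | None  # K2P at which shared_pct crosses 50


def _as_genome(g: Genome | CollapsedGenome) -> Genome:
    return g.as_genome() if isinstance(g, CollapsedGenome) else g


def shared_dna(
    query: Genome | CollapsedGenome,
    subject: Genome | CollapsedGenome,
    params: RepeatParams | None = None,
) -> SharedDNAResult:
    """Query-side coverage of all hits between two (collapsed) genomes.

    Uses the same alignment parameters as the repeat scan.  Callers are
    expected to pass large-repeat-collapsed genomes; passing raw genomes is
    allowed but inflates shared DNA through multicopy sequence.
    """
    params = params or RepeatParams()
    q, s = _as_genome(query), _as_genome(subject)
    hits = find_hsps(
        q,
        s,
        word_size=params.word_size,
        evalue_max=params.evalue_max,
        scheme=params.scheme,
        min_len=params.min_repeat_len,
    )
    intervals = merge_intervals([h.query for h in hits])
    bp = interval_union_length(intervals)
    pct = 100.0 * bp / q.length_bp if q.length_bp else 0.0
    return SharedDNAResult(
        query_id=q.id,
        subject_id=s.id,
        shared_bp=bp,
        shared_pct=pct,
        intervals=intervals,
    )


def shared_dna_matrix(
    genomes: list[Genome | CollapsedGenome], params: RepeatParams | None = None
) -> SharedDNAMatrix:
    """All ordered pairwise comparisons; the diagonal is the genome length.

    Each unordered pair is aligned once; the query-side union of the scan
    gives q->s coverage and the subject-side union gives s->q coverage.
    """
    params = params or RepeatParams()
    gs = [_as_genome(g) for g in genomes]
    ids = [g.id for g in gs]
    bp: dict[str, dict[str, int]] = {i: {} for i in ids}
    pct: dict[str, dict[str, float]] = {i: {} for i in ids}
    for g in gs:
        bp[g.id][g.id] = g.length_bp
        pct[g.id][g.id] = 100.0
    for i, q in enumerate(gs):
        for s in gs[i + 1 :]:
            hits = find_hsps(
                q,
                s,
                word_size=params.word_size,
                evalue_max=params.evalue_max,
                scheme=params.scheme,
                min_len=params.min_repeat_len,
            )
            q_bp = interval_union_length([h.query for h in hits])
            s_bp = interval_union_length(
                [Interval(h.subject.start, h.subject.end) for h in hits]
            )
            bp[q.id][s.id] = q_bp
            bp[s.id][q.id] = s_bp
            pct[q.id][s.id] = 100.0 * q_bp / q.length_bp if q.length_bp else 0.0
            pct[s.id][q.id] = 100.0 * s_bp / s.length_bp if s.length_bp else 0.0
    return SharedDNAMatrix(genome_ids=ids, shared_bp=bp, shared_pct=pct)


def mipt_scan(
    mito: Genome,
    plastome: Genome,
    params: RepeatParams | None = None,
    min_len: int = 100,
) -> MIPTReport:
    """Plastome-derived insertions: mito-vs-plastome hits >= ``min_len``."""
    params = params or RepeatParams()
    hits = find_hsps(
        mito,
        plastome,
        word_size=params.word_size,
        evalue_max=params.evalue_max,
        scheme=params.scheme,
        min_len=max(min_len, params.min_repeat_len),
    )
    hits = [h for h in hits if h.aligned_len >= min_len]
    mipts = [
        (h.query, h.subject, h.identity)
        for h in sorted(hits, key=lambda h: (h.query.start, -h.score))
    ]
    total = interval_union_length([h.query for h in hits])
    pct = 100.0 * total / mito.length_bp if mito.length_bp else 0.0
    return MIPTReport(
        genome_id=mito.id, mipts=mipts, total_bp=total, pct_of_genome=pct
    )


def decay_analysis(
    shared: SharedDNAMatrix,
    dist: dict[str, dict[str, float]],
    query_id: str,
) -> DecayTable:
    """Shared-DNA-vs-distance table for one query, with correlations and
    the interpolated distance at which shared_pct crosses 50 ("half-life").

    ``dist`` is a K2P distance matrix keyed like the shared matrix.  With
    fewer than 3 subjects correlations are undefined (None) but the table
    is still produced.
    """
    rows = []
    for s in shared.genome_ids:
        if s == query_id or s not in dist.get(query_id, {}):
            continue
        rows.append(
            DecayRow(
                subject_id=s,
                k2p=dist[query_id][s],
                shared_bp=shared.shared_bp[query_id][s],
                shared_pct=shared.shared_pct[query_id][s],
            )
        )
    rows.sort(key=lambda r: r.k2p)
    pearson = spearman = None
    if len(rows) >= 3:
        x = np.array([r.k2p for r in rows])
        y = np.array([r.shared_bp for r in rows], dtype=float)
        if np.ptp(y) == 0 or np.ptp(x) == 0:
            warnings.warn("no variance in decay table; correlation undefined")
            pearson = 0.0
            spearman = 0.0
        else:
            pearson = float(stats.pearsonr(x, y)[0])
            spearman = float(stats.spearmanr(x, y)[0])
    half_life = _interpolate_half_life(rows)
    return DecayTable(
        query_id=query_id,
        rows=rows,
        pearson_r=pearson,
        spearman_rho=spearman,
        half_life=half_life,
    )


def _interpolate_half_life(rows: list[DecayRow]) -> float | None:
    """Linear interpolation of the K2P distance where shared_pct hits 50."""
    prev = None
    for r in rows:  # rows sorted by K2P ascending
        if r.shared_pct <= 50.0:
            if prev is None or prev.shared_pct == r.shared_pct:
                return r.k2p
            frac = (prev.shared_pct - 50.0) / (prev.shared_pct - r.shared_pct)
            return prev.k2p + frac * (r.k2p - prev.k2p)
        prev = r
    return None


def hgt_profile(
    query: Genome | CollapsedGenome,
    subjects: list[Genome | CollapsedGenome],
    params: RepeatParams | None = None,
) -> HGTProfile:
    """Shared DNA of one query against >= 2 subjects; the maximal subject is
    the putative donor lineage."""
    if len(subjects) < 2:
        raise ValueError("hgt_profile requires at least 2 subjects")
    q = _as_genome(query)
    prof: dict[str, int] = {}
    for s in subjects:
        prof[_as_genome(s).id] = shared_dna(q, s, params).shared_bp
    return HGTProfile(query_id=q.id, shared_bp_by_subject=prof)


def profile_consistency(a: HGTProfile, b: HGTProfile) -> tuple[dict[str, float], float]:
    """Per-subject 100*a/b over common subjects and the arithmetic mean.

    Subjects with a zero denominator are excluded with a warning.
    """
    common = [
        s
        for s in a.shared_bp_by_subject
        if s in b.shared_bp_by_subject
    ]
    if len(common) < 2:
        raise ValueError("profile_consistency requires >= 2 common subjects")
    per_subject: dict[str, float] = {}
    for s in common:
        denom = b.shared_bp_by_subject[s]
        if denom == 0:
            warnings.warn(f"subject {s}: zero denominator; excluded")
            continue
        per_subject[s] = 100.0 * a.shared_bp_by_subject[s] / denom
    if not per_subject:
        raise ValueError("no subjects with nonzero denominator")
    mean = sum(per_subject.values()) / len(per_subject)
    return per_subject, mean
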