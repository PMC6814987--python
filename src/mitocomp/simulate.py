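"""Synthetic mitogenome-family evolution along a phylogeny.

Generates leaf genomes with a conserved genic core, fast-turnover
intergenic spacers (segmental replacement), planted repeats, plastome
insertions and HGT tracts — with exact ground truth for every downstream
measurement (repeat intervals, plastome-insert intervals, HGT tracts, true
pairwise distances, true shared fractions).

Substitutions follow the Kimura two-parameter process (branch lengths in
expected substitutions/site); IGS turnover is segmental replacement rather
than point indels, so spacers vanish wholesale while coding sequence
persists.  One global seed; per-branch substreams are derived by stable
hashing of the branch's leaf-set signature, so adding a leaf does not
perturb other lineages.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .seqio import Genome, Interval

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_DECODE = {0: "A", 1: "C", 2: "G", 3: "T"}
# transitions: A<->G (0<->2), C<->T (1<->3)
_TRANSITION = np.array([2, 3, 0, 1], dtype=np.uint8)
_STOP_CODONS = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}  # TAA TAG TGA


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _substream(seed: int, *labels: str) -> np.random.Generator:
    h = hashlib.sha256(("|".join(map(str, (seed,) + labels))).encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:8], "big"))


@dataclass(frozen=True)
class RepeatEvent:
    leaf: str
    length: int
    copies: int
    kind: str = "dispersed"  # or "tandem"


@dataclass(frozen=True)
class MiptEvent:
    leaf: str
    length: int


@dataclass(frozen=True)
class HgtEvent:
    donor: str
    recipient: str
    tract_bp: int


def default_gene_set(n_genes: int = 25, gene_len: int = 600) -> list[tuple[str, int]]:
    return [(f"gene{i + 1:02d}", gene_len) for i in range(n_genes)]


@dataclass
class SimulationConfig:
    tree: str  # newick with branch lengths in expected substitutions/site
    genome_len: int = 60_000
    gene_set: list[tuple[str, int]] = field(default_factory=default_gene_set)
    kappa: float = 2.0
    igs_turnover: float = 0.0  # expected IGS fraction replaced per unit branch
    igs_segment_mean: float = 2000.0
    repeat_events: list[RepeatEvent] = field(default_factory=list)
    mipt_events: list[MiptEvent] = field(default_factory=list)
    hgt_events: list[HgtEvent] = field(default_factory=list)
    plastome_len: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(l for _, l in self.gene_set) >= self.genome_len:
            raise ValueError("total gene length must be < genome_len")
        if self.kappa < 0 or self.igs_turnover < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class SimTruth:
    """Ground truth emitted alongside the simulated leaves."""

    gene_intervals: dict[str, dict[str, Interval]]  # leaf -> gene -> interval
    repeat_intervals: dict[str, list[Interval]]
    mipt_intervals: dict[str, list[Interval]]
    hgt_tracts: dict[str, list[Interval]]
    true_distance: dict[str, dict[str, float]]
    true_shared: dict[str, dict[str, float]]  # fraction of ancestral frame
    plastome: Genome | None = None


# ---------------------------------------------------------------------------
# K2P substitution process
# ---------------------------------------------------------------------------

def _k2p_probs(t: float, kappa: float) -> tuple[float, float]:
    """(transition prob, per-transversion prob) after distance ``t``."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = math.exp(-4.0 * beta * t)
    e2 = math.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
    return p_ts, p_tv


def _substitute(
    codes: np.ndarray, t: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    if t <= 0:
        return codes.copy()
    p_ts, p_tv = _k2p_probs(t, kappa)
    u = rng.random(len(codes))
    out = codes.copy()
    ts_mask = u < p_ts
    out[ts_mask] = _TRANSITION[codes[ts_mask]]
    tv1 = (u >= p_ts) & (u < p_ts + p_tv)
    tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    # +1/+3 rotations are always cross-class moves (transition partner is ^2)
    out[tv1] = (codes[tv1] + 1) % 4
    out[tv2] = (codes[tv2] + 3) % 4
    return out


def _repair_stops(
    child: np.ndarray, parent: np.ndarray, genes: dict[str, Interval]
) -> None:
    """Revert any codon that a substitution turned into an internal stop.

    Keeps planted intact genes classifiable as intact at any simulated
    divergence.
    """
    for iv in genes.values():
        seg = child[iv.start : iv.end]
        for c in range(0, len(seg) - 3, 3):  # skip the terminal stop codon
            if (int(seg[c]), int(seg[c + 1]), int(seg[c + 2])) in _STOP_CODONS:
                seg[c : c + 3] = parent[iv.start + c : iv.start + c + 3]


# ---------------------------------------------------------------------------
# IGS segmental replacement
# ---------------------------------------------------------------------------

def _replace_igs(
    codes: np.ndarray,
    igs: list[Interval],
    frac: float,
    segment_mean: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Replace ~``frac`` of IGS bp with fresh random sequence; returns the
    per-position replacement mask for this branch."""
    mask = np.zeros(len(codes), dtype=bool)
    if frac <= 0 or not igs:
        return mask
    total_igs = sum(iv.length for iv in igs)
    target = min(frac, 1.0) * total_igs
    weights = np.array([iv.length for iv in igs], dtype=float)
    weights /= weights.sum()
    covered = 0
    guard = 0
    while covered < target and guard < 10_000:
        guard += 1
        iv = igs[rng.choice(len(igs), p=weights)]
        seg_len = max(50, int(rng.exponential(segment_mean)))
        seg_len = min(seg_len, iv.length)
        start = iv.start + int(rng.integers(0, iv.length - seg_len + 1))
        covered += int(np.count_nonzero(~mask[start : start + seg_len]))
        mask[start : start + seg_len] = True
    pos = np.nonzero(mask)[0]
    codes[pos] = rng.integers(0, 4, len(pos), dtype=np.uint8)
    return mask


# ---------------------------------------------------------------------------
# Main evolution driver
# ---------------------------------------------------------------------------

def _build_ancestor(cfg: SimulationConfig, rng: np.random.Generator):
    """Uniform-random ancestor with evenly spaced stop-free genes."""
    total_gene = sum(l for _, l in cfg.gene_set)
    n = len(cfg.gene_set)
    gap = (cfg.genome_len - total_gene) // (n + 1)
    codes = rng.integers(0, 4, cfg.genome_len, dtype=np.uint8)
    genes: dict[str, Interval] = {}
    pos = gap
    for name, length in cfg.gene_set:
        if length % 3 != 0:
            raise ValueError(f"{name}: gene length must be divisible by 3")
        genes[name] = Interval(pos, pos + length)
        # stop-free codons, then a terminal stop
        for c in range(pos, pos + length - 3, 3):
            while (int(codes[c]), int(codes[c + 1]), int(codes[c + 2])) in _STOP_CODONS:
                codes[c : c + 3] = rng.integers(0, 4, 3, dtype=np.uint8)
        codes[pos + length - 3 : pos + length] = [3, 0, 0]  # TAA
        pos += length + gap
    return codes, genes


def _leafset_signature(node) -> str:
    return ",".join(sorted(lf.taxon.label for lf in node.leaf_iter()))


def evolve(cfg: SimulationConfig) -> tuple[dict[str, Genome], SimTruth]:
    """Evolve the configured family; returns leaf genomes plus ground truth.

    Deterministic for a fixed config + seed (byte-identical sequences).
    """
    tree = dendropy.Tree.get(data=cfg.tree, schema="newick")
    leaves = [t.label for t in tree.taxon_namespace]
    if any(l is None for l in leaves):
        raise ValueError("all leaves must be labeled")

    rng_anc = _substream(cfg.seed, "ancestor")
    anc_codes, genes = _build_ancestor(cfg, rng_anc)
    igs: list[Interval] = []
    pos = 0
    for iv in sorted(genes.values(), key=lambda iv: iv.start):
        if iv.start > pos:
            igs.append(Interval(pos, iv.start))
        pos = iv.end
    if pos < cfg.genome_len:
        igs.append(Interval(pos, cfg.genome_len))

    # descend the tree; per node keep (codes, list of branch masks on the
    # path from the root)
    node_seqs: dict[int, np.ndarray] = {id(tree.seed_node): anc_codes}
    branch_masks: dict[str, np.ndarray] = {}
    node_paths: dict[int, list[str]] = {id(tree.seed_node): []}

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_codes = node_seqs[id(node.parent_node)]
        sig = _leafset_signature(node)
        t = node.edge.length or 0.0
        rng_b = _substream(cfg.seed, "branch", sig)
        child = _substitute(parent_codes, t, cfg.kappa, rng_b)
        _repair_stops(child, parent_codes, genes)
        mask = _replace_igs(
            child, igs, cfg.igs_turnover * t, cfg.igs_segment_mean, rng_b
        )
        branch_masks[sig] = mask
        node_seqs[id(node)] = child
        node_paths[id(node)] = node_paths[id(node.parent_node)] + [sig]

    leaf_codes: dict[str, np.ndarray] = {}
    leaf_paths: dict[str, list[str]] = {}
    for leaf in tree.leaf_node_iter():
        leaf_codes[leaf.taxon.label] = node_seqs[id(leaf)]
        leaf_paths[leaf.taxon.label] = node_paths[id(leaf)]

    # per-leaf gene coordinate tracking through insertions
    leaf_genes: dict[str, dict[str, Interval]] = {
        l: dict(genes) for l in leaf_codes
    }
    repeat_tr: dict[str, list[Interval]] = {l: [] for l in leaf_codes}
    mipt_tr: dict[str, list[Interval]] = {l: [] for l in leaf_codes}
    hgt_tr: dict[str, list[Interval]] = {l: [] for l in leaf_codes}

    plastome = None
    if cfg.mipt_events:
        rng_p = _substream(cfg.seed, "plastome")
        plastome = Genome(
            id="plastome",
            sequence=_decode(rng_p.integers(0, 4, cfg.plastome_len, dtype=np.uint8)),
        )

    def insert(leaf: str, at: int, segment: np.ndarray) -> Interval:
        codes = leaf_codes[leaf]
        leaf_codes[leaf] = np.concatenate([codes[:at], segment, codes[at:]])
        shift = len(segment)
        for table in (repeat_tr, mipt_tr, hgt_tr):
            table[leaf] = [
                Interval(
                    iv.start + shift if iv.start >= at else iv.start,
                    iv.end + shift if iv.start >= at else iv.end,
                    iv.strand,
                )
                for iv in table[leaf]
            ]
        leaf_genes[leaf] = {
            g: (
                Interval(iv.start + shift, iv.end + shift, iv.strand)
                if iv.start >= at
                else iv
            )
            for g, iv in leaf_genes[leaf].items()
        }
        return Interval(at, at + shift)

    def igs_position(leaf: str, rng: np.random.Generator) -> int:
        """A position between genes (never splits a gene)."""
        gene_ivs = sorted(leaf_genes[leaf].values(), key=lambda iv: iv.start)
        gaps = []
        pos = 0
        for iv in gene_ivs:
            if iv.start > pos:
                gaps.append((pos, iv.start))
            pos = iv.end
        n = len(leaf_codes[leaf])
        if pos < n:
            gaps.append((pos, n))
        lo, hi = gaps[int(rng.integers(0, len(gaps)))]
        return int(rng.integers(lo, hi + 1))

    for k, ev in enumerate(cfg.repeat_events):
        rng_e = _substream(cfg.seed, "repeat", str(k))
        codes = leaf_codes[ev.leaf]
        src = int(rng_e.integers(0, len(codes) - ev.length))
        motif = codes[src : src + ev.length].copy()
        if ev.kind == "tandem":
            at = igs_position(ev.leaf, rng_e)
            arr = np.tile(motif, ev.copies)
            iv = insert(ev.leaf, at, arr)
            repeat_tr[ev.leaf].append(iv)
        else:
            repeat_tr[ev.leaf].append(Interval(src, src + ev.length))
            for _ in range(max(0, ev.copies - 1)):
                at = igs_position(ev.leaf, rng_e)
                iv = insert(ev.leaf, at, motif)
                repeat_tr[ev.leaf].append(iv)

    for k, ev in enumerate(cfg.mipt_events):
        rng_e = _substream(cfg.seed, "mipt", str(k))
        psrc = int(rng_e.integers(0, plastome.length_bp - ev.length))
        seg = _encode(plastome.sequence[psrc : psrc + ev.length])
        at = igs_position(ev.leaf, rng_e)
        iv = insert(ev.leaf, at, seg)
        mipt_tr[ev.leaf].append(iv)

    for k, ev in enumerate(cfg.hgt_events):
        rng_e = _substream(cfg.seed, "hgt", str(k))
        donor = leaf_codes[ev.donor]
        if ev.tract_bp > len(donor):
            raise ValueError("tract_bp exceeds donor length")
        src = int(rng_e.integers(0, len(donor) - ev.tract_bp + 1))
        seg = donor[src : src + ev.tract_bp].copy()
        at = igs_position(ev.recipient, rng_e)
        iv = insert(ev.recipient, at, seg)
        hgt_tr[ev.recipient].append(iv)

    genomes = {l: Genome(id=l, sequence=_decode(c)) for l, c in leaf_codes.items()}

    # truth matrices
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    true_dist: dict[str, dict[str, float]] = {l: {} for l in leaf_codes}
    true_shared: dict[str, dict[str, float]] = {l: {} for l in leaf_codes}
    labels = sorted(leaf_codes)
    for a in labels:
        true_dist[a][a] = 0.0
        true_shared[a][a] = 1.0
        for b in labels:
            if b <= a:
                continue
            d = pdm.patristic_distance(taxa[a], taxa[b])
            true_dist[a][b] = d
            true_dist[b][a] = d
            pa, pb = set(leaf_paths[a]), set(leaf_paths[b])
            below_mrca = pa.symmetric_difference(pb)
            replaced = np.zeros(cfg.genome_len, dtype=bool)
            for sig in below_mrca:
                replaced |= branch_masks[sig]
            frac = 1.0 - replaced.mean()
            true_shared[a][b] = frac
            true_shared[b][a] = frac

    truth = SimTruth(
        gene_intervals=leaf_genes,
        repeat_intervals=repeat_tr,
        mipt_intervals=mipt_tr,
        hgt_tracts=hgt_tr,
        true_distance=true_dist,
        true_shared=true_shared,
        plastome=plastome,
    )
    return genomes, truth


def ladder_tree(n_leaves: int, step: float) -> str:
    """Newick ladder (...((L1,L2),L3)...,Ln); every branch has length
    ``step``, so the L1->Lk distance grows as k*step."""
    if n_leaves < 2:
        raise ValueError("need >= 2 leaves")
    tree = f"(L1:{step},L2:{step})"
    for i in range(3, n_leaves + 1):
        tree = f"({tree}:{step},L{i}:{step})"
    return tree + ";"


def make_parasite(
    donor: Genome,
    tract_bp: int,
    background_bp: int,
    seed: int = 0,
    chunk_bp: int = 10_000,
    parasite_id: str = "parasite",
) -> tuple[Genome, list[Interval]]:
    """Parasite genome = donor tracts interleaved with random background.

    Returns the genome and the truth intervals (parasite coordinates) of
    donor-derived tracts.
    """
    if tract_bp > donor.length_bp:
        raise ValueError("tract_bp exceeds donor length")
    rng = _substream(seed, "parasite", donor.id)
    donor_codes = _encode(donor.sequence)
    chunks: list[tuple[str, np.ndarray]] = []
    remaining = tract_bp
    while remaining > 0:
        size = min(chunk_bp, remaining)
        src = int(rng.integers(0, donor.length_bp - size + 1))
        chunks.append(("donor", donor_codes[src : src + size].copy()))
        remaining -= size
    remaining = background_bp
    while remaining > 0:
        size = min(chunk_bp, remaining)
        chunks.append(("bg", rng.integers(0, 4, size, dtype=np.uint8)))
        remaining -= size
    order = rng.permutation(len(chunks))
    tracts: list[Interval] = []
    parts: list[np.ndarray] = []
    pos = 0
    for i in order:
        kind, seg = chunks[i]
        if kind == "donor":
            tracts.append(Interval(pos, pos + len(seg)))
        parts.append(seg)
        pos += len(seg)
    seq = _decode(np.concatenate(parts)) if parts else ""
    return Genome(id=parasite_id, sequence=seq), tracts
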