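"""Similarity-driven gene copy-number detection, clustering and context calls.

A reference strain's genes are searched against every genome with a k-mer
seed prescreen followed by glocal verification (global over the query gene,
free end gaps on the genomic window), and a hit counts as a copy when both
identity and query coverage strictly exceed the 95% cutoffs — chosen to
exceed the maximum average divergence between strains of a within-species
complex, so every duplication arising since their divergence is detected.

Reference genes whose pairwise hits pass the same cutoffs are pooled into
paralog clusters by single linkage (the *asnT/asnU/asnV/asnW* situation:
any member finds the others). Per-strain copy counting queries a genome with
every cluster member and unions the hit loci. Slightly diverged selfish
elements can surface as near-duplicate clusters hitting the same loci;
:func:`cull_redundant_sets` keeps one of each such pair, mirroring the
manual culling that produces a conservative duplicate-gene set.

Context classification distinguishes the two routes to extra gene copies:
``tandem_array`` (consecutive same-strand copies, i.e. within-genome
duplication) versus ``phage_flanked`` insertions (phage-mediated lateral
transfer) versus ``host_flanked`` originals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from scipy import stats as _scipy_stats

from .io_core import AnnotatedGenome, GeneFeature

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AlignmentStats:
    identity: float  # matches / aligned query positions
    coverage: float  # aligned query positions / query length
    score: float


@dataclass
class Hit:
    """One located gene copy on a genome."""

    start: int
    end: int
    strand: str
    identity: float
    coverage: float
    score: float


@dataclass
class CopyCluster:
    cluster_id: str
    members: list[str]  # reference gene ids
    hits: dict[str, list[Hit]] = field(default_factory=dict)  # strain -> hits

    @property
    def copy_count(self) -> dict[str, int]:
        return {s: len(h) for s, h in self.hits.items()}


@dataclass
class ContextCall:
    locus: tuple[int, int]
    call: str  # tandem_array | phage_flanked | host_flanked | ambiguous
    flank_left: tuple[str, str] | None  # (gene_id, category)
    flank_right: tuple[str, str] | None
    identity_to_original: float | None = None


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    # free end gaps on the subject (glocal): the genomic window may overhang
    # the query gene at no cost; overhanging subject letters pair with end
    # gaps in the query row ("deletions" in Bio.Align's naming)
    aligner.open_end_deletion_score = 0
    aligner.extend_end_deletion_score = 0
    return aligner


_ALIGNER = _make_aligner()


def align_stats(query: str, subject: str) -> AlignmentStats:
    """Glocal alignment statistics of a gene against a genomic window.

    Identity is matches over aligned query positions; coverage is aligned
    query positions over query length. A sequence aligned to itself scores
    identity 1, coverage 1.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    aln = _ALIGNER.align(subject, query)[0]
    counts = aln.counts()
    aligned = counts.identities + counts.mismatches
    return AlignmentStats(
        identity=counts.identities / aligned if aligned else 0.0,
        coverage=aligned / len(query),
        score=float(aln.score),
    )


def _aligned_subject_span(query: str, subject: str) -> tuple[int, int, float,
                                                             float, float]:
    """(subject start, subject end, identity, coverage, score) of the hit."""
    aln = _ALIGNER.align(subject, query)[0]
    counts = aln.counts()
    aligned = counts.identities + counts.mismatches
    blocks = aln.aligned[0]  # subject-coordinate blocks
    if len(blocks) == 0:
        return 0, 0, 0.0, 0.0, float(aln.score)
    return (int(blocks[0][0]), int(blocks[-1][1]),
            counts.identities / aligned if aligned else 0.0,
            aligned / len(query), float(aln.score))


# ---------------------------------------------------------------------------
# k-mer seeded copy search
# ---------------------------------------------------------------------------

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer codes of all k-mers; k-mers containing non-ACGT get code -1."""
    codes = _encode(seq)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    weights = 4 ** np.arange(k, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        col = codes[j:j + n]
        out += np.where(col >= 0, col, 0) * weights[j]
        bad |= col < 0
    out[bad] = -1
    return out


class GenomeIndex:
    """Cached 2-bit k-mer codes of a genome, for repeated seed scans."""

    def __init__(self, genome: AnnotatedGenome, k: int = 12):
        self.genome = genome
        self.k = k
        self.codes = _kmer_codes(genome.sequence, k)

    def seed_positions(self, query: str) -> np.ndarray:
        """Genome positions whose k-mer occurs in the query (either strand)."""
        qk = np.concatenate([_kmer_codes(query, self.k),
                             _kmer_codes(_revcomp(query), self.k)])
        qk = np.unique(qk[qk >= 0])
        if qk.size == 0:
            return np.arange(len(self.codes))  # query shorter than k: full scan
        return np.flatnonzero(np.isin(self.codes, qk))


def _candidate_windows(positions: np.ndarray, qlen: int,
                       margin: int | None = None) -> list[tuple[int, int]]:
    """Group seed positions into candidate windows.

    The margin defaults to the query length so that a copy is fully inside
    its window even when its only seed k-mer sits at the far end of the
    copy (divergence can wipe out the seeds of one flank).
    """
    if positions.size == 0:
        return []
    margin = qlen if margin is None else margin
    windows = []
    start = prev = int(positions[0])
    for p in positions[1:]:
        p = int(p)
        if p - prev > qlen:
            windows.append((max(0, start - margin), prev + qlen + margin))
            start = p
        prev = p
    windows.append((max(0, start - margin), prev + qlen + margin))
    return windows


def _gapless_peaks(window_codes: np.ndarray, query_codes: np.ndarray,
                   min_identity: float) -> tuple[list[tuple[int, int]], float]:
    """All non-overlapping gapless placements of the query in a window.

    Returns ``([(offset, matches), ...], best_identity)``; placements are
    greedy maxima of the per-offset match count, suppressing overlaps.
    """
    q = len(query_codes)
    m = len(window_codes)
    if m < q:
        return [], 0.0
    view = np.lib.stride_tricks.sliding_window_view(window_codes, q)
    matches = (view == query_codes).sum(axis=1)
    best_identity = float(matches.max()) / q
    passing = np.flatnonzero(matches > min_identity * q)
    peaks: list[tuple[int, int]] = []
    for off in passing[np.argsort(matches[passing])[::-1]]:
        if all(abs(int(off) - p) >= q for p, _ in peaks):
            peaks.append((int(off), int(matches[off])))
    return sorted(peaks), best_identity


def find_copies(reference_gene: str, target: AnnotatedGenome | GenomeIndex,
                min_identity: float = 0.95, min_coverage: float = 0.95,
                k: int = 12) -> list[Hit]:
    """Locate copies of a reference gene in a genome at the 95/95 cutoffs.

    Seed-and-extend: a k-mer prescreen (both strands) proposes candidate
    windows; within each window every gapless placement of the query that
    strictly exceeds both cutoffs (0.95 exactly fails) is a hit, and a
    window whose best gapless identity lands just below the cutoff is
    re-verified by glocal alignment (to admit indel-containing copies).
    Overlapping hits are merged keeping the best score.
    """
    index = target if isinstance(target, GenomeIndex) else GenomeIndex(target, k)
    genome = index.genome
    qlen = len(reference_gene)
    queries = {"+": _encode(reference_gene),
               "-": _encode(_revcomp(reference_gene))}
    hits: list[Hit] = []
    for w0, w1 in _candidate_windows(index.seed_positions(reference_gene), qlen):
        window_codes = _encode(genome.sequence[w0:w1])
        window_hits: list[Hit] = []
        needs_gapped = False
        for strand, qcodes in queries.items():
            peaks, best_ident = _gapless_peaks(window_codes, qcodes,
                                               min_identity)
            for off, matches in peaks:
                window_hits.append(Hit(w0 + off, w0 + off + qlen, strand,
                                       matches / qlen, 1.0,
                                       float(2 * matches - qlen)))
            if not peaks and best_ident > min_identity - 0.15:
                needs_gapped = True
        if not window_hits and needs_gapped:
            window = genome.sequence[w0:w1]
            for strand, query in (("+", reference_gene),
                                  ("-", _revcomp(reference_gene))):
                s0, s1, ident, cov, score = _aligned_subject_span(query, window)
                if ident > min_identity and cov > min_coverage:
                    window_hits.append(Hit(w0 + s0, w0 + s1, strand, ident,
                                           cov, score))
        hits.extend(window_hits)
    return _merge_overlapping(hits)


def _merge_overlapping(hits: list[Hit]) -> list[Hit]:
    """Merge overlapping hits, keeping the single best-scoring one."""
    hits = sorted(hits, key=lambda h: (h.start, h.end))
    merged: list[Hit] = []
    for h in hits:
        if merged and h.start < merged[-1].end:
            if h.score > merged[-1].score:
                merged[-1] = h
        else:
            merged.append(h)
    return merged


# ---------------------------------------------------------------------------
# clustering and per-strain counting
# ---------------------------------------------------------------------------

def build_clusters(reference_genes: Mapping[str, str],
                   min_identity: float = 0.95,
                   min_coverage: float = 0.95) -> list[CopyCluster]:
    """Single-linkage paralog clusters over the 95/95 similarity relation.

    ``reference_genes`` maps gene id to coding sequence (one reference
    strain). Two genes are linked when a glocal alignment of either onto
    the other passes both cutoffs; each gene ends up in exactly one cluster.
    """
    ids = sorted(reference_genes)
    parent = {g: g for g in ids}

    def find(g: str) -> str:
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if find(a) == find(b):
                continue
            # skip clearly incomparable lengths before aligning
            la, lb = len(reference_genes[a]), len(reference_genes[b])
            if min(la, lb) < min_coverage * max(la, lb):
                continue
            st = align_stats(reference_genes[a], reference_genes[b])
            if st.identity > min_identity and st.coverage > min_coverage:
                parent[find(b)] = find(a)
    groups: dict[str, list[str]] = {}
    for g in ids:
        groups.setdefault(find(g), []).append(g)
    clusters = [CopyCluster(cluster_id=min(members), members=sorted(members))
                for members in groups.values()]
    return sorted(clusters, key=lambda c: c.cluster_id)


def count_copies(clusters: Sequence[CopyCluster],
                 reference_genes: Mapping[str, str],
                 genomes: Mapping[str, AnnotatedGenome],
                 min_identity: float = 0.95, min_coverage: float = 0.95,
                 k: int = 12) -> None:
    """Locate each cluster's copies in every genome (hits stored in place).

    Every cluster member is used as a query and the hit loci are unioned —
    if a strain carries any one member, that member's own sequence finds
    its siblings.
    """
    for strain, genome in genomes.items():
        index = GenomeIndex(genome, k)
        for cluster in clusters:
            pooled: list[Hit] = []
            # identical paralogs (e.g. a fresh tandem array) query once
            for query in dict.fromkeys(reference_genes[m]
                                       for m in cluster.members):
                pooled.extend(find_copies(query, index,
                                          min_identity, min_coverage, k))
            cluster.hits[strain] = _merge_overlapping(pooled)


def cull_redundant_sets(clusters: Sequence[CopyCluster],
                        min_reciprocal_overlap: float = 0.5
                        ) -> list[CopyCluster]:
    """Drop near-duplicate clusters that hit the same loci.

    If two clusters' located hits overlap reciprocally in more than half of
    their members (per strain, counting hits whose intervals intersect a
    hit of the other cluster), the cluster with fewer reference members is
    dropped; ties drop the lexicographically later id. Deterministic and
    idempotent.
    """

    def overlap_fraction(a: CopyCluster, b: CopyCluster) -> float:
        total = matched = 0
        for strain, hits in a.hits.items():
            others = b.hits.get(strain, [])
            for h in hits:
                total += 1
                if any(h.start < o.end and o.start < h.end for o in others):
                    matched += 1
        return matched / total if total else 0.0

    alive = {c.cluster_id: c for c in clusters}
    order = sorted(alive)
    for i, ida in enumerate(order):
        for idb in order[i + 1:]:
            if ida not in alive or idb not in alive:
                continue
            a, b = alive[ida], alive[idb]
            if (overlap_fraction(a, b) > min_reciprocal_overlap
                    and overlap_fraction(b, a) > min_reciprocal_overlap):
                if len(a.members) < len(b.members):
                    drop = ida
                elif len(b.members) < len(a.members):
                    drop = idb
                else:
                    drop = max(ida, idb)
                del alive[drop]
    return [alive[cid] for cid in sorted(alive)]


# ---------------------------------------------------------------------------
# genomic context
# ---------------------------------------------------------------------------

def detect_tandem(loci: Sequence[tuple[int, int, str]],
                  window: int = 5000) -> list[bool]:
    """Mark loci lying in tandem arrays.

    ``loci`` are (start, end, strand) of same-cluster copies on one genome.
    A maximal run of >= 2 same-strand loci with successive gaps <= window is
    a tandem array.
    """
    order = sorted(range(len(loci)), key=lambda i: loci[i][0])
    flags = [False] * len(loci)
    run: list[int] = []

    def close_run() -> None:
        if len(run) >= 2:
            for i in run:
                flags[i] = True

    for idx in order:
        if run:
            p = loci[run[-1]]
            q = loci[idx]
            if q[2] == p[2] and q[0] - p[1] <= window:
                run.append(idx)
                continue
            close_run()
        run = [idx]
    close_run()
    return flags


def classify_context(genome: AnnotatedGenome, locus: tuple[int, int],
                     cluster_loci: Sequence[tuple] = (),
                     flank_window: int = 10_000,
                     original_seq: str | None = None,
                     locus_seq: str | None = None,
                     locus_strand: str | None = None,
                     tandem_window: int = 5000) -> ContextCall:
    """Classify the genomic context of one gene copy.

    The nearest annotated feature on each side (within ``flank_window``,
    excluding features overlapping any same-cluster locus) decides the
    call: phage on either side -> ``phage_flanked``; host on both sides ->
    ``host_flanked``; no neighbors -> ``ambiguous``. A copy forms a
    ``tandem_array`` with another same-cluster copy when the two lie on the
    same strand within the tandem window with no unrelated gene between
    them (tandem arrays are contiguous duplications). When ``original_seq``
    is given, the copy's identity to the designated original is reported.

    ``cluster_loci`` entries are ``(start, end)`` or ``(start, end, strand)``.
    """
    start, end = locus

    def in_cluster(f: GeneFeature) -> bool:
        return any(f.start < loc[1] and loc[0] < f.end
                   for loc in cluster_loci) or (
            f.start < end and start < f.end)

    left = right = None
    for f in genome.features:
        if in_cluster(f):
            continue
        if f.end <= start and start - f.end <= flank_window:
            if left is None or f.end > left.end:
                left = f
        elif f.start >= end and f.start - end <= flank_window:
            if right is None or f.start < right.start:
                right = f
                break

    def contiguous(a: tuple[int, int], b: tuple[int, int]) -> bool:
        lo, hi = (a[1], b[0]) if a[1] <= b[0] else (b[1], a[0])
        return not any(f.start < hi and f.end > lo and not in_cluster(f)
                       for f in genome.features)

    near_same = False
    for loc in cluster_loci:
        s, e = loc[0], loc[1]
        if (s, e) == (start, end):
            continue
        strand_ok = (locus_strand is None or len(loc) < 3
                     or loc[2] == locus_strand)
        gap = s - end if s >= end else start - e
        if strand_ok and 0 <= gap <= tandem_window and contiguous(
                (start, end), (s, e)):
            near_same = True
            break
    if near_same:
        call = "tandem_array"
    elif (left and left.category == "phage") or (right and right.category == "phage"):
        call = "phage_flanked"
    elif left and right and left.category == "host" and right.category == "host":
        call = "host_flanked"
    else:
        call = "ambiguous"
    identity = None
    if original_seq is not None:
        seq = locus_seq or genome.sequence[start:end]
        fwd = align_stats(seq, original_seq)
        rev = align_stats(_revcomp(seq), original_seq)
        identity = max(fwd.identity, rev.identity)
    return ContextCall((start, end), call,
                       (left.gene_id, left.category) if left else None,
                       (right.gene_id, right.category) if right else None,
                       identity)


# ---------------------------------------------------------------------------
# group comparison of SGE totals
# ---------------------------------------------------------------------------

def sge_group_ttest(counts_a: Sequence[float],
                    counts_b: Sequence[float]) -> tuple[float, float]:
    """Welch two-sample t test of per-strain SGE totals (two-sided).

    Degenerate rule: identical constant groups give t = 0, p = 1.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 strains per group")
    if a.std() == 0 and b.std() == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    t, p = _scipy_stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# external tabular search results (BLAST outfmt-6-like adapter)
# ---------------------------------------------------------------------------

def hits_from_tabular(tsv_path, query_lengths: Mapping[str, int],
                      min_identity: float = 0.95, min_coverage: float = 0.95
                      ) -> dict[str, list[Hit]]:
    """Read 12-column tabular search results into per-query hit lists.

    Columns follow the common tabular dialect: query, subject, %identity,
    alignment length, mismatches, gap opens, qstart, qend, sstart, send,
    evalue, bitscore. Coverage is alignment length over query length;
    subject coordinates are converted to 0-based half-open with strand from
    their orientation.
    """
    out: dict[str, list[Hit]] = {}
    with open(tsv_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            c = line.rstrip("\n").split("\t")
            q, _s = c[0], c[1]
            ident = float(c[2]) / 100.0
            alen = int(c[3])
            sstart, send = int(c[8]), int(c[9])
            strand = "+" if send >= sstart else "-"
            lo, hi = sorted((sstart, send))
            cov = alen / query_lengths[q]
            if ident > min_identity and cov > min_coverage:
                out.setdefault(q, []).append(
                    Hit(lo - 1, hi, strand, ident, cov, float(c[11])))
    for q in out:
        out[q] = _merge_overlapping(out[q])
    return out


__all__ = [
    "AlignmentStats", "Hit", "CopyCluster", "ContextCall", "GenomeIndex",
    "align_stats", "find_copies", "build_clusters", "count_copies",
    "cull_redundant_sets", "detect_tandem", "classify_context",
    "sge_group_ttest", "hits_from_tabular",
]
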