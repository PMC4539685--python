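"""Codon usage tables, fold enrichment, codon ranking and the rank-sum test.

Relative codon usage is normalized per amino-acid group (the bacterial code,
NCBI translation table 11), so the synonymous codons of each amino acid — and
the three stop codons as one group — sum to 1. The leading triplet of every
CDS is credited to methionine regardless of its identity, because bacterial
start codons (ATG/GTG/TTG) are all read as fMet.

Fold enrichment of a gene subset is the ratio of its per-amino-acid relative
codon frequency to that of the whole genome (all genes *including* the
subset, a deliberately conservative denominator). Codons are ranked 1..64
from most to least enriched, and the evidence that a chosen set of k codons
sits unusually high in that ranking is the one-tailed rank-sum test: the
observed sum of their ranks against the null of k ranks drawn at random
from 1..n. Both an exact p (dynamic programming over rank sums) and a
Monte-Carlo p are provided.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

BASES = "ACGT"
CODONS: tuple[str, ...] = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES
)

_table11 = CodonTable.unambiguous_dna_by_id[11]
#: codon -> single-letter amino acid, stop codons mapped to '*'
CODON_TO_AA: dict[str, str] = {
    **{c: aa for c, aa in _table11.forward_table.items() if c in CODONS},
    **{c: "*" for c in _table11.stop_codons},
}
#: amino acid (incl. '*') -> tuple of synonymous codons
AA_GROUPS: dict[str, tuple[str, ...]] = {}
for _c in CODONS:
    AA_GROUPS.setdefault(CODON_TO_AA[_c], tuple())
AA_GROUPS = {
    aa: tuple(c for c in CODONS if CODON_TO_AA[c] == aa) for aa in AA_GROUPS
}

ARG_CODONS = AA_GROUPS["R"]  # CGT, CGC, CGA, CGG, AGA, AGG


@dataclass
class CodonUsageTable:
    """Absolute codon counts and per-amino-acid relative frequencies.

    ``rel[c]`` is NaN for codons whose amino-acid group has zero total count
    (the group is flagged rather than silently zeroed).
    """

    counts: dict[str, int]
    rel: dict[str, float] = field(init=False)
    genetic_code: str = "11"

    def __post_init__(self) -> None:
        if set(self.counts) != set(CODONS):
            self.counts = {c: self.counts.get(c, 0) for c in CODONS}
        self.rel = {}
        for aa, group in AA_GROUPS.items():
            total = sum(self.counts[c] for c in group)
            for c in group:
                self.rel[c] = self.counts[c] / total if total > 0 else math.nan
        for aa, group in AA_GROUPS.items():
            s = sum(self.rel[c] for c in group)
            if not math.isnan(s):
                assert abs(s - 1.0) < 1e-9

    @classmethod
    def from_rel(cls, rel: Mapping[str, float]) -> "CodonUsageTable":
        """Build a table from per-amino-acid relative frequencies.

        The values are taken as (possibly fractional) weights; per-group
        normalization reproduces them exactly when each group sums to 1.
        """
        return cls(counts={c: float(rel.get(c, 0.0)) for c in CODONS})

    def zero_groups(self) -> list[str]:
        """Amino acids whose relative usage is undefined (zero counts)."""
        return [aa for aa, group in AA_GROUPS.items()
                if all(self.counts[c] == 0 for c in group)]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class EnrichmentRanking:
    """Per-codon fold enrichment of a subset vs. the genome, with ranks."""

    fold: dict[str, float]
    rank: dict[str, int]
    ci99: dict[str, tuple[float, float]] | None = None


@dataclass
class RankTestResult:
    observed_sum: int
    k: int
    n: int
    p_mc: float
    p_exact: float
    reps: int
    seed: int
    mode: str


# ---------------------------------------------------------------------------
# counting and relative usage
# ---------------------------------------------------------------------------

def count_codons(cds_list: Iterable[str | tuple[str, str]],
                 first_codon_as_met: bool = True) -> dict[str, int]:
    """Tally in-frame codons over a list of coding sequences.

    Accepts plain sequences or ``(gene_id, sequence)`` pairs. The first
    triplet of each CDS is credited to ATG (methionine) when
    ``first_codon_as_met``; codons containing N are skipped; any other
    non-ACGT character rejects the sequence.
    """
    counts = {c: 0 for c in CODONS}
    valid = set("ACGTN")
    for item in cds_list:
        seq = item[1] if isinstance(item, tuple) else item
        seq = seq.upper()
        if len(seq) % 3 != 0:
            raise ValueError("CDS length not divisible by 3")
        if set(seq) - valid:
            raise ValueError(f"non-ACGTN character in CDS: "
                             f"{sorted(set(seq) - valid)}")
        for i in range(0, len(seq), 3):
            codon = seq[i:i + 3]
            if "N" in codon:
                continue
            if i == 0 and first_codon_as_met:
                counts["ATG"] += 1
            else:
                counts[codon] += 1
    return counts


def relative_usage(counts: Mapping[str, int]) -> CodonUsageTable:
    """Per-amino-acid relative codon usage (groups each sum to 1)."""
    return CodonUsageTable(counts=dict(counts))


def usage_from_cds(cds_list: Iterable[str | tuple[str, str]]) -> CodonUsageTable:
    return relative_usage(count_codons(cds_list))


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def fold_enrichment(subset: CodonUsageTable,
                    genome: CodonUsageTable) -> dict[str, float]:
    """E_c = rel_subset[c] / rel_genome[c], per codon.

    genome rel 0 with subset rel > 0 is flagged +inf; both 0 gives 1.0
    (no evidence either way); an undefined group propagates NaN.
    """
    fold: dict[str, float] = {}
    for c in CODONS:
        rs, rg = subset.rel[c], genome.rel[c]
        if math.isnan(rs) or math.isnan(rg):
            fold[c] = math.nan
        elif rg == 0.0:
            fold[c] = 1.0 if rs == 0.0 else math.inf
        else:
            fold[c] = rs / rg
    return fold


def enrichment_ci(per_strain_folds: Sequence[Mapping[str, float]],
                  level: float = 0.99) -> dict[str, tuple[float, float]]:
    """Cross-strain t confidence interval of each codon's fold enrichment.

    mean +/- t_{(1+level)/2, n-1} * s / sqrt(n). Requires >= 2 strains;
    codons with any NaN/inf fold across strains get a NaN interval.
    """
    n = len(per_strain_folds)
    if n < 2:
        raise ValueError("confidence interval requires >= 2 strains")
    tcrit = stats.t.ppf((1 + level) / 2, df=n - 1)
    out: dict[str, tuple[float, float]] = {}
    for c in CODONS:
        vals = np.array([f[c] for f in per_strain_folds], dtype=float)
        if not np.all(np.isfinite(vals)):
            out[c] = (math.nan, math.nan)
            continue
        m = vals.mean()
        half = tcrit * vals.std(ddof=1) / math.sqrt(n)
        out[c] = (m - half, m + half)
    return out


def rank_codons(fold: Mapping[str, float]) -> dict[str, int]:
    """Ordinal ranks 1..64, most enriched first.

    Infinite folds rank first; NaN (undefined groups) last; ties broken by
    codon lexicographic order so the ranking is a deterministic permutation.
    """
    def key(c: str) -> tuple:
        f = fold[c]
        if math.isnan(f):
            return (2, 0.0, c)
        if math.isinf(f):
            return (0, 0.0, c)
        return (1, -f, c)

    ordered = sorted(fold, key=key)
    return {c: i + 1 for i, c in enumerate(ordered)}


def rank_sum(targets: Iterable[str], rank: Mapping[str, int]) -> int:
    """Sum of the ranks of the target codons."""
    targets = list(targets)
    if not targets:
        raise ValueError("empty target codon set")
    missing = [c for c in targets if c not in rank]
    if missing:
        raise KeyError(f"target codons not in ranking: {missing}")
    return int(sum(rank[c] for c in targets))


# ---------------------------------------------------------------------------
# rank-sum null distribution
# ---------------------------------------------------------------------------

def _distinct_sum_counts(k: int, n: int) -> np.ndarray:
    """counts[s] = number of k-subsets of {1..n} with sum s (DP)."""
    max_sum = sum(range(n - k + 1, n + 1))
    # dp[j, s]: subsets of size j with sum s using values 1..i
    dp = np.zeros((k + 1, max_sum + 1), dtype=np.int64)
    dp[0, 0] = 1
    for value in range(1, n + 1):
        for j in range(min(k, value), 0, -1):
            dp[j, value:] += dp[j - 1, :-value or None]
    return dp[k]


def _replacement_sum_counts(k: int, n: int) -> np.ndarray:
    """counts[s] = number of ordered k-tuples from {1..n} with sum s."""
    dp = np.zeros(n * k + 1, dtype=np.int64)
    dp[0] = 1
    for _ in range(k):
        new = np.zeros_like(dp)
        for value in range(1, n + 1):
            new[value:] += dp[:-value]
        dp = new
    return dp


def exact_rank_sum_p(S: int, k: int, n: int = 64,
                     mode: str = "distinct") -> float:
    """Exact one-tailed P(sum of k random ranks from 1..n <= S).

    ``distinct`` draws a k-subset (a "set of k numbers"); ``with_replacement``
    draws an ordered k-tuple. Computed by dynamic programming over rank sums.
    """
    if k > n:
        raise ValueError("k must not exceed n")
    if mode == "distinct":
        if S < k * (k + 1) // 2:
            return 0.0
        counts = _distinct_sum_counts(k, n)
        total = math.comb(n, k)
    elif mode == "with_replacement":
        if S < k:
            return 0.0
        counts = _replacement_sum_counts(k, n)
        total = n ** k
    else:
        raise ValueError(f"unknown mode {mode!r}")
    S = min(S, len(counts) - 1)
    return float(counts[: S + 1].sum() / total)


def enumerate_rank_sum_p(S: int, k: int, n: int = 64,
                         mode: str = "distinct") -> float:
    """Brute-force enumeration of the rank-sum null; independent of the DP.

    Only feasible for small k; used as a cross-check.
    """
    if mode == "distinct":
        space = itertools.combinations(range(1, n + 1), k)
        total = math.comb(n, k)
    else:
        space = itertools.product(range(1, n + 1), repeat=k)
        total = n ** k
    hits = sum(1 for combo in space if sum(combo) <= S)
    return hits / total


def permutation_rank_test(S: int, k: int, n: int = 64, reps: int = 10_000,
                          seed: int = 0, mode: str = "distinct") -> RankTestResult:
    """One-tailed Monte-Carlo rank-sum test with an exact companion p.

    p_mc = (#draws with sum <= S + 1) / (reps + 1), the add-one estimator,
    so a finite number of replicates never reports p = 0.
    """
    rng = np.random.default_rng(seed)
    if mode == "with_replacement":
        sums = rng.integers(1, n + 1, size=(reps, k)).sum(axis=1)
    elif mode == "distinct":
        draws = rng.integers(1, n + 1, size=(reps, k))
        bad = np.ones(reps, dtype=bool)
        while bad.any():
            # redraw rows containing duplicate ranks
            srt = np.sort(draws[bad], axis=1)
            dup = (np.diff(srt, axis=1) == 0).any(axis=1)
            idx = np.flatnonzero(bad)
            bad[:] = False
            bad[idx[dup]] = True
            if bad.any():
                draws[bad] = rng.integers(1, n + 1, size=(int(bad.sum()), k))
        sums = draws.sum(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    p_mc = (int((sums <= S).sum()) + 1) / (reps + 1)
    return RankTestResult(
        observed_sum=S, k=k, n=n, p_mc=p_mc,
        p_exact=exact_rank_sum_p(S, k, n, mode), reps=reps, seed=seed, mode=mode,
    )


# ---------------------------------------------------------------------------
# absolute codon influx from SGE proliferation
# ---------------------------------------------------------------------------

def absolute_codon_influx(sge_cds_by_strain: Mapping[str, Sequence[str]],
                          ) -> tuple[dict[str, dict[str, int]], dict[str, float]]:
    """Absolute codon counts introduced by SGE copies, per strain and mean.

    Input maps each strain to the coding sequences of *all* its SGE gene
    copies (every copy counts; that is the point). Returns per-strain codon
    counts and the cross-strain mean per codon.
    """
    per_strain: dict[str, dict[str, int]] = {}
    for strain, cds in sge_cds_by_strain.items():
        per_strain[strain] = count_codons(cds) if cds else {c: 0 for c in CODONS}
    strains = list(per_strain)
    mean = {c: float(np.mean([per_strain[s][c] for s in strains]))
            for c in CODONS} if strains else {}
    return per_strain, mean


__all__ = [
    "BASES", "CODONS", "CODON_TO_AA", "AA_GROUPS", "ARG_CODONS",
    "CodonUsageTable", "EnrichmentRanking", "RankTestResult",
    "count_codons", "relative_usage", "usage_from_cds", "fold_enrichment",
    "enrichment_ci", "rank_codons", "rank_sum", "exact_rank_sum_p",
    "enumerate_rank_sum_p", "permutation_rank_test", "absolute_codon_influx",
]
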