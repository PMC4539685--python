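"""Codon counting, enrichment, ranking and the rank-sum permutation test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mobilecodon.codon_stats import (
    AA_GROUPS, CODON_TO_AA, CODONS, CodonUsageTable, count_codons,
    enrichment_ci, enumerate_rank_sum_p, exact_rank_sum_p, fold_enrichment,
    permutation_rank_test, rank_codons, rank_sum, relative_usage,
)


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def test_empty_input_gives_all_zero_counts():
    counts = count_codons([])
    assert set(counts) == set(CODONS)
    assert all(v == 0 for v in counts.values())


def test_alternative_start_codon_counted_as_methionine():
    counts = count_codons(["GTGAAATAA"])
    assert counts["ATG"] == 1  # GTG start credited to the Met group
    assert counts["GTG"] == 0
    assert counts["AAA"] == 1
    assert counts["TAA"] == 1


def test_codons_with_n_skipped_and_bad_characters_rejected():
    counts = count_codons(["ATGANATAA"])
    assert sum(counts.values()) == 2  # start + stop, ANA skipped
    with pytest.raises(ValueError):
        count_codons(["ATGXXXTAA"])


def test_counts_match_brute_force_tally(rng):
    seqs = ["ATG" + "".join(rng.choice(list(CODONS), size=20)) + "TAA"
            for _ in range(5)]
    counts = count_codons(seqs, first_codon_as_met=False)
    brute = {c: 0 for c in CODONS}
    for s in seqs:
        for i in range(0, len(s), 3):
            brute[s[i:i + 3]] += 1
    assert counts == brute


# ---------------------------------------------------------------------------
# relative usage
# ---------------------------------------------------------------------------

def test_alanine_printed_frequencies():
    counts = {c: 0 for c in CODONS}
    counts.update({"GCG": 36, "GCC": 27, "GCA": 21, "GCT": 16})
    t = relative_usage(counts)
    assert t.rel["GCG"] == pytest.approx(0.36)
    assert t.rel["GCC"] == pytest.approx(0.27)
    assert t.rel["GCA"] == pytest.approx(0.21)
    assert t.rel["GCT"] == pytest.approx(0.16)


def test_single_nonzero_codon_in_group_gets_one():
    counts = {c: 0 for c in CODONS}
    counts["AGA"] = 5
    t = relative_usage(counts)
    assert t.rel["AGA"] == 1.0
    assert t.rel["CGT"] == 0.0
    assert math.isnan(t.rel["GCA"])  # alanine group has zero counts


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.dictionaries(st.sampled_from(CODONS), st.integers(0, 1000),
                       min_size=1))
def test_every_nonzero_group_sums_to_one(partial_counts):
    t = relative_usage(partial_counts)
    for aa, group in AA_GROUPS.items():
        total = sum(t.counts[c] for c in group)
        s = sum(t.rel[c] for c in group)
        if total > 0:
            assert s == pytest.approx(1.0, abs=1e-9)
        else:
            assert all(math.isnan(t.rel[c]) for c in group)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def _uniform_table(overrides=None):
    rel = {}
    for aa, group in AA_GROUPS.items():
        for c in group:
            rel[c] = 1.0 / len(group)
    if overrides:
        rel.update(overrides)
    return CodonUsageTable.from_rel(rel)


def test_subset_equal_to_genome_gives_unit_folds():
    t = _uniform_table()
    fold = fold_enrichment(t, t)
    assert all(f == pytest.approx(1.0) for f in fold.values())


def test_printed_arginine_example_full_precision():
    # AGA relative use 0.23 in the subset vs 0.03 genome-wide: the ratio at
    # printed precision is 23/3 = 7.67, not the rounded-input 7.9
    subset = _uniform_table({"AGA": 0.23, "AGG": 0.77, "CGT": 0, "CGC": 0,
                             "CGA": 0, "CGG": 0})
    genome = _uniform_table({"AGA": 0.03, "AGG": 0.97, "CGT": 0, "CGC": 0,
                             "CGA": 0, "CGG": 0})
    fold = fold_enrichment(subset, genome)
    assert fold["AGA"] == pytest.approx(0.23 / 0.03)
    assert fold["AGA"] == pytest.approx(7.667, abs=1e-3)


def test_zero_handling_flags():
    subset = _uniform_table({"AGA": 0.5, "AGG": 0.5, "CGT": 0, "CGC": 0,
                             "CGA": 0, "CGG": 0})
    genome = _uniform_table({"AGA": 0.0, "AGG": 1.0, "CGT": 0, "CGC": 0,
                             "CGA": 0, "CGG": 0})
    fold = fold_enrichment(subset, genome)
    assert math.isinf(fold["AGA"])  # subset > 0, genome 0
    assert fold["CGT"] == 1.0       # both zero


def test_ci_hand_computation_and_monotonicity():
    folds = [{c: float(v) for c in CODONS} for v in (1, 2, 3, 4, 5)]
    ci99 = enrichment_ci(folds, 0.99)
    lo, hi = ci99["AAA"]
    # mean 3 +/- t_{0.995,4} * sd/sqrt(5) = 3 +/- 4.604 * 1.5811 / sqrt(5)
    assert lo == pytest.approx(3 - 4.604 * 1.5811 / math.sqrt(5), abs=5e-3)
    assert hi == pytest.approx(3 + 4.604 * 1.5811 / math.sqrt(5), abs=5e-3)
    ci95 = enrichment_ci(folds, 0.95)
    assert ci95["AAA"][0] > lo and ci95["AAA"][1] < hi
    identical = [{c: 2.0 for c in CODONS}] * 3
    z = enrichment_ci(identical, 0.99)["AAA"]
    assert z[0] == pytest.approx(2.0) and z[1] == pytest.approx(2.0)
    with pytest.raises(ValueError):
        enrichment_ci(folds[:1])


# ---------------------------------------------------------------------------
# ranking and rank sums
# ---------------------------------------------------------------------------

def test_rank_ties_broken_lexicographically():
    fold = {c: 1.0 for c in CODONS}
    rank = rank_codons(fold)
    ordered = sorted(CODONS)
    assert [c for c, _ in sorted(rank.items(), key=lambda kv: kv[1])] == ordered


def test_rank_example_and_permutation_property(rng):
    fold = {c: 1.0 for c in CODONS}
    fold.update({"AGA": 4.1, "GGA": 3.0, "ACA": 2.5})
    rank = rank_codons(fold)
    assert rank["AGA"] == 1 and rank["GGA"] == 2 and rank["ACA"] == 3
    noisy = {c: float(v) for c, v in zip(CODONS, rng.random(64))}
    r = rank_codons(noisy)
    assert sorted(r.values()) == list(range(1, 65))
    # independent sort oracle
    expect = {c: i + 1 for i, c in enumerate(
        sorted(CODONS, key=lambda c: (-noisy[c], c)))}
    assert r == expect


def test_rank_sum_values_and_empty_rejection():
    rank = {c: i + 1 for i, c in enumerate(CODONS)}
    three = list(rank)[:3]
    assert rank_sum(three, rank) == 6
    rank2 = {"AGA": 2, "GGA": 3, "ACA": 4}
    assert rank_sum(["AGA", "GGA", "ACA"], rank2) == 9
    assert rank_sum(["A", "B", "C"], {"A": 62, "B": 63, "C": 64}) == 189
    with pytest.raises(ValueError):
        rank_sum([], rank)


# ---------------------------------------------------------------------------
# rank-sum null distribution
# ---------------------------------------------------------------------------

def test_exact_p_reference_values():
    assert exact_rank_sum_p(6, 3, 64) == pytest.approx(1 / 41664)
    assert exact_rank_sum_p(9, 3, 64) == pytest.approx(7 / 41664)
    assert exact_rank_sum_p(189, 3, 64) == 1.0


@pytest.mark.parametrize("mode", ["distinct", "with_replacement"])
@pytest.mark.parametrize("k,n", [(2, 10), (3, 12), (4, 9)])
def test_dp_agrees_with_enumeration(mode, k, n):
    for S in range(k, k * n + 1, 3):
        assert exact_rank_sum_p(S, k, n, mode) == pytest.approx(
            enumerate_rank_sum_p(S, k, n, mode))


def test_exact_p_monotone_in_sum():
    prev = 0.0
    for S in range(6, 190):
        p = exact_rank_sum_p(S, 3, 64)
        assert p >= prev
        prev = p
    assert prev == 1.0


def test_monte_carlo_determinism_and_extremes():
    a = permutation_rank_test(9, 3, 64, reps=20_000, seed=5)
    b = permutation_rank_test(9, 3, 64, reps=20_000, seed=5)
    assert a.p_mc == b.p_mc
    full = permutation_rank_test(189, 3, 64, reps=1000, seed=0)
    assert full.p_mc == 1.0  # add-one convention: (1000+1)/(1000+1)


def test_monte_carlo_converges_to_exact():
    reps = 200_000
    res = permutation_rank_test(60, 3, 64, reps=reps, seed=7)
    se = math.sqrt(res.p_exact * (1 - res.p_exact) / reps)
    assert abs(res.p_mc - res.p_exact) < 3 * se + 1 / reps
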