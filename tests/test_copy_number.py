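"""Alignment statistics, copy search, clustering, culling and contexts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mobilecodon.copy_number import (
    CopyCluster, Hit, align_stats, build_clusters, classify_context,
    count_copies, cull_redundant_sets, detect_tandem, find_copies,
    hits_from_tabular, sge_group_ttest,
)
from mobilecodon.io_core import AnnotatedGenome, GeneFeature
from mobilecodon.synthetic import mutate_sequence, plant_copies, random_dna, sample_gene, default_background_usage

BG = default_background_usage()


# ---------------------------------------------------------------------------
# align_stats
# ---------------------------------------------------------------------------

def test_self_alignment_is_perfect(rng):
    q = random_dna(120, rng)
    st_ = align_stats(q, q)
    assert st_.identity == 1.0 and st_.coverage == 1.0


def test_truncated_subject_halves_coverage(rng):
    q = random_dna(100, rng)
    st_ = align_stats(q, q[:50])
    assert st_.coverage == pytest.approx(0.5)
    assert st_.identity == 1.0


def test_three_substitutions_on_77bp(rng):
    q = random_dna(77, rng)
    m = mutate_sequence(q, 4.0, rng)  # round(0.04*77) = 3 substitutions
    st_ = align_stats(m, q)
    assert st_.identity == pytest.approx(74 / 77)


@settings(max_examples=15, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_identity_symmetric_for_equal_length(seed):
    r = np.random.default_rng(seed)
    a = random_dna(60, r)
    b = mutate_sequence(a, float(r.integers(0, 10)), r)
    assert align_stats(a, b).identity == pytest.approx(
        align_stats(b, a).identity)


# ---------------------------------------------------------------------------
# find_copies
# ---------------------------------------------------------------------------

def _backbone(rng, n=40):
    parts, feats, pos = [], [], 0
    for i in range(n):
        sp = random_dna(200, rng)
        gene = sample_gene(80, BG, rng)
        parts += [sp, gene]
        pos += len(sp)
        feats.append(GeneFeature(f"h{i}", pos, pos + len(gene), "+", "host"))
        pos += len(gene)
    parts.append(random_dna(200, rng))
    return AnnotatedGenome("b", "".join(parts), feats)


def test_three_identical_copies_found(rng):
    g = _backbone(rng)
    element = sample_gene(100, BG, rng)
    g, _ = plant_copies(g, element, 3, "host_flanked", 0.0, rng,
                        category="sge", id_prefix="e")
    hits = find_copies(element, g)
    assert len(hits) == 3
    assert all(h.identity == 1.0 and h.coverage == 1.0 for h in hits)


def test_six_percent_divergence_excluded_four_percent_found(rng):
    g = _backbone(rng)
    element = sample_gene(100, BG, rng)
    g, _ = plant_copies(g, element, 2, "host_flanked", 6.0, rng,
                        category="sge", id_prefix="far")
    assert find_copies(element, g) == []
    g2, _ = plant_copies(g, element, 2, "host_flanked", 4.0, rng,
                         category="sge", id_prefix="near")
    hits = find_copies(element, g2)
    assert len(hits) == 2
    assert all(h.identity == pytest.approx(0.96, abs=0.001) for h in hits)


def test_reverse_strand_copy_found_with_minus_strand(rng):
    g = _backbone(rng)
    element = sample_gene(100, BG, rng)
    comp = str.maketrans("ACGT", "TGCA")
    rc = element.translate(comp)[::-1]
    seq = g.sequence[:4000] + rc + g.sequence[4000:]
    g2 = AnnotatedGenome("b", seq, [])
    hits = find_copies(element, g2)
    assert len(hits) == 1
    assert hits[0].strand == "-"
    assert hits[0].start == 4000 and hits[0].end == 4000 + len(element)


def test_tandem_copies_in_one_window_all_found(rng):
    g = _backbone(rng)
    element = random_dna(77, rng)
    g, ids = plant_copies(g, element, 3, "tandem", 0.0, rng, id_prefix="gly")
    hits = find_copies(element, g)
    assert len(hits) == 3


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def test_identical_paralogs_form_one_cluster(rng):
    e = sample_gene(100, BG, rng)
    clusters = build_clusters({f"g{i}": e for i in range(4)})
    assert len(clusters) == 1
    assert len(clusters[0].members) == 4


def test_single_linkage_chains_through_intermediate(rng):
    a = sample_gene(200, BG, rng)
    b = mutate_sequence(a, 4.0, rng)       # a~b 96%
    c = mutate_sequence(b, 4.0, rng)       # b~c 96%, a~c ~92%
    assert align_stats(a, c).identity < 0.95
    clusters = build_clusters({"A": a, "B": b, "C": c})
    assert len(clusters) == 1 and clusters[0].members == ["A", "B", "C"]


def test_distinct_families_stay_separate(rng):
    a = sample_gene(100, BG, rng)
    b = mutate_sequence(a, 20.0, rng)  # ~80% identity
    clusters = build_clusters({"A": a, "B": b})
    assert len(clusters) == 2


def test_union_counting_over_members(rng):
    g = _backbone(rng)
    a = sample_gene(100, BG, rng)
    b = mutate_sequence(a, 4.0, rng)
    g, _ = plant_copies(g, a, 1, "host_flanked", 0.0, rng, category="sge",
                        id_prefix="a")
    g, _ = plant_copies(g, b, 1, "host_flanked", 0.0, rng, category="sge",
                        id_prefix="b")
    clusters = build_clusters({"A": a, "B": b})
    assert len(clusters) == 1
    count_copies(clusters, {"A": a, "B": b}, {"g": g})
    assert clusters[0].copy_count == {"g": 2}


# ---------------------------------------------------------------------------
# culling
# ---------------------------------------------------------------------------

def _cluster(cid, members, hits):
    c = CopyCluster(cid, members)
    c.hits = hits
    return c


def test_cull_keeps_disjoint_clusters_and_is_idempotent():
    c1 = _cluster("a", ["a"], {"s": [Hit(0, 100, "+", 1, 1, 100)]})
    c2 = _cluster("b", ["b"], {"s": [Hit(5000, 5100, "+", 1, 1, 100)]})
    out = cull_redundant_sets([c1, c2])
    assert [c.cluster_id for c in out] == ["a", "b"]
    assert [c.cluster_id for c in cull_redundant_sets(out)] == ["a", "b"]


def test_cull_drops_duplicate_set_over_same_loci():
    shared = [Hit(0, 100, "+", 1, 1, 100), Hit(900, 1000, "+", 1, 1, 100)]
    big = _cluster("is1", ["is1", "is1b"], {"s": shared})
    dup = _cluster("is1_shadow", ["is1_shadow"],
                   {"s": [Hit(2, 98, "+", 0.96, 1, 88),
                          Hit(903, 998, "+", 0.96, 1, 88)]})
    out = cull_redundant_sets([big, dup])
    assert [c.cluster_id for c in out] == ["is1"]  # fewer members culled
    tie1 = _cluster("x", ["x"], {"s": shared})
    tie2 = _cluster("y", ["y"], {"s": [Hit(1, 99, "+", 1, 1, 99),
                                       Hit(901, 999, "+", 1, 1, 99)]})
    out2 = cull_redundant_sets([tie1, tie2])
    assert [c.cluster_id for c in out2] == ["x"]  # tie: later id culled


# ---------------------------------------------------------------------------
# contexts
# ---------------------------------------------------------------------------

def test_detect_tandem_runs():
    loci = [(0, 77, "+"), (277, 354, "+"), (554, 631, "+")]
    assert detect_tandem(loci) == [True, True, True]
    far = [(0, 77, "+"), (100_000, 100_077, "+")]
    assert detect_tandem(far) == [False, False]
    opposite = [(0, 77, "+"), (200, 277, "-")]
    assert detect_tandem(opposite) == [False, False]


def test_classify_contexts_on_planted_genome(rng):
    g = _backbone(rng)
    element = random_dna(77, rng)
    g, orig = plant_copies(g, element, 1, "host_flanked", 0.0, rng,
                           id_prefix="orig", anticodon="TCT")
    g, extra = plant_copies(g, element, 3, "phage_flanked", 4.0, rng,
                            id_prefix="lgt", anticodon="TCT")
    g, arr = plant_copies(g, element, 3, "tandem", 0.0, rng,
                          id_prefix="arr", anticodon="TCT")
    feats = {f.gene_id: f for f in g.features if f.anticodon == "TCT"}
    loci = [(f.start, f.end, f.strand) for f in feats.values()]
    calls = {}
    for gid, f in feats.items():
        call = classify_context(g, (f.start, f.end), loci,
                                locus_strand=f.strand, original_seq=element)
        calls[gid] = call
    assert calls[orig[0]].call == "host_flanked"
    assert calls[orig[0]].identity_to_original == 1.0
    for gid in extra:
        assert calls[gid].call == "phage_flanked"
        assert calls[gid].identity_to_original == pytest.approx(74 / 77)
    for gid in arr:
        assert calls[gid].call == "tandem_array"


# ---------------------------------------------------------------------------
# group t test
# ---------------------------------------------------------------------------

def test_welch_identical_groups_give_p_one():
    assert sge_group_ttest([5, 5, 5], [5, 5, 5]) == (0.0, 1.0)


def test_welch_separated_groups_and_symmetry():
    t, p = sge_group_ttest([440, 441, 439], [10, 11, 9])
    assert p < 1e-4
    t2, p2 = sge_group_ttest([10, 11, 9], [440, 441, 439])
    assert p2 == pytest.approx(p)
    assert t2 == pytest.approx(-t)


# ---------------------------------------------------------------------------
# external tabular adapter
# ---------------------------------------------------------------------------

def test_tabular_hits_adapter(tmp_path):
    tsv = tmp_path / "hits.tsv"
    tsv.write_text(
        "q1\tchr\t100.0\t100\t0\t0\t1\t100\t201\t300\t1e-50\t185\n"
        "q1\tchr\t96.0\t100\t4\t0\t1\t100\t900\t801\t1e-40\t160\n"
        "q1\tchr\t90.0\t100\t10\t0\t1\t100\t2000\t2099\t1e-20\t120\n"
        "q2\tchr\t99.0\t40\t0\t0\t1\t40\t50\t89\t1e-10\t70\n")
    hits = hits_from_tabular(tsv, {"q1": 100, "q2": 100})
    assert [(h.start, h.end, h.strand) for h in hits["q1"]] == \
           [(200, 300, "+"), (800, 900, "-")]  # 90% identity filtered
    assert "q2" not in hits  # coverage 0.4 fails
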