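"""The synthetic strain-set generator and its ground truth."""

import json
import math

import numpy as np
import pytest

from mobilecodon.codon_stats import AA_GROUPS, count_codons
from mobilecodon.io_core import AnnotatedGenome, GeneFeature
from mobilecodon.synthetic import (
    LgtGain, PlacementError, SgeFamily, SimulationConfig, TrnaPlant,
    bias_usage, default_background_usage, default_config, mutate_sequence,
    plant_copies, quota_gene, sample_gene, simulate_strains,
)

BG = default_background_usage()


# ---------------------------------------------------------------------------
# gene sampling
# ---------------------------------------------------------------------------

def test_minimal_gene_is_start_plus_stop(rng):
    g = sample_gene(2, BG, rng)
    assert g.startswith("ATG") and len(g) == 6
    assert g[3:] in AA_GROUPS["*"]
    with pytest.raises(ValueError):
        sample_gene(1, BG, rng)


def test_sampled_genes_reproduce_alanine_profile(rng):
    # law of large numbers: the GCG share of alanine codons approaches the
    # background profile's 0.36
    counts = count_codons([sample_gene(300, BG, rng) for _ in range(2000)],
                          first_codon_as_met=False)
    ala = {c: counts[c] for c in ("GCG", "GCC", "GCA", "GCT")}
    share = ala["GCG"] / sum(ala.values())
    assert share == pytest.approx(0.36, abs=0.01)


def test_fixed_seed_gives_identical_bytes():
    a = sample_gene(50, BG, np.random.default_rng(99))
    b = sample_gene(50, BG, np.random.default_rng(99))
    assert a == b


def test_quota_gene_composition_is_deterministic(rng):
    biased = bias_usage(BG, {"AGA": 5.0})
    g = quota_gene(3002, biased, rng)
    counts = count_codons([g], first_codon_as_met=False)
    arg = {c: counts[c] for c in AA_GROUPS["R"]}
    # AGA holds half the arginine group (5 / (5 + 5)), realized exactly
    # up to rounding of the expected counts
    assert arg["AGA"] / sum(arg.values()) == pytest.approx(0.5, abs=0.01)


# ---------------------------------------------------------------------------
# usage biasing
# ---------------------------------------------------------------------------

def test_bias_identity_and_renormalization():
    same = bias_usage(BG, {c: 1.0 for c in ("AGA", "GCA")})
    assert all(
        (math.isnan(same.rel[c]) and math.isnan(BG.rel[c]))
        or same.rel[c] == pytest.approx(BG.rel[c]) for c in same.rel)
    t = bias_usage(BG, {"GCA": 4.0})
    # hand renormalization: (0.36, 0.27, 0.84, 0.16) / 1.63
    total = 0.36 + 0.27 + 0.84 + 0.16
    assert t.rel["GCG"] == pytest.approx(0.36 / total, abs=1e-9)
    assert t.rel["GCC"] == pytest.approx(0.27 / total, abs=1e-9)
    assert t.rel["GCA"] == pytest.approx(0.84 / total, abs=1e-9)
    assert t.rel["GCT"] == pytest.approx(0.16 / total, abs=1e-9)


def test_single_codon_amino_acid_stays_one_and_zero_stays_zero():
    t = bias_usage(BG, {"ATG": 7.0})
    assert t.rel["ATG"] == 1.0
    from mobilecodon.codon_stats import CodonUsageTable
    base = CodonUsageTable.from_rel(
        {**{c: BG.rel[c] for c in BG.rel}, "AGA": 0.0, "AGG": 1 / 3})
    t2 = bias_usage(base, {"AGA": 10.0})
    assert t2.rel["AGA"] == 0.0
    with pytest.raises(ValueError):
        bias_usage(BG, {"AGA": 0.0})


# ---------------------------------------------------------------------------
# mutation model
# ---------------------------------------------------------------------------

def test_mutation_count_is_exact(rng):
    seq = sample_gene(300, BG, rng)
    m = mutate_sequence(seq, 4.0, rng)
    diffs = sum(a != b for a, b in zip(seq, m))
    assert diffs == round(0.04 * len(seq))
    assert mutate_sequence(seq, 0.0, rng) == seq
    with pytest.raises(ValueError):
        mutate_sequence(seq, 60.0, rng)


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------

def _host_backbone(rng, n_genes=30):
    parts, feats, pos = [], [], 0
    for i in range(n_genes):
        spacer = "".join(rng.choice(list("ACGT"), size=200))
        gene = sample_gene(60, BG, rng)
        parts += [spacer, gene]
        pos += len(spacer)
        feats.append(GeneFeature(f"h{i}", pos, pos + len(gene), "+", "host"))
        pos += len(gene)
    parts.append("".join(rng.choice(list("ACGT"), size=200)))
    return AnnotatedGenome("t", "".join(parts), feats)


def test_tandem_plant_three_identical_copies(rng):
    g = _host_backbone(rng)
    element = "".join(rng.choice(list("ACGT"), size=77))
    g2, ids = plant_copies(g, element, 3, "tandem", 0.0, rng, id_prefix="gly")
    feats = [f for f in g2.features if f.gene_id in ids]
    assert len(feats) == 3
    assert len({f.strand for f in feats}) == 1
    assert feats[-1].end - feats[0].start < 5000
    for f in feats:
        assert g2.feature_seq(f) == element  # 100% pairwise identity


def test_phage_flanked_copies_with_divergence(rng):
    g = _host_backbone(rng)
    element = "".join(rng.choice(list("ACGT"), size=77))
    g2, ids = plant_copies(g, element, 7, "phage_flanked", 4.0, rng,
                           id_prefix="arg", anticodon="TCT")
    idents = []
    by_id = {f.gene_id: f for f in g2.features}
    for gid in ids:
        f = by_id[gid]
        seq = g2.feature_seq(f)
        matches = sum(a == b for a, b in zip(seq, element))
        idents.append(matches / len(element))
        i = g2.features.index(f)
        assert g2.features[i - 1].category == "phage"
        assert g2.features[i + 1].category == "phage"
    assert np.mean(idents) == pytest.approx(0.96, abs=0.02)


def test_host_flanked_copy_neighbors_are_host(rng):
    g = _host_backbone(rng)
    element = "".join(rng.choice(list("ACGT"), size=77))
    g2, ids = plant_copies(g, element, 1, "host_flanked", 0.0, rng)
    f = next(f for f in g2.features if f.gene_id == ids[0])
    i = g2.features.index(f)
    assert g2.features[i - 1].category == "host"
    assert g2.features[i + 1].category == "host"


def test_plant_into_too_small_genome_raises(rng):
    g = AnnotatedGenome("s", "ACGT" * 5, [])
    with pytest.raises(PlacementError):
        plant_copies(g, "ACGTACGTACGT" * 20, 1, "host_flanked", 0.0, rng)


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------

def _mini_config(seed, **overrides):
    cfg = SimulationConfig(
        seed=seed,
        tree_newick="((A:1,B:1)AB:1,(C:1,D:1)CD:1)ROOT;",
        n_host_genes=120,
        gene_length_codons=(80.0, 10.0),
        sge_families=[SgeFamily("FAM", {"A": 5, "B": 5, "C": 1, "D": 1},
                                {"AGA": 4.0})],
        trna_plants=[TrnaPlant("TCT", {"A": 1, "B": 1, "C": 1, "D": 1},
                               "host_flanked", 0.0, tag="orig")],
        lgt_gains=[LgtGain("ROOT", 3, {"AGA": 2.0}, length_codons=60),
                   LgtGain("AB", 2, {"AGA": 4.0}, length_codons=60)],
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def test_root_gain_present_in_all_tips_and_cherry_recovered(tmp_path):
    genomes, truth = simulate_strains(_mini_config(5), out_dir=tmp_path)
    for gid, node in truth.lgt_nodes.items():
        tips_with = {s for s in genomes
                     if any(f.gene_id == gid for f in genomes[s].features)}
        if node == "ROOT":
            assert tips_with == set(genomes)
        elif node == "AB":
            assert tips_with == {"A", "B"}
    presence = (tmp_path / "presence.tsv").read_text().splitlines()
    header = presence[0].split("\t")[1:]
    for line in presence[1:]:
        gid, *vals = line.split("\t")
        tips = {s for s, v in zip(header, vals) if v == "1"}
        assert tips == ({"A", "B"} if truth.lgt_nodes[gid] == "AB"
                        else set(header))


def test_fixed_seed_reproduces_truth_and_sequences(tmp_path):
    g1, t1 = simulate_strains(_mini_config(9), out_dir=tmp_path / "r1")
    g2, t2 = simulate_strains(_mini_config(9), out_dir=tmp_path / "r2")
    assert (tmp_path / "r1" / "truth.json").read_text() == \
           (tmp_path / "r2" / "truth.json").read_text()
    for s in g1:
        assert g1[s].sequence == g2[s].sequence


def test_unknown_gain_node_rejected():
    cfg = _mini_config(1)
    cfg.lgt_gains.append(LgtGain("NOPE", 1, {}))
    with pytest.raises(ValueError, match="NOPE"):
        simulate_strains(cfg)


def test_truth_audit_matches_annotations_and_bias_direction(tmp_path):
    genomes, truth = simulate_strains(_mini_config(3))
    # self-audit already ran inside simulate_strains; recheck one invariant
    for s, g in genomes.items():
        n_trna = len(g.features_of("trna"))
        assert n_trna == sum(per.get(s, 0) for per in truth.trna_counts.values())
    # realized SGE codon usage leans toward the planted AGA bias
    counts = truth.sge_codon_counts["A"]["FAM"]
    arg = {c: counts[c] for c in AA_GROUPS["R"]}
    assert arg["AGA"] / sum(arg.values()) > 1 / 6 * 2


def test_default_config_matches_declared_conditions():
    cfg = default_config(seed=1)
    assert cfg.n_host_genes == 2000
    fam_sizes = [max(f.copies_per_strain.values()) for f in cfg.sge_families]
    assert all(30 <= n <= 150 for n in fam_sizes)
    assert sorted(f.divergence_pct for f in cfg.sge_families) == [0.0, 2.0, 4.0]
    assert any(f.decoy_copies_per_strain for f in cfg.sge_families)
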