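"""Synthetic annotated strain sets with machine-readable ground truth.

The generator emulates the genome features that drive the analysis of
codon-use/tRNA coevolution in an *E. coli*-like strain complex:

* a host gene complement with a fixed background codon-usage profile,
  inherited verbatim by every strain (so cross-strain similarity search at
  95% identity is meaningful);
* selfish-genetic-element (SGE) families present in tens-to-hundreds of
  near-identical copies per strain in a designated pathogen-like group, with
  codon usage multiplicatively shifted toward chosen codons;
* tRNA genes planted in controlled genomic contexts — tandem arrays,
  phage-flanked insertions, or host-flanked originals — with controlled
  sequence divergence;
* laterally transferred (LGT) gene sets gained at named internal nodes of
  the strain tree and present in exactly the descendant tips.

Divergence is modelled as an exact count of ``round(pct/100 * L)`` distinct
substituted positions (no indels), so identity against the original copy is
deterministic: a 4%-diverged copy always passes a >95% identity cutoff and a
6%-diverged copy always fails it.

Every generated strain set comes with a :class:`TruthSet` recording planted
copy numbers, contexts, per-gene categories, LGT gain nodes and realized
codon counts; the generator self-audits the emitted annotations against it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .codon_stats import AA_GROUPS, CODONS, ARG_CODONS, CodonUsageTable, count_codons
from .io_core import AnnotatedGenome, GeneFeature, StrainTree, write_genome, write_table

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class PlacementError(ValueError):
    """The genome has no room for the requested insertion."""


# ---------------------------------------------------------------------------
# background usage and biasing
# ---------------------------------------------------------------------------

def default_background_usage() -> CodonUsageTable:
    """Background per-amino-acid codon profile.

    Alanine uses the canonical *E. coli* profile GCG 0.36, GCC 0.27,
    GCA 0.21, GCT 0.16; every other amino-acid group (and the stop group)
    is uniform.
    """
    rel = {}
    ala = {"GCG": 0.36, "GCC": 0.27, "GCA": 0.21, "GCT": 0.16}
    for aa, group in AA_GROUPS.items():
        for c in group:
            rel[c] = ala[c] if c in ala else 1.0 / len(group)
    return CodonUsageTable.from_rel(rel)


def usage_from_yaml(path: str | Path) -> CodonUsageTable:
    """Load a per-amino-acid relative usage table from a flat YAML mapping."""
    rel = yaml.safe_load(Path(path).read_text())
    return CodonUsageTable.from_rel({c: float(rel.get(c, 0.0)) for c in CODONS})


def usage_to_yaml(table: CodonUsageTable, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(
        {c: float(table.rel[c]) for c in CODONS
         if not math.isnan(table.rel[c])}, sort_keys=True))


def bias_usage(base: CodonUsageTable,
               bias: Mapping[str, float]) -> CodonUsageTable:
    """Multiply chosen codons' frequencies and renormalize each group to 1.

    Multipliers must be positive; codons absent from ``bias`` keep
    multiplier 1. A zero-frequency codon stays zero whatever its
    multiplier, and a single-codon amino acid (ATG, TGG) stays at 1.0.
    """
    for c, m in bias.items():
        if m <= 0:
            raise ValueError(f"multiplier for {c} must be > 0")
        if c not in CODONS:
            raise KeyError(f"unknown codon {c!r}")
    new_rel = {}
    for c in CODONS:
        v = base.rel[c]
        v = 0.0 if math.isnan(v) else v
        new_rel[c] = v * bias.get(c, 1.0)
    return CodonUsageTable.from_rel(new_rel)


# ---------------------------------------------------------------------------
# sequence sampling and mutation
# ---------------------------------------------------------------------------

def _sample_codons(n: int, usage: CodonUsageTable,
                   rng: np.random.Generator) -> list[str]:
    """Draw n sense codons: uniform amino acid, then codon per usage."""
    aa_list = [aa for aa in sorted(AA_GROUPS) if aa != "*"
               and not math.isnan(usage.rel[AA_GROUPS[aa][0]])]
    out = np.empty(n, dtype="<U3")
    aa_idx = rng.integers(0, len(aa_list), size=n)
    for i, aa in enumerate(aa_list):
        pos = np.flatnonzero(aa_idx == i)
        if pos.size == 0:
            continue
        group = AA_GROUPS[aa]
        p = np.array([usage.rel[c] for c in group], dtype=float)
        out[pos] = rng.choice(group, size=pos.size, p=p / p.sum())
    return out.tolist()


def sample_gene(length_codons: int, usage: CodonUsageTable,
                rng: np.random.Generator) -> str:
    """Sample a coding sequence of ``length_codons`` total codons.

    Starts with ATG and ends with one stop codon drawn from the stop
    group's relative frequencies; the ``length_codons - 2`` internal codons
    come from a uniform amino-acid draw followed by a within-group draw at
    the table's relative frequencies.
    """
    if length_codons < 2:
        raise ValueError("a gene needs at least a start and a stop codon")
    stops = AA_GROUPS["*"]
    p = np.array([usage.rel[c] for c in stops], dtype=float)
    if np.isnan(p).any():
        p = np.ones(len(stops))
    stop = rng.choice(stops, p=p / p.sum())
    internal = _sample_codons(length_codons - 2, usage, rng)
    return "ATG" + "".join(internal) + stop


def quota_gene(length_codons: int, usage: CodonUsageTable,
               rng: np.random.Generator) -> str:
    """A coding sequence whose codon composition matches ``usage`` exactly.

    Internal codon counts are the expected counts of a uniform amino-acid
    draw times the within-group frequencies, rounded by largest remainder;
    only the codon *order* is random. Used for planted element families so
    that the planted codon bias is the realized composition, not one noisy
    multinomial draw.
    """
    if length_codons < 2:
        raise ValueError("a gene needs at least a start and a stop codon")
    n = length_codons - 2
    aa_list = [aa for aa in sorted(AA_GROUPS) if aa != "*"
               and not math.isnan(usage.rel[AA_GROUPS[aa][0]])]
    codons = [c for aa in aa_list for c in AA_GROUPS[aa]]
    w = np.array([usage.rel[c] / len(aa_list) for c in codons])
    ideal = w / w.sum() * n
    counts = np.floor(ideal).astype(int)
    rem = n - counts.sum()
    counts[np.argsort(ideal - np.floor(ideal))[::-1][:rem]] += 1
    body = np.repeat(codons, counts)
    rng.shuffle(body)
    stops = AA_GROUPS["*"]
    p = np.array([usage.rel[c] for c in stops], dtype=float)
    if np.isnan(p).any():
        p = np.ones(len(stops))
    stop = rng.choice(stops, p=p / p.sum())
    return "ATG" + "".join(body) + stop


def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def mutate_sequence(seq: str, divergence_pct: float,
                    rng: np.random.Generator) -> str:
    """Substitute exactly round(pct/100 * L) distinct positions.

    No indels; each chosen site gets a uniformly random *different* base,
    so identity to the original is exactly ``1 - round(pct*L/100)/L``.
    """
    if not 0 <= divergence_pct <= 50:
        raise ValueError("divergence_pct must be in [0, 50]")
    m = round(divergence_pct / 100 * len(seq))
    if m == 0:
        return seq
    pos = rng.choice(len(seq), size=m, replace=False)
    chars = list(seq)
    for i in pos:
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


# ---------------------------------------------------------------------------
# planting copies into an existing genome
# ---------------------------------------------------------------------------

def _intergenic_gaps(genome: AnnotatedGenome, min_len: int,
                     require_host: bool) -> list[tuple[int, int]]:
    gaps = []
    prev_end, prev_cat = 0, None
    for f in genome.features + [None]:
        start = len(genome.sequence) if f is None else f.start
        cat = None if f is None else f.category
        if start - prev_end >= min_len:
            if not require_host or (prev_cat == "host" and cat == "host"):
                gaps.append((prev_end, start))
        if f is not None:
            prev_end, prev_cat = max(prev_end, f.end), f.category
    return gaps


def _insert_block(genome: AnnotatedGenome, pos: int, seq: str,
                  feats: list[GeneFeature]) -> AnnotatedGenome:
    """Splice ``seq`` (carrying block-relative ``feats``) in at ``pos``."""
    new_seq = genome.sequence[:pos] + seq + genome.sequence[pos:]
    shifted = [
        GeneFeature(f.gene_id, f.start + len(seq) if f.start >= pos else f.start,
                    f.end + len(seq) if f.start >= pos else f.end,
                    f.strand, f.category, f.product, f.anticodon)
        for f in genome.features
    ]
    placed = [GeneFeature(f.gene_id, f.start + pos, f.end + pos, f.strand,
                          f.category, f.product, f.anticodon) for f in feats]
    return AnnotatedGenome(genome.strain_id, new_seq, shifted + placed,
                           genome.circular)


def plant_copies(genome: AnnotatedGenome, element: str, n: int, context: str,
                 divergence_pct: float, rng: np.random.Generator,
                 category: str = "trna", anticodon: str | None = None,
                 id_prefix: str = "planted",
                 tandem_spacer: int = 50) -> tuple[AnnotatedGenome, list[str]]:
    """Plant ``n`` copies of ``element`` into a genome in a chosen context.

    ``tandem``: all copies consecutive on the same strand within 5 kb, with
    0% divergence (tandem arrays are recent within-genome duplications).
    ``phage_flanked``: each copy at a random intergenic locus with a phage
    gene immediately on both sides, mutated at ``divergence_pct``.
    ``host_flanked``: each copy alone between two host genes.

    Returns the new genome and the planted gene ids.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if context not in ("tandem", "phage_flanked", "host_flanked"):
        raise ValueError(f"unknown context {context!r}")
    usage = default_background_usage()
    ids: list[str] = []

    def copy_seq() -> str:
        return element if context == "tandem" else mutate_sequence(
            element, divergence_pct, rng)

    blocks: list[tuple[str, list[GeneFeature]]] = []
    if context == "tandem":
        strand = "+" if rng.random() < 0.5 else "-"
        seq_parts, feats, off = [], [], 0
        for i in range(n):
            gid = f"{id_prefix}_t{i}"
            genomic = element if strand == "+" else _revcomp(element)
            feats.append(GeneFeature(gid, off, off + len(element), strand,
                                     category, anticodon=anticodon))
            seq_parts.append(genomic)
            off += len(element)
            if i < n - 1:
                sp = random_dna(tandem_spacer, rng)
                seq_parts.append(sp)
                off += len(sp)
            ids.append(gid)
        if off >= 5000:
            raise PlacementError("tandem array would span >= 5 kb")
        blocks.append(("".join(seq_parts), feats))
    else:
        for i in range(n):
            gid = f"{id_prefix}_p{i}"
            strand = "+" if rng.random() < 0.5 else "-"
            copy = copy_seq()
            genomic = copy if strand == "+" else _revcomp(copy)
            if context == "phage_flanked":
                left = sample_gene(100, usage, rng)
                right = sample_gene(100, usage, rng)
                gap1, gap2 = random_dna(30, rng), random_dna(30, rng)
                seq = left + gap1 + genomic + gap2 + right
                feats = [
                    GeneFeature(f"{gid}_phL", 0, len(left), "+", "phage"),
                    GeneFeature(gid, len(left) + 30, len(left) + 30 + len(copy),
                                strand, category, anticodon=anticodon),
                    GeneFeature(f"{gid}_phR", len(seq) - len(right), len(seq),
                                "+", "phage"),
                ]
            else:
                seq, feats = genomic, [
                    GeneFeature(gid, 0, len(copy), strand, category,
                                anticodon=anticodon)]
            ids.append(gid)
            blocks.append((seq, feats))

    for seq, feats in blocks:
        gaps = _intergenic_gaps(genome, min_len=60,
                                require_host=(context == "host_flanked"))
        if not gaps:
            raise PlacementError(
                f"no intergenic gap available for {context} insertion")
        g0, g1 = gaps[rng.integers(0, len(gaps))]
        pos = (g0 + g1) // 2
        genome = _insert_block(genome, pos, seq, feats)
    return genome, ids


# ---------------------------------------------------------------------------
# simulation configuration
# ---------------------------------------------------------------------------

@dataclass
class SgeFamily:
    """One selfish-element family: a single gene planted in many copies.

    Each strain with >= 1 copies receives copy 0 verbatim (the family
    original) and the rest mutated at ``divergence_pct``. ``decoy_copies``
    are additional copies at ``decoy_divergence_pct`` (default 6%), designed
    to fall below a >95% identity cutoff.
    """

    family_id: str
    copies_per_strain: dict[str, int]
    codon_bias: dict[str, float]
    divergence_pct: float = 0.0
    length_codons: int = 300
    decoy_copies_per_strain: dict[str, int] = field(default_factory=dict)
    decoy_divergence_pct: float = 6.0


@dataclass
class TrnaPlant:
    """tRNA copies of one anticodon planted in one genomic context."""

    anticodon: str
    copies_per_strain: dict[str, int]
    context: str  # tandem | phage_flanked | host_flanked
    divergence_pct: float = 0.0
    tag: str = "x"


@dataclass
class LgtGain:
    """A set of genes gained on the branch above ``node_id``."""

    node_id: str
    n_genes: int
    codon_bias: dict[str, float]
    length_codons: int = 300


@dataclass
class SimulationConfig:
    seed: int
    tree_newick: str
    n_host_genes: int = 2000
    gene_length_codons: tuple[float, float] = (300.0, 80.0)  # mean, sd
    min_gene_codons: int = 60
    spacer_bp: tuple[int, int] = (150, 250)
    trna_length_bp: int = 77
    background_usage: CodonUsageTable | None = None
    sge_families: list[SgeFamily] = field(default_factory=list)
    trna_plants: list[TrnaPlant] = field(default_factory=list)
    lgt_gains: list[LgtGain] = field(default_factory=list)

    def validate(self, tree: StrainTree) -> None:
        tips = set(tree.tips)
        node_labels = tips | {
            (nd.taxon.label if nd.taxon else nd.label)
            for nd in tree.tree.preorder_node_iter()
            if nd.taxon or nd.label}
        for fam in self.sge_families:
            for c, m in fam.codon_bias.items():
                if m <= 0:
                    raise ValueError(f"{fam.family_id}: multiplier {c} <= 0")
            if not 0 <= fam.divergence_pct <= 50:
                raise ValueError(f"{fam.family_id}: divergence out of range")
            if any(v < 0 for v in fam.copies_per_strain.values()):
                raise ValueError(f"{fam.family_id}: negative copy count")
            if set(fam.copies_per_strain) - tips:
                raise ValueError(f"{fam.family_id}: unknown strains")
        for plant in self.trna_plants:
            if plant.context not in ("tandem", "phage_flanked", "host_flanked"):
                raise ValueError(f"unknown context {plant.context!r}")
            if set(plant.copies_per_strain) - tips:
                raise ValueError(f"tRNA plant {plant.anticodon}: unknown strains")
        for gain in self.lgt_gains:
            if gain.node_id not in node_labels:
                raise ValueError(f"LGT gain node {gain.node_id!r} not in tree")


@dataclass
class TruthSet:
    """Ground truth emitted alongside a simulated strain set."""

    strains: list[str]
    reference: str
    sge_counts: dict  # family -> strain -> {"planted": n, "decoy": n}
    trna_counts: dict  # anticodon -> strain -> total copies
    trna_contexts: dict  # strain -> gene_id -> context
    trna_identity: dict  # strain -> gene_id -> identity to original
    gene_categories: dict  # strain -> gene_id -> category
    lgt_nodes: dict  # gene_id -> node_id
    node_genes: dict  # node_id -> [gene_id]
    sge_codon_counts: dict  # strain -> family -> codon -> count (planted only)
    lgt_node_arg: dict  # node_id -> {"aga": n, "arg": n}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        return cls(**json.loads(Path(path).read_text()))

    def audit(self, genomes: Mapping[str, AnnotatedGenome]) -> None:
        """Recount features in the emitted annotations against the truth."""
        for strain in self.strains:
            g = genomes[strain]
            cats = {f.gene_id: f.category for f in g.features}
            if cats != self.gene_categories[strain]:
                raise AssertionError(f"{strain}: feature/category mismatch")
            ac_counts: dict[str, int] = {}
            for f in g.features_of("trna"):
                ac_counts[f.anticodon] = ac_counts.get(f.anticodon, 0) + 1
            expect = {ac: per[strain] for ac, per in self.trna_counts.items()
                      if per.get(strain, 0) > 0}
            if ac_counts != expect:
                raise AssertionError(f"{strain}: anticodon count mismatch")
        for fam, per in self.sge_counts.items():
            for strain, nums in per.items():
                planted = sum(
                    1 for f in genomes[strain].features_of("sge")
                    if f.gene_id.startswith(f"{fam}_{strain}_c"))
                if planted != nums["planted"]:
                    raise AssertionError(f"{strain}/{fam}: planted count mismatch")


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

def _descendant_tips(tree: StrainTree, node_id: str) -> set[str]:
    for nd in tree.tree.preorder_node_iter():
        label = nd.taxon.label if nd.taxon else nd.label
        if label == node_id:
            return {lf.taxon.label for lf in nd.leaf_iter()}
    raise ValueError(f"node {node_id!r} not found in tree")


def simulate_strains(config: SimulationConfig,
                     out_dir: str | Path | None = None,
                     reference: str | None = None,
                     ) -> tuple[dict[str, AnnotatedGenome], TruthSet]:
    """Generate the annotated strain set described by ``config``.

    Host genes are sampled once at the root and inherited verbatim by every
    tip; SGE/tRNA/LGT insertions are placed into distinct host-intergenic
    slots per strain (genomes are assembled in one pass from a segment
    layout). When ``out_dir`` is given, per-strain FASTA+GFF3, the tree, an
    LGT presence/absence TSV and ``truth.json`` are written there.
    """
    rng = np.random.default_rng(config.seed)
    tree = StrainTree.from_newick(config.tree_newick)
    config.validate(tree)
    strains = sorted(tree.tips)
    reference = reference or strains[0]
    bg = config.background_usage or default_background_usage()

    # --- shared material (generated once, before any per-strain draws) ---
    mean_len, sd_len = config.gene_length_codons
    lengths = np.maximum(
        np.round(rng.normal(mean_len, sd_len, size=config.n_host_genes)),
        config.min_gene_codons).astype(int)
    host = [(f"host{i:05d}", sample_gene(int(L), bg, rng),
             "+" if rng.random() < 0.5 else "-")
            for i, L in enumerate(lengths)]
    lo, hi = config.spacer_bp
    spacers = [random_dna(int(rng.integers(lo, hi + 1)), rng)
               for _ in range(config.n_host_genes + 1)]

    fam_elements = {
        fam.family_id: quota_gene(fam.length_codons,
                                  bias_usage(bg, fam.codon_bias), rng)
        for fam in config.sge_families
    }
    trna_elements: dict[str, str] = {}
    for plant in config.trna_plants:
        if plant.anticodon not in trna_elements:
            trna_elements[plant.anticodon] = random_dna(config.trna_length_bp, rng)

    lgt_genes: dict[str, list[tuple[str, str]]] = {}
    lgt_tips: dict[str, set[str]] = {}
    truth_lgt_nodes: dict[str, str] = {}
    lgt_node_arg: dict[str, dict[str, int]] = {}
    for gain in config.lgt_gains:
        usage = bias_usage(bg, gain.codon_bias)
        genes = [(f"lgt_{gain.node_id}_{i:03d}",
                  sample_gene(gain.length_codons, usage, rng))
                 for i in range(gain.n_genes)]
        lgt_genes[gain.node_id] = genes
        lgt_tips[gain.node_id] = _descendant_tips(tree, gain.node_id)
        counts = count_codons([s for _, s in genes])
        lgt_node_arg[gain.node_id] = {
            "aga": counts["AGA"], "arg": sum(counts[c] for c in ARG_CODONS)}
        for gid, _ in genes:
            truth_lgt_nodes[gid] = gain.node_id

    # --- per-strain assembly ---
    genomes: dict[str, AnnotatedGenome] = {}
    truth = TruthSet(
        strains=strains, reference=reference,
        sge_counts={f.family_id: {} for f in config.sge_families},
        trna_counts={}, trna_contexts={}, trna_identity={},
        gene_categories={}, lgt_nodes=truth_lgt_nodes,
        node_genes={nid: [g for g, _ in gs] for nid, gs in lgt_genes.items()},
        sge_codon_counts={}, lgt_node_arg=lgt_node_arg,
    )

    for strain in strains:
        blocks: list[tuple[str, list[GeneFeature]]] = []
        cats: dict[str, str] = {gid: "host" for gid, _, _ in host}
        contexts: dict[str, str] = {}
        identities: dict[str, float] = {}
        ac_totals: dict[str, int] = {}
        sge_codons: dict[str, dict[str, int]] = {}

        def gene_block(gid: str, coding: str, category: str,
                       anticodon: str | None = None,
                       strand: str | None = None) -> tuple[str, list[GeneFeature]]:
            strand = strand or ("+" if rng.random() < 0.5 else "-")
            genomic = coding if strand == "+" else _revcomp(coding)
            return genomic, [GeneFeature(gid, 0, len(coding), strand, category,
                                         anticodon=anticodon)]

        for fam in config.sge_families:
            n = fam.copies_per_strain.get(strain, 0)
            n_dec = fam.decoy_copies_per_strain.get(strain, 0)
            element = fam_elements[fam.family_id]
            copies = []
            for j in range(n):
                seq = element if j == 0 else mutate_sequence(
                    element, fam.divergence_pct, rng)
                gid = f"{fam.family_id}_{strain}_c{j}"
                copies.append(seq)
                blocks.append(gene_block(gid, seq, "sge"))
                cats[gid] = "sge"
            for j in range(n_dec):
                seq = mutate_sequence(element, fam.decoy_divergence_pct, rng)
                gid = f"{fam.family_id}_{strain}_d{j}"
                blocks.append(gene_block(gid, seq, "sge"))
                cats[gid] = "sge"
            truth.sge_counts[fam.family_id][strain] = {
                "planted": n, "decoy": n_dec}
            sge_codons[fam.family_id] = count_codons(copies) if copies else \
                {c: 0 for c in CODONS}

        for plant in config.trna_plants:
            n = plant.copies_per_strain.get(strain, 0)
            if n == 0:
                continue
            element = trna_elements[plant.anticodon]
            base = f"trna{plant.anticodon}_{plant.tag}_{strain}"
            if plant.context == "tandem":
                strand = "+" if rng.random() < 0.5 else "-"
                parts, feats, off = [], [], 0
                for j in range(n):
                    gid = f"{base}_t{j}"
                    parts.append(element if strand == "+" else _revcomp(element))
                    feats.append(GeneFeature(gid, off, off + len(element),
                                             strand, "trna",
                                             anticodon=plant.anticodon))
                    off += len(element)
                    if j < n - 1:
                        sp = random_dna(50, rng)
                        parts.append(sp)
                        off += len(sp)
                    cats[gid] = "trna"
                    contexts[gid] = "tandem_array"
                    identities[gid] = 1.0
                blocks.append(("".join(parts), feats))
            else:
                for j in range(n):
                    gid = f"{base}_{'p' if plant.context == 'phage_flanked' else 'h'}{j}"
                    seq = mutate_sequence(element, plant.divergence_pct, rng)
                    strand = "+" if rng.random() < 0.5 else "-"
                    genomic = seq if strand == "+" else _revcomp(seq)
                    if plant.context == "phage_flanked":
                        left = sample_gene(100, bg, rng)
                        right = sample_gene(100, bg, rng)
                        g1, g2 = random_dna(30, rng), random_dna(30, rng)
                        seq_all = left + g1 + genomic + g2 + right
                        feats = [
                            GeneFeature(f"{gid}_phL", 0, len(left), "+", "phage"),
                            GeneFeature(gid, len(left) + 30,
                                        len(left) + 30 + len(seq), strand,
                                        "trna", anticodon=plant.anticodon),
                            GeneFeature(f"{gid}_phR", len(seq_all) - len(right),
                                        len(seq_all), "+", "phage"),
                        ]
                        cats[f"{gid}_phL"] = cats[f"{gid}_phR"] = "phage"
                        blocks.append((seq_all, feats))
                        contexts[gid] = "phage_flanked"
                    else:
                        blocks.append((genomic, [GeneFeature(
                            gid, 0, len(seq), strand, "trna",
                            anticodon=plant.anticodon)]))
                        contexts[gid] = "host_flanked"
                    cats[gid] = "trna"
                    identities[gid] = 1.0 - round(
                        plant.divergence_pct / 100 * len(element)) / len(element)
            ac_totals[plant.anticodon] = ac_totals.get(plant.anticodon, 0) + n

        for node_id, genes in lgt_genes.items():
            if strain not in lgt_tips[node_id]:
                continue
            for gid, seq in genes:
                blocks.append(gene_block(gid, seq, "lgt"))
                cats[gid] = "lgt"

        # reserve one distinct host-intergenic slot per block
        n_slots = len(spacers)
        if len(blocks) > n_slots:
            raise PlacementError(f"{strain}: more insertions than host spacers")
        slot_of_block = rng.choice(n_slots, size=len(blocks), replace=False)
        by_slot = {int(s): b for s, b in zip(slot_of_block, blocks)}

        seq_parts: list[str] = []
        feats: list[GeneFeature] = []
        off = 0

        def emit_spacer(i: int) -> None:
            nonlocal off
            sp = spacers[i]
            if i in by_slot:
                half = len(sp) // 2
                seq_parts.append(sp[:half])
                off += half
                block_seq, block_feats = by_slot[i]
                for bf in block_feats:
                    feats.append(GeneFeature(bf.gene_id, bf.start + off,
                                             bf.end + off, bf.strand,
                                             bf.category, bf.product,
                                             bf.anticodon))
                seq_parts.append(block_seq)
                off += len(block_seq)
                seq_parts.append(sp[half:])
                off += len(sp) - half
            else:
                seq_parts.append(sp)
                off += len(sp)

        for i, (gid, coding, strand) in enumerate(host):
            emit_spacer(i)
            genomic = coding if strand == "+" else _revcomp(coding)
            feats.append(GeneFeature(gid, off, off + len(coding), strand, "host"))
            seq_parts.append(genomic)
            off += len(coding)
        emit_spacer(config.n_host_genes)

        genomes[strain] = AnnotatedGenome(strain, "".join(seq_parts), feats)
        truth.gene_categories[strain] = cats
        truth.trna_contexts[strain] = contexts
        truth.trna_identity[strain] = identities
        truth.sge_codon_counts[strain] = sge_codons
        for ac, n in ac_totals.items():
            truth.trna_counts.setdefault(ac, {})[strain] = n
    for ac in truth.trna_counts:
        for strain in strains:
            truth.trna_counts[ac].setdefault(strain, 0)

    truth.audit(genomes)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for strain, g in genomes.items():
            write_genome(g, out_dir / f"{strain}.fasta", out_dir / f"{strain}.gff3")
        (out_dir / "tree.nwk").write_text(config.tree_newick.strip() + "\n")
        truth.to_json(out_dir / "truth.json")
        lgt_ids = sorted(truth.lgt_nodes)
        rows = [[gid] + [int(strain in lgt_tips[truth.lgt_nodes[gid]])
                         for strain in strains] for gid in lgt_ids]
        write_table(rows, out_dir / "presence.tsv", header=["gene"] + strains)
    return genomes, truth


# ---------------------------------------------------------------------------
# the default study conditions
# ---------------------------------------------------------------------------

DEFAULT_TREE = (
    "(((((SF301:1,SF2457T:1)N4:1,SB227:1)N3:1,SD197:1)N2:1,SS046:1)N1:1,"
    "((MG1655:1,W3110:1)E1:1,((APEC01:1,UTI89:1)E3:1,"
    "(CFT073:1,(IAI1:1,ED1a:1)E5:1)E4:1)E2:1)E0:1)ROOT;"
)

SHIGELLA_GROUP = ("SF301", "SF2457T", "SB227", "SD197", "SS046")
OTHER_GROUP = ("MG1655", "W3110", "APEC01", "UTI89", "CFT073", "IAI1", "ED1a")
REFERENCE_STRAIN = "MG1655"

#: codon bias planted in every SGE family: the three codons whose tRNAs are
#: amplified in the pathogen-like clade, plus an ATA-ile shift with no
#: matching tRNA amplification.
SGE_BIAS = {"AGA": 5.0, "GGA": 5.0, "ACA": 4.0, "ATA": 4.0}

TARGET_CODONS = ("AGA", "GGA", "ACA")
#: anticodons decoding the target codons (reverse complements)
TARGET_ANTICODONS = ("TCT", "TCC", "TGT")


def default_config(seed: int, n_host_genes: int = 2000) -> SimulationConfig:
    """The default 12-strain study conditions.

    Five pathogen-like strains (a nested clade) carry three SGE families at
    30-150 copies each with codon bias toward AGA/GGA/ACA/ATA, amplified
    phage-flanked tRNAs for the matching anticodons, and LGT gene sets of
    increasing AGA content gained at successive clade nodes; seven other
    strains carry a handful of SGE copies and single-copy tRNAs. One
    glycine anticodon is a three-copy tandem array in every strain.
    """
    shig = {s: 1 for s in SHIGELLA_GROUP}
    everyone = {s: 1 for s in SHIGELLA_GROUP + OTHER_GROUP}
    return SimulationConfig(
        seed=seed,
        tree_newick=DEFAULT_TREE,
        n_host_genes=n_host_genes,
        sge_families=[
            SgeFamily("IS1L", {"SF301": 141, "SF2457T": 138, "SB227": 147,
                               "SD197": 133, "SS046": 150,
                               "MG1655": 3, "W3110": 3, "APEC01": 2,
                               "UTI89": 4, "CFT073": 3, "IAI1": 2, "ED1a": 3},
                      dict(SGE_BIAS), divergence_pct=0.0),
            SgeFamily("IS2L", {"SF301": 65, "SF2457T": 61, "SB227": 70,
                               "SD197": 58, "SS046": 67,
                               "MG1655": 2, "W3110": 2, "APEC01": 1,
                               "UTI89": 2, "CFT073": 3, "IAI1": 1, "ED1a": 2},
                      dict(SGE_BIAS), divergence_pct=2.0),
            SgeFamily("IS600L", {"SF301": 91, "SF2457T": 95, "SB227": 88,
                                 "SD197": 84, "SS046": 93,
                                 "MG1655": 1, "W3110": 1, "APEC01": 1,
                                 "UTI89": 1, "CFT073": 1, "IAI1": 2, "ED1a": 1},
                      dict(SGE_BIAS), divergence_pct=4.0,
                      decoy_copies_per_strain={s: 8 for s in SHIGELLA_GROUP}),
        ],
        trna_plants=[
            TrnaPlant("TCT", dict(everyone), "host_flanked", 0.0, tag="orig"),
            TrnaPlant("TCC", dict(everyone), "host_flanked", 0.0, tag="orig"),
            TrnaPlant("TGT", dict(everyone), "host_flanked", 0.0, tag="orig"),
            TrnaPlant("GCC", {s: 3 for s in everyone}, "tandem", 0.0,
                      tag="gly"),
            TrnaPlant("TCT", {"SS046": 1, "SD197": 2, "SB227": 3,
                              "SF2457T": 4, "SF301": 5},
                      "phage_flanked", 4.0, tag="lgt"),
            TrnaPlant("TCC", {s: 4 for s in shig}, "phage_flanked", 4.0,
                      tag="lgt"),
            TrnaPlant("TGT", {s: 3 for s in shig}, "phage_flanked", 4.0,
                      tag="lgt"),
        ],
        lgt_gains=[
            LgtGain("N1", 30, {"AGA": 1.0}),
            LgtGain("N2", 20, {"AGA": 2.0}),
            LgtGain("N3", 15, {"AGA": 4.0}),
            LgtGain("N4", 10, {"AGA": 8.0}),
            LgtGain("SF301", 8, {"AGA": 16.0}),
        ],
    )


# ---------------------------------------------------------------------------
# auxiliary simulators for the phylogenetic statistics
# ---------------------------------------------------------------------------

def random_bifurcating_tree(n_tips: int, rng: np.random.Generator,
                            mean_branch: float = 1.0) -> StrainTree:
    """A random fully resolved rooted tree with exponential branch lengths."""
    import dendropy
    nodes = []
    ns = dendropy.TaxonNamespace()
    for i in range(n_tips):
        nd = dendropy.Node()
        nd.taxon = ns.new_taxon(f"t{i}")
        nd.edge.length = float(rng.exponential(mean_branch))
        nodes.append(nd)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.exponential(mean_branch))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent.add_child(left)
        parent.add_child(right)
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = nodes[0]
    tree.seed_node.edge.length = None
    return StrainTree(tree)


def simulate_brownian(tree: StrainTree, rng: np.random.Generator,
                      correlation: float = 0.0
                      ) -> tuple[dict[str, float], dict[str, float]]:
    """Two traits evolved by correlated Brownian motion along a tree."""
    cov = np.array([[1.0, correlation], [correlation, 1.0]])
    chol = np.linalg.cholesky(cov)
    values: dict[int, np.ndarray] = {id(tree.tree.seed_node): np.zeros(2)}
    x, y = {}, {}
    for nd in tree.tree.preorder_node_iter():
        if nd is tree.tree.seed_node:
            continue
        b = nd.edge.length if nd.edge.length else 1.0
        step = chol @ rng.standard_normal(2) * math.sqrt(b)
        values[id(nd)] = values[id(nd.parent_node)] + step
        if nd.is_leaf():
            x[nd.taxon.label] = float(values[id(nd)][0])
            y[nd.taxon.label] = float(values[id(nd)][1])
    return x, y


__all__ = [
    "PlacementError", "default_background_usage", "usage_from_yaml",
    "usage_to_yaml", "bias_usage", "sample_gene", "random_dna",
    "mutate_sequence", "plant_copies", "SgeFamily", "TrnaPlant", "LgtGain",
    "quota_gene", "SimulationConfig", "TruthSet", "simulate_strains",
    "default_config",
    "DEFAULT_TREE", "SHIGELLA_GROUP", "OTHER_GROUP", "REFERENCE_STRAIN",
    "SGE_BIAS", "TARGET_CODONS", "TARGET_ANTICODONS",
    "random_bifurcating_tree", "simulate_brownian",
]
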