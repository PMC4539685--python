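"""LGT gene gain-node assignment and phylogenetically independent contrasts.

A laterally transferred gene observed in a subset of strains is assigned to
the most recent common ancestor of the strains that carry it — a single
gain with no subsequent loss, which matches binning genes to the clade at
whose stem they arrived. Walking the root-to-tip path and unioning the node
gene sets yields each strain's cumulative LGT complement.

Codon use of a gene set is summarized as the fraction of arginine sites
encoded by AGA, the rare-codon statistic at the heart of the tRNA(AGA)
story. Correlation between codon use and tRNA gene number across strains is
computed on Felsenstein's independent contrasts: trait differences at each
internal node, standardized by the branch lengths, with the correlation
taken through the origin and t-tested on N_contrasts - 1 degrees of
freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .codon_stats import ARG_CODONS
from .io_core import StrainTree


class PolytomyError(ValueError):
    """PIC requires a fully resolved tree; resolve polytomies first."""


@dataclass
class PicResult:
    contrasts_x: np.ndarray
    contrasts_y: np.ndarray
    r: float
    t: float | None
    df: int
    p: float | None


# ---------------------------------------------------------------------------
# presence/absence and gain nodes
# ---------------------------------------------------------------------------

def read_presence_matrix(tsv_path: str | Path) -> pd.DataFrame:
    """gene x strain boolean matrix from TSV (genes in rows, header row)."""
    df = pd.read_csv(tsv_path, sep="\t", index_col=0)
    df = df.astype(int).astype(bool)
    if (~df).all(axis=1).any():
        raise ValueError("presence matrix contains all-absent genes")
    return df


def _node_label(nd: dendropy.Node) -> str | None:
    return nd.taxon.label if nd.taxon else nd.label


def assign_gain_node(presence_tips: Sequence[str], tree: StrainTree) -> str:
    """MRCA of the tips carrying a gene — its single-gain point.

    A gene present in one tip is assigned to that tip (a gain on its
    terminal branch); a gene present in all tips belongs to the root.
    Returns the node label (tips keep their taxon label; unlabeled internal
    nodes get stable ``node<k>`` preorder labels).
    """
    _ensure_node_labels(tree)
    return _node_label(_mrca(tree, list(presence_tips)))


def _mrca(tree: StrainTree, tip_labels: Sequence[str]) -> dendropy.Node:
    labels = set(tip_labels)
    missing = labels - set(tree.tips)
    if missing:
        raise KeyError(f"tips not in tree: {sorted(missing)}")
    if not labels:
        raise ValueError("at least one presence tip required")
    if len(labels) == 1:
        (label,) = labels
        return tree.tree.find_node_with_taxon_label(label)
    taxa = [tree.tree.taxon_namespace.get_taxon(t) for t in labels]
    return tree.tree.mrca(taxa=taxa)


def assign_gain_nodes(presence: pd.DataFrame,
                      tree: StrainTree) -> dict[str, str]:
    """Assign every gene in a presence matrix to its gain node label.

    Internal nodes are identified by their Newick labels; unlabeled nodes
    get a stable synthetic label ``node<k>`` (preorder numbering).
    """
    out = {}
    for gene, row in presence.iterrows():
        tips = [s for s in presence.columns if row[s]]
        out[gene] = assign_gain_node(tips, tree)
    return out


def _ensure_node_labels(tree: StrainTree) -> None:
    k = 0
    for nd in tree.tree.preorder_node_iter():
        if _node_label(nd) is None:
            nd.label = f"node{k}"
        k += 1


def cumulative_sets(assignments: Mapping[str, str],
                    tree: StrainTree) -> dict[str, set[str]]:
    """Per-tip cumulative LGT gene sets (union along the root-to-tip path)."""
    _ensure_node_labels(tree)
    by_node: dict[str, set[str]] = {}
    for gene, node in assignments.items():
        by_node.setdefault(node, set()).add(gene)
    out: dict[str, set[str]] = {}
    for leaf in tree.tree.leaf_node_iter():
        acc: set[str] = set()
        nd = leaf
        while nd is not None:
            acc |= by_node.get(_node_label(nd), set())
            nd = nd.parent_node
        out[leaf.taxon.label] = acc
    return out


def node_sets(assignments: Mapping[str, str]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for gene, node in assignments.items():
        out.setdefault(node, set()).add(gene)
    return out


# ---------------------------------------------------------------------------
# AGA fraction of arginine sites
# ---------------------------------------------------------------------------

def aga_arg_proportion(gene_ids: Sequence[str],
                       cds_source: Mapping[str, str]) -> float:
    """(#AGA codons) / (#arginine codons) over a gene set.

    NaN (flagged undefined) for an empty set or a set with no arginine
    codons. The leading start triplet of each CDS is skipped (it encodes
    fMet whatever its identity).
    """
    aga = arg = 0
    for gid in gene_ids:
        seq = cds_source[gid].upper()
        for i in range(3, len(seq) - 2, 3):
            codon = seq[i:i + 3]
            if codon in ARG_CODONS:
                arg += 1
                if codon == "AGA":
                    aga += 1
    return aga / arg if arg else math.nan


# ---------------------------------------------------------------------------
# phylogenetically independent contrasts
# ---------------------------------------------------------------------------

def pic_contrasts(tree: StrainTree, trait: Mapping[str, float],
                  resolve_polytomies: bool = False,
                  default_branch_length: float = 1.0) -> np.ndarray:
    """Felsenstein's standardized independent contrasts of one trait.

    At each internal node of a fully resolved tree the contrast is
    (x_i - x_j) / sqrt(b_i + b_j); the node's ancestral value is the
    1/b-weighted average of its children and its parent branch is
    lengthened by b_i * b_j / (b_i + b_j). Trees without branch lengths
    get ``default_branch_length`` everywhere. Polytomies are rejected
    unless ``resolve_polytomies`` (arbitrary zero-length resolution).
    """
    contrasts, _ = _pic(tree, trait, resolve_polytomies, default_branch_length)
    return contrasts


def _pic(tree: StrainTree, trait: Mapping[str, float],
         resolve_polytomies: bool, default_branch_length: float
         ) -> tuple[np.ndarray, list[dendropy.Node]]:
    work = tree.tree.clone(depth=1)
    missing = {lf.taxon.label for lf in work.leaf_node_iter()} - set(trait)
    if missing:
        raise KeyError(f"trait missing for tips: {sorted(missing)}")
    for nd in work.preorder_node_iter():
        n_children = len(nd.child_nodes())
        if n_children > 2:
            if not resolve_polytomies:
                raise PolytomyError(
                    "tree contains a polytomy; pass resolve_polytomies=True "
                    "for an arbitrary zero-length resolution")
    if resolve_polytomies:
        work.resolve_polytomies(limit=2, update_bipartitions=False)
    has_lengths = any(e.length for e in work.preorder_edge_iter())

    contrasts: list[float] = []
    nodes: list[dendropy.Node] = []
    # postorder pruning: (value, effective branch length) per node
    value: dict[int, float] = {}
    blen: dict[int, float] = {}
    for nd in work.postorder_node_iter():
        edge = nd.edge.length
        if edge is None or not has_lengths:
            edge = default_branch_length if nd.parent_node is not None else 0.0
        if nd.is_leaf():
            value[id(nd)] = float(trait[nd.taxon.label])
            blen[id(nd)] = float(edge)
            continue
        children = nd.child_nodes()
        if len(children) == 1:  # knuckle: pass through, accumulate length
            c = children[0]
            value[id(nd)] = value[id(c)]
            blen[id(nd)] = float(edge) + blen[id(c)]
            continue
        ci, cj = children
        bi, bj = blen[id(ci)], blen[id(cj)]
        if bi + bj <= 0:
            bi = bj = max(bi, bj, 1e-12)
        contrasts.append((value[id(ci)] - value[id(cj)]) / math.sqrt(bi + bj))
        nodes.append(nd)
        value[id(nd)] = (value[id(ci)] / bi + value[id(cj)] / bj) / (1 / bi + 1 / bj)
        blen[id(nd)] = float(edge) + bi * bj / (bi + bj)
    return np.array(contrasts), nodes


def pic_correlation(tree: StrainTree, x: Mapping[str, float],
                    y: Mapping[str, float],
                    resolve_polytomies: bool = False,
                    default_branch_length: float = 1.0) -> PicResult:
    """Correlation of two traits through the origin of their contrasts.

    r = sum(u v) / sqrt(sum u^2 sum v^2); t = r sqrt(df) / sqrt(1 - r^2)
    with df = N_contrasts - 1, two-sided p. With fewer than 3 contrasts r
    is reported and p is None.
    """
    if set(x) != set(y):
        raise ValueError("x and y must cover the same tips")
    u = pic_contrasts(tree, x, resolve_polytomies, default_branch_length)
    v = pic_contrasts(tree, y, resolve_polytomies, default_branch_length)
    denom = math.sqrt(float(u @ u) * float(v @ v))
    r = float(u @ v) / denom if denom > 0 else math.nan
    df = len(u) - 1
    if len(u) < 3 or not math.isfinite(r) or abs(r) >= 1.0:
        t = None
        p = None if (len(u) < 3 or not math.isfinite(r)) else 0.0
        if abs(r) >= 1.0 and len(u) >= 3:
            t = math.inf
        return PicResult(u, v, r, t, df, p)
    t = r * math.sqrt(df) / math.sqrt(1 - r * r)
    p = 2 * float(_scipy_stats.t.sf(abs(t), df))
    return PicResult(u, v, r, t, df, p)


def pearson_star(x: Sequence[float], y: Sequence[float]) -> float:
    """Ordinary Pearson correlation — the star-tree limit of PIC."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.corrcoef(x, y)[0, 1])


__all__ = [
    "PolytomyError", "PicResult", "read_presence_matrix", "assign_gain_node",
    "assign_gain_nodes",
    "cumulative_sets", "node_sets", "aga_arg_proportion", "pic_contrasts",
    "pic_correlation", "pearson_star",
]
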