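"""Anticodon-level tRNA copy-number tables, fold changes and group tests.

Counting is at the anticodon level, not the gene-name level: a laterally
acquired tRNA gene and a native gene that read the same codon pool into one
statistic, which is the quantity translation actually sees. Anticodons are
reported in the DNA alphabet; the decoded codon is the reverse complement.

Fold change is each strain's anticodon count divided by the count in an
ancestral reference strain (MG1655-like). Anticodons whose group mean fold
change exceeds a threshold (default 2) are tested with the Mann-Whitney U
test against the remaining strains; the exact null is enumerated for small
samples (ties handled by midranks), with a tie- and continuity-corrected
normal approximation otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .codon_stats import CODONS
from .io_core import AnnotatedGenome

ANTICODONS = CODONS  # same 64 triplets, DNA alphabet

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def decoded_codon(anticodon: str) -> str:
    """The codon read by an anticodon (reverse complement, DNA alphabet)."""
    return anticodon.translate(_COMPLEMENT)[::-1]


@dataclass
class GroupTestResult:
    anticodon: str
    group_mean_fc: float
    others_mean_fc: float
    passed_threshold: bool
    U: float | None
    p: float | None


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def anticodon_counts(genomes: Mapping[str, AnnotatedGenome]) -> pd.DataFrame:
    """strain x anticodon copy-number matrix from tRNA annotations.

    tRNA features lacking an anticodon go to an ``unknown`` column (with a
    warning via the package logger); the 64 anticodon columns are always
    present.
    """
    from .io_core import logger
    rows = {}
    for strain, genome in sorted(genomes.items()):
        counts = dict.fromkeys(ANTICODONS, 0)
        for f in genome.features_of("trna"):
            ac = (f.anticodon or "").upper()
            if ac in counts:
                counts[ac] += 1
            else:
                logger.warning("%s/%s: tRNA without anticodon", strain, f.gene_id)
                counts["unknown"] = counts.get("unknown", 0) + 1
        rows[strain] = counts
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)


def anticodon_counts_from_scan(tsv_path: str | Path) -> pd.DataFrame:
    """strain x anticodon matrix from external tRNA-scan tabular output.

    Expects the classic tabular layout (one data row per tRNA): sequence
    name, tRNA number, begin, end, tRNA type, anticodon, ... Header lines
    (and the dashed separator) are skipped. The sequence name is taken as
    the strain id; anticodons are uppercased to the DNA alphabet (U -> T).
    """
    rows: dict[str, dict[str, int]] = {}
    with open(tsv_path) as fh:
        for line in fh:
            parts = [p.strip() for p in line.rstrip("\n").split("\t")]
            if len(parts) < 6 or not parts[2].strip().isdigit():
                continue  # header / separator lines
            strain = parts[0]
            ac = parts[5].upper().replace("U", "T")
            counts = rows.setdefault(strain, dict.fromkeys(ANTICODONS, 0))
            if ac in counts:
                counts[ac] += 1
            else:
                counts["unknown"] = counts.get("unknown", 0) + 1
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)


# ---------------------------------------------------------------------------
# fold change
# ---------------------------------------------------------------------------

def fold_change(table: pd.DataFrame,
                reference_strain: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-anticodon fold change of each strain vs. the reference strain.

    0/0 -> 1.0 (absent everywhere, no change); x/0 with x > 0 is a *novel*
    anticodon — flagged, with the absolute count reported as the value (the
    anticodon-level analogue of a gene absent from the ancestor).
    Returns ``(fold_change, novel_flags)``.
    """
    if reference_strain not in table.index:
        raise KeyError(f"reference strain {reference_strain!r} not in table")
    ref = table.loc[reference_strain].astype(float)
    fc = pd.DataFrame(index=table.index, columns=table.columns, dtype=float)
    novel = pd.DataFrame(False, index=table.index, columns=table.columns)
    for col in table.columns:
        r = ref[col]
        if r > 0:
            fc[col] = table[col] / r
        else:
            fc[col] = table[col].astype(float)  # absolute counts
            fc.loc[table[col] == 0, col] = 1.0
            novel.loc[table[col] > 0, col] = True
    return fc, novel


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of x over y: #pairs x > y plus half the ties."""
    diff = x[:, None] - y[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   alternative: str = "two-sided",
                   exact_max_n: int = 8) -> tuple[float, float]:
    """Mann-Whitney U test of two independent samples.

    The exact p enumerates every assignment of the pooled values to the two
    groups (valid under ties) when ``min(len(x), len(y)) <= exact_max_n``;
    larger samples use the normal approximation with tie and continuity
    corrections. ``alternative`` is ``two-sided``, ``greater`` (x tends
    larger) or ``less``. All values tied across both samples gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = len(x), len(y)
    U = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return U, 1.0

    if min(n1, n2) <= exact_max_n and math.comb(n1 + n2, n1) <= 200_000:
        null = np.array([
            _u_statistic(pooled[list(idx)],
                         np.delete(pooled, list(idx)))
            for idx in itertools.combinations(range(n1 + n2), n1)
        ])
        total = len(null)
        p_ge = (null >= U).sum() / total
        p_le = (null <= U).sum() / total
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            mu = n1 * n2 / 2.0
            p = (np.abs(null - mu) >= abs(U - mu) - 1e-12).sum() / total
        return U, float(min(p, 1.0))

    # normal approximation with tie correction
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return U, 1.0
    sigma = math.sqrt(sigma2)
    if alternative == "greater":
        z = (U - mu - 0.5) / sigma
        p = _scipy_stats.norm.sf(z)
    elif alternative == "less":
        z = (U - mu + 0.5) / sigma
        p = _scipy_stats.norm.cdf(z)
    else:
        z = (abs(U - mu) - 0.5) / sigma
        p = 2 * _scipy_stats.norm.sf(z)
    return U, float(min(p, 1.0))


def group_enrichment_test(fold_table: pd.DataFrame,
                          group_members: Sequence[str],
                          others: Sequence[str],
                          threshold: float = 2.0,
                          alternative: str = "greater"
                          ) -> list[GroupTestResult]:
    """Per-anticodon group test of fold-change enrichment.

    An anticodon whose mean fold change in ``group_members`` exceeds
    ``threshold`` is compared to ``others`` with the Mann-Whitney U test;
    every anticodon is reported with its pass/fail flag (U and p are None
    below the threshold).
    """
    group_members = list(group_members)
    others = list(others)
    if set(group_members) & set(others):
        raise ValueError("groups must be disjoint")
    if len(group_members) < 2 or len(others) < 2:
        raise ValueError("need >= 2 strains per group")
    results = []
    for ac in fold_table.columns:
        g = fold_table.loc[group_members, ac].to_numpy(dtype=float)
        o = fold_table.loc[others, ac].to_numpy(dtype=float)
        passed = bool(g.mean() > threshold)
        U = p = None
        if passed:
            U, p = mann_whitney_u(g, o, alternative=alternative)
        results.append(GroupTestResult(ac, float(g.mean()), float(o.mean()),
                                       passed, U, p))
    return results


__all__ = [
    "ANTICODONS", "decoded_codon", "GroupTestResult", "anticodon_counts",
    "anticodon_counts_from_scan", "fold_change", "mann_whitney_u",
    "group_enrichment_test",
]
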