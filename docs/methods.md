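# Methods

## Scope and data model

All analyses operate on `AnnotatedGenome` objects: one replicon sequence per
strain plus typed gene features (`host`, `sge`, `trna`, `lgt`, `phage`,
`other`). Coordinates are 0-based half-open internally; GFF3's 1-based
inclusive convention is converted only at the file boundary. Feature
categories travel in a GFF3 `category=` attribute; for genomes derived from
public annotations the intended mapping is mobile-element/IS annotations →
`sge`, prophage regions → `phage`. tRNA features carry an `anticodon=`
attribute (DNA alphabet); tRNA gene finding itself is out of scope — loci are
consumed from annotations, or from an external tRNA-scanner's tabular output
via `trna_profile.anticodon_counts_from_scan`. Plasmids are not modelled;
analyses are chromosome-only.

## Codon usage

`count_codons` tallies in-frame triplets per CDS. The leading triplet is
credited to methionine whatever its identity, since bacterial start codons
are all read as fMet; codons containing N are skipped (a gene is only
dropped when >10% of its bases are ambiguous); CDS lengths not divisible by
3 are flagged unusable and excluded. Relative usage normalizes within each
synonymous family of the bacterial genetic code (translation table 11),
with the three stop codons forming one family; a family with zero counts
has undefined (NaN) relative usage rather than silent zeros.

Fold enrichment divides the subset's per-family relative frequency by the
whole-genome value, with the subset included in the genome denominator — a
deliberately conservative choice that can only shrink the measured
enrichment. `0/0` maps to 1 (no evidence), `x/0` to +inf (flagged).
Cross-strain uncertainty uses the Student-t interval
`mean ± t_{(1+γ)/2, n−1}·s/√n` at γ = 0.99 by default, matching the error
bars a small strain panel supports.

## The rank-sum permutation test

Codons are ranked 1..64 by descending fold enrichment. Infinite folds rank
first and NaN last; ties break lexicographically so the ranking is always a
permutation of 1..64 and the statistic's support matches the null. For a
target set of k codons the statistic is the sum of their ranks, tested
one-tailed against k ranks drawn from 1..n. Two nulls are provided —
distinct ranks ("a set of k numbers", the default) and ordered draws with
replacement — because "random sets of k numbers between 1 and n" is
ambiguous; both are exact via dynamic programming over rank sums (the DP is
cross-checked against brute-force enumeration in the tests). The
Monte-Carlo companion uses the add-one estimator
`p = (#{sum ≤ S} + 1)/(reps + 1)` so finite replication never reports 0.
The ranking size is configurable to n = 61 (sense codons only) but defaults
to the full 64.

## Copy-number detection

The search is reference-driven: each reference-strain gene is located in
every genome by seed-and-extend. A 2-bit k-mer scan (k = 12, both strands)
proposes candidate windows; the window margin equals the query length so a
copy is fully contained even when divergence has destroyed the seeds of one
flank. Within a window, every non-overlapping gapless placement of the
query whose identity strictly exceeds the cutoff is a hit (identity =
matches / aligned query positions; coverage = aligned query positions /
query length; both must strictly exceed 0.95 — 0.95 exactly fails). When
the best gapless identity falls just below the cutoff (within 0.15) the
window is re-verified by glocal alignment — global over the query with free
end gaps on the genomic window (match +1, mismatch −1, gap −2, via
Bio.Align.PairwiseAligner) — to admit indel-containing copies. Overlapping
hits are merged keeping the best score. An adapter ingests 12-column
tabular results from an external search tool instead, for genomes where an
established aligner is preferred.

The 95/95 cutoff is chosen to exceed the maximum average divergence within
a closely related strain complex (≈0.1–2.4%), so duplications arising since
the strains diverged are detected while older paralogy is excluded.
Reference genes are pooled into paralog clusters by single linkage over the
same 95/95 relation; per-strain counting queries with *every* cluster
member (deduplicated by sequence) and unions the hit loci, so a strain
carrying any one member reveals its siblings. Slightly diverged IS copies
can surface as two near-identical clusters hitting the same loci;
`cull_redundant_sets` drops, of any pair with >50% reciprocal hit overlap,
the cluster with fewer members (ties drop the lexicographically later id) —
a deterministic automation of what is otherwise manual curation, yielding a
conservative duplicate-gene set.

Context classification: a copy is part of a `tandem_array` when another
same-cluster copy lies on the same strand within 5 kb *with no unrelated
gene between them* (tandem duplications are contiguous; a distance-only
rule would misread a mobile copy that happens to insert one slot away).
Otherwise the nearest non-cluster feature within 10 kb on each side decides
the call: phage on either side → `phage_flanked`; host on both →
`host_flanked`; else ambiguous. Identity to the designated original copy is
reported when an original is supplied (the copy syntenic with the reference
strain).

## tRNA profile

Counting is at anticodon level, not gene-name level: a phage-derived tRNA
and a native tRNA reading the same codon pool into one number, which is the
quantity the translation machinery sees. Fold change divides each strain's
anticodon count by the count in a designated ancestral reference strain;
0/0 → 1, and an anticodon absent from the reference but present in a strain
is flagged *novel* with its absolute count reported (the printed-formula
fold is undefined there). Anticodons whose focal-group mean fold change
exceeds 2 are tested against the remaining strains with the Mann–Whitney U
test, one-sided "greater" by default (the hypothesis is enrichment; the
sidedness is configurable). The exact p enumerates all assignments of the
pooled values to the two groups (valid under ties, handled by midranks)
whenever the smaller sample has ≤8 observations; larger samples use the
tie- and continuity-corrected normal approximation.

## LGT phylogenetics

A gene's gain node is the MRCA of the strains that carry it — a single
gain with no loss. This matches cumulative clade binning and needs no
gene-tree evidence; genes present in one strain sit on that terminal
branch, genes in all strains at the root. Cumulative per-strain LGT sets
union the node sets along the root-to-tip path. Codon use of a gene set is
the AGA share of its arginine codons (leading start triplets excluded).

Independent contrasts follow Felsenstein's pruning: at each internal node
of a fully resolved tree, contrast `(x_i − x_j)/√(b_i + b_j)`, ancestral
value the 1/b-weighted average, parent branch extended by
`b_i·b_j/(b_i+b_j)`. Trees without branch lengths get unit lengths
(configurable); polytomies are rejected unless an explicit zero-length
resolution is requested. The correlation of two traits' contrasts is taken
through the origin, `r = Σuv/√(Σu²Σv²)`, with `t = r√(df)/√(1−r²)`,
df = N_contrasts − 1, two-sided p. On a star tree with equal branch lengths
this reduces exactly to the Pearson correlation of tip values (the
standardized contrast vectors form an orthonormal basis of the complement
of the mean), which the tests verify to 1e-9, alongside a cross-check of
the contrasts against R's `ape::pic`.

## The synthetic generator

`synthetic.simulate_strains` builds an annotated strain set from a tree:

* **Host genes** are sampled once at the root (lengths Normal(300, 80)
  codons, floored at 60; codon draw = uniform amino acid, then synonymous
  codon at the background table's frequencies) and inherited verbatim by
  every tip, so cross-strain similarity search at 95% identity is
  meaningful. The background table uses the canonical alanine profile
  GCG/GCC/GCA/GCT = 0.36/0.27/0.21/0.16 and uniform frequencies elsewhere.
* **SGE families** are single genes planted in many copies. The family
  element is built with *quota* composition — expected codon counts of the
  biased table, largest-remainder rounded, randomly ordered — because the
  planted bias is a study condition; a single multinomial draw of 300
  codons would carry ±0.3 fold units of idiosyncratic noise per codon and
  mask its own signal. Bias multiplies chosen codons within their synonymous
  family and renormalizes.
* **Divergence** is an exact count of `round(pct/100·L)` distinct
  substituted positions (no indels). This makes identity to the original
  deterministic: 4% → exactly 0.96 (detected at the >0.95 cutoff), 6% →
  exactly 0.94 (excluded). Bernoulli per-site substitution would let ~12%
  of 6%-"decoy" copies drift above the cutoff and turn exactness checks
  into coin flips. Each strain's copy 0 is the unmutated original, so
  single-linkage clustering always bridges the diverged siblings.
* **tRNA plants** place copies of a per-anticodon 77 bp element as a
  host-flanked original, a same-strand tandem array (identical copies,
  50 bp apart), or per-copy phage-flanked insertions mutated at the
  requested divergence.
* **LGT gains** generate gene sets once and place them in exactly the tips
  descending from the named node; a presence/absence TSV is emitted.
* **Assembly** reserves one distinct host-intergenic slot per insertion and
  splices the genome in a single pass, guaranteeing host-gene flanks for
  every block and linear-time construction. The public `plant_copies`
  splices an existing genome directly and serves small-scale fixtures.

Every run emits a truth set (planted copy numbers, contexts, categories,
gain nodes, realized codon counts) and self-audits the emitted annotations
against it before returning.

**Default study conditions**: 12 strains — a nested 5-strain pathogen-like
clade and 7 others — with 2000 host genes (~2.6 Mb genomes); three SGE
families at 58–150 copies per pathogen strain (1–4 elsewhere) at 0%, 2% and
4% divergence, all biased toward AGA×5, GGA×5, ACA×4 plus an ATA×4 shift
with no matching tRNA amplification; eight 6% decoy copies per pathogen
strain on the 4% family; anticodons TCT/TCC/TGT as host-flanked singletons
everywhere plus 2–5 phage-flanked extra copies (4% divergence) in the
pathogen clade; a three-copy tandem GCC array in every strain; and LGT gene
sets of 30/20/15/10/8 genes with AGA bias doubling at each successive clade
node. These sizes keep a full pipeline run at roughly 80 seconds on one
CPU while leaving every statistic far from its decision boundary.

**What the generator does not emulate** — and hence what passing tests do
not establish about real genomes: realistic phage or IS sequence models,
indels and rearrangements, recombination, gene loss after LGT gain,
GC-content structure (base composition is emergent from the codon model),
multi-replicon genomes, and annotation error. Copy-number exactness on
synthetic data shows the search machinery is correct at its thresholds, not
that 95/95 is optimal for any particular real dataset.

## Numerical and degenerate-case choices

* Identity 0.95 or coverage 0.95 *exactly* fail the strict cutoffs.
* Welch's t on SGE totals returns p = 1 (t = 0) when both groups are
  constant and equal; constant unequal groups return p = 0 (infinite t).
* Mann–Whitney with all values tied returns p = 1.
* `enrichment_ci` requires ≥2 strains; single-strain folds are reported
  without intervals.
* `pic_correlation` with fewer than 3 contrasts reports r without p; |r| = 1
  reports p = 0 with infinite t.
* All generator and pipeline randomness flows from one root seed, split per
  stage via `numpy.random.SeedSequence` and logged in JSON sidecars; fixed
  seeds reproduce byte-identical outputs.

## Known limitations

* The copy search is nucleotide-level and reference-driven: genes absent
  from the reference strain are invisible unless added to the query set.
* The gapless-first verification assumes substitutions dominate recent
  divergence; heavily indel-ridden copies near the coverage boundary are
  only caught by the glocal fallback band (0.15 below the identity cutoff).
* Gain-node assignment ignores gene loss and convergent gain; presence
  patterns produced by loss are attributed to an older, single gain.
* The rank-sum test treats the codon ranking as exchangeable under the
  null; codons of the same amino acid are in reality weakly coupled through
  the per-family normalization.
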