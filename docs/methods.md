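# Methods

## Synthetic study system

The simulator (`panclade.simulate`) produces a clade of N genomes split
into labeled lineages, with gene families in four classes: **core**
(exactly one copy in every genome), **accessory** (i.i.d. Bernoulli
presence per genome with probability `accessory_presence_prob`, optionally
restricted to one lineage to emulate lineage-specific gene content),
**singleton** (Poisson(`singleton_rate`) fresh families per genome), and
**hgt** (genes of inserted clusters, shared verbatim by all recipients —
a recent-transfer model). The true tree is a star of lineages: root →
lineage ancestor (branch `stem`, default 0.02 substitutions/site) → leaf
(branch `terminal`, default 0.005). Defaults mirror the study system the
package targets: tight lineages whose within-lineage identity (~99 %) and
between-lineage identity (~93–94 %) straddle the 95 % ANI species cutoff,
genomic GC 46.7 %, and an HGT cluster at 38.6 % GC.

Sequence evolution is Jukes–Cantor: on a branch of length d, each site
changes with probability (3/4)(1 − e^(−4d/3)) to one of the three other
bases uniformly — the exact JC transition probabilities, so the process
composes correctly across consecutive branches. Two deliberate deviations:

* codons that would become internal stops are reverted to the parent codon
  (start/stop codons held fixed), so every CDS stays translatable; the
  departure from pure JC affects O(p) of a handful of AT-rich codons;
* intergenic spacers (fixed 100 bp, one per gene) are generated once
  ancestrally and inherited/evolved with their gene, so genome-wide
  divergence — which ANI measures — equals the tree divergence rather than
  being diluted by unrelated intergenic DNA.

CDS base composition is calibrated: rejecting stop codons during sampling
enriches GC by up to ~1 percentage point, so the sampling bias is solved by
bisection such that the realized non-stop codon GC hits the target. HGT
clusters (n genes of `gene_length` bp at `target_gc`, 100-bp internal
spacers) land within ±0.01 of their target GC for regions ≥ 10 kb.

What the generator does **not** emulate: operon structure, codon-usage and
amino-acid composition biases, rearrangements/inversions, minus-strand
genes, indels within genes, paralogs, and recombination. Passing tests
therefore demonstrate correctness of the algorithms under tree-like
vertical descent with substitutions plus clean horizontal insertions — not
robustness to real-genome complications such as repeats, mobile elements,
or recombined regions.

## Orthology

Proteins are compared by global dynamic programming (match 2, mismatch −1,
gap open −4, extend −1 by default) rather than a database search tool:
scores are deterministic and independent of database composition. A gene's
best hit in another strain is the highest-scoring candidate with score > 0
and identity ≥ 0.5 over aligned columns (ties broken by smallest gene id);
an RBH edge requires best-hit status in both directions. Families are
connected components of the RBH graph; isolated genes are singleton
families; family ids are assigned by each component's smallest member so
output is independent of input order. A shared 5-mer prefilter skips
candidate pairs sharing no k-mer; at the divergences where RBH orthology is
meaningful (≲ 0.05 subst/site) true orthologs share many exact 5-mers, and
the suite checks the prefilter removes no edge. Limitations: no
duplication-aware tree splitting; recent paralogs merge into one family.

## Pan-genome models

Accumulation curves average pan(n) (families in ≥ 1 of the first n genomes)
and core(n) (families in all n) over `n_permutations` (default 100) random
genome orderings. Heap's law is fitted on permutation means by ordinary
least squares on log P(n) = log κ + γ log n, matching the log-log linearity
by which openness is usually judged; γ > 0 classifies the pan-genome as
open. Core decay C(n) = Ω + A e^(−n/τ) is fitted by bounded
Levenberg–Marquardt (scipy `curve_fit`) with multi-start τ₀ ∈ {1, 3, 10},
Ω₀ = min core(n), A₀ = core(1) − Ω₀, keeping the lowest-loss fit. Both fits
recover noiseless generative data exactly (γ, κ to machine precision; Ω
within 1 family), and Ω errs ≤ 5 % (median) under σ = 10 family noise.
Error bars are standard deviations over permutations.

## ANI

Query genomes are cut into consecutive `fragment_length` = 1020 bp
fragments (trailing partials discarded — fragment counts are exact
bookkeeping). Each fragment is located in the subject by shared 15-mer
seeding on both strands; the best diagonal is the most-seeded one, and the
fraction of the fragment spanned by seeds within ±100 bp of that diagonal
is its alignable coverage. Fragments with coverage ≥ 0.70 are aligned
semi-globally (edlib, banded by the window) and kept if identity ≥ 0.30
over aligned columns; ANI is the mean identity of kept fragments × 100.
Self-ANI is exactly 100; for JC-mutated pairs ANI tracks 100(1 − p_obs)
within 0.5 points up to p ≈ 0.1; unrelated sequence finds (almost) no seeds
and is excluded, rather than dragging the mean down. Pairwise ANI is
symmetrized as the mean of the two directions; species clusters are
connected components of the ≥ 95 % graph. The seed-extent coverage is a
deliberate approximation to local-alignment coverage chosen for speed; it
is lenient at high divergence, where the identity filter dominates anyway.

## Core-SNP phylogeny

Each single-copy core family is aligned by center-star MSA: the center
minimizes the summed pairwise edit distances (edlib), others are aligned to
it by global DP with gaps strictly costlier than mismatches (match 1,
mismatch −1, open −4, extend −2) — substitution-only homologs therefore
align gap-free instead of taking equal-edit-cost shifted paths — and gaps
merge by once-a-gap-always-a-gap. Alignments are concatenated in the order
of the genes on a reference genome; columns containing any gap or ambiguous
character are dropped (complete deletion) and remaining polymorphic columns
form the SNP matrix, with per-site provenance.

Distances over SNP columns are p-distances by default; Jukes–Cantor
(−(3/4)ln(1 − 4p/3), undefined at p ≥ 3/4) and Poisson (−ln(1 − p), the
protein correction) are options. Neighbor joining is the canonical
Saitou–Nei agglomeration with the Q criterion, ties broken by the
lexicographically smallest label pair, and negative branch lengths clamped
to zero with the deficit moved to the sibling edge; on additive matrices NJ
provably recovers the generating topology, which the suite verifies against
random trees. Bootstrap resamples SNP columns with replacement (default 100
replicates); support for each original bipartition is the percentage of
replicates containing it, attached as internal node labels in the Newick
output. Trees are unrooted; optional rooting on a named outgroup.

## Cluster screening and GC deviation

BSR(query, genome) = best global-alignment score of the query against the
genome's annotated gene set / the query's self-score, clamped to [0, 1].
Cells are called present (≥ 0.8), divergent ([0.4, 0.8)) or absent (< 0.4);
a cluster is present in a genome when ≥ 0.8 of its genes are present. All
thresholds are parameters. Screening runs against annotated gene sets, not
raw genomes — symmetric with orthology and avoiding six-frame searches.

GC deviation: region GC and genome GC are computed over unambiguous bases
only. The null distribution is the GC of non-overlapping 10-kb windows
tiling the genome, excluding windows overlapping the regions under test
(so a large insertion cannot contaminate its own null — important on
desk-scale genomes where a cluster is a sizable genome fraction). A region
is flagged when |z| ≥ 2; regions < 200 bp are reported as low-confidence.
Note that the reported ΔGC (region − whole genome) shrinks on small
genomes because the whole-genome average itself includes the deviant
region.

## Pairwise dN/dS (NG86)

Synonymous site counts average, per codon position, the fraction of the
three single-base changes preserving the amino acid; changes creating a
stop count as nonsynonymous, preserving S + N = 3 × codons. Site counts are
averaged over the two sequences. Codons differing at k positions average
Sd/Nd over all k! minimal pathways, excluding pathways through stop codons
(all pathways are used in the degenerate case where every one is blocked).
pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected; ω = dN/dS. ω is
*undefined* (never 0 or ∞ silently) when dS = 0 or a proportion reaches the
JC pole at 3/4; shared terminal stop codons are stripped. The bacterial
code (table 11) is fixed. The implementation is verified against exhaustive
pathway enumeration on all 4096 codon pairs. Because the simulator's
substitution process is neutral, cross-lineage ω on synthetic core genes
centers on 1; the purifying-selection regime (ω < 1) arises only from real
data or synonymous-biased inputs.

## Numerical and interface conventions

Internal coordinates are 0-based half-open; GFF3 on disk is 1-based
inclusive (conversions are involutive and property-tested). Ambiguous
nucleotides are retained in sequences but excluded from GC and identity
denominators. Matrices are TSV with headers; trees are Newick with supports
as internal labels; fits are JSON. Every stochastic step takes an explicit
seed (numpy Generator); identical config + seed reproduces output byte for
byte, independent of file or dict ordering.

## Problem sizes

The test suite and the acceptance script run on clades of 6–14 genomes with
25–120 core families, genes of 300–900 bp and genomes of ~20–80 kb — large
enough for every statistic to be in its asymptotic regime (hundreds of
fragments, thousands of SNP columns) while keeping each stage in seconds to
a few minutes. All algorithms scale to real bacterial genomes; the
all-vs-all orthology stage is the dominant cost there and exposes its
k-mer prefilter and thresholds for tuning.
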