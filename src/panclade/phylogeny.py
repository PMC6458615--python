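"""Core-SNP phylogeny: center-star MSA, SNP extraction, NJ, bootstrap.

Single-copy core genes are aligned per family with a center-star multiple
alignment (the center is the sequence minimizing the sum of pairwise edit
distances; all others are aligned to it by global dynamic programming and
merged with once-a-gap-always-a-gap).  Alignments are concatenated in a
reference gene order, columns with gaps or ambiguous characters are dropped
(complete deletion), and the remaining polymorphic columns form the SNP
matrix.  Trees are built by canonical Saitou-Nei neighbor joining on
p-distances (Jukes-Cantor and Poisson corrections available) and supported
by column-resampling bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import edlib
import numpy as np
import pandas as pd
from Bio import Align


# ---------------------------------------------------------------------------
# center-star multiple alignment
# ---------------------------------------------------------------------------

# gaps strictly costlier than mismatches, so substitution-only homologs
# align gap-free instead of via equal-edit-cost shifted paths
_STAR_ALIGNER = Align.PairwiseAligner()
_STAR_ALIGNER.mode = "global"
_STAR_ALIGNER.match_score = 1.0
_STAR_ALIGNER.mismatch_score = -1.0
_STAR_ALIGNER.open_gap_score = -4.0
_STAR_ALIGNER.extend_gap_score = -2.0


def _pairwise_aligned(query: str, target: str) -> tuple[str, str]:
    """Globally aligned (query_row, target_row) strings."""
    aln = _STAR_ALIGNER.align(query, target)[0]
    return aln[0], aln[1]


def center_star_msa(seqs: dict[str, str]) -> dict[str, str]:
    """Center-star multiple alignment; deterministic (ties by taxon id)."""
    if not seqs:
        raise ValueError("center_star_msa requires >= 1 sequence")
    taxa = sorted(seqs)
    if any(not seqs[t] for t in taxa):
        raise ValueError("center_star_msa: empty sequence")
    if len(taxa) == 1:
        return dict(seqs)
    # center = argmin of summed pairwise edit distances, ties to smallest id
    totals = {}
    for t in taxa:
        totals[t] = sum(
            edlib.align(seqs[t], seqs[u], mode="NW", task="distance")["editDistance"]
            for u in taxa
            if u != t
        )
    center = min(taxa, key=lambda t: (totals[t], t))

    master = seqs[center]  # center row with accumulated gaps
    rows: dict[str, str] = {center: master}
    for t in taxa:
        if t == center:
            continue
        s_aln, c_aln = _pairwise_aligned(seqs[t], seqs[center])
        new_master: list[str] = []
        new_row: list[str] = []
        inserts: list[tuple[int, int]] = []  # (position in old master, gap run)
        i = j = 0
        while i < len(master) or j < len(c_aln):
            if i < len(master) and master[i] == "-":
                # gap column introduced by an earlier sequence
                new_master.append("-")
                new_row.append("-")
                i += 1
            elif j < len(c_aln) and c_aln[j] == "-":
                # insertion in the new sequence: open a gap for all others
                inserts.append((i, 1))
                new_master.append("-")
                new_row.append(s_aln[j])
                j += 1
            else:
                new_master.append(master[i])
                new_row.append(s_aln[j])
                i += 1
                j += 1
        # replay the insertions into previously aligned rows
        if inserts:
            for u in rows:
                old = rows[u]
                out: list[str] = []
                nxt = 0
                ins_iter = iter(inserts)
                pending = next(ins_iter, None)
                for pos_i in range(len(old) + 1):
                    while pending is not None and pending[0] == pos_i:
                        out.append("-" * pending[1])
                        pending = next(ins_iter, None)
                    if pos_i < len(old):
                        out.append(old[pos_i])
                rows[u] = "".join(out)
        master = "".join(new_master)
        rows[t] = "".join(new_row)
    assert len({len(v) for v in rows.values()}) == 1
    return {t: rows[t] for t in taxa}


# ---------------------------------------------------------------------------
# SNP concatenation
# ---------------------------------------------------------------------------

@dataclass
class SnpMatrix:
    taxa: list[str]
    columns: np.ndarray  # (n_taxa, n_sites) of single characters
    provenance: list[tuple[str, int]]  # (gene_id, column offset in its alignment)

    @property
    def n_sites(self) -> int:
        return self.columns.shape[1]


def concat_and_extract_snps(
    alignments: dict[str, dict[str, str]], gene_order: list[str]
) -> SnpMatrix:
    """Concatenate per-gene alignments in reference order and keep SNP columns.

    Columns containing any gap or non-ACGT character are dropped entirely;
    remaining columns are kept iff polymorphic.  Site provenance (gene,
    offset) is retained.
    """
    if not gene_order:
        raise ValueError("gene_order is empty")
    taxa = sorted(alignments[gene_order[0]])
    cols: list[list[str]] = []
    provenance: list[tuple[str, int]] = []
    for gene in gene_order:
        block = alignments[gene]
        if sorted(block) != taxa:
            raise ValueError(f"gene {gene}: taxa differ from other genes")
        length = len(next(iter(block.values())))
        if any(len(block[t]) != length for t in taxa):
            raise ValueError(f"gene {gene}: unequal alignment row lengths")
        mat = np.array([list(block[t]) for t in taxa])
        for offset in range(length):
            col = mat[:, offset]
            if not np.all(np.isin(col, list("ACGT"))):
                continue
            if len(set(col)) >= 2:
                cols.append(list(col))
                provenance.append((gene, offset))
    columns = (
        np.array(cols).T if cols else np.empty((len(taxa), 0), dtype="<U1")
    )
    return SnpMatrix(taxa=taxa, columns=columns, provenance=provenance)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def snp_distance_matrix(snps: SnpMatrix, model: str = "p") -> pd.DataFrame:
    """Pairwise distances over SNP columns.

    model: 'p' (proportion of differing sites), 'jc' (Jukes-Cantor
    correction, undefined at p >= 0.75) or 'poisson' (-ln(1-p), the
    Poisson correction used for protein distances).
    """
    n = len(snps.taxa)
    d = np.zeros((n, n))
    if snps.n_sites == 0:
        return pd.DataFrame(d, index=snps.taxa, columns=snps.taxa)
    for i in range(n):
        for j in range(i + 1, n):
            p = float(np.mean(snps.columns[i] != snps.columns[j]))
            d[i, j] = d[j, i] = _correct_distance(p, model)
    return pd.DataFrame(d, index=snps.taxa, columns=snps.taxa)


def _correct_distance(p: float, model: str) -> float:
    if model == "p":
        return p
    if model == "jc":
        if p >= 0.75:
            raise ValueError(f"JC distance undefined at p = {p:.4f} >= 0.75")
        return -0.75 * np.log(1.0 - 4.0 * p / 3.0)
    if model == "poisson":
        if p >= 1.0:
            raise ValueError("Poisson distance undefined at p >= 1")
        return -np.log(1.0 - p)
    raise ValueError(f"unknown distance model {model!r}")


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: pd.DataFrame) -> str:
    """Canonical Saitou-Nei neighbor joining; returns an unrooted newick.

    Ties in the Q criterion are broken by the lexicographically smallest
    (label_i, label_j) pair; negative branch lengths are clamped to zero
    with the deficit moved to the sibling edge.
    """
    labels = list(dm.index)
    if len(labels) < 3:
        raise ValueError("nj_tree requires >= 3 taxa")
    mat = dm.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(mat < 0) or not np.allclose(np.diag(mat), 0):
        raise ValueError("distances must be non-negative with zero diagonal")

    nodes = [(lab, lab) for lab in labels]  # (tie-break key, newick repr)
    d = {(a, b): mat[i, j] for i, (a, _) in enumerate(nodes) for j, (b, _) in enumerate(nodes)}

    def dist(a: str, b: str) -> float:
        return 0.0 if a == b else d[(a, b)]

    active = [key for key, _ in nodes]
    reprs = {key: rep for key, rep in nodes}
    while len(active) > 3:
        m = len(active)
        r = {a: sum(dist(a, b) for b in active) for a in active}
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = active[ii], active[jj]
                q = (m - 2) * dist(a, b) - r[a] - r[b]
                key = (q, *sorted((a, b)))
                if best is None or key < best:
                    best = key
        _, a, b = best  # a < b lexicographically
        dab = dist(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        if la < 0:
            la, lb = 0.0, dab
        if lb < 0:
            la, lb = dab, 0.0
        new_key = min(a, b)
        new_rep = f"({reprs[a]}:{la:.10g},{reprs[b]}:{lb:.10g})"
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (dist(a, c) + dist(b, c) - dab)
            d[(new_key, c)] = d[(c, new_key)] = max(duc, 0.0)
        active = [c for c in active if c not in (a, b)]
        active.append(new_key)
        active.sort()
        reprs[new_key] = new_rep

    x, y, z = active
    lx = 0.5 * (dist(x, y) + dist(x, z) - dist(y, z))
    ly = 0.5 * (dist(x, y) + dist(y, z) - dist(x, z))
    lz = 0.5 * (dist(x, z) + dist(y, z) - dist(x, y))
    lx, ly, lz = (max(v, 0.0) for v in (lx, ly, lz))
    return f"({reprs[x]}:{lx:.10g},{reprs[y]}:{ly:.10g},{reprs[z]}:{lz:.10g});"


def parse_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def root_at_outgroup(newick: str, outgroup: str) -> str:
    """Root the tree on the edge leading to the named outgroup leaf."""
    tree = parse_tree(newick)
    node = tree.find_node_with_taxon_label(outgroup)
    if node is None:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    tree.reroot_at_edge(node.edge, update_bipartitions=False)
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def split_key(side: set[str] | frozenset[str], taxa: list[str]) -> frozenset[str]:
    """Canonical name of an unrooted split: the side not containing the
    alphabetically first taxon.  Use to look up bipartition supports."""
    ref = min(taxa)
    side = frozenset(side)
    return side if ref not in side else frozenset(taxa) - side


def bipartitions(newick: str) -> set[frozenset[str]]:
    """Non-trivial unrooted bipartitions, each named by the side not
    containing the alphabetically first taxon (root-independent)."""
    tree = parse_tree(newick)
    taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    ref = taxa[0]
    full = frozenset(taxa)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        side = below if ref not in below else full - below
        if 2 <= len(side) <= len(full) - 2:
            out.add(side)
    return out


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@dataclass
class SupportedTree:
    newick: str  # supports as internal node labels
    supports: dict[frozenset[str], float]  # bipartition -> percent


def bootstrap_support(
    snps: SnpMatrix,
    n_reps: int = 100,
    seed: int = 0,
    model: str = "p",
) -> SupportedTree:
    """Column-resampling bootstrap support for the NJ tree of a SNP matrix."""
    if snps.n_sites < 1:
        raise ValueError("bootstrap requires >= 1 SNP column")
    base_newick = nj_tree(snp_distance_matrix(snps, model))
    base_bips = bipartitions(base_newick)
    counts = {bip: 0 for bip in base_bips}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        idx = rng.integers(0, snps.n_sites, size=snps.n_sites)
        rep = SnpMatrix(
            taxa=snps.taxa,
            columns=snps.columns[:, idx],
            provenance=[snps.provenance[i] for i in idx],
        )
        rep_bips = bipartitions(nj_tree(snp_distance_matrix(rep, model)))
        for bip in base_bips:
            if bip in rep_bips:
                counts[bip] += 1
    supports = {bip: 100.0 * c / n_reps for bip, c in counts.items()}

    tree = parse_tree(base_newick)
    taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    ref, full = taxa[0], frozenset(taxa)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        side = below if ref not in below else full - below
        if side in supports:
            node.label = f"{supports[side]:g}"
    newick = tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()
    return SupportedTree(newick=newick, supports=supports)
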