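"""Fragment-based average nucleotide identity (ANI) and species delineation.

The query genome is cut into consecutive fixed-length fragments (1020 bp by
convention; trailing partial fragments are discarded).  Each fragment is
placed in the subject by shared-k-mer seeding on the best diagonal (both
strands).  The fraction of the fragment spanned by seeds near that diagonal
is its alignable coverage; fragments passing ``min_fragment_coverage`` are
aligned semi-globally in a band around the diagonal and kept iff their
identity reaches ``min_fragment_identity``.  ANI is the mean identity of
kept fragments, in percent.  Non-homologous fragments find no seeds (or
seeds spanning too little of the fragment) and fail the coverage filter,
as in the fragment-ANI convention.  Genome pairs with ANI >= 95% are conventionally conspecific;
species clusters are the connected components of that graph.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import networkx as nx
import numpy as np
import pandas as pd

from panclade.io import GenomeRecord, reverse_complement

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class ANIParams:
    fragment_length: int = 1020
    min_fragment_identity: float = 0.30
    min_fragment_coverage: float = 0.70
    seed_kmer: int = 15
    band_pad: int = 100

    def validate(self) -> None:
        if self.fragment_length <= 0:
            raise ValueError("fragment_length must be > 0")
        for name in ("min_fragment_identity", "min_fragment_coverage"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")


@dataclass
class ANIResult:
    query: str
    subject: str
    ani: float | None  # percent; None when no fragment passed the filters
    n_fragments_used: int
    n_fragments_total: int


def _sequences(genome: GenomeRecord | dict[str, str] | str) -> dict[str, str]:
    if isinstance(genome, GenomeRecord):
        return genome.sequences
    if isinstance(genome, str):
        return {"seq": genome}
    return genome


def _strain_id(genome, fallback: str) -> str:
    return genome.strain_id if isinstance(genome, GenomeRecord) else fallback


def fragments(sequences: dict[str, str], fragment_length: int) -> list[str]:
    """Consecutive fragments per contig; trailing partials discarded."""
    out = []
    for name in sequences:
        seq = sequences[name]
        for i in range(0, len(seq) - fragment_length + 1, fragment_length):
            out.append(seq[i : i + fragment_length])
    return out


def build_kmer_index(sequences: dict[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for name in sorted(sequences):
        seq = sequences[name]
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((name, i))
    return index


@dataclass
class _SeedHit:
    contig: str
    diag: int
    n_seeds: int
    coverage: float  # fraction of the fragment spanned by seeds near the diagonal


def _best_diagonal(
    fragment: str, index: dict[str, list[tuple[str, int]]], k: int, pad: int
) -> _SeedHit | None:
    """Most-seeded diagonal plus the fragment extent its seeds span."""
    counts: dict[tuple[str, int], int] = {}
    qpos_by_key: dict[tuple[str, int], list[int]] = {}
    for qpos in range(len(fragment) - k + 1):
        for contig, tpos in index.get(fragment[qpos : qpos + k], ()):
            key = (contig, tpos - qpos)
            counts[key] = counts.get(key, 0) + 1
            qpos_by_key.setdefault(key, []).append(qpos)
    if not counts:
        return None
    (contig, diag), n = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    # seeds on nearby diagonals (within the band) count toward the extent
    qmin, qmax = len(fragment), -1
    for (c, dg), positions in qpos_by_key.items():
        if c == contig and abs(dg - diag) <= pad:
            qmin = min(qmin, min(positions))
            qmax = max(qmax, max(positions))
    coverage = (qmax + k - qmin) / len(fragment) if qmax >= 0 else 0.0
    return _SeedHit(contig=contig, diag=diag, n_seeds=n, coverage=coverage)


def _align_fragment(
    fragment: str, sequences: dict[str, str], contig: str, diag: int, pad: int
) -> float:
    """Identity of the fragment aligned (banded, semi-global) in its window."""
    target = sequences[contig]
    lo = max(0, diag - pad)
    hi = min(len(target), diag + len(fragment) + pad)
    window = target[lo:hi]
    res = edlib.align(fragment, window, mode="HW", task="path")
    matches = columns = 0
    for num, op in _CIGAR_RE.findall(res["cigar"] or ""):
        n = int(num)
        columns += n
        if op == "=":
            matches += n
    return matches / columns if columns else 0.0


def compute_ani(
    query: GenomeRecord | dict[str, str] | str,
    subject: GenomeRecord | dict[str, str] | str,
    params: ANIParams = ANIParams(),
    _subject_index: dict | None = None,
) -> ANIResult:
    """One-directional fragment ANI of query against subject."""
    params.validate()
    qseqs = _sequences(query)
    sseqs = _sequences(subject)
    if not any(qseqs.values()) or not any(sseqs.values()):
        raise ValueError("compute_ani requires non-empty genomes")
    index = _subject_index or build_kmer_index(sseqs, params.seed_kmer)
    identities = []
    frags = fragments(qseqs, params.fragment_length)
    for frag in frags:
        fwd = _best_diagonal(frag, index, params.seed_kmer, params.band_pad)
        rc = reverse_complement(frag)
        rev = _best_diagonal(rc, index, params.seed_kmer, params.band_pad)
        if fwd is None and rev is None:
            continue
        if rev is None or (fwd is not None and fwd.n_seeds >= rev.n_seeds):
            hit, seq = fwd, frag
        else:
            hit, seq = rev, rc
        if hit.coverage < params.min_fragment_coverage:
            continue
        ident = _align_fragment(seq, sseqs, hit.contig, hit.diag, params.band_pad)
        if ident >= params.min_fragment_identity:
            identities.append(ident)
    ani = 100.0 * float(np.mean(identities)) if identities else None
    return ANIResult(
        query=_strain_id(query, "query"),
        subject=_strain_id(subject, "subject"),
        ani=ani,
        n_fragments_used=len(identities),
        n_fragments_total=len(frags),
    )


def ani_matrix_and_species(
    genomes: list[GenomeRecord],
    params: ANIParams = ANIParams(),
    cutoff: float = 95.0,
) -> tuple[pd.DataFrame, list[set[str]], list[tuple[str, str]]]:
    """Symmetrized pairwise ANI matrix plus >= cutoff species clusters.

    Pairwise ANI is the mean of the two directions.  Pairs where both
    directions are undefined are excluded from the species graph and
    reported in the third return value.
    """
    if len(genomes) < 2:
        raise ValueError("need >= 2 genomes")
    ids = [g.strain_id for g in genomes]
    index_cache = {
        g.strain_id: build_kmer_index(g.sequences, params.seed_kmer) for g in genomes
    }
    mat = pd.DataFrame(np.full((len(ids), len(ids)), np.nan), index=ids, columns=ids)
    np.fill_diagonal(mat.values, 100.0)
    undefined: list[tuple[str, str]] = []
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(ids)
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1 :]:
            fwd = compute_ani(ga, gb, params, _subject_index=index_cache[gb.strain_id])
            rev = compute_ani(gb, ga, params, _subject_index=index_cache[ga.strain_id])
            vals = [r.ani for r in (fwd, rev) if r.ani is not None]
            if not vals:
                undefined.append((ga.strain_id, gb.strain_id))
                continue
            ani = float(np.mean(vals))
            mat.loc[ga.strain_id, gb.strain_id] = ani
            mat.loc[gb.strain_id, ga.strain_id] = ani
            if ani >= cutoff:
                graph.add_edge(ga.strain_id, gb.strain_id)
    clusters = sorted(
        (set(c) for c in nx.connected_components(graph)), key=lambda c: sorted(c)[0]
    )
    return mat, clusters, undefined
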