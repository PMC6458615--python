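"""Blast-score-ratio screening of gene clusters and GC-deviation HGT flags.

The blast score ratio (BSR) of a query gene against a genome is the score
of its best alignment to that genome's gene set divided by the query's
self-alignment score, clamped to [0, 1]: 1 means a verbatim copy, values
near 0 mean no credible homolog.  Cells are called present (>= 0.8),
divergent ([0.4, 0.8)) or absent (< 0.4); a cluster is called present in a
genome when at least a fraction f (default 0.8) of its genes are present.

Horizontally acquired regions are flagged by GC deviation: each region's
GC is compared with the null distribution of non-overlapping fixed-size
windows tiling the host genome, and |z| >= threshold flags the region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from panclade.io import GenomeRecord, gc_fraction
from panclade.orthology import Scoring, _candidate_hits, _kmers, _make_aligner

BSR_PRESENT = 0.8
BSR_DIVERGENT = 0.4


def bsr_call(bsr: float, present: float = BSR_PRESENT, divergent: float = BSR_DIVERGENT) -> str:
    if bsr >= present:
        return "present"
    if bsr >= divergent:
        return "divergent"
    return "absent"


def compute_bsr(
    query_gene: str,
    gene_set: dict[str, str],
    scoring: Scoring = Scoring(),
    kmer: int = 5,
    prefilter: bool = True,
) -> float:
    """Best-hit score of the query against a gene set over its self-score."""
    if not query_gene:
        raise ValueError("query gene is empty")
    aligner = _make_aligner(scoring)
    self_score = aligner.score(query_gene, query_gene)
    assert self_score > 0, "self-score must be positive under a positive match score"
    if prefilter:
        index: dict[str, list[str]] = {}
        for gid in sorted(gene_set):
            for km in _kmers(gene_set[gid], kmer):
                index.setdefault(km, []).append(gid)
        candidates = _candidate_hits(query_gene, index, kmer, 1)
    else:
        candidates = sorted(gene_set)
    best = 0.0
    for cand in candidates:
        best = max(best, aligner.score(query_gene, gene_set[cand]))
    return float(min(max(best / self_score, 0.0), 1.0))


@dataclass
class ClusterScreenResult:
    bsr: pd.DataFrame  # rows: (cluster, gene) MultiIndex; columns: genomes
    calls: pd.DataFrame  # same shape, present/divergent/absent strings
    summary: pd.DataFrame  # rows: clusters; columns: genomes; boolean present


def screen_clusters(
    clusters: dict[str, dict[str, str]],
    panel: dict[str, dict[str, str]],
    scoring: Scoring = Scoring(),
    present_threshold: float = BSR_PRESENT,
    divergent_threshold: float = BSR_DIVERGENT,
    cluster_presence_fraction: float = 0.8,
) -> ClusterScreenResult:
    """Screen reference gene clusters against a panel of genome gene sets.

    ``clusters`` maps cluster name -> {gene_id: protein sequence} from the
    reference genome; ``panel`` maps genome id -> {gene_id: protein}.
    """
    if not clusters or not panel:
        raise ValueError("need >= 1 cluster and >= 1 panel genome")
    genomes = sorted(panel)
    rows = []
    index = []
    for cname in sorted(clusters):
        genes = clusters[cname]
        if not genes:
            continue  # zero-gene clusters are skipped
        for gid in sorted(genes):
            index.append((cname, gid))
            rows.append(
                [compute_bsr(genes[gid], panel[g], scoring) for g in genomes]
            )
    bsr = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["cluster", "gene"]),
        columns=genomes,
    )
    calls = bsr.map(lambda v: bsr_call(v, present_threshold, divergent_threshold))
    present = calls == "present"
    summary = present.groupby(level="cluster").mean() >= cluster_presence_fraction
    return ClusterScreenResult(bsr=bsr, calls=calls, summary=summary)


# ---------------------------------------------------------------------------
# GC deviation scan
# ---------------------------------------------------------------------------

@dataclass
class GCDeviationReport:
    region_id: str
    region_gc: float
    genome_gc: float
    delta_gc_points: float  # percentage points, region minus genome
    z_score: float
    flagged: bool
    low_confidence: bool


def tiling_window_gc(
    seq: str, window: int, exclude: list[tuple[int, int]] | None = None
) -> np.ndarray:
    """GC of non-overlapping windows tiling a contig.

    Windows overlapping any ``exclude`` interval are dropped, so the null
    distribution reflects the host background rather than the regions under
    test.  The trailing partial window is kept only when it is the sole one.
    """
    exclude = exclude or []
    gcs = []
    for i in range(0, len(seq) - window + 1, window):
        if any(i < e and s < i + window for s, e in exclude):
            continue
        gcs.append(gc_fraction(seq[i : i + window]))
    if not gcs:
        gcs.append(gc_fraction(seq))
    return np.array(gcs)


def gc_deviation_scan(
    genome: GenomeRecord,
    regions: list[tuple[str, str, int, int]] | None = None,
    window: int = 10_000,
    z_threshold: float = 2.0,
) -> list[GCDeviationReport]:
    """GC deviation of regions against the genome's tiling-window null.

    ``regions`` is a list of (region_id, contig, start, end) with internal
    0-based half-open coordinates; by default the genome's annotated
    clusters are scanned.  Regions shorter than 200 bp are reported but
    marked low-confidence.
    """
    if regions is None:
        regions = [(c.name, c.contig, c.start, c.end) for c in genome.clusters]
    exclude_by_contig: dict[str, list[tuple[int, int]]] = {}
    for _rid, contig, start, end in regions:
        exclude_by_contig.setdefault(contig, []).append((start, end))
    window_gcs = np.concatenate(
        [
            tiling_window_gc(
                genome.sequences[name], window, exclude_by_contig.get(name)
            )
            for name in sorted(genome.sequences)
        ]
    )
    null_mean = float(window_gcs.mean())
    null_sd = float(window_gcs.std(ddof=1)) if len(window_gcs) > 1 else 0.0
    genome_gc = gc_fraction("".join(genome.sequences[n] for n in sorted(genome.sequences)))
    reports = []
    for region_id, contig, start, end in regions:
        if contig not in genome.sequences:
            raise ValueError(f"region {region_id}: unknown contig {contig}")
        if not 0 <= start < end <= len(genome.sequences[contig]):
            raise ValueError(f"region {region_id}: [{start},{end}) out of bounds")
        region_gc = gc_fraction(genome.sequences[contig][start:end])
        z = (region_gc - null_mean) / null_sd if null_sd > 0 else 0.0
        reports.append(
            GCDeviationReport(
                region_id=region_id,
                region_gc=region_gc,
                genome_gc=genome_gc,
                delta_gc_points=100.0 * (region_gc - genome_gc),
                z_score=float(z),
                flagged=abs(z) >= z_threshold,
                low_confidence=(end - start) < 200,
            )
        )
    return reports


def gc_reports_frame(reports: list[GCDeviationReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region": r.region_id,
                "region_gc": r.region_gc,
                "genome_gc": r.genome_gc,
                "delta_gc_points": r.delta_gc_points,
                "z_score": r.z_score,
                "flagged": r.flagged,
                "low_confidence": r.low_confidence,
            }
            for r in reports
        ]
    )
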