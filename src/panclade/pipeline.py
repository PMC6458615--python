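"""End-to-end stage runners operating on an on-disk dataset layout.

A dataset directory (as written by :func:`panclade.simulate.write_dataset`,
or assembled by hand from real annotations) holds per-strain files under
``genomes/``: ``<strain>.fna`` (genome FASTA), ``<strain>.gff`` (gene and
gene_cluster features), plus optional ``<strain>_cds.fna`` / ``<strain>.faa``.
Each stage reads those or earlier stage outputs and writes TSV/Newick/JSON
into its own output directory, never mutating its inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from panclade import ani as ani_mod
from panclade import orthology, pangenome, phylogeny, screening, selection
from panclade.io import GenomeRecord, read_genome
from panclade.simulate import CladeConfig, simulate_clade, write_dataset


def load_genomes(data_dir: str | Path) -> list[GenomeRecord]:
    gdir = Path(data_dir) / "genomes"
    fastas = sorted(gdir.glob("*.fna"))
    fastas = [f for f in fastas if not f.name.endswith("_cds.fna")]
    if not fastas:
        raise FileNotFoundError(f"no genome FASTA files under {gdir}")
    genomes = []
    for fasta in fastas:
        strain = fasta.stem
        gff = gdir / f"{strain}.gff"
        genomes.append(read_genome(strain, fasta, gff if gff.exists() else None))
    return genomes


def run_simulate(config: CladeConfig, outdir: str | Path) -> None:
    dataset = simulate_clade(config)
    write_dataset(dataset, outdir)


def run_cluster(
    data_dir: str | Path,
    outdir: str | Path,
    min_identity: float = 0.5,
    min_score: float = 0.0,
) -> list[orthology.GeneFamily]:
    genomes = load_genomes(data_dir)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    proteomes = {g.strain_id: g.proteome() for g in genomes}
    edges = orthology.build_rbh_graph(
        proteomes, min_identity=min_identity, min_score=min_score
    )
    all_genes = [
        (g.strain_id, gene.gene_id) for g in genomes for gene in g.genes
    ]
    families = orthology.cluster_families(edges, all_genes)
    orthology.write_families_tsv(families, out / "families.tsv")
    core = orthology.single_copy_core(families, sorted(proteomes))
    orthology.write_families_tsv(core, out / "single_copy_core.tsv")
    return families


def run_pangenome(
    families_tsv: str | Path,
    outdir: str | Path,
    n_permutations: int = 100,
    seed: int = 0,
) -> dict:
    families = orthology.read_families_tsv(families_tsv)
    genomes = sorted({s for fam in families for s, _ in fam.members})
    counts = {
        fam.family_id: {g: fam.copy_number(g) for g in fam.strains()}
        for fam in families
    }
    matrix = pangenome.presence_matrix(counts, genomes)
    curve = pangenome.accumulation_curves(matrix, n_permutations, seed)
    heaps = pangenome.fit_heaps(curve)
    decay = pangenome.fit_core_decay(curve)
    n_singleton, frac = pangenome.singleton_stats(matrix)
    pan, core = pangenome.pan_core_sizes(matrix)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    curve.to_frame().to_csv(out / "accumulation_curve.tsv", sep="\t", index=False)
    fits = {
        "heaps": {"kappa": heaps.kappa, "gamma": heaps.gamma, "r2": heaps.r2},
        "core_decay": {
            "amplitude": decay.amplitude, "tau": decay.tau, "omega": decay.omega,
        },
        "pan_size": pan,
        "core_size": core,
        "n_singleton": n_singleton,
        "singleton_fraction": frac,
        "n_permutations": n_permutations,
        "seed": seed,
    }
    with open(out / "pangenome_fits.json", "w") as fh:
        json.dump(fits, fh, indent=2)
    return fits


def run_ani(
    data_dir: str | Path,
    outdir: str | Path,
    cutoff: float = 95.0,
    params: ani_mod.ANIParams = ani_mod.ANIParams(),
) -> tuple[pd.DataFrame, list[set[str]]]:
    genomes = load_genomes(data_dir)
    matrix, clusters, undefined = ani_mod.ani_matrix_and_species(genomes, params, cutoff)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(out / "ani_matrix.tsv", sep="\t")
    with open(out / "species_clusters.tsv", "w") as fh:
        fh.write("cluster\tstrains\n")
        for i, cl in enumerate(clusters, start=1):
            fh.write(f"species_{i}\t{','.join(sorted(cl))}\n")
    with open(out / "ani_params.json", "w") as fh:
        json.dump(
            {
                "fragment_length": params.fragment_length,
                "min_fragment_identity": params.min_fragment_identity,
                "min_fragment_coverage": params.min_fragment_coverage,
                "seed_kmer": params.seed_kmer,
                "cutoff": cutoff,
                "undefined_pairs": [list(p) for p in undefined],
            },
            fh,
            indent=2,
        )
    return matrix, clusters


def _reference_gene_order(
    reference: GenomeRecord, core: list[orthology.GeneFamily]
) -> list[str]:
    """Single-copy core family ids ordered by gene position on the reference."""
    pos = {g.gene_id: (g.contig, g.start) for g in reference.genes}
    order = []
    for fam in core:
        for strain, gene in fam.members:
            if strain == reference.strain_id:
                order.append((pos[gene], fam.family_id))
    order.sort()
    return [fam_id for _, fam_id in order]


def run_phylo(
    data_dir: str | Path,
    cluster_dir: str | Path,
    outdir: str | Path,
    reference: str | None = None,
    n_bootstrap: int = 100,
    seed: int = 0,
    model: str = "p",
    outgroup: str | None = None,
) -> phylogeny.SupportedTree:
    genomes = {g.strain_id: g for g in load_genomes(data_dir)}
    core = orthology.read_families_tsv(Path(cluster_dir) / "single_copy_core.tsv")
    if not core:
        raise ValueError("no single-copy core families; cannot build a tree")
    ref_id = reference or sorted(genomes)[0]
    gene_order = _reference_gene_order(genomes[ref_id], core)
    cds_of = {
        strain: {g.gene_id: g.cds for g in rec.genes} for strain, rec in genomes.items()
    }
    alignments: dict[str, dict[str, str]] = {}
    for fam in core:
        seqs = {strain: cds_of[strain][gene] for strain, gene in fam.members}
        alignments[fam.family_id] = phylogeny.center_star_msa(seqs)
    snps = phylogeny.concat_and_extract_snps(alignments, gene_order)
    dm = phylogeny.snp_distance_matrix(snps, model)
    supported = phylogeny.bootstrap_support(snps, n_bootstrap, seed, model)
    newick = supported.newick
    if outgroup is not None:
        newick = phylogeny.root_at_outgroup(newick, outgroup)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dm.to_csv(out / "snp_distances.tsv", sep="\t")
    with open(out / "tree.nwk", "w") as fh:
        fh.write(newick + "\n")
    with open(out / "snp_sites.tsv", "w") as fh:
        fh.write("gene\toffset\n")
        for gene, offset in snps.provenance:
            fh.write(f"{gene}\t{offset}\n")
    return supported


def run_screen(
    data_dir: str | Path,
    outdir: str | Path,
    reference: str | None = None,
    window: int = 10_000,
    z_threshold: float = 2.0,
) -> screening.ClusterScreenResult:
    genomes = load_genomes(data_dir)
    by_id = {g.strain_id: g for g in genomes}
    ref_id = reference
    if ref_id is None:
        annotated = sorted(g.strain_id for g in genomes if g.clusters)
        if not annotated:
            raise ValueError("no genome carries cluster annotations to screen")
        ref_id = annotated[0]
    ref = by_id[ref_id]
    proteins = ref.proteome()
    clusters = {
        c.name: {gid: proteins[gid] for gid in c.genes} for c in ref.clusters
    }
    panel = {g.strain_id: g.proteome() for g in genomes}
    result = screening.screen_clusters(clusters, panel)
    reports = []
    for g in genomes:
        for rep in screening.gc_deviation_scan(g, window=window, z_threshold=z_threshold):
            reports.append({"strain": g.strain_id, **screening.gc_reports_frame([rep]).iloc[0].to_dict()})
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.bsr.to_csv(out / "bsr_matrix.tsv", sep="\t")
    result.summary.to_csv(out / "cluster_summary.tsv", sep="\t")
    pd.DataFrame(reports).to_csv(out / "gc_report.tsv", sep="\t", index=False)
    return result


def run_dnds(cds_fasta: str | Path, outdir: str | Path) -> pd.DataFrame:
    """All-pairs NG86 on an in-frame CDS FASTA of equal-length sequences."""
    from panclade.io import parse_fasta

    seqs = parse_fasta(cds_fasta)
    names = list(seqs)
    if len(names) < 2:
        raise ValueError("dN/dS needs >= 2 sequences")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            r = selection.ng86_pairwise(seqs[a], seqs[b])
            rows.append(
                {
                    "seq1": a, "seq2": b, "S": r.s_sites, "N": r.n_sites,
                    "Sd": r.s_diffs, "Nd": r.n_diffs, "pS": r.ps, "pN": r.pn,
                    "dS": r.ds, "dN": r.dn, "omega": r.omega,
                    "classification": r.classification,
                }
            )
    df = pd.DataFrame(rows)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "dnds.tsv", sep="\t", index=False)
    return df
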