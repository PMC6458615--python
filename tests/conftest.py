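import pytest

from panclade.simulate import (
    BranchLengths,
    CladeConfig,
    HgtClusterSpec,
    simulate_clade,
)


@pytest.fixture(scope="session")
def two_lineage_clade():
    """Small two-lineage clade with one lineage-restricted HGT cluster.

    Low divergence (terminal 0.005, stem 0.02) so orthology and screening
    can be checked exactly against the truth table.
    """
    config = CladeConfig(
        n_genomes=6,
        lineage_assignment=["P"] * 3 + ["L"] * 3,
        n_core=25,
        n_accessory=10,
        accessory_presence_prob=0.5,
        singleton_rate=2.0,
        gene_length_range=(300, 450),
        tree_branch_lengths=BranchLengths(stem=0.02, terminal=0.005),
        hgt_clusters=[
            HgtClusterSpec(
                cluster_name="bac",
                n_genes=5,
                target_gc=0.35,
                recipient_genomes=["P01", "P02", "P03"],
                gene_length=1200,
            )
        ],
        base_gc=0.5,
        seed=7,
    )
    return simulate_clade(config)


@pytest.fixture(scope="session")
def clade_families(two_lineage_clade):
    """RBH families recovered from the fixture clade's proteomes."""
    from panclade import orthology

    ds = two_lineage_clade
    edges = orthology.build_rbh_graph(ds.proteomes())
    all_genes = [(g.strain_id, x.gene_id) for g in ds.genomes for x in g.genes]
    return orthology.cluster_families(edges, all_genes)
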