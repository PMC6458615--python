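"""Synthetic two-lineage clade generator with complete ground truth.

The simulator emulates a small bacterial clade of the kind comparative
pan-genomics studies analyze: N genomes split into tight lineages (plus
optional outliers), gene families partitioned into core / accessory /
singleton classes, tree-structured Jukes-Cantor nucleotide substitution,
and laterally transferred gene clusters whose GC composition deviates from
the host genome.  Every emitted gene is recorded in a :class:`TruthTable`
so downstream stages (orthology, pan-genome fits, ANI, phylogeny,
screening, selection) can be tested against known truth.

Layout conventions: genes are non-overlapping, forward strand, separated by
fixed 100-bp intergenic spacers.  Each CDS starts with ATG, ends with TAA,
and contains no internal stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

from panclade.io import (
    ClusterInterval,
    GeneFeature,
    GenomeRecord,
    gc_fraction,
    translate_cds,
    write_fasta,
    write_gff,
)

SPACER_LENGTH = 100
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}


class CladeConfigError(ValueError):
    """Invalid simulator configuration; the message names the field."""


@dataclass
class BranchLengths:
    """Expected substitutions/site on lineage stems and terminal branches."""

    stem: float = 0.02
    terminal: float = 0.005


@dataclass
class HgtClusterSpec:
    """A laterally transferred gene cluster to splice into recipient genomes."""

    cluster_name: str
    n_genes: int
    target_gc: float
    recipient_genomes: list[str]
    insertion_locus: int | str = "end"
    gene_length: int = 1500

    def validate(self) -> None:
        if self.n_genes < 1:
            raise CladeConfigError(f"n_genes must be >= 1 (cluster {self.cluster_name})")
        if not 0 < self.target_gc < 1:
            raise CladeConfigError(f"target_gc must be in (0,1) (cluster {self.cluster_name})")
        if not self.recipient_genomes:
            raise CladeConfigError(f"recipient_genomes empty (cluster {self.cluster_name})")
        if self.gene_length % 3 != 0 or self.gene_length < 9:
            raise CladeConfigError(f"gene_length must be a multiple of 3 >= 9 (cluster {self.cluster_name})")

    @property
    def total_length(self) -> int:
        """Inserted region length: genes plus internal spacers."""
        return self.n_genes * self.gene_length + (self.n_genes - 1) * SPACER_LENGTH


@dataclass
class CladeConfig:
    n_genomes: int = 14
    lineage_assignment: list[str] = field(default_factory=lambda: ["P"] * 7 + ["L"] * 7)
    n_core: int = 120
    n_accessory: int = 60
    accessory_presence_prob: float = 0.5
    accessory_lineage_restricted: bool = False
    singleton_rate: float = 5.0
    gene_length_range: tuple[int, int] = (300, 900)
    tree_branch_lengths: BranchLengths = field(default_factory=BranchLengths)
    hgt_clusters: list[HgtClusterSpec] = field(default_factory=list)
    base_gc: float = 0.467
    seed: int = 0

    def validate(self) -> None:
        if self.n_genomes < 2:
            raise CladeConfigError("n_genomes must be >= 2")
        if len(self.lineage_assignment) != self.n_genomes:
            raise CladeConfigError("lineage_assignment length must equal n_genomes")
        if self.n_core < 0:
            raise CladeConfigError("n_core must be >= 0")
        if self.n_accessory < 0:
            raise CladeConfigError("n_accessory must be >= 0")
        if not 0 <= self.accessory_presence_prob <= 1:
            raise CladeConfigError("accessory_presence_prob must be in [0,1]")
        if self.singleton_rate < 0:
            raise CladeConfigError("singleton_rate must be >= 0")
        lo, hi = self.gene_length_range
        if lo % 3 or hi % 3 or lo < 9 or hi < lo:
            raise CladeConfigError("gene_length_range bounds must be multiples of 3, >= 9, lo <= hi")
        if self.tree_branch_lengths.stem < 0 or self.tree_branch_lengths.terminal < 0:
            raise CladeConfigError("tree_branch_lengths must be >= 0")
        if not 0 < self.base_gc < 1:
            raise CladeConfigError("base_gc must be in (0,1)")
        for spec in self.hgt_clusters:
            spec.validate()
        ids = self.genome_ids()
        for spec in self.hgt_clusters:
            unknown = set(spec.recipient_genomes) - set(ids)
            if unknown:
                raise CladeConfigError(
                    f"recipient_genomes not in clade: {sorted(unknown)} (cluster {spec.cluster_name})"
                )

    def genome_ids(self) -> list[str]:
        """Deterministic strain ids: lineage label + within-lineage ordinal."""
        counts: dict[str, int] = {}
        ids = []
        for lin in self.lineage_assignment:
            counts[lin] = counts.get(lin, 0) + 1
            ids.append(f"{lin}{counts[lin]:02d}")
        return ids

    def lineages(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gid, lin in zip(self.genome_ids(), self.lineage_assignment):
            out.setdefault(lin, []).append(gid)
        return out


@dataclass
class TruthTable:
    """Ground truth for a simulated clade."""

    gene_to_family: dict[tuple[str, str], str]
    family_class: dict[str, str]  # core | accessory | singleton | hgt
    cluster_to_recipients: dict[str, list[str]]
    true_tree: str  # newick

    def presence_counts(self) -> dict[str, dict[str, int]]:
        """family -> genome -> copy count, rebuilt from gene_to_family."""
        table: dict[str, dict[str, int]] = {}
        for (strain, _gene), fam in self.gene_to_family.items():
            row = table.setdefault(fam, {})
            row[strain] = row.get(strain, 0) + 1
        return table

    def families_of_class(self, cls: str) -> list[str]:
        return sorted(f for f, c in self.family_class.items() if c == cls)


@dataclass
class SyntheticDataset:
    config: CladeConfig
    genomes: list[GenomeRecord]
    truth: TruthTable

    def genome(self, strain_id: str) -> GenomeRecord:
        for g in self.genomes:
            if g.strain_id == strain_id:
                return g
        raise KeyError(strain_id)

    def proteomes(self) -> dict[str, dict[str, str]]:
        return {g.strain_id: g.proteome() for g in self.genomes}

    def cds_sets(self) -> dict[str, dict[str, str]]:
        return {g.strain_id: g.cds_set() for g in self.genomes}


# ---------------------------------------------------------------------------
# sequence-level primitives
# ---------------------------------------------------------------------------

def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    """I.i.d. nucleotides with P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode()


@lru_cache(maxsize=None)
def _cds_sampling_gc(target_gc: float) -> float:
    """Base-sampling GC whose non-stop codons average ``target_gc``.

    Rejecting the AT-rich stop codons enriches realized GC by up to ~1
    percentage point, so the sampling bias is solved for by bisection.
    """
    from itertools import product

    codons = ["".join(c) for c in product("ACGT", repeat=3)]

    def realized(g: float) -> float:
        p = {"A": (1 - g) / 2, "T": (1 - g) / 2, "G": g / 2, "C": g / 2}
        tot = gc = 0.0
        for codon in codons:
            if codon in _STOPS:
                continue
            prob = p[codon[0]] * p[codon[1]] * p[codon[2]]
            tot += prob
            gc += prob * sum(b in "GC" for b in codon) / 3
        return gc / tot

    lo, hi = 1e-6, 1 - 1e-6
    for _ in range(60):
        mid = (lo + hi) / 2
        if realized(mid) < target_gc:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def random_cds(length: int, gc: float, rng: np.random.Generator) -> str:
    """ATG + random non-stop codons + TAA, GC-calibrated base sampling."""
    if length % 3 or length < 9:
        raise CladeConfigError("CDS length must be a multiple of 3 and >= 9")
    n_internal = length // 3 - 2
    sampling_gc = _cds_sampling_gc(round(gc, 6))
    codons = []
    while len(codons) < n_internal:
        chunk = random_sequence(3 * (n_internal - len(codons)), sampling_gc, rng)
        for i in range(0, len(chunk), 3):
            codon = chunk[i : i + 3]
            if codon not in _STOPS:
                codons.append(codon)
            if len(codons) == n_internal:
                break
    return "ATG" + "".join(codons) + "TAA"


def evolve_sequence(seq: str, branch_length: float, seed: int | np.random.Generator) -> str:
    """Jukes-Cantor substitution along one branch.

    Each site changes with probability (3/4)(1 - e^(-4d/3)), to one of the
    three other bases uniformly — the exact JC transition probabilities, so
    the process composes correctly across consecutive branches.  Non-ACGT
    characters are left untouched.
    """
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    if branch_length == 0 or not seq:
        return seq
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_change = 0.75 * (1.0 - np.exp(-4.0 * branch_length / 3.0))
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    code = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        code[b] = i
    idx = code[arr]
    valid = idx >= 0
    hit = (rng.random(arr.size) < p_change) & valid
    shift = rng.integers(1, 4, size=arr.size)
    new_idx = (idx + shift) % 4
    arr[hit] = _BASES[new_idx[hit]]
    return arr.tobytes().decode()


def _evolve_cds(cds: str, branch_length: float, rng: np.random.Generator) -> str:
    """Evolve a CDS under JC, then revert any codon that became a stop.

    Keeps start/stop structure intact so proteins stay translatable; the
    deviation from pure JC affects ~p^1 of a few AT-rich codons only.
    """
    out = evolve_sequence(cds, branch_length, rng)
    body = list(out)
    body[0:3] = cds[0:3]  # keep start codon
    body[-3:] = cds[-3:]  # keep stop codon
    for i in range(3, len(cds) - 3, 3):
        if "".join(body[i : i + 3]) in _STOPS:
            body[i : i + 3] = cds[i : i + 3]
    return "".join(body)


def build_hgt_cluster(
    spec: HgtClusterSpec, rng: np.random.Generator
) -> tuple[str, list[tuple[str, int, int]]]:
    """Generate the cluster region once: (sequence, [(gene_id, start, end)])."""
    spec.validate()
    parts: list[str] = []
    coords: list[tuple[str, int, int]] = []
    pos = 0
    for j in range(spec.n_genes):
        if j > 0:
            parts.append(random_sequence(SPACER_LENGTH, spec.target_gc, rng))
            pos += SPACER_LENGTH
        cds = random_cds(spec.gene_length, spec.target_gc, rng)
        gene_id = f"{spec.cluster_name}_g{j + 1:02d}"
        coords.append((gene_id, pos, pos + len(cds)))
        parts.append(cds)
        pos += len(cds)
    return "".join(parts), coords


def insert_hgt_cluster(
    genome_seq: str, spec: HgtClusterSpec, seed: int | np.random.Generator
) -> tuple[str, ClusterInterval, list[tuple[str, int, int]]]:
    """Splice a freshly generated cluster into a genome sequence.

    Returns the new sequence, the cluster interval on it, and absolute
    (gene_id, start, end) coordinates of the inserted genes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    region, rel = build_hgt_cluster(spec, rng)
    locus = len(genome_seq) if spec.insertion_locus == "end" else int(spec.insertion_locus)
    if not 0 <= locus <= len(genome_seq):
        raise CladeConfigError(
            f"insertion_locus {locus} outside genome of length {len(genome_seq)} "
            f"(cluster {spec.cluster_name})"
        )
    new_seq = genome_seq[:locus] + region + genome_seq[locus:]
    interval = ClusterInterval(
        name=spec.cluster_name, contig="", start=locus, end=locus + len(region),
        genes=[g for g, _, _ in rel],
    )
    abs_coords = [(g, locus + s, locus + e) for g, s, e in rel]
    return new_seq, interval, abs_coords


# ---------------------------------------------------------------------------
# clade simulation
# ---------------------------------------------------------------------------

def _true_tree_newick(config: CladeConfig) -> str:
    stem = config.tree_branch_lengths.stem
    term = config.tree_branch_lengths.terminal
    parts = []
    for lin, members in sorted(config.lineages().items()):
        leaves = ",".join(f"{m}:{term:g}" for m in members)
        if len(members) == 1:
            parts.append(f"{members[0]}:{stem + term:g}")
        else:
            parts.append(f"({leaves}):{stem:g}")
    return f"({','.join(parts)});"


def simulate_clade(config: CladeConfig) -> SyntheticDataset:
    """Simulate a clade per the configuration; fully seeded and deterministic."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome_ids = config.genome_ids()
    lineages = config.lineages()
    lineage_of = dict(zip(genome_ids, config.lineage_assignment))
    stem = config.tree_branch_lengths.stem
    term = config.tree_branch_lengths.terminal
    lo, hi = config.gene_length_range

    def draw_length() -> int:
        return 3 * int(rng.integers(lo // 3, hi // 3 + 1))

    # --- family plan -------------------------------------------------------
    families: list[str] = []
    family_class: dict[str, str] = {}
    presence: dict[str, list[str]] = {}  # family -> recipient genomes
    for i in range(config.n_core):
        fam = f"C{i + 1:05d}"
        families.append(fam)
        family_class[fam] = "core"
        presence[fam] = list(genome_ids)
    lineage_labels = sorted(lineages)
    for i in range(config.n_accessory):
        fam = f"A{i + 1:05d}"
        families.append(fam)
        family_class[fam] = "accessory"
        if config.accessory_lineage_restricted:
            lin = lineage_labels[int(rng.integers(len(lineage_labels)))]
            pool = lineages[lin]
        else:
            pool = genome_ids
        draws = rng.random(len(pool)) < config.accessory_presence_prob
        members = [g for g, keep in zip(pool, draws) if keep]
        if not members:  # keep family count fixed: re-home to one random genome
            members = [pool[int(rng.integers(len(pool)))]]
        presence[fam] = members

    # --- ancestral sequences and tree-structured evolution -----------------
    # Each family carries its downstream intergenic spacer, which is inherited
    # and evolves with it, so intergenic DNA diverges at the same rate as genes.
    ancestral: dict[str, tuple[str, str]] = {
        fam: (
            random_cds(draw_length(), config.base_gc, rng),
            random_sequence(SPACER_LENGTH, config.base_gc, rng),
        )
        for fam in families
    }
    lineage_seqs: dict[str, dict[str, tuple[str, str]]] = {}
    for lin in lineage_labels:
        lineage_seqs[lin] = {
            fam: (
                _evolve_cds(ancestral[fam][0], stem, rng),
                evolve_sequence(ancestral[fam][1], stem, rng),
            )
            for fam in families
        }

    gene_to_family: dict[tuple[str, str], str] = {}
    # per genome: (gene_id, family, cds, downstream spacer)
    genome_gene_lists: dict[str, list[tuple[str, str, str, str]]] = {}
    for gid in genome_ids:
        lin = lineage_of[gid]
        entries: list[tuple[str, str, str, str]] = []
        for fam in families:
            if gid in presence[fam]:
                cds0, spacer0 = lineage_seqs[lin][fam]
                cds = _evolve_cds(cds0, term, rng)
                spacer = evolve_sequence(spacer0, term, rng)
                entries.append((f"{gid}_{fam}", fam, cds, spacer))
        n_single = int(rng.poisson(config.singleton_rate))
        for s in range(n_single):
            fam = f"S_{gid}_{s + 1:03d}"
            family_class[fam] = "singleton"
            cds = random_cds(draw_length(), config.base_gc, rng)
            spacer = random_sequence(SPACER_LENGTH, config.base_gc, rng)
            entries.append((f"{gid}_{fam}", fam, cds, spacer))
        genome_gene_lists[gid] = entries

    # --- HGT clusters (one realization, shared verbatim by recipients) -----
    cluster_regions: dict[str, tuple[str, list[tuple[str, int, int]]]] = {}
    for spec in config.hgt_clusters:
        cluster_regions[spec.cluster_name] = build_hgt_cluster(spec, rng)
        for j in range(spec.n_genes):
            family_class[f"H_{spec.cluster_name}_g{j + 1:02d}"] = "hgt"

    # --- assemble genomes --------------------------------------------------
    genomes: list[GenomeRecord] = []
    for gid in genome_ids:
        contig = f"{gid}_chr"
        parts: list[str] = [random_sequence(SPACER_LENGTH, config.base_gc, rng)]
        pos = SPACER_LENGTH
        genes: list[GeneFeature] = []
        for gene_id, fam, cds, spacer in genome_gene_lists[gid]:
            genes.append(
                GeneFeature(
                    gene_id=gene_id, contig=contig, start=pos, end=pos + len(cds),
                    strand="+", cds=cds, protein=translate_cds(cds),
                )
            )
            gene_to_family[(gid, gene_id)] = fam
            parts.append(cds)
            pos += len(cds)
            parts.append(spacer)
            pos += SPACER_LENGTH
        clusters: list[ClusterInterval] = []
        for spec in config.hgt_clusters:
            if gid not in spec.recipient_genomes:
                continue
            region, rel = cluster_regions[spec.cluster_name]
            start = pos
            for gname, s, e in rel:
                gene_id = f"{gid}_{gname}"
                genes.append(
                    GeneFeature(
                        gene_id=gene_id, contig=contig, start=start + s, end=start + e,
                        strand="+", cds=region[s:e], protein=translate_cds(region[s:e]),
                    )
                )
                gene_to_family[(gid, gene_id)] = f"H_{gname}"
            parts.append(region)
            pos += len(region)
            clusters.append(
                ClusterInterval(
                    name=spec.cluster_name, contig=contig, start=start, end=pos,
                    genes=[f"{gid}_{g}" for g, _, _ in rel],
                )
            )
            parts.append(random_sequence(SPACER_LENGTH, config.base_gc, rng))
            pos += SPACER_LENGTH
        rec = GenomeRecord(
            strain_id=gid, sequences={contig: "".join(parts)},
            genes=genes, clusters=clusters,
        )
        rec.validate()
        genomes.append(rec)

    truth = TruthTable(
        gene_to_family=gene_to_family,
        family_class=family_class,
        cluster_to_recipients={
            spec.cluster_name: list(spec.recipient_genomes) for spec in config.hgt_clusters
        },
        true_tree=_true_tree_newick(config),
    )
    return SyntheticDataset(config=config, genomes=genomes, truth=truth)


# ---------------------------------------------------------------------------
# on-disk emission
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Emit per-strain FASTA/GFF3/CDS/protein files plus truth TSVs and tree."""
    out = Path(outdir)
    gdir = out / "genomes"
    tdir = out / "truth"
    gdir.mkdir(parents=True, exist_ok=True)
    tdir.mkdir(parents=True, exist_ok=True)
    for rec in dataset.genomes:
        write_fasta(rec.sequences, gdir / f"{rec.strain_id}.fna")
        write_gff(rec, gdir / f"{rec.strain_id}.gff")
        write_fasta(rec.cds_set(), gdir / f"{rec.strain_id}_cds.fna")
        write_fasta(rec.proteome(), gdir / f"{rec.strain_id}.faa")
    with open(tdir / "gene_to_family.tsv", "w") as fh:
        fh.write("strain\tgene\tfamily\n")
        for (strain, gene), fam in sorted(dataset.truth.gene_to_family.items()):
            fh.write(f"{strain}\t{gene}\t{fam}\n")
    with open(tdir / "family_class.tsv", "w") as fh:
        fh.write("family\tclass\n")
        for fam in sorted(dataset.truth.family_class):
            fh.write(f"{fam}\t{dataset.truth.family_class[fam]}\n")
    with open(tdir / "cluster_recipients.tsv", "w") as fh:
        fh.write("cluster\trecipients\n")
        for name, rec_ids in sorted(dataset.truth.cluster_to_recipients.items()):
            fh.write(f"{name}\t{','.join(rec_ids)}\n")
    with open(tdir / "true_tree.nwk", "w") as fh:
        fh.write(dataset.truth.true_tree + "\n")


def cluster_gc_check(dataset: SyntheticDataset, cluster_name: str) -> dict[str, float]:
    """Realized GC of an inserted cluster per recipient genome."""
    out: dict[str, float] = {}
    for rec in dataset.genomes:
        for c in rec.clusters:
            if c.name == cluster_name:
                out[rec.strain_id] = gc_fraction(rec.sequences[c.contig][c.start : c.end])
    return out
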