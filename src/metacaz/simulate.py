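"""Ground-truthed synthetic metagenome bundles for end-to-end testing.

The generator emulates the *structure* of a gut shotgun-metagenome
analysis without any sequence realism: a ranked bacterial taxonomy, a
Dirichlet community over genera, contigs carrying genes, noisy gene-level
taxonomic top hits (a configurable fraction violating the E-value /
identity filters, a rate ``misassignment_rate`` pointing at the wrong
genus), read counts drawn multinomially proportional to abundance x
length, and three-channel enzyme-annotation evidence with stated
per-channel sensitivity and false-positive rates.  Every random draw
flows through one seeded generator, so a bundle regenerates
byte-identically from its config.

Proteins are random amino-acid strings except where the peptide
classifier needs planted family peptides; nothing downstream of the
parsed tables inspects sequence content otherwise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .abundance import AbundanceProfile, SampleMeta, sample_abundance_profile
from .cazyme import AMINO_ACIDS, DomainHit, ECEvidence, PeptideHit
from .taxonomy import GeneHit, TaxonomyTree, write_taxonomy

#: family, EC, substrate triples planted on annotated genes by default.
DEFAULT_INVENTORY = (
    ("GH18", "3.2.1.14", "Chitin"),
    ("GH20", "3.2.1.52", "Chitin"),
    ("GH55", "3.2.1.58", "β-Glucan"),
    ("GH81", "3.2.1.39", "β-Glucan"),
    ("GH5", "3.2.1.4", "Cellulose"),
    ("GH10", "3.2.1.8", "Hemicellulose"),
    ("GH38", "3.2.1.24", "Mannan"),
    ("GH76", "3.2.1.-", "Mannan"),
    ("GH2", "3.2.1.23", "Galactan"),
    ("PL1", "4.2.2.2", "Pectin"),
)

EC_CHANNELS = ("enzyme_homology", "orthology_group", "kegg_mapper")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults emulate one deeply-annotated sample.

    Community and catalogue sizes (60 genera over 10 orders, 500 contigs
    with ~40 genes each, 2x10^5 mapped reads of 150 bp) put the typical
    contig in the regime the vote-filtered consensus is designed for:
    well over 20 classified genes, so that both single and double
    wrong-genus votes fall below the 10% support cutoff.  Gene-level
    noise is a 5% misassignment rate and ~10% of hits failing the
    alignment-quality filters.
    """

    seed: int = 0
    sample_id: str = "S1"
    # taxonomy / community
    n_phyla: int = 5
    n_orders: int = 10
    n_genera: int = 60
    concentration: float = 1.0
    # contig catalogue
    n_contigs: int = 500
    contig_length_meanlog: float = 10.4
    contig_length_sdlog: float = 0.35
    genes_per_contig_mean: float = 40.0
    # gene-level taxonomic hits
    misassignment_rate: float = 0.05
    filter_violation_rate: float = 0.10
    # sequencing
    read_depth: int = 200_000
    read_length_bp: int = 150
    # annotation channels
    sensitivity: float = 0.9
    false_positive_rate: float = 0.05
    annotated_fraction: float = 0.30
    overlap_rate: float = 0.10
    inventory: tuple = DEFAULT_INVENTORY

    def __post_init__(self) -> None:
        for name in ("misassignment_rate", "filter_violation_rate", "sensitivity",
                     "false_positive_rate", "annotated_fraction", "overlap_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for name in ("n_phyla", "n_orders", "n_genera", "n_contigs", "read_depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


# -- taxonomy & community ----------------------------------------------------------------


def make_taxonomy(config: SimulationConfig) -> TaxonomyTree:
    """Balanced-ish ranked tree root -> superkingdom -> phylum -> ... -> genus.

    Orders are distributed round-robin over phyla (one class per phylum),
    genera round-robin over orders (one family per order).  Construction
    is deterministic, so the same tree is shared across samples of a
    study.
    """
    records = [("root", "root", "root", "root"), ("sk1", "root", "superkingdom", "Bacteria")]
    for p in range(config.n_phyla):
        records.append((f"p{p + 1}", "sk1", "phylum", f"Phylum_{p + 1}"))
        records.append((f"c{p + 1}", f"p{p + 1}", "class", f"Class_{p + 1}"))
    for o in range(config.n_orders):
        phylum = o % config.n_phyla
        records.append((f"o{o + 1}", f"c{phylum + 1}", "order", f"Order_{o + 1}"))
        records.append((f"f{o + 1}", f"o{o + 1}", "family", f"Family_{o + 1}"))
    for g in range(config.n_genera):
        order = g % config.n_orders
        records.append((f"g{g + 1}", f"f{order + 1}", "genus", f"Genus_{g + 1}"))
    return TaxonomyTree.from_records(records)


#: Diet presets: order position -> Dirichlet-weight multiplier.  The first two
#: orders play the Bacteroidales/Clostridiales role (heavy in fungus farmers),
#: the third the Spirochaetales role (heavy in wood feeders).
DIET_PRESETS: Mapping[str, Mapping[int, float]] = {
    "fungus": {0: 8.0, 1: 8.0},
    "wood": {2: 8.0, 0: 1.5, 1: 1.5},
    "litter": {2: 4.0, 3: 2.0},
    "humus": {3: 3.0, 4: 3.0},
    "dung": {4: 2.0, 5: 2.0},
    "soil": {5: 3.0, 6: 3.0},
}


def make_community(
    config: SimulationConfig,
    tree: TaxonomyTree,
    rng: np.random.Generator,
    preset: str | None = None,
) -> pd.Series:
    """Dirichlet draw of genus abundances (sums to 1), optionally diet-biased."""
    genera = tree.taxa_at_rank("genus")
    alpha = np.full(len(genera), config.concentration)
    if preset is not None:
        weights = DIET_PRESETS[preset]
        for i, genus in enumerate(genera):
            order_id = tree.lineage_at_rank(genus, "order")
            order_pos = int(order_id[1:]) - 1
            alpha[i] *= weights.get(order_pos, 1.0)
    values = rng.dirichlet(alpha)
    return pd.Series(values, index=pd.Index(genera, name="taxon_id"), name="abundance")


# -- contigs, genes, reads ---------------------------------------------------------------


def make_contigs_genes(
    config: SimulationConfig,
    community: pd.Series,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign contigs to genera proportional to abundance; draw lengths and genes.

    Contig lengths are log-normal; gene counts per contig are Poisson
    (floored at 1) and gene ids follow ``<contig>_<n>``.  Each contig
    carries an ``ab_share`` column: its genus's abundance divided by the
    genus's contig count, the ground-truth share of community mass the
    contig represents.
    """
    genera = list(community.index)
    genus_of = rng.choice(len(genera), size=config.n_contigs, p=community.to_numpy())
    lengths = np.maximum(
        500,
        rng.lognormal(config.contig_length_meanlog, config.contig_length_sdlog,
                      config.n_contigs).astype(int),
    )
    n_genes = np.maximum(1, rng.poisson(config.genes_per_contig_mean, config.n_contigs))
    counts = np.bincount(genus_of, minlength=len(genera))
    contigs = pd.DataFrame(
        {
            "contig_id": [f"contig{i + 1}" for i in range(config.n_contigs)],
            "length_bp": lengths,
            "genus": [genera[i] for i in genus_of],
            "n_genes": n_genes,
        }
    )
    contigs["ab_share"] = [
        community.iloc[g] / counts[g] for g in genus_of
    ]
    gene_rows = [
        (f"{contig}_{j + 1}", contig, genus)
        for contig, genus, k in zip(contigs["contig_id"], contigs["genus"], n_genes)
        for j in range(int(k))
    ]
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "contig_id", "true_genus"])
    return contigs, genes


def make_read_counts(
    config: SimulationConfig, contigs: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, SampleMeta]:
    """Multinomial mapped reads, probability proportional to ab_share x length."""
    weights = contigs["ab_share"].to_numpy() * contigs["length_bp"].to_numpy()
    reads = rng.multinomial(config.read_depth, weights / weights.sum())
    out = contigs.copy()
    out["mapped_reads"] = reads
    meta = SampleMeta(
        sample_id=config.sample_id,
        total_clean_bases=float(config.read_depth * config.read_length_bp),
        read_length_bp=config.read_length_bp,
    )
    return out, meta


def make_gene_hits(
    config: SimulationConfig,
    genes: pd.DataFrame,
    tree: TaxonomyTree,
    rng: np.random.Generator,
) -> list[GeneHit]:
    """Noisy top-hit tables per gene.

    With probability ``1 - misassignment_rate`` the top hit carries the
    true genus, otherwise a uniformly-chosen other genus.  A configured
    fraction of genes get hits violating the E-value/identity filters
    (split evenly between the two violations) and therefore drop out of
    classification.  Each gene may also get a lower-scoring decoy hit.
    """
    genera = tree.taxa_at_rank("genus")
    hits: list[GeneHit] = []
    for gene_id, contig_id, true_genus in genes[
        ["gene_id", "contig_id", "true_genus"]
    ].itertuples(index=False):
        if rng.random() < config.misassignment_rate and len(genera) > 1:
            taxon = true_genus
            while taxon == true_genus:
                taxon = genera[int(rng.integers(len(genera)))]
        else:
            taxon = true_genus
        if rng.random() < config.filter_violation_rate:
            if rng.random() < 0.5:
                evalue = 10.0 ** rng.uniform(-4.9, -2.0)  # fails E-value cutoff
                identity = rng.uniform(40.0, 95.0)
            else:
                evalue = 10.0 ** rng.uniform(-30.0, -6.0)
                identity = rng.uniform(15.0, 29.9)  # fails identity cutoff
        else:
            evalue = 10.0 ** rng.uniform(-30.0, -6.0)
            identity = rng.uniform(35.0, 99.0)
        top_score = rng.uniform(200.0, 500.0)
        hits.append(
            GeneHit(gene_id=gene_id, contig_id=contig_id, subject_taxon=taxon,
                    evalue=evalue, percent_identity=identity, bit_score=top_score)
        )
        if rng.random() < 0.7:  # decoy below the top hit
            hits.append(
                GeneHit(
                    gene_id=gene_id, contig_id=contig_id,
                    subject_taxon=genera[int(rng.integers(len(genera)))],
                    evalue=10.0 ** rng.uniform(-20.0, -6.0),
                    percent_identity=rng.uniform(30.0, 90.0),
                    bit_score=top_score - rng.uniform(20.0, 150.0),
                )
            )
    return hits


# -- annotation evidence -----------------------------------------------------------------


def make_annotation_tables(
    config: SimulationConfig, genes: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, list[DomainHit], list[PeptideHit], list[ECEvidence]]:
    """Plant family/EC truth on a fraction of genes; emit noisy channel evidence.

    Every channel reports the true label with probability ``sensitivity``
    and, independently, a random wrong label with probability
    ``false_positive_rate`` (unannotated genes can only produce the
    latter).  A fraction ``overlap_rate`` of true HMM hits is shadowed by
    a shorter overlapping domain of another family, exercising the
    longest-match resolution rule.
    """
    families = [fam for fam, _, _ in config.inventory]
    ecs = [ec for _, ec, _ in config.inventory]
    truth = genes.copy()
    annotated = rng.random(len(genes)) < config.annotated_fraction
    planted = rng.integers(len(config.inventory), size=len(genes))
    truth["family"] = [
        families[planted[i]] if annotated[i] else None for i in range(len(genes))
    ]
    truth["ec"] = [ecs[planted[i]] if annotated[i] else None for i in range(len(genes))]

    s, f = config.sensitivity, config.false_positive_rate
    domain_hits: list[DomainHit] = []
    peptide_hits: list[PeptideHit] = []
    ec_evidence: list[ECEvidence] = []

    def wrong(options: Sequence[str], exclude: str | None) -> str:
        choice = exclude
        while choice == exclude:
            choice = options[int(rng.integers(len(options)))]
        return choice

    def domain(gene_id: str, family: str, start: int, length: int) -> DomainHit:
        return DomainHit(
            gene_id=gene_id, family=family, align_start=start, align_end=start + length - 1,
            profile_length=max(20, length + int(rng.integers(-10, 11))),
            evalue=10.0 ** rng.uniform(-30.0, -6.0),
        )

    for row in truth.itertuples(index=False):
        fam, ec = row.family, row.ec
        if fam is not None:
            if rng.random() < s:
                start = int(rng.integers(1, 150))
                length = int(rng.integers(120, 300))
                domain_hits.append(domain(row.gene_id, fam, start, length))
                if rng.random() < config.overlap_rate:
                    # shorter overlapping distractor; the longest-match rule removes it
                    d_start = start + int(rng.integers(0, length // 2))
                    d_length = int(rng.integers(30, max(31, length - 20)))
                    domain_hits.append(
                        domain(row.gene_id, wrong(families, fam), d_start, d_length)
                    )
            if rng.random() < s:
                n = int(rng.integers(2, 9))
                peptide_hits.append(
                    PeptideHit(row.gene_id, fam, n_matched=n, score=float(n * 3))
                )
        if rng.random() < f:
            domain_hits.append(
                domain(row.gene_id, wrong(families, fam),
                       start=int(rng.integers(600, 800)), length=int(rng.integers(60, 200)))
            )
        if rng.random() < f:
            peptide_hits.append(
                PeptideHit(row.gene_id, wrong(families, fam), n_matched=2, score=6.0)
            )
        for channel in EC_CHANNELS:
            if ec is not None and rng.random() < s:
                ec_evidence.append(ECEvidence(row.gene_id, channel, ec))
            if rng.random() < f:
                ec_evidence.append(ECEvidence(row.gene_id, channel, wrong(ecs, ec)))
    return truth, domain_hits, peptide_hits, ec_evidence


# -- protein helpers for the peptide classifier ------------------------------------------


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def protein_with_peptides(
    rng: np.random.Generator, peptides: Sequence[str], length: int = 300
) -> str:
    """Random protein with the given peptides planted at spaced positions."""
    seq = list(random_protein(rng, length))
    slot = max(len(p) for p in peptides) + 4
    for i, pep in enumerate(peptides):
        start = (i * slot) % max(1, length - len(pep))
        seq[start : start + len(pep)] = pep
    return "".join(seq)


def family_training_set(
    rng: np.random.Generator, motifs: Sequence[str], n_sequences: int = 5, length: int = 300
) -> list[str]:
    """Training proteins all sharing the family's motif set."""
    return [protein_with_peptides(rng, motifs, length) for _ in range(n_sequences)]


# -- bundle ------------------------------------------------------------------------------


@dataclass
class FixtureBundle:
    """A complete synthetic input set plus the ground truth behind it."""

    config: SimulationConfig
    tree: TaxonomyTree
    community: pd.Series = field(repr=False)
    contigs: pd.DataFrame = field(repr=False)
    genes: pd.DataFrame = field(repr=False)
    gene_hits: list = field(repr=False)
    domain_hits: list = field(repr=False)
    peptide_hits: list = field(repr=False)
    ec_evidence: list = field(repr=False)
    sample_meta: SampleMeta = None

    # ---- ground truth views

    @property
    def true_contig_taxa(self) -> dict[str, str]:
        return dict(zip(self.contigs["contig_id"], self.contigs["genus"]))

    @property
    def true_genus_composition(self) -> pd.Series:
        """Realized genus composition of the contig catalogue (sums to 1).

        Genera that received no contig cannot be recovered from any
        downstream table, so the truth is the community renormalized over
        genera present in the catalogue.
        """
        shares = self.contigs.groupby("genus")["ab_share"].sum()
        return (shares / shares.sum()).rename("abundance")

    def abundance_profile(self) -> AbundanceProfile:
        """Realized coverage-based contig abundances (from the drawn read counts)."""
        return sample_abundance_profile(
            self.contigs[["contig_id", "length_bp", "mapped_reads"]], self.sample_meta
        )

    def true_enzyme_profile(self, display_scale: float = 1e6) -> pd.Series:
        """Join of planted gene->EC truth with realized contig abundances."""
        profile = self.abundance_profile()
        sums: dict[str, float] = {}
        for gene_id, contig_id, ec in self.genes[["gene_id", "contig_id", "ec"]].itertuples(
            index=False
        ):
            if ec is None:
                continue
            sums[ec] = sums.get(ec, 0.0) + float(profile.abundances[contig_id])
        return pd.Series(
            {ec: display_scale * v for ec, v in sorted(sums.items())}, dtype=float
        )

    @property
    def true_families(self) -> set[tuple[str, str]]:
        return {
            (g, fam)
            for g, fam in zip(self.genes["gene_id"], self.genes["family"])
            if fam is not None
        }

    @property
    def true_ecs(self) -> set[tuple[str, str]]:
        return {
            (g, ec) for g, ec in zip(self.genes["gene_id"], self.genes["ec"]) if ec is not None
        }

    # ---- serialization

    def write(self, outdir: str | Path) -> None:
        """Write every dialect the pipeline reads, plus ground truth and config."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_taxonomy(self.tree, outdir / "nodes.dmp", outdir / "names.dmp")
        mio.write_contig_table(
            self.contigs[["contig_id", "length_bp", "mapped_reads"]], outdir / "contigs.tsv"
        )
        mio.write_gene_hits(self.gene_hits, outdir / "gene_hits.tsv")
        mio.write_domain_tsv(self.domain_hits, outdir / "domain_hits.tsv")
        mio.write_peptide_hits(self.peptide_hits, outdir / "peptide_hits.tsv")
        mio.write_ec_evidence(self.ec_evidence, outdir / "ec_evidence.tsv")
        with open(outdir / "sample.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "sample_id": self.sample_meta.sample_id,
                    "total_clean_bases": self.sample_meta.total_clean_bases,
                    "read_length_bp": self.sample_meta.read_length_bp,
                },
                fh, sort_keys=True,
            )
        truth_dir = outdir / "truth"
        truth_dir.mkdir(exist_ok=True)
        self.community.to_csv(truth_dir / "community.tsv", sep="\t")
        self.contigs.to_csv(truth_dir / "contigs.tsv", sep="\t", index=False)
        self.genes.to_csv(truth_dir / "genes.tsv", sep="\t", index=False)
        with open(outdir / "config.yaml", "w") as fh:
            cfg = dataclasses.asdict(self.config)
            cfg["inventory"] = [list(item) for item in cfg["inventory"]]
            yaml.safe_dump(cfg, fh, sort_keys=True)


def simulate_bundle(config: SimulationConfig, preset: str | None = None) -> FixtureBundle:
    """Generate a full input bundle from one seeded generator."""
    rng = np.random.default_rng(config.seed)
    tree = make_taxonomy(config)
    community = make_community(config, tree, rng, preset=preset)
    contigs, genes = make_contigs_genes(config, community, rng)
    contigs, meta = make_read_counts(config, contigs, rng)
    gene_hits = make_gene_hits(config, genes, tree, rng)
    genes, domain_hits, peptide_hits, ec_evidence = make_annotation_tables(
        config, genes, rng
    )
    return FixtureBundle(
        config=config, tree=tree, community=community, contigs=contigs, genes=genes,
        gene_hits=gene_hits, domain_hits=domain_hits, peptide_hits=peptide_hits,
        ec_evidence=ec_evidence, sample_meta=meta,
    )


#: sample id -> diet of the nine-sample study-shaped preset.
STUDY_SAMPLES = {
    "Mn": "fungus", "Od": "fungus", "Cu": "soil", "Aw": "dung", "Nt": "humus",
    "Th": "humus", "Co": "litter", "Mp": "wood", "Nc": "wood",
}


def simulate_study(
    seed: int = 0, base_config: SimulationConfig | None = None
) -> dict[str, FixtureBundle]:
    """Nine diet-biased samples sharing one taxonomy, for demo profiles and plots."""
    base = base_config or SimulationConfig(
        seed=seed, n_contigs=200, read_depth=50_000, genes_per_contig_mean=12.0
    )
    bundles = {}
    for i, (sample_id, diet) in enumerate(STUDY_SAMPLES.items()):
        config = dataclasses.replace(base, seed=base.seed + i, sample_id=sample_id)
        bundles[sample_id] = simulate_bundle(config, preset=diet)
    return bundles
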