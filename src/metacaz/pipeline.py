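"""Configurable multi-stage pipeline with stable on-disk outputs.

Stages (in dependency order): ``taxonomy`` (gene hits -> filtered top
hits -> vote-filtered LCA contig taxa), ``abundance`` (contig table ->
scaled coverages -> relative abundances and taxon profiles),
``annotate`` (domain + peptide evidence -> consensus family calls; EC
evidence -> multi-channel EC assignments) and ``profile`` (enzyme and
taxon x enzyme matrices, fold change, CLR + PCA, clustering).  Requested
stages re-use in-memory results when run together and fall back to
reading the upstream stage's files; a missing upstream output raises a
:class:`~metacaz.errors.DependencyError` naming the stage.

Every output TSV starts with a provenance comment (tool version, config
hash, seed), and re-runs overwrite deterministically.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from . import __version__
from . import io as mio
from .abundance import SampleMeta, AbundanceProfile, sample_abundance_profile, taxon_abundance
from .cazyme import (
    assign_ec,
    consensus_families,
    filter_domain_hits,
    resolve_overlapping_domains,
)
from .errors import ConfigError, DependencyError
from .profiles import clr, enzyme_profile, fold_change, hclust_profiles, pca, taxon_enzyme_profile
from .taxonomy import (
    UNCLASSIFIED,
    assign_contig_taxa,
    assign_gene_taxon,
    filter_hits,
    load_taxonomy,
)

STAGES = ("taxonomy", "abundance", "annotate", "profile")


@dataclass(frozen=True)
class Thresholds:
    """Filtering cutoffs; defaults are the pipeline's canonical values."""

    max_evalue_tax: float = 1e-5
    min_identity: float = 30.0
    min_support: float = 0.10
    max_evalue_dom: float = 1e-5
    min_channels: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.min_support <= 1:
            raise ConfigError("min_support must be in [0, 1]")
        if not 0 <= self.min_identity <= 100:
            raise ConfigError("min_identity must be in [0, 100]")
        if self.min_channels < 1:
            raise ConfigError("min_channels must be >= 1")


@dataclass(frozen=True)
class SampleInputs:
    sample_id: str
    contig_table: Path
    gene_hits: Path
    domain_hits: Path
    peptide_hits: Path
    ec_evidence: Path
    total_clean_bases: float
    read_length_bp: int = 150

    def meta(self) -> SampleMeta:
        return SampleMeta(self.sample_id, self.total_clean_bases, self.read_length_bp)


@dataclass
class RunConfig:
    taxonomy_nodes: Path
    taxonomy_names: Path
    samples: list[SampleInputs]
    outdir: Path
    thresholds: Thresholds = field(default_factory=Thresholds)
    ranks: tuple = ("phylum", "order", "genus")
    profile_rank: str = "order"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            samples = [
                SampleInputs(
                    sample_id=s["sample_id"],
                    contig_table=Path(s["contig_table"]),
                    gene_hits=Path(s["gene_hits"]),
                    domain_hits=Path(s["domain_hits"]),
                    peptide_hits=Path(s["peptide_hits"]),
                    ec_evidence=Path(s["ec_evidence"]),
                    total_clean_bases=float(s["total_clean_bases"]),
                    read_length_bp=int(s.get("read_length_bp", 150)),
                )
                for s in raw["samples"]
            ]
            config = cls(
                taxonomy_nodes=Path(raw["taxonomy"]["nodes"]),
                taxonomy_names=Path(raw["taxonomy"]["names"]),
                samples=samples,
                outdir=Path(raw["outdir"]),
                thresholds=Thresholds(**raw.get("thresholds", {})),
                ranks=tuple(raw.get("ranks", ("phylum", "order", "genus"))),
                profile_rank=raw.get("profile_rank", "order"),
                seed=int(raw.get("seed", 0)),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"invalid run config {path}: {exc}") from exc
        return config

    def validate(self) -> None:
        if not self.samples:
            raise ConfigError("no samples configured")
        paths = [self.taxonomy_nodes, self.taxonomy_names]
        for s in self.samples:
            paths += [s.contig_table, s.gene_hits, s.domain_hits, s.peptide_hits, s.ec_evidence]
        missing = [str(p) for p in paths if not Path(p).exists()]
        if missing:
            raise ConfigError(f"missing input files: {missing}")

    def config_hash(self) -> str:
        digest = hashlib.sha256(repr(self).encode()).hexdigest()
        return digest[:12]

    def provenance(self) -> str:
        return f"metacaz {__version__} | config_sha={self.config_hash()} | seed={self.seed}"


def config_for_bundle_dir(
    bundle_dir: str | Path, outdir: str | Path, **kwargs
) -> RunConfig:
    """Build a single-sample RunConfig pointing at a written FixtureBundle."""
    bundle_dir = Path(bundle_dir)
    with open(bundle_dir / "sample.yaml") as fh:
        meta = yaml.safe_load(fh)
    sample = SampleInputs(
        sample_id=meta["sample_id"],
        contig_table=bundle_dir / "contigs.tsv",
        gene_hits=bundle_dir / "gene_hits.tsv",
        domain_hits=bundle_dir / "domain_hits.tsv",
        peptide_hits=bundle_dir / "peptide_hits.tsv",
        ec_evidence=bundle_dir / "ec_evidence.tsv",
        total_clean_bases=float(meta["total_clean_bases"]),
        read_length_bp=int(meta["read_length_bp"]),
    )
    return RunConfig(
        taxonomy_nodes=bundle_dir / "nodes.dmp",
        taxonomy_names=bundle_dir / "names.dmp",
        samples=[sample],
        outdir=Path(outdir),
        **kwargs,
    )


# -- execution ---------------------------------------------------------------------------


class _Run:
    """One pipeline execution: holds config, loaded tree and per-sample artifacts."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.tree = load_taxonomy(config.taxonomy_nodes, config.taxonomy_names)
        self.contig_taxa: dict[str, dict[str, str]] = {}
        self.abundances: dict[str, AbundanceProfile] = {}
        self.assignments: dict[str, list] = {}
        self.written: list[Path] = []

    def sample_dir(self, sample_id: str) -> Path:
        d = Path(self.config.outdir) / "samples" / sample_id
        d.mkdir(parents=True, exist_ok=True)
        return d

    def _write(self, frame, path: Path) -> None:
        mio.write_profile_tsv(frame, path, provenance=self.config.provenance())
        self.written.append(path)

    # ---- stages

    def run_taxonomy(self) -> None:
        t = self.config.thresholds
        for sample in self.config.samples:
            hits = mio.read_gene_hits(sample.gene_hits)
            kept = filter_hits(hits, max_evalue=t.max_evalue_tax, min_identity=t.min_identity)
            gene_taxa = assign_gene_taxon(kept)
            contig_taxa = assign_contig_taxa(self.tree, gene_taxa, min_support=t.min_support)
            self.contig_taxa[sample.sample_id] = contig_taxa
            d = self.sample_dir(sample.sample_id)
            self._write(
                pd.Series(gene_taxa, name="taxon_id").rename_axis("gene_id"),
                d / "gene_taxa.tsv",
            )
            self._write(
                pd.Series(contig_taxa, name="taxon_id").rename_axis("contig_id"),
                d / "contig_taxa.tsv",
            )

    def _need_contig_taxa(self, sample: SampleInputs, stage: str) -> dict[str, str]:
        if sample.sample_id in self.contig_taxa:
            return self.contig_taxa[sample.sample_id]
        path = self.sample_dir(sample.sample_id) / "contig_taxa.tsv"
        if not path.exists():
            raise DependencyError(
                f"stage '{stage}' needs taxonomy output for sample "
                f"{sample.sample_id} (run the 'taxonomy' stage first)"
            )
        series = mio.read_profile_tsv(path)["taxon_id"]
        return dict(series)

    def run_abundance(self) -> None:
        for sample in self.config.samples:
            contigs = mio.read_contig_table(sample.contig_table)
            profile = sample_abundance_profile(contigs, sample.meta())
            self.abundances[sample.sample_id] = profile
            d = self.sample_dir(sample.sample_id)
            self._write(
                profile.abundances.rename("abundance").rename_axis("contig_id"),
                d / "contig_abundance.tsv",
            )
            contig_taxa = self._need_contig_taxa(sample, "abundance")
            for rank in self.config.ranks:
                tp = taxon_abundance(profile, contig_taxa, self.tree, rank)
                self._write(
                    tp.abundances.rename("abundance"), d / f"taxon_profile.{rank}.tsv"
                )

    def run_annotate(self) -> None:
        t = self.config.thresholds
        for sample in self.config.samples:
            reader = (
                mio.read_domtblout
                if str(sample.domain_hits).endswith(("domtblout", "domtbl"))
                else mio.read_domain_tsv
            )
            domain_hits = filter_domain_hits(reader(sample.domain_hits), t.max_evalue_dom)
            per_gene: dict[str, list] = {}
            for h in domain_hits:
                per_gene.setdefault(h.gene_id, []).append(h)
            resolved = [
                h for hits in per_gene.values() for h in resolve_overlapping_domains(hits)
            ]
            peptide_hits = mio.read_peptide_hits(sample.peptide_hits)
            calls = consensus_families(resolved, peptide_hits)
            evidence = mio.read_ec_evidence(sample.ec_evidence)
            assignments = assign_ec(evidence, min_channels=t.min_channels)
            self.assignments[sample.sample_id] = assignments
            d = self.sample_dir(sample.sample_id)
            self._write(
                pd.DataFrame(
                    [(c.gene_id, c.family) for c in calls], columns=["gene_id", "family"]
                ).set_index("gene_id"),
                d / "consensus_families.tsv",
            )
            self._write(
                pd.DataFrame(
                    [(a.gene_id, a.ec, a.n_channels) for a in assignments],
                    columns=["gene_id", "ec", "n_channels"],
                ).set_index("gene_id"),
                d / "ec_assignments.tsv",
            )

    def _need_abundance(self, sample: SampleInputs, stage: str) -> AbundanceProfile:
        if sample.sample_id in self.abundances:
            return self.abundances[sample.sample_id]
        path = self.sample_dir(sample.sample_id) / "contig_abundance.tsv"
        if not path.exists():
            raise DependencyError(
                f"stage '{stage}' needs abundance output for sample "
                f"{sample.sample_id} (run the 'abundance' stage first)"
            )
        series = mio.read_profile_tsv(path)["abundance"]
        return AbundanceProfile(sample_id=sample.sample_id, abundances=series)

    def _need_assignments(self, sample: SampleInputs, stage: str) -> list:
        if sample.sample_id in self.assignments:
            return self.assignments[sample.sample_id]
        path = self.sample_dir(sample.sample_id) / "ec_assignments.tsv"
        if not path.exists():
            raise DependencyError(
                f"stage '{stage}' needs annotation output for sample "
                f"{sample.sample_id} (run the 'annotate' stage first)"
            )
        from .cazyme import ECAssignment

        df = mio.read_profile_tsv(path).reset_index()
        return [
            ECAssignment(gene_id=r.gene_id, ec=r.ec, n_channels=int(r.n_channels))
            for r in df.itertuples(index=False)
        ]

    def run_profile(self) -> None:
        rows = {}
        all_ecs: list[str] = []
        per_sample = {}
        for sample in self.config.samples:
            assignments = self._need_assignments(sample, "profile")
            abundance = self._need_abundance(sample, "profile")
            per_sample[sample.sample_id] = (assignments, abundance)
            for a in assignments:
                if a.ec not in all_ecs:
                    all_ecs.append(a.ec)
        all_ecs.sort()
        outdir = Path(self.config.outdir)
        for sample in self.config.samples:
            assignments, abundance = per_sample[sample.sample_id]
            rows[sample.sample_id] = enzyme_profile(assignments, abundance, enzymes=all_ecs)
            contig_taxa = self._need_contig_taxa(sample, "profile")
            taxon_matrix = taxon_enzyme_profile(
                assignments, contig_taxa, self.tree, abundance,
                rank=self.config.profile_rank, enzymes=all_ecs,
            )
            self._write(
                taxon_matrix,
                self.sample_dir(sample.sample_id)
                / f"taxon_enzyme_profile.{self.config.profile_rank}.tsv",
            )
        matrix = pd.DataFrame(rows).T
        matrix.index.name = "sample_id"
        self._write(matrix, outdir / "enzyme_profile.tsv")
        if len(matrix) >= 2:
            fc = fold_change(matrix)
            self._write(fc.ratio, outdir / "fold_change_ratio.tsv")
            self._write(fc.display(), outdir / "fold_change_log2.tsv")
            nonzero = matrix.loc[:, matrix.sum(axis=0) > 0]
            transformed = clr(nonzero)
            self._write(transformed, outdir / "clr.tsv")
            n_comp = min(2, *transformed.shape)
            result = pca(transformed, n_components=n_comp)
            self._write(result.scores, outdir / "pca_scores.tsv")
            clustering = hclust_profiles(matrix)
            order = pd.Series(
                range(len(clustering.leaf_order)), index=clustering.leaf_order,
                name="position",
            ).rename_axis("sample_id")
            self._write(order, outdir / "cluster_leaf_order.tsv")


def run_pipeline(config: RunConfig, stages: Iterable[str] | None = None) -> list[Path]:
    """Run the requested stages in dependency order; returns written paths."""
    config.validate()
    requested: Sequence[str] = tuple(stages) if stages is not None else STAGES
    unknown = [s for s in requested if s not in STAGES]
    if unknown:
        raise ConfigError(f"unknown stages {unknown}; valid stages: {list(STAGES)}")
    Path(config.outdir).mkdir(parents=True, exist_ok=True)
    run = _Run(config)
    for stage in STAGES:
        if stage in requested:
            getattr(run, f"run_{stage}")()
    return run.written
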