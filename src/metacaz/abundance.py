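"""Coverage-normalized relative abundances of contigs and taxa.

Per-contig mapped-read counts are first scaled to a common sequencing
effort (10 Gb of clean sequence per metagenome by default) so samples of
different depth are comparable.  Coverage of a contig is then
``scaled_reads x read_length / contig_length``, and the relative
abundance of the contig is its coverage divided by the summed coverage
of all contigs in the sample.  Summing contig abundances over the taxa
their contigs were assigned to gives the taxonomic composition at any
rank; unassignable mass is pooled under ``UNCLASSIFIED`` so every
profile still sums to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .taxonomy import UNCLASSIFIED, TaxonomyTree

#: Common sequencing effort the read counts are scaled to (bp).
TARGET_BASES = 1e10

#: Columns a contig table must carry.
CONTIG_COLUMNS = ("contig_id", "length_bp", "mapped_reads")


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample sequencing metadata."""

    sample_id: str
    total_clean_bases: float
    read_length_bp: int = 150

    def __post_init__(self) -> None:
        if self.total_clean_bases <= 0:
            raise ValueError("total_clean_bases must be positive")
        if self.read_length_bp <= 0:
            raise ValueError("read_length_bp must be positive")


@dataclass(frozen=True)
class AbundanceProfile:
    """Per-contig relative abundances of one sample (sums to 1)."""

    sample_id: str
    abundances: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        total = float(self.abundances.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total}, expected 1")
        if (self.abundances < 0).any():
            raise ValueError("negative abundance")


@dataclass(frozen=True)
class TaxonProfile:
    """Taxon-level relative abundances of one sample at a fixed rank."""

    sample_id: str
    rank: str
    abundances: pd.Series = field(repr=False)


def scale_read_counts(
    contigs: pd.DataFrame, meta: SampleMeta, target_bases: float = TARGET_BASES
) -> pd.Series:
    """Scale mapped-read counts to an equivalent of ``target_bases`` of sequence.

    ``scaled = mapped_reads * target_bases / total_clean_bases``.  The
    factor cancels in relative abundances but matters whenever absolute
    coverages are exported or compared across samples.
    """
    if meta.total_clean_bases <= 0:
        raise ValueError("total_clean_bases must be positive")
    _check_contig_table(contigs)
    scaled = contigs["mapped_reads"].astype(float) * (target_bases / meta.total_clean_bases)
    scaled.index = pd.Index(contigs["contig_id"], name="contig_id")
    return scaled


def contig_coverage(length_bp: float, scaled_reads: float, read_length_bp: int) -> float:
    """Coverage of a single contig: ``scaled_reads * read_length / length``."""
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    return scaled_reads * read_length_bp / length_bp


def coverage_table(
    contigs: pd.DataFrame, scaled_reads: pd.Series, read_length_bp: int
) -> pd.Series:
    """Vectorized :func:`contig_coverage` over a contig table."""
    _check_contig_table(contigs)
    lengths = pd.Series(
        contigs["length_bp"].to_numpy(float), index=pd.Index(contigs["contig_id"])
    )
    if (lengths <= 0).any():
        raise ValueError("contig lengths must be positive")
    return scaled_reads * read_length_bp / lengths


def relative_abundance(coverages: pd.Series, sample_id: str = "") -> AbundanceProfile:
    """Close coverages to a relative-abundance profile summing to 1."""
    total = float(coverages.sum())
    if total <= 0:
        raise DegenerateInputError("all contig coverages are zero")
    return AbundanceProfile(sample_id=sample_id, abundances=coverages / total)


def sample_abundance_profile(
    contigs: pd.DataFrame,
    meta: SampleMeta,
    target_bases: float = TARGET_BASES,
) -> AbundanceProfile:
    """Contig table + sample metadata -> relative-abundance profile."""
    scaled = scale_read_counts(contigs, meta, target_bases=target_bases)
    cov = coverage_table(contigs, scaled, meta.read_length_bp)
    return relative_abundance(cov, sample_id=meta.sample_id)


def taxon_abundance(
    profile: AbundanceProfile,
    contig_taxa: Mapping[str, str],
    tree: TaxonomyTree,
    rank: str,
) -> TaxonProfile:
    """Roll contig abundances up to taxa at ``rank``.

    Each contig's abundance is added to the ancestor of its assigned
    taxon at the requested rank.  Contigs that are unclassified, missing
    from ``contig_taxa``, or whose lineage skips the rank pool into
    ``UNCLASSIFIED``.  Total mass is conserved.
    """
    sums: dict[str, float] = {}
    for contig, value in profile.abundances.items():
        taxon = contig_taxa.get(contig, UNCLASSIFIED)
        if taxon != UNCLASSIFIED:
            taxon = tree.lineage_at_rank(taxon, rank) or UNCLASSIFIED
        sums[taxon] = sums.get(taxon, 0.0) + float(value)
    named = sorted(t for t in sums if t != UNCLASSIFIED)
    if UNCLASSIFIED in sums:
        named.append(UNCLASSIFIED)
    series = pd.Series({t: sums[t] for t in named}, dtype=float)
    series.index.name = "taxon_id"
    return TaxonProfile(sample_id=profile.sample_id, rank=rank, abundances=series)


def _check_contig_table(contigs: pd.DataFrame) -> None:
    missing = [c for c in CONTIG_COLUMNS if c not in contigs.columns]
    if missing:
        raise ValueError(f"contig table lacks columns {missing}")
    if (np.asarray(contigs["mapped_reads"], dtype=float) < 0).any():
        raise ValueError("negative mapped_reads")
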