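"""Dual-evidence CAZyme family calls and multi-channel EC assignment.

A gene is called as a member of a CAZyme family only when two independent
annotation channels agree: a profile-HMM domain search (filtered on
E-value, with overlapping domains resolved in favour of the longest
aligned match) and a peptide-pattern classifier that counts occurrences
of short family-specific conserved peptides in the protein.  Enzyme
function (EC number) is assigned per gene when at least two of three
evidence channels (enzyme-database homology, orthologous-group search,
orthology-based pathway mapping) report a compatible EC; a partial EC
such as ``3.1.1.-`` supports a full EC with the same first three fields,
and the most specific agreed form is reported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import DataError

EC_PATTERN = re.compile(r"^\d+\.\d+\.\d+\.(\d+|-)$")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class DomainHit:
    """One profile-HMM domain match on a protein (1-based inclusive coords)."""

    gene_id: str
    family: str
    align_start: int
    align_end: int
    profile_length: int
    evalue: float

    def __post_init__(self) -> None:
        if not 1 <= self.align_start <= self.align_end:
            raise ValueError(
                f"bad alignment interval {self.align_start}-{self.align_end} "
                f"for {self.gene_id}/{self.family}"
            )

    @property
    def matched_length(self) -> int:
        return self.align_end - self.align_start + 1

    def overlaps(self, other: "DomainHit") -> bool:
        return self.align_start <= other.align_end and other.align_start <= self.align_end


@dataclass(frozen=True)
class PeptideModel:
    """Family-specific conserved peptides with their training occurrence counts."""

    family: str
    k: int
    peptides: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.peptides:
            raise ValueError(f"empty peptide model for {self.family}")
        for pep in self.peptides:
            if len(pep) != self.k:
                raise ValueError(f"peptide {pep!r} is not length {self.k}")


@dataclass(frozen=True)
class PeptideHit:
    gene_id: str
    family: str
    n_matched: int
    score: float


@dataclass(frozen=True)
class ConsensusCall:
    """A family call supported by both the HMM and the peptide channel."""

    gene_id: str
    family: str
    evidence: frozenset = field(default=frozenset({"hmm", "peptide"}))


@dataclass(frozen=True)
class ECEvidence:
    gene_id: str
    channel: str
    ec: str

    def __post_init__(self) -> None:
        if not EC_PATTERN.match(self.ec):
            raise DataError(f"malformed EC string {self.ec!r} for gene {self.gene_id}")


@dataclass(frozen=True)
class ECAssignment:
    gene_id: str
    ec: str
    n_channels: int


# -- peptide-pattern classifier ----------------------------------------------------------


def train_peptide_model(
    family_proteins: Sequence[str],
    family: str = "",
    k: int = 6,
    min_count: int = 2,
    top_n: int = 200,
) -> PeptideModel:
    """Learn a family's conserved peptides from training protein sequences.

    Every k-mer across the family is counted by the number of *distinct*
    sequences it occurs in; k-mers present in at least ``min_count``
    sequences survive, and the ``top_n`` by count (ties broken
    lexicographically) form the model.
    """
    if len(family_proteins) < 2:
        raise DataError(f"need >=2 training sequences for family {family!r}")
    counts: dict[str, int] = {}
    for seq in family_proteins:
        for kmer in {seq[i : i + k] for i in range(len(seq) - k + 1)}:
            counts[kmer] = counts.get(kmer, 0) + 1
    kept = {p: c for p, c in counts.items() if c >= min_count}
    if not kept:
        raise DataError(f"no peptide occurs in >= {min_count} sequences for {family!r}")
    ranked = sorted(kept.items(), key=lambda item: (-item[1], item[0]))[:top_n]
    return PeptideModel(family=family, k=k, peptides=dict(ranked))


def classify_peptides(
    gene_id: str,
    protein: str,
    models: Iterable[PeptideModel],
    min_hits: int = 2,
) -> list[PeptideHit]:
    """Count model peptides occurring in a protein; emit a hit per qualifying family.

    A family qualifies when at least ``min_hits`` distinct model peptides
    occur as substrings; multi-family proteins yield several hits.  The
    hit score is the sum of the matched peptides' training counts.
    """
    if not protein:
        raise DataError(f"empty protein sequence for {gene_id}")
    hits = []
    for model in models:
        matched = [p for p in model.peptides if p in protein]
        if len(matched) >= min_hits:
            hits.append(
                PeptideHit(
                    gene_id=gene_id,
                    family=model.family,
                    n_matched=len(matched),
                    score=float(sum(model.peptides[p] for p in matched)),
                )
            )
    return sorted(hits, key=lambda h: h.family)


# -- HMM-domain channel ------------------------------------------------------------------


def filter_domain_hits(hits: Iterable[DomainHit], max_evalue: float = 1e-5) -> list[DomainHit]:
    """Keep domain hits with E-value <= ``max_evalue`` (inclusive bound)."""
    return [h for h in hits if h.evalue <= max_evalue]


def _domain_priority(hit: DomainHit) -> tuple[float, float, str]:
    return (-hit.matched_length, hit.evalue, hit.family)


def resolve_overlapping_domains(hits: Sequence[DomainHit]) -> list[DomainHit]:
    """Resolve overlapping domain matches on one protein: longest match wins.

    Among hits whose aligned intervals share at least one position, the
    one with the greatest matched length is kept (ties break on smaller
    E-value, then family label); elimination repeats until the retained
    intervals are pairwise non-overlapping.  Disjoint hits all survive.
    """
    kept: list[DomainHit] = []
    for hit in sorted(hits, key=_domain_priority):
        if not any(hit.overlaps(k) for k in kept):
            kept.append(hit)
    return sorted(kept, key=lambda h: (h.align_start, h.family))


def consensus_families(
    domain_hits: Iterable[DomainHit],
    peptide_hits: Iterable[PeptideHit],
) -> list[ConsensusCall]:
    """Families supported by both channels, per gene.

    Domain hits are expected to be E-value-filtered and overlap-resolved
    already; output families are the per-gene intersection of the two
    channels' family sets.
    """
    hmm: dict[str, set[str]] = {}
    for h in domain_hits:
        hmm.setdefault(h.gene_id, set()).add(h.family)
    pep: dict[str, set[str]] = {}
    for p in peptide_hits:
        pep.setdefault(p.gene_id, set()).add(p.family)
    calls = [
        ConsensusCall(gene_id=gene, family=fam)
        for gene in sorted(hmm.keys() & pep.keys())
        for fam in sorted(hmm[gene] & pep[gene])
    ]
    return calls


# -- EC consensus ------------------------------------------------------------------------


def _ec_fields(ec: str) -> tuple[str, str, str, str]:
    a, b, c, d = ec.split(".")
    return a, b, c, d


def _ec_compatible(a: str, b: str) -> bool:
    fa, fb = _ec_fields(a), _ec_fields(b)
    if fa[:3] != fb[:3]:
        return False
    return fa[3] == fb[3] or fa[3] == "-" or fb[3] == "-"


def assign_ec(evidence: Iterable[ECEvidence], min_channels: int = 2) -> list[ECAssignment]:
    """Assign ECs supported by at least ``min_channels`` distinct channels.

    Support counting is prefix-aware: a partial EC (``x.y.z.-``) counts
    toward any full EC sharing its first three fields and vice versa.
    When a full EC qualifies, the partial form covering it is not
    reported separately; all qualifying (most specific) ECs of a gene
    are emitted.
    """
    per_gene: dict[str, list[ECEvidence]] = {}
    for ev in evidence:
        per_gene.setdefault(ev.gene_id, []).append(ev)

    assignments: list[ECAssignment] = []
    for gene in sorted(per_gene):
        records = {(ev.channel, ev.ec) for ev in per_gene[gene]}
        candidates = {ec for _, ec in records}
        support = {
            cand: len({ch for ch, ec in records if _ec_compatible(ec, cand)})
            for cand in candidates
        }
        qualifying = {c for c, n in support.items() if n >= min_channels}
        full = {c for c in qualifying if not c.endswith(".-")}
        for cand in sorted(qualifying):
            if cand.endswith(".-") and any(
                _ec_fields(f)[:3] == _ec_fields(cand)[:3] for f in full
            ):
                continue  # a more specific agreed form exists
            assignments.append(
                ECAssignment(gene_id=gene, ec=cand, n_channels=support[cand])
            )
    return assignments
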