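"""Ranked taxonomy trees and gene-vote LCA assignment of contigs.

Gene-level taxonomy comes from homology searches of predicted proteins
against a reference database: hits are filtered on E-value and percent
identity, and each gene takes the taxon of its best surviving hit.  A
contig is then classified by a vote-filtered lowest common ancestor
(LCA): taxa supported by fewer than a minimum fraction of the contig's
classified genes are discarded as noise, and the contig receives the LCA
of the surviving genes' taxa.  Contigs with no surviving evidence are
reported as :data:`UNCLASSIFIED` rather than pushed to the root, so that
"classified" totals stay meaningful.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import TaxonomyError

#: Ordered rank vocabulary, coarsest first.
RANKS = ("root", "superkingdom", "phylum", "class", "order", "family", "genus", "species")

_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}

#: Sentinel for contigs that could not be classified.
UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class GeneHit:
    """A single homology hit of a protein-coding gene against a reference.

    ``subject_taxon`` is the taxon identifier of the database subject;
    ``bit_score`` / ``evalue`` / ``percent_identity`` are the usual
    alignment statistics from a tabular search report.
    """

    gene_id: str
    contig_id: str
    subject_taxon: str
    evalue: float
    percent_identity: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value for {self.gene_id}")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"percent identity out of [0, 100] for {self.gene_id}")


class TaxonomyTree:
    """A rooted, ranked taxonomy with LCA and rank roll-up queries.

    Parameters
    ----------
    parents :
        Mapping ``taxon_id -> parent_id``. The (single) root points at
        itself.
    ranks :
        Mapping ``taxon_id -> rank``; ranks must come from :data:`RANKS`
        and may never be coarser than the parent's rank.
    names :
        Optional mapping ``taxon_id -> display name``.
    """

    def __init__(
        self,
        parents: Mapping[str, str],
        ranks: Mapping[str, str],
        names: Mapping[str, str] | None = None,
    ) -> None:
        self._parents = dict(parents)
        self._ranks = dict(ranks)
        self._names = dict(names) if names is not None else {}
        self._root = self._validate()
        self._lineage_cache: dict[str, tuple[str, ...]] = {}

    # -- construction & validation -------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, str, str]]) -> "TaxonomyTree":
        """Build a tree from ``(taxon_id, parent_id, rank, name)`` tuples."""
        parents, ranks, names = {}, {}, {}
        for taxon_id, parent_id, rank, name in records:
            if taxon_id in parents:
                raise TaxonomyError(f"duplicate taxon id {taxon_id!r}")
            parents[taxon_id] = parent_id
            ranks[taxon_id] = rank
            names[taxon_id] = name
        return cls(parents, ranks, names)

    def _validate(self) -> str:
        roots = [t for t, p in self._parents.items() if p == t]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}")
        root = roots[0]
        for taxon, parent in self._parents.items():
            if parent not in self._parents:
                raise TaxonomyError(f"taxon {taxon!r} has missing parent {parent!r}")
            rank = self._ranks.get(taxon)
            if rank not in _RANK_INDEX:
                raise TaxonomyError(f"taxon {taxon!r} has unknown rank {rank!r}")
        # acyclicity + rank monotonicity along every root path
        ok: set[str] = {root}
        for taxon in self._parents:
            path = []
            node = taxon
            seen = set()
            while node not in ok:
                if node in seen:
                    raise TaxonomyError(f"cycle in taxonomy involving {node!r}")
                seen.add(node)
                path.append(node)
                node = self._parents[node]
            ok.update(path)
        for taxon, parent in self._parents.items():
            if taxon == parent:
                continue
            if _RANK_INDEX[self._ranks[parent]] > _RANK_INDEX[self._ranks[taxon]]:
                raise TaxonomyError(
                    f"rank of {taxon!r} ({self._ranks[taxon]}) is coarser than its "
                    f"parent {parent!r} ({self._ranks[parent]})"
                )
        return root

    # -- basic queries ---------------------------------------------------------------

    @property
    def root(self) -> str:
        return self._root

    def __len__(self) -> int:
        return len(self._parents)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._parents

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxonomyTree):
            return NotImplemented
        return (
            self._parents == other._parents
            and self._ranks == other._ranks
            and self._names == other._names
        )

    def taxon_ids(self) -> list[str]:
        return sorted(self._parents)

    def parent(self, taxon_id: str) -> str:
        return self._parents[taxon_id]

    def rank(self, taxon_id: str) -> str:
        return self._ranks[taxon_id]

    def name(self, taxon_id: str) -> str:
        return self._names.get(taxon_id, taxon_id)

    def taxa_at_rank(self, rank: str) -> list[str]:
        if rank not in _RANK_INDEX:
            raise ValueError(f"unknown rank {rank!r}")
        return sorted(t for t, r in self._ranks.items() if r == rank)

    def lineage(self, taxon_id: str) -> tuple[str, ...]:
        """Path from the root down to (and including) ``taxon_id``."""
        if taxon_id not in self._parents:
            raise KeyError(taxon_id)
        cached = self._lineage_cache.get(taxon_id)
        if cached is not None:
            return cached
        path = [taxon_id]
        node = taxon_id
        while node != self._root:
            node = self._parents[node]
            path.append(node)
        result = tuple(reversed(path))
        self._lineage_cache[taxon_id] = result
        return result

    # -- LCA & rank roll-up ------------------------------------------------------------

    def lca(self, taxa: Iterable[str]) -> str:
        """Lowest common ancestor: the deepest node ancestral-or-equal to all inputs."""
        taxa = list(taxa)
        if not taxa:
            raise ValueError("lca() of an empty taxon set")
        paths = [self.lineage(t) for t in taxa]
        shortest = min(len(p) for p in paths)
        ancestor = self._root
        for depth in range(shortest):
            level = {p[depth] for p in paths}
            if len(level) > 1:
                break
            ancestor = next(iter(level))
        return ancestor

    def lineage_at_rank(self, taxon_id: str, rank: str) -> str | None:
        """Ancestor-or-self of ``taxon_id`` at ``rank``, or None if the lineage skips it."""
        if rank not in _RANK_INDEX:
            raise ValueError(f"unknown rank {rank!r}")
        for node in self.lineage(taxon_id):
            if self._ranks[node] == rank:
                return node
        return None


# -- taxonomy dump I/O (pipe-delimited nodes/names dialect) ------------------------------


def _split_dump_line(line: str) -> list[str]:
    return [field.strip("\t ") for field in line.rstrip("\n").rstrip("|\t ").split("|")]


def load_taxonomy(nodes_path: str | Path, names_path: str | Path) -> TaxonomyTree:
    """Load a tree from pipe-delimited ``nodes``/``names`` dump files.

    The nodes file carries ``id | parent | rank``; the names file
    ``id | name | unique name | name class`` (the "scientific name" row wins
    when a taxon has several names).  Ranks outside the vocabulary are
    mapped to the nearest coarser known rank (the closest ancestor with a
    recognised rank) with a warning.
    """
    parents: dict[str, str] = {}
    raw_ranks: dict[str, str] = {}
    with open(nodes_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = _split_dump_line(line)
            if len(fields) < 3:
                raise TaxonomyError(f"malformed nodes line: {line!r}")
            taxon_id, parent_id, rank = fields[0], fields[1], fields[2]
            parents[taxon_id] = parent_id
            raw_ranks[taxon_id] = rank

    names: dict[str, str] = {}
    with open(names_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = _split_dump_line(line)
            taxon_id, name = fields[0], fields[1]
            name_class = fields[3] if len(fields) > 3 else ""
            if taxon_id not in names or name_class == "scientific name":
                names[taxon_id] = name

    # Resolve unknown ranks to the nearest coarser (ancestral) known rank.
    for taxon, parent in parents.items():
        if parent not in parents:
            raise TaxonomyError(f"taxon {taxon!r} has missing parent {parent!r}")
    ranks: dict[str, str] = {}
    remapped = []
    for taxon in parents:
        rank = raw_ranks[taxon]
        if rank in _RANK_INDEX:
            ranks[taxon] = rank
            continue
        node, hops = taxon, 0
        while raw_ranks[node] not in _RANK_INDEX and parents[node] != node:
            node = parents[node]
            hops += 1
            if hops > len(parents):
                raise TaxonomyError(f"cycle in taxonomy involving {taxon!r}")
        ranks[taxon] = raw_ranks[node] if raw_ranks[node] in _RANK_INDEX else "root"
        remapped.append(taxon)
    if remapped:
        warnings.warn(
            f"{len(remapped)} taxa had unrecognised ranks and were mapped to the "
            f"nearest coarser rank (e.g. {remapped[0]!r})",
            stacklevel=2,
        )
    return TaxonomyTree(parents, ranks, names)


def write_taxonomy(tree: TaxonomyTree, nodes_path: str | Path, names_path: str | Path) -> None:
    """Write a tree in the pipe-delimited nodes/names dump dialect."""
    with open(nodes_path, "w") as fh:
        for taxon in tree.taxon_ids():
            fh.write(f"{taxon}\t|\t{tree.parent(taxon)}\t|\t{tree.rank(taxon)}\t|\n")
    with open(names_path, "w") as fh:
        for taxon in tree.taxon_ids():
            fh.write(f"{taxon}\t|\t{tree.name(taxon)}\t|\t\t|\tscientific name\t|\n")


# -- gene- and contig-level assignment ----------------------------------------------------


def filter_hits(
    hits: Iterable[GeneHit],
    max_evalue: float = 1e-5,
    min_identity: float = 30.0,
) -> list[GeneHit]:
    """Drop hits with E-value above ``max_evalue`` or identity below ``min_identity``.

    Removal is strict (> / <), so boundary values survive: a hit at exactly
    E = 1e-5 and 30% identity is kept.
    """
    return [
        h for h in hits if h.evalue <= max_evalue and h.percent_identity >= min_identity
    ]


def assign_gene_taxon(hits: Iterable[GeneHit]) -> dict[str, str]:
    """Assign each gene the taxon of its top hit.

    The top hit is the one with maximal bit score; ties break on smaller
    E-value, then lexicographically smaller subject taxon, so the result
    is deterministic regardless of input order.  Genes with no hits are
    absent from the returned mapping.
    """
    best: dict[str, GeneHit] = {}
    for hit in hits:
        incumbent = best.get(hit.gene_id)
        if incumbent is None or _hit_priority(hit) < _hit_priority(incumbent):
            best[hit.gene_id] = hit
    return {gene: hit.subject_taxon for gene, hit in best.items()}


def _hit_priority(hit: GeneHit) -> tuple[float, float, str]:
    return (-hit.bit_score, hit.evalue, hit.subject_taxon)


def contig_consensus_taxon(
    tree: TaxonomyTree,
    gene_taxa: Sequence[str],
    min_support: float = 0.10,
) -> str:
    """Vote-filtered LCA classification of one contig.

    ``gene_taxa`` holds the taxa of the contig's classified genes (one
    entry per gene).  The support of a distinct taxon is the fraction of
    classified genes assigned exactly that taxon; taxa with support
    strictly below ``min_support`` are discarded, and the contig receives
    the LCA of the survivors.  An empty list, or one in which every taxon
    is discarded, yields :data:`UNCLASSIFIED`.
    """
    if not gene_taxa:
        return UNCLASSIFIED
    counts = Counter(gene_taxa)
    total = sum(counts.values())
    survivors = [t for t, c in counts.items() if c / total >= min_support]
    if not survivors:
        return UNCLASSIFIED
    return tree.lca(survivors)


def assign_contig_taxa(
    tree: TaxonomyTree,
    gene_taxa: Mapping[str, str],
    gene_to_contig: Mapping[str, str] | None = None,
    min_support: float = 0.10,
) -> dict[str, str]:
    """Apply :func:`contig_consensus_taxon` across a whole gene->taxon map.

    ``gene_to_contig`` defaults to parsing the ``<contig>_<n>`` gene id
    convention.
    """
    per_contig: dict[str, list[str]] = {}
    for gene, taxon in gene_taxa.items():
        contig = (
            gene_to_contig[gene] if gene_to_contig is not None else contig_of_gene(gene)
        )
        per_contig.setdefault(contig, []).append(taxon)
    return {
        contig: contig_consensus_taxon(tree, taxa, min_support=min_support)
        for contig, taxa in per_contig.items()
    }


def contig_of_gene(gene_id: str) -> str:
    """Contig id encoded in a ``<contig>_<n>`` gene id."""
    contig, _, suffix = gene_id.rpartition("_")
    if not contig or not suffix.isdigit():
        raise ValueError(f"gene id {gene_id!r} does not follow '<contig>_<n>'")
    return contig
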