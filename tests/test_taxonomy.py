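"""Taxonomy tree structure, hit filtering, top-hit assignment and vote-filtered LCA."""

from collections import Counter

import numpy as np
import pytest

from metacaz.errors import TaxonomyError
from metacaz.taxonomy import (
    RANKS,
    UNCLASSIFIED,
    GeneHit,
    TaxonomyTree,
    assign_gene_taxon,
    contig_consensus_taxon,
    contig_of_gene,
    filter_hits,
    load_taxonomy,
    write_taxonomy,
)

from conftest import lca_by_path_intersection, random_ranked_tree


def make_hit(gene="c1_1", taxon="t1", evalue=1e-10, identity=90.0, score=100.0):
    return GeneHit(
        gene_id=gene, contig_id=contig_of_gene(gene), subject_taxon=taxon,
        evalue=evalue, percent_identity=identity, bit_score=score,
    )


class TestTreeStructure:
    def test_minimal_three_node_dump_loads(self, tmp_path):
        (tmp_path / "nodes.dmp").write_text(
            "1\t|\t1\t|\troot\t|\n2\t|\t1\t|\tsuperkingdom\t|\n10\t|\t2\t|\tphylum\t|\n"
        )
        (tmp_path / "names.dmp").write_text(
            "1\t|\troot\t|\t\t|\tscientific name\t|\n"
            "2\t|\tBacteria\t|\t\t|\tscientific name\t|\n"
            "10\t|\tFirmicutes\t|\t\t|\tscientific name\t|\n"
        )
        tree = load_taxonomy(tmp_path / "nodes.dmp", tmp_path / "names.dmp")
        assert len(tree) == 3
        assert tree.rank(tree.root) == "root"
        assert tree.name("10") == "Firmicutes"

    def test_missing_parent_is_structural_error(self, tmp_path):
        (tmp_path / "nodes.dmp").write_text("1\t|\t1\t|\troot\t|\n5\t|\t99\t|\tphylum\t|\n")
        (tmp_path / "names.dmp").write_text("1\t|\troot\t|\t\t|\tscientific name\t|\n")
        with pytest.raises(TaxonomyError, match="5"):
            load_taxonomy(tmp_path / "nodes.dmp", tmp_path / "names.dmp")

    def test_cycle_detected(self):
        with pytest.raises(TaxonomyError, match="cycle|root"):
            TaxonomyTree.from_records(
                [("a", "b", "phylum", "A"), ("b", "a", "phylum", "B")]
            )

    def test_two_roots_rejected(self):
        with pytest.raises(TaxonomyError):
            TaxonomyTree.from_records(
                [("a", "a", "root", "A"), ("b", "b", "root", "B")]
            )

    def test_unknown_rank_mapped_to_nearest_coarser_with_warning(self, tmp_path):
        (tmp_path / "nodes.dmp").write_text(
            "1\t|\t1\t|\troot\t|\n2\t|\t1\t|\tphylum\t|\n3\t|\t2\t|\tno rank\t|\n"
        )
        (tmp_path / "names.dmp").write_text("1\t|\troot\t|\t\t|\tscientific name\t|\n")
        with pytest.warns(UserWarning, match="unrecognised ranks"):
            tree = load_taxonomy(tmp_path / "nodes.dmp", tmp_path / "names.dmp")
        assert tree.rank("3") == "phylum"

    def test_random_tree_roundtrips_through_dump_files(self, rng, tmp_path):
        tree = random_ranked_tree(rng, n_nodes=50)
        write_taxonomy(tree, tmp_path / "nodes.dmp", tmp_path / "names.dmp")
        reloaded = load_taxonomy(tmp_path / "nodes.dmp", tmp_path / "names.dmp")
        assert reloaded == tree


class TestFilterHits:
    @pytest.mark.parametrize(
        "evalue,identity,kept",
        [
            (1e-4, 95.0, False),  # E-value above cutoff is removed
            (1e-5, 30.0, True),  # both exactly at the boundary survive
            (1e-6, 29.9, False),  # identity below cutoff is removed
            (1e-6, 30.0, True),
        ],
    )
    def test_boundary_semantics(self, evalue, identity, kept):
        hits = filter_hits([make_hit(evalue=evalue, identity=identity)])
        assert bool(hits) is kept

    def test_matches_bruteforce_predicate_on_random_hits(self, rng):
        hits = [
            make_hit(
                gene=f"c{i}_1",
                evalue=float(10.0 ** rng.uniform(-12, -2)),
                identity=float(rng.uniform(0, 100)),
            )
            for i in range(1000)
        ]
        expected = [h for h in hits if h.evalue <= 1e-5 and h.percent_identity >= 30.0]
        assert filter_hits(hits) == expected

    def test_empty_in_empty_out(self):
        assert filter_hits([]) == []


class TestAssignGeneTaxon:
    def test_highest_bitscore_wins(self):
        hits = [make_hit(taxon="A", score=120), make_hit(taxon="B", score=90)]
        assert assign_gene_taxon(hits) == {"c1_1": "A"}

    def test_tie_breaks_on_evalue_then_taxon(self):
        hits = [
            make_hit(taxon="B", score=100, evalue=1e-10),
            make_hit(taxon="A", score=100, evalue=1e-20),
        ]
        assert assign_gene_taxon(hits) == {"c1_1": "A"}
        hits = [
            make_hit(taxon="B", score=100, evalue=1e-20),
            make_hit(taxon="A", score=100, evalue=1e-20),
        ]
        assert assign_gene_taxon(hits) == {"c1_1": "A"}

    def test_matches_exhaustive_sort_oracle(self, rng):
        hits = []
        for i in range(200):
            for _ in range(int(rng.integers(1, 5))):
                hits.append(
                    make_hit(
                        gene=f"c{i}_1",
                        taxon=f"t{int(rng.integers(5))}",
                        score=float(rng.choice([50.0, 100.0])),
                        evalue=float(rng.choice([1e-20, 1e-10])),
                    )
                )
        result = assign_gene_taxon(hits)
        for gene in {h.gene_id for h in hits}:
            ordered = sorted(
                (h for h in hits if h.gene_id == gene),
                key=lambda h: (-h.bit_score, h.evalue, h.subject_taxon),
            )
            assert result[gene] == ordered[0].subject_taxon

    def test_gene_without_hits_absent(self):
        assert "c9_1" not in assign_gene_taxon([make_hit(gene="c1_1")])


class TestLCA:
    def test_singleton_is_itself(self, small_tree):
        assert small_tree.lca(["14"]) == "14"

    def test_sibling_genera_meet_at_family(self, small_tree):
        assert small_tree.lca(["14", "15"]) == "13"

    def test_cross_phylum_meets_at_superkingdom(self, small_tree):
        assert small_tree.lca(["14", "24"]) == "2"

    def test_empty_set_is_an_error(self, small_tree):
        with pytest.raises(ValueError):
            small_tree.lca([])

    def test_matches_path_intersection_oracle_on_random_trees(self, rng):
        for _ in range(20):
            tree = random_ranked_tree(rng, n_nodes=50)
            ids = tree.taxon_ids()
            for _ in range(10):
                subset = list(rng.choice(ids, size=int(rng.integers(1, 8)), replace=True))
                assert tree.lca(subset) == lca_by_path_intersection(tree, subset)


class TestLineageAtRank:
    def test_genus_to_phylum(self, small_tree):
        assert small_tree.lineage_at_rank("14", "phylum") == "10"

    def test_identity_at_own_rank(self, small_tree):
        assert small_tree.lineage_at_rank("10", "phylum") == "10"

    def test_missing_rank_gives_none(self):
        tree = TaxonomyTree.from_records(
            [("1", "1", "root", "root"), ("2", "1", "phylum", "P"),
             ("3", "2", "order", "O")]  # lineage skips "class"
        )
        assert tree.lineage_at_rank("3", "class") is None

    def test_unknown_rank_label_rejected(self, small_tree):
        with pytest.raises(ValueError):
            small_tree.lineage_at_rank("14", "tribe")


def consensus_oracle(tree, gene_taxa, min_support=0.10):
    """Brute force: count distinct taxa, filter on support, intersect root paths."""
    if not gene_taxa:
        return UNCLASSIFIED
    counts = Counter(gene_taxa)
    total = len(gene_taxa)
    survivors = [t for t, c in counts.items() if c / total >= min_support]
    if not survivors:
        return UNCLASSIFIED
    return lca_by_path_intersection(tree, survivors)


class TestContigConsensus:
    def test_ten_genes_nine_one_keeps_minority_at_boundary(self, small_tree):
        # support 1/10 = 0.10 is not < 0.10, so the minority genus survives
        taxa = ["14"] * 9 + ["15"]
        assert contig_consensus_taxon(small_tree, taxa) == "13"
        assert contig_consensus_taxon(small_tree, taxa) == consensus_oracle(small_tree, taxa)

    def test_eleven_genes_ten_one_drops_minority(self, small_tree):
        taxa = ["14"] * 10 + ["15"]  # support 1/11 < 0.10
        assert contig_consensus_taxon(small_tree, taxa) == "14"

    def test_no_classified_genes_unclassified(self, small_tree):
        assert contig_consensus_taxon(small_tree, []) == UNCLASSIFIED

    def test_single_gene_contig_gets_that_taxon(self, small_tree):
        assert contig_consensus_taxon(small_tree, ["24"]) == "24"

    def test_matches_bruteforce_oracle_on_random_contigs(self, rng):
        checked = 0
        for _ in range(10):
            tree = random_ranked_tree(rng, n_nodes=50)
            ids = tree.taxon_ids()
            for _ in range(60):
                taxa = list(rng.choice(ids, size=int(rng.integers(1, 30)), replace=True))
                assert contig_consensus_taxon(tree, taxa) == consensus_oracle(tree, taxa)
                checked += 1
        assert checked >= 500

    def test_monotone_under_more_votes_for_winner(self, rng):
        """Extra votes for the assigned taxon never move the assignment out of
        its subtree, and never change it at all when no minority sits at the
        support boundary (boundary taxa can be diluted below 10% by the new
        votes, which is the one legitimate way the call can sharpen)."""
        for _ in range(100):
            tree = random_ranked_tree(rng, n_nodes=30)
            ids = tree.taxon_ids()
            taxa = list(rng.choice(ids, size=int(rng.integers(1, 15)), replace=True))
            assigned = contig_consensus_taxon(tree, taxa)
            if assigned == UNCLASSIFIED:
                continue
            k = int(rng.integers(1, len(taxa) + 1))
            boosted = taxa + [assigned] * k
            new = contig_consensus_taxon(tree, boosted)
            assert assigned in tree.lineage(new)  # stays in the assigned subtree
            counts = Counter(taxa)
            if all(c / len(taxa) >= 0.2 for c in counts.values() if c / len(taxa) >= 0.1):
                assert new == assigned
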