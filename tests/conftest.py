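"""Shared fixtures: random ranked trees and a small reference taxonomy."""

import numpy as np
import pytest

from metacaz.taxonomy import RANKS, TaxonomyTree


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_tree():
    """root -> Bacteria -> {Firmicutes -> Clostridia -> Clostridiales -> Lachnospiraceae
    -> 2 genera; Bacteroidetes -> ... -> 1 genus}."""
    return TaxonomyTree.from_records(
        [
            ("1", "1", "root", "root"),
            ("2", "1", "superkingdom", "Bacteria"),
            ("10", "2", "phylum", "Firmicutes"),
            ("11", "10", "class", "Clostridia"),
            ("12", "11", "order", "Clostridiales"),
            ("13", "12", "family", "Lachnospiraceae"),
            ("14", "13", "genus", "Blautia"),
            ("15", "13", "genus", "Roseburia"),
            ("20", "2", "phylum", "Bacteroidetes"),
            ("21", "20", "class", "Bacteroidia"),
            ("22", "21", "order", "Bacteroidales"),
            ("23", "22", "family", "Rikenellaceae"),
            ("24", "23", "genus", "Alistipes"),
            ("25", "24", "species", "Alistipes sp."),
        ]
    )


def random_ranked_tree(rng: np.random.Generator, n_nodes: int = 50) -> TaxonomyTree:
    """Random valid ranked tree: each node attaches below an earlier node at an
    equal-or-deeper rank."""
    records = [("t0", "t0", "root", "root")]
    rank_idx = {"t0": 0}
    for i in range(1, n_nodes):
        parent = f"t{int(rng.integers(i))}"
        lo = max(rank_idx[parent], 1)
        ridx = int(rng.integers(lo, len(RANKS)))
        records.append((f"t{i}", parent, RANKS[ridx], f"name{i}"))
        rank_idx[f"t{i}"] = ridx
    return TaxonomyTree.from_records(records)


def lca_by_path_intersection(tree: TaxonomyTree, taxa) -> str:
    """Independent LCA oracle: deepest element common to every root path."""
    paths = [tree.lineage(t) for t in taxa]
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    # deepest = the common node whose root path is longest
    return max(common, key=lambda node: len(tree.lineage(node)))
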