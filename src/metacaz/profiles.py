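"""Enzyme and taxon profile matrices and their comparative statistics.

The central outputs of the pipeline are nonnegative relative-abundance
matrices: samples x enzymes (each cell the summed relative abundance of
the contigs carrying genes assigned that EC, conventionally displayed
x10^6) and taxa x enzymes (the same mass routed to the bacterial order,
or any other rank, the carrying contig was assigned to).  On top of
these the module provides the comparative statistics used to contrast
communities: per-enzyme fold change against the cross-sample mean
(log2-transformed for heatmaps), the centered log-ratio transform that
makes compositions amenable to ordination, column-centered PCA, and
hierarchical clustering of profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .abundance import AbundanceProfile
from .cazyme import ECAssignment
from .errors import DataError, DegenerateInputError
from .taxonomy import UNCLASSIFIED, TaxonomyTree, contig_of_gene

#: Display scaling applied to relative-abundance profile cells.
DISPLAY_SCALE = 1e6


def enzyme_profile(
    assignments: Iterable[ECAssignment],
    abundance: AbundanceProfile,
    gene_to_contig: Mapping[str, str] | None = None,
    enzymes: Sequence[str] | None = None,
    display_scale: float = DISPLAY_SCALE,
) -> pd.Series:
    """One sample's enzyme profile: summed contig abundance per assigned EC.

    Every qualifying gene contributes its contig's relative abundance, so
    a contig carrying ``g`` genes with the same EC contributes ``g``
    times.  ``enzymes`` fixes the output index (absent enzymes get 0.0,
    matching the zero cells of a printed profile table); otherwise the
    observed ECs are used.  Cells are multiplied by ``display_scale``.
    """
    sums: dict[str, float] = {}
    for a in assignments:
        contig = (
            gene_to_contig[a.gene_id]
            if gene_to_contig is not None
            else contig_of_gene(a.gene_id)
        )
        if contig not in abundance.abundances.index:
            raise DataError(f"gene {a.gene_id} maps to unknown contig {contig!r}")
        sums[a.ec] = sums.get(a.ec, 0.0) + float(abundance.abundances[contig])
    index = list(enzymes) if enzymes is not None else sorted(sums)
    out = pd.Series(
        [display_scale * sums.get(e, 0.0) for e in index],
        index=pd.Index(index, name="enzyme"),
        name=abundance.sample_id,
        dtype=float,
    )
    return out


def taxon_enzyme_profile(
    assignments: Iterable[ECAssignment],
    contig_taxa: Mapping[str, str],
    tree: TaxonomyTree,
    abundance: AbundanceProfile,
    rank: str = "order",
    gene_to_contig: Mapping[str, str] | None = None,
    enzymes: Sequence[str] | None = None,
    display_scale: float = DISPLAY_SCALE,
) -> pd.DataFrame:
    """Taxa x enzymes matrix: enzyme mass routed to each carrier taxon at ``rank``.

    Contributions whose contig is unclassified, or whose lineage skips
    the rank, pool into an ``UNCLASSIFIED`` row, so column sums equal the
    corresponding :func:`enzyme_profile` entries exactly.
    """
    cells: dict[tuple[str, str], float] = {}
    observed: list[str] = []
    for a in assignments:
        contig = (
            gene_to_contig[a.gene_id]
            if gene_to_contig is not None
            else contig_of_gene(a.gene_id)
        )
        if contig not in abundance.abundances.index:
            raise DataError(f"gene {a.gene_id} maps to unknown contig {contig!r}")
        taxon = contig_taxa.get(contig, UNCLASSIFIED)
        if taxon != UNCLASSIFIED:
            taxon = tree.lineage_at_rank(taxon, rank) or UNCLASSIFIED
        cells[(taxon, a.ec)] = cells.get((taxon, a.ec), 0.0) + float(
            abundance.abundances[contig]
        )
        if a.ec not in observed:
            observed.append(a.ec)
    columns = list(enzymes) if enzymes is not None else sorted(observed)
    taxa = sorted({t for t, _ in cells} - {UNCLASSIFIED})
    if any(t == UNCLASSIFIED for t, _ in cells):
        taxa.append(UNCLASSIFIED)
    matrix = pd.DataFrame(0.0, index=pd.Index(taxa, name="taxon_id"), columns=columns)
    for (taxon, ec), value in cells.items():
        if ec in matrix.columns:
            matrix.loc[taxon, ec] = matrix.loc[taxon, ec] + display_scale * value
    return matrix


# -- fold change -------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldChangeResult:
    """Per-cell ratio to the column mean, and its log2 transform.

    Zero cells over a positive column mean have ratio 0 and log2 ``-inf``
    (kept as a sentinel in the numeric output; use :meth:`display` for a
    floored heatmap-friendly matrix).  Columns whose mean is zero are
    dropped and listed in ``dropped_columns``.
    """

    ratio: pd.DataFrame = field(repr=False)
    log2: pd.DataFrame = field(repr=False)
    dropped_columns: tuple = ()

    def display(self, floor: float = -10.0) -> pd.DataFrame:
        """log2 matrix with ``-inf`` replaced by ``floor`` for plotting."""
        return self.log2.replace(-np.inf, floor)


def fold_change(matrix: pd.DataFrame) -> FoldChangeResult:
    """Fold change of each row against the mean across rows, per column."""
    if matrix.shape[0] < 2:
        raise ValueError("fold change needs at least two rows")
    means = matrix.mean(axis=0)
    dropped = tuple(means.index[means == 0])
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} all-zero columns from fold change", stacklevel=2
        )
    kept = matrix.loc[:, means > 0]
    ratio = kept / means[means > 0]
    with np.errstate(divide="ignore"):
        log2 = np.log2(ratio)
    return FoldChangeResult(ratio=ratio, log2=log2, dropped_columns=dropped)


# -- centered log-ratio ------------------------------------------------------------------


def multiplicative_replacement(closed: np.ndarray, delta: float) -> np.ndarray:
    """Replace zeros in closed compositions by ``delta``, shrinking the rest.

    Each row is assumed to sum to 1; nonzero parts are multiplied by
    ``1 - z * delta`` (z = number of zeros in the row) so the row still
    sums to 1.
    """
    out = closed.copy()
    zeros = closed == 0
    z = zeros.sum(axis=1, keepdims=True)
    out = np.where(zeros, delta, out * (1 - z * delta))
    return out


def clr(
    matrix: pd.DataFrame,
    zero_replacement: str | Callable[[np.ndarray, float], np.ndarray] = "multiplicative",
    delta: float | None = None,
) -> pd.DataFrame:
    """Centered log-ratio transform, row-wise.

    Rows are closed to proportions; zeros are replaced (default:
    multiplicative replacement with ``delta`` = half the smallest
    positive value of the closed matrix), then each row becomes
    ``log(x) - mean(log(x))`` and sums to 0.
    """
    if matrix.shape[1] < 2:
        raise ValueError("clr needs at least two columns")
    values = matrix.to_numpy(float)
    if (values < 0).any():
        raise DataError("negative entries are not a composition")
    row_sums = values.sum(axis=1, keepdims=True)
    if (row_sums == 0).any():
        bad = matrix.index[(values.sum(axis=1) == 0)].tolist()
        raise DegenerateInputError(f"all-zero rows cannot be CLR-transformed: {bad}")
    closed = values / row_sums
    if (closed == 0).any():
        if delta is None:
            delta = 0.5 * closed[closed > 0].min()
        replace = (
            multiplicative_replacement if zero_replacement == "multiplicative" else zero_replacement
        )
        if not callable(replace):
            raise ValueError(f"unknown zero-replacement strategy {zero_replacement!r}")
        closed = replace(closed, delta)
    logs = np.log(closed)
    centered = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(centered, index=matrix.index, columns=matrix.columns)


# -- PCA ---------------------------------------------------------------------------------


@dataclass(frozen=True)
class PCAResult:
    """Scores, loadings and explained-variance fractions of a PCA."""

    scores: pd.DataFrame = field(repr=False)
    loadings: pd.DataFrame = field(repr=False)
    explained_variance_ratio: np.ndarray = field(repr=False)


def pca(matrix: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """Column-centered PCA by singular value decomposition.

    Sign convention: within each component the largest-magnitude loading
    is made positive, so results are deterministic.  Explained-variance
    fractions are relative to the total variance of the centered data.
    """
    n_rows, n_cols = matrix.shape
    if n_rows < 2:
        raise ValueError("pca needs at least two rows")
    if n_components > min(n_rows, n_cols):
        raise ValueError(
            f"n_components={n_components} exceeds min(rows, cols)={min(n_rows, n_cols)}"
        )
    X = matrix.to_numpy(float)
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for i in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    total = float((S**2).sum())
    evr = (S[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(
        U[:, :n_components] * S[:n_components], index=matrix.index, columns=comp_names
    )
    loadings = pd.DataFrame(Vt[:n_components].T, index=matrix.columns, columns=comp_names)
    return PCAResult(scores=scores, loadings=loadings, explained_variance_ratio=evr)


# -- hierarchical clustering -------------------------------------------------------------


@dataclass(frozen=True)
class ClusterResult:
    """Agglomeration of profile rows: scipy-format linkage plus row labels."""

    linkage: np.ndarray = field(repr=False)
    labels: tuple

    @property
    def leaf_order(self) -> tuple:
        return tuple(self.labels[i] for i in hierarchy.leaves_list(self.linkage))

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def hclust_profiles(
    matrix: pd.DataFrame, metric: str = "euclidean", method: str = "average"
) -> ClusterResult:
    """Hierarchically cluster profile rows (default Euclidean / average linkage)."""
    if matrix.shape[0] < 2:
        raise ValueError("clustering needs at least two rows")
    dist = pdist(matrix.to_numpy(float), metric=metric)
    Z = hierarchy.linkage(dist, method=method)
    return ClusterResult(linkage=Z, labels=tuple(matrix.index))
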