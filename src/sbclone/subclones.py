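"""Adjacency-matrix construction, subclone clustering and cell assignment.

Subclones are groups of insertion sites that co-occur across cells.  The
substrate is the site-by-site adjacency matrix M, where M[i][j] counts
the cells harbouring both site i and site j (diagonal: cells harbouring
site i).  Sites are clustered by average-linkage agglomerative clustering
on the normalised co-occurrence distance

    d(i, j) = 1 - M[i][j] / min(M[i][i], M[j][j]),

with pairs supported by fewer than ``min_support`` cells forced to
distance 1 so that private-site coincidences in single cells cannot seed
clusters.  The tree is cut at a fixed distance threshold and clusters
smaller than ``min_cluster_sites`` are dissolved into a singleton pool.
Each cell is then assigned to the unique subclone its sites overlap
(MULTI for doublet suspects overlapping several, UNASSIGNED for none).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .calling import CellProfile, InsertionSite, SampleDataset
from .reference import AnnotationIndex

MULTI = "MULTI"
UNASSIGNED = "UNASSIGNED"


@dataclass
class AdjacencyMatrix:
    """Symmetric site x site cell-sharing counts over a sample."""

    sites: list[InsertionSite]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sites)
        if self.matrix.shape != (n, n):
            raise ValueError("adjacency matrix shape does not match site list")


def build_adjacency(sample: SampleDataset) -> AdjacencyMatrix:
    """M[i][j] = number of cells harbouring both site i and site j.

    Site order is the sample's sorted nonredundant site list; computed as
    B^T B over the sparse cell-site incidence matrix.
    """
    sites = list(sample.nonredundant_sites)
    idx = {s: i for i, s in enumerate(sites)}
    rows, cols = [], []
    for ci, cell in enumerate(sample.cells):
        for s in cell.site_counts:
            j = idx.get(s)
            if j is not None:
                rows.append(ci)
                cols.append(j)
    B = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)),
        shape=(len(sample.cells), len(sites)),
    )
    M = (B.T @ B).toarray()
    return AdjacencyMatrix(sites, M)


@dataclass
class Subclone:
    """A recovered subclone: its site set, assigned cells and drivers."""

    subclone_id: str
    site_set: frozenset[InsertionSite]
    assigned_cells: set[str] = field(default_factory=set)
    driver_genes: set[str] = field(default_factory=set)


def cluster_sites(
    adjacency: AdjacencyMatrix,
    min_support: int = 2,
    linkage_method: str = "average",
    cut: float = 0.5,
    min_cluster_sites: int = 2,
) -> tuple[list[Subclone], list[InsertionSite]]:
    """Hierarchically cluster the adjacency matrix into disjoint site sets.

    Returns ``(subclones, pooled_sites)``; pooled sites are those left in
    clusters smaller than ``min_cluster_sites`` (typically the private
    sites of singleton cells).  Subclone ids are assigned in decreasing
    order of site-set size.
    """
    sites = adjacency.sites
    n = len(sites)
    if n == 0:
        return [], []
    if n == 1:
        if min_cluster_sites <= 1:
            return [Subclone("s1", frozenset(sites))], []
        return [], list(sites)
    M = adjacency.matrix.astype(float)
    diag = np.diag(M)
    denom = np.minimum.outer(diag, diag)
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(denom > 0, M / denom, 0.0)
    sim[adjacency.matrix < min_support] = 0.0
    D = 1.0 - sim
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method=linkage_method)
    labels = fcluster(Z, t=cut, criterion="distance")

    groups: dict[int, list[InsertionSite]] = {}
    for site, lab in zip(sites, labels):
        groups.setdefault(int(lab), []).append(site)

    clusters = [g for g in groups.values() if len(g) >= min_cluster_sites]
    pooled = [s for g in groups.values() if len(g) < min_cluster_sites for s in g]
    clusters.sort(key=lambda g: (-len(g), sorted(g)[0]))
    subclones = [
        Subclone(f"s{i + 1}", frozenset(g)) for i, g in enumerate(clusters)
    ]
    return subclones, sorted(pooled)


def assign_cells(
    cells: list[CellProfile],
    subclones: list[Subclone],
    min_overlap_sites: int = 1,
    min_reads_per_site: int = 10,
) -> dict[str, str]:
    """Label every cell with its unique subclone, MULTI, or UNASSIGNED.

    A cell is assigned to a subclone iff exactly one subclone's site set
    overlaps the cell's qualifying sites by at least
    ``min_overlap_sites``; overlaps with two or more mark a doublet
    suspect (MULTI).
    """
    assignment: dict[str, str] = {}
    for cell in cells:
        cell_sites = cell.qualifying_sites(min_reads_per_site)
        hits = [
            sc.subclone_id
            for sc in subclones
            if len(cell_sites & sc.site_set) >= min_overlap_sites
        ]
        if len(hits) == 1:
            assignment[cell.cell_barcode] = hits[0]
            for sc in subclones:
                if sc.subclone_id == hits[0]:
                    sc.assigned_cells.add(cell.cell_barcode)
        elif len(hits) > 1:
            assignment[cell.cell_barcode] = MULTI
        else:
            assignment[cell.cell_barcode] = UNASSIGNED
    return assignment


def annotate_drivers(
    subclones: list[Subclone],
    driver_genes: set[str],
    annotation: AnnotationIndex,
) -> list[Subclone]:
    """Mark each subclone with the driver genes its sites hit.

    ``driver_genes`` is the significant gene list from the bulk-tumour
    analysis (FDR <= 0.05); a gene is reported for a subclone iff at
    least one subclone site falls in the gene body or promoter window.
    Orientation is collapsed for annotation.
    """
    import logging

    if not driver_genes:
        logging.getLogger(__name__).warning(
            "empty driver gene list: all subclones annotated driverless"
        )
    for sc in subclones:
        hit: set[str] = set()
        for site in sc.site_set:
            hit |= annotation.annotate(*site.coordinate)
        sc.driver_genes = hit & set(driver_genes)
    return subclones


def load_driver_list(path) -> set[str]:
    """Read a driver gene list from TSV (column ``gene_id`` or first column)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    if "gene_id" in df.columns:
        return set(df["gene_id"].astype(str))
    first = pd.read_csv(path, sep="\t", comment="#", header=None)
    return set(first[0].astype(str))
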