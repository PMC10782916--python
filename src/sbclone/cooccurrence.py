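"""Recurrent co-occurring mutations and the TA-replacement permutation test.

A co-occurrence event for a gene pair is a pair of *distinct* insertion
sites, one annotated to each gene, observed together in at least one
cell.  Each unique site may contribute to at most one event, so events
within a cluster of related cells are counted once: the event count k is
the size of a maximum matching in the bipartite graph whose nodes are
the two genes' sites and whose edges join sites sharing a cell.

Significance is assessed by a structure-preserving permutation: every
nonredundant insertion site in a sample is replaced by a TA dinucleotide
drawn uniformly without replacement from the reference genome, the
cell-site incidence structure is carried over unchanged, and the
replaced sites are re-annotated against the same gene universe.  The raw
p-value of a pair is the fraction of trials showing at least one
co-occurrence event (the single co-occurrence rate; e.g. 3 positive
trials in 10 000 gives p = 0.003), Benjamini-Hochberg adjusted within
the sample's pair family.  The estimated p-value for observing k events
is the adjusted single-event p-value raised to the power k.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import maximum_bipartite_matching
from statsmodels.stats.multitest import multipletests

from .calling import CellProfile, InsertionSite, SampleDataset
from .reference import AnnotationIndex, TASiteIndex


def gene_site_map(
    sample: SampleDataset, annotation: AnnotationIndex
) -> dict[str, set[tuple[str, int]]]:
    """Map every annotated gene to its distinct hit coordinates in the sample.

    Orientation is collapsed: two insertions on opposite strands of one
    TA are one coordinate for annotation and co-occurrence purposes.
    """
    out: dict[str, set[tuple[str, int]]] = {}
    for site in sample.nonredundant_sites:
        coord = site.coordinate
        for gid in annotation.annotate(*coord):
            out.setdefault(gid, set()).add(coord)
    return out


def _cell_coords(cell: CellProfile) -> set[tuple[str, int]]:
    return {s.coordinate for s in cell.site_counts}


def _matching_size(edges: set[tuple], sites_a: list, sites_b: list) -> int:
    if not edges:
        return 0
    ai = {s: i for i, s in enumerate(sites_a)}
    bi = {s: i for i, s in enumerate(sites_b)}
    rows = [ai[a] for a, b in edges]
    cols = [bi[b] for a, b in edges]
    biadj = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(sites_a), len(sites_b)),
    )
    match = maximum_bipartite_matching(biadj, perm_type="column")
    return int((match != -1).sum())


def _greedy_size(edges: set[tuple]) -> int:
    used_a, used_b = set(), set()
    k = 0
    for a, b in sorted(edges):
        if a not in used_a and b not in used_b:
            used_a.add(a)
            used_b.add(b)
            k += 1
    return k


def count_pair_events(
    sample: SampleDataset,
    gene_a: str,
    gene_b: str,
    annotation: AnnotationIndex | None = None,
    gsmap: dict[str, set[tuple[str, int]]] | None = None,
    method: str = "matching",
) -> int:
    """Observed co-occurrence event count k for one gene pair.

    ``method="matching"`` (default) uses a maximum bipartite matching,
    which is deterministic and order-independent; ``"greedy"`` pairs
    sites first-come in sorted edge order, offered for sensitivity
    analysis.  A site annotated to both genes is never paired with
    itself.
    """
    if gene_a == gene_b:
        raise ValueError("co-occurrence requires two distinct genes")
    if gsmap is None:
        if annotation is None:
            raise ValueError("provide either a gene-site map or an annotation index")
        gsmap = gene_site_map(sample, annotation)
    sites_a = sorted(gsmap.get(gene_a, ()))
    sites_b = sorted(gsmap.get(gene_b, ()))
    if not sites_a or not sites_b:
        return 0
    set_a, set_b = set(sites_a), set(sites_b)
    edges: set[tuple] = set()
    for cell in sample.cells:
        coords = _cell_coords(cell)
        in_a = coords & set_a
        in_b = coords & set_b
        for a in in_a:
            for b in in_b:
                if a != b:
                    edges.add((a, b))
    if method == "greedy":
        return _greedy_size(edges)
    return _matching_size(edges, sites_a, sites_b)


def permute_sample(
    sample: SampleDataset,
    ta_index: TASiteIndex,
    seed: int | np.random.Generator,
) -> SampleDataset:
    """Replace every nonredundant site by a random TA site (bijection).

    Sites are drawn uniformly without replacement so distinct observed
    sites remain distinct; every cell's site list is rewritten through
    the bijection, preserving cell count, per-cell multiplicities and the
    cell-site incidence structure exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sites = list(sample.nonredundant_sites)
    names, cidx, pos = ta_index.flat()
    if len(pos) < len(sites):
        raise ValueError(
            f"fewer TA sites ({len(pos)}) than nonredundant sites ({len(sites)})"
        )
    draw = rng.choice(len(pos), size=len(sites), replace=False)
    mapping = {
        s: InsertionSite(names[int(cidx[d])], int(pos[d]), s.orientation)
        for s, d in zip(sites, draw)
    }
    new_cells = [
        CellProfile(
            c.cell_barcode,
            {mapping.get(s, s): n for s, n in c.site_counts.items()},
        )
        for c in sample.cells
    ]
    return SampleDataset(
        sample_id=sample.sample_id,
        cells=new_cells,
        nonredundant_sites=tuple(sorted(mapping[s] for s in sites)),
        audit=dict(sample.audit, permuted=True),
    )


def _incidence(sample: SampleDataset) -> tuple[list[InsertionSite], sparse.csr_matrix]:
    sites = list(sample.nonredundant_sites)
    idx = {s: i for i, s in enumerate(sites)}
    rows, cols = [], []
    for ci, cell in enumerate(sample.cells):
        for s in cell.site_counts:
            j = idx.get(s)
            if j is not None:
                rows.append(ci)
                cols.append(j)
    X = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int32), (rows, cols)),
        shape=(len(sample.cells), len(sites)),
    )
    return sites, X


def _trial_pair_events(
    X: sparse.csr_matrix,
    G: sparse.csc_matrix,
    col_a: int,
    col_b: int,
) -> int:
    """Exact event count for one pair in one permuted trial (site level)."""
    rows_a = G.indices[G.indptr[col_a] : G.indptr[col_a + 1]]
    rows_b = G.indices[G.indptr[col_b] : G.indptr[col_b + 1]]
    if len(rows_a) == 0 or len(rows_b) == 0:
        return 0
    XA = X[:, rows_a]
    XB = X[:, rows_b]
    E = (XA.T @ XB).toarray()
    # a site annotated to both genes cannot pair with itself
    for i, ga in enumerate(rows_a):
        for j, gb in enumerate(rows_b):
            if ga == gb:
                E[i, j] = 0
    biadj = sparse.csr_matrix(E > 0)
    if biadj.nnz == 0:
        return 0
    match = maximum_bipartite_matching(biadj, perm_type="column")
    return int((match != -1).sum())


def permutation_pvalues(
    sample: SampleDataset,
    pairs: list[tuple[str, str]],
    annotation: AnnotationIndex,
    ta_index: TASiteIndex,
    n_iter: int = 10_000,
    seed: int = 0,
    min_events: int | list[int] | None = None,
) -> pd.DataFrame:
    """Per-pair positive-trial counts c and raw p-values c / n_iter.

    For each of ``n_iter`` trials the sample's sites are replaced by
    random TA sites (structure preserved), re-annotated against the gene
    universe spanned by ``pairs``, and each pair is scored positive if it
    shows at least ``min_events`` co-occurrence events (default 1, the
    single co-occurrence rate).  Pairs with c = 0 are reported at the
    resolution bound 1 / n_iter and flagged.

    Trials derive their RNG streams from (seed, trial index), so results
    are reproducible and independent of evaluation order.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if seed < 0:
        raise ValueError("seed must be non-negative")
    for a, b in pairs:
        if a == b:
            raise ValueError(f"gene pair ({a!r}, {b!r}) is not a pair")
    thresholds = np.ones(len(pairs), dtype=np.int64)
    if min_events is not None:
        thresholds[:] = min_events
    if (thresholds < 1).any():
        raise ValueError("min_events must be >= 1")

    sites, X = _incidence(sample)
    n_sites = len(sites)
    universe = sorted({g for p in pairs for g in p})
    gene_order, ta_gene = annotation.ta_membership(ta_index, universe)
    col = {g: j for j, g in enumerate(gene_order)}
    ia = np.array([col[a] for a, _ in pairs], dtype=np.int64)
    ib = np.array([col[b] for _, b in pairs], dtype=np.int64)
    n_ta = ta_gene.shape[0]
    if n_ta < n_sites:
        raise ValueError(f"fewer TA sites ({n_ta}) than nonredundant sites ({n_sites})")

    deep = np.flatnonzero(thresholds > 1)
    c = np.zeros(len(pairs), dtype=np.int64)
    for t in range(n_iter):
        rng = np.random.default_rng([seed, t])
        idx = rng.choice(n_ta, size=n_sites, replace=False)
        G = ta_gene[idx]
        Y = (X @ G).toarray()
        ya = Y[:, ia]
        yb = Y[:, ib]
        both = (ya > 0) & (yb > 0)
        hit = both.any(axis=0)
        if hit.any():
            Gc = G.tocsc()
            # degenerate case: the only co-occurring "pair" is one site
            # annotated to both genes; such cells carry no event
            shared = Gc[:, ia].multiply(Gc[:, ib])
            if shared.nnz:
                shared_counts = (X @ shared).toarray()
                degenerate = (ya == 1) & (yb == 1) & (shared_counts == 1)
                hit = (both & ~degenerate).any(axis=0)
            for p in deep:
                if hit[p]:
                    k = _trial_pair_events(X, Gc, int(ia[p]), int(ib[p]))
                    hit[p] = k >= thresholds[p]
        c += hit
    p_raw = c / n_iter
    flagged = c == 0
    p_raw = np.where(flagged, 1.0 / n_iter, p_raw)
    return pd.DataFrame(
        {
            "gene_a": [a for a, _ in pairs],
            "gene_b": [b for _, b in pairs],
            "min_events": thresholds,
            "c": c,
            "n_iter": n_iter,
            "p_raw": p_raw,
            "p_raw_is_bound": flagged,
        }
    )


def raw_pvalue(c: int, n_iter: int) -> float:
    """Raw permutation p-value: positive-trial count over trial count."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not 0 <= c <= n_iter:
        raise ValueError("c must be between 0 and n_iter")
    return c / n_iter


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved.

    The family is all evaluated gene pairs within one sample.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def estimated_multi_p(p_adj: float, k: int) -> float:
    """Estimated p-value for observing k co-occurrence events: p_adj ** k.

    Identity for k = 1 (a single event's estimated p is its adjusted p).
    """
    if not (isinstance(k, (int, np.integer)) and k >= 1):
        raise ValueError(f"k must be an integer >= 1, got {k!r}")
    if not 0.0 < p_adj <= 1.0:
        raise ValueError(f"p_adj must be in (0, 1], got {p_adj!r}")
    return float(p_adj) ** int(k)


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (reporting convention)."""
    if x == 0:
        return 0.0
    return float(f"{x:.{sig - 1}e}")


def observed_pair_counts(
    sample: SampleDataset, annotation: AnnotationIndex
) -> pd.DataFrame:
    """Event counts for every gene pair with at least one event in a sample."""
    gsmap = gene_site_map(sample, annotation)
    genes = sorted(gsmap)
    rows = []
    for a, b in itertools.combinations(genes, 2):
        k = count_pair_events(sample, a, b, gsmap=gsmap)
        if k >= 1:
            rows.append({"gene_a": a, "gene_b": b, "k": k})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "k"])


def discover_recurrent_pairs(
    samples: list[SampleDataset], annotation: AnnotationIndex
) -> list[tuple[str, str]]:
    """Pairs recurrent within a sample (k >= 2) or across samples (k >= 1 twice)."""
    seen: dict[tuple[str, str], list[int]] = {}
    for sample in samples:
        df = observed_pair_counts(sample, annotation)
        for _, row in df.iterrows():
            seen.setdefault((row["gene_a"], row["gene_b"]), []).append(int(row["k"]))
    return sorted(
        pair
        for pair, ks in seen.items()
        if max(ks) >= 2 or len(ks) >= 2
    )


def analyze_cooccurrence(
    samples: list[SampleDataset],
    pairs: list[tuple[str, str]],
    annotation: AnnotationIndex,
    ta_index: TASiteIndex,
    n_iter: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Full per-pair result table across samples.

    For every supplied pair and every sample: observed event count k, raw
    permutation p, BH-adjusted p (family = all evaluated pairs within the
    sample), and the estimated p-value for k events (p_adj ** k, reported
    for pairs with k >= 1).
    """
    frames = []
    for si, sample in enumerate(samples):
        gsmap = gene_site_map(sample, annotation)
        ks = [count_pair_events(sample, a, b, gsmap=gsmap) for a, b in pairs]
        perm = permutation_pvalues(
            sample, pairs, annotation, ta_index, n_iter=n_iter, seed=seed + si
        )
        p_adj = bh_adjust(perm["p_raw"])
        p_est = [
            estimated_multi_p(pa, k) if k >= 1 else np.nan
            for pa, k in zip(p_adj, ks)
        ]
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sample.sample_id,
                    "gene_a": [a for a, _ in pairs],
                    "gene_b": [b for _, b in pairs],
                    "k": ks,
                    "c": perm["c"],
                    "p_raw": perm["p_raw"],
                    "p_raw_is_bound": perm["p_raw_is_bound"],
                    "p_adj": p_adj,
                    "p_est": p_est,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def find_recurrent_pairs(results: pd.DataFrame) -> pd.DataFrame:
    """Flag pairs recurrent across samples (k >= 1 in >= 2 samples) or
    within one sample (k >= 2)."""
    rows = []
    for (a, b), grp in results[results["k"] >= 1].groupby(["gene_a", "gene_b"]):
        rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "n_samples_with_events": len(grp),
                "max_k": int(grp["k"].max()),
                "recurrent_across_samples": len(grp) >= 2,
                "recurrent_within_sample": bool((grp["k"] >= 2).any()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_a",
            "gene_b",
            "n_samples_with_events",
            "max_k",
            "recurrent_across_samples",
            "recurrent_within_sample",
        ],
    )
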