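import itertools
import math

import numpy as np
import pandas as pd
import pytest

from sbclone.cooccurrence import (
    bh_adjust,
    count_pair_events,
    estimated_multi_p,
    find_recurrent_pairs,
    gene_site_map,
    permutation_pvalues,
    permute_sample,
    raw_pvalue,
    round_sig,
)
from sbclone.reference import AnnotationIndex, GeneModel, Genome, build_ta_index

from _reference_tables import CLEAN, TABLE_ROWS
from conftest import make_sample, site


def _annotation(gene_spans, window=0):
    genes = [GeneModel(gid, "chr1", "+", lo, hi) for gid, (lo, hi) in gene_spans.items()]
    return AnnotationIndex(genes, promoter_window=window)


def _matching_oracle(edges):
    """Exhaustive maximum-matching size by recursion over edges."""
    edges = list(edges)

    def best(i, used_a, used_b):
        if i == len(edges):
            return 0
        a, b = edges[i]
        skip = best(i + 1, used_a, used_b)
        if a not in used_a and b not in used_b:
            return max(skip, 1 + best(i + 1, used_a | {a}, used_b | {b}))
        return skip

    return best(0, frozenset(), frozenset())


class TestGeneSiteMap:
    def test_counts_sites_per_gene(self):
        ann = _annotation({"geneA": (0, 1000)})
        sample = make_sample({
            "c1": {site(10): 15, site(20): 15},
            "c2": {site(30): 15, site(5000): 15},
        })
        gsmap = gene_site_map(sample, ann)
        assert len(gsmap["geneA"]) == 3

    def test_intergenic_sample_is_empty(self):
        ann = _annotation({"geneA": (100_000, 101_000)})
        sample = make_sample({"c1": {site(10): 15, site(20): 15}})
        assert gene_site_map(sample, ann) == {}

    def test_agrees_with_per_site_annotation(self):
        rng = np.random.default_rng(2)
        ann = _annotation({f"g{i}": (i * 500, i * 500 + 400) for i in range(8)},
                          window=50)
        cells = {}
        for c in range(20):
            positions = rng.integers(0, 4200, size=3)
            cells[f"c{c}"] = {site(int(p)): 15 for p in positions}
        sample = make_sample(cells)
        gsmap = gene_site_map(sample, ann)
        inverted = {}
        for s in sample.nonredundant_sites:
            for gid in ann.annotate(*s.coordinate):
                inverted.setdefault(gid, set()).add(s.coordinate)
        assert gsmap == inverted


class TestCountPairEvents:
    def test_many_cells_one_subclone_counts_once(self):
        ann = _annotation({"A": (0, 100), "B": (200, 300)})
        cells = {f"c{i}": {site(10): 15, site(250): 15} for i in range(50)}
        sample = make_sample(cells)
        assert count_pair_events(sample, "A", "B", annotation=ann) == 1

    def test_independent_subclones_count_independently(self):
        ann = _annotation({"A": (0, 100), "B": (200, 300)})
        cells = {}
        for k in range(3):
            for i in range(10):
                cells[f"s{k}c{i}"] = {site(10 + k): 15, site(250 + k): 15}
        sample = make_sample(cells)
        assert count_pair_events(sample, "A", "B", annotation=ann) == 3

    def test_one_shared_a_site_two_b_sites_is_one_event(self):
        ann = _annotation({"A": (0, 100), "B": (200, 300)})
        cells = {
            "c1": {site(10): 15, site(250): 15},
            "c2": {site(10): 15, site(260): 15},
        }
        sample = make_sample(cells)
        assert count_pair_events(sample, "A", "B", annotation=ann) == 1

    def test_same_gene_rejected(self):
        ann = _annotation({"A": (0, 100)})
        sample = make_sample({"c": {site(10): 15, site(20): 15}})
        with pytest.raises(ValueError, match="distinct genes"):
            count_pair_events(sample, "A", "A", annotation=ann)

    def test_site_in_both_genes_never_pairs_with_itself(self):
        # overlapping genes share the site at 150
        ann = _annotation({"A": (0, 200), "B": (100, 300)})
        cells = {f"c{i}": {site(150): 15, site(150, orientation="-"): 15}
                 for i in range(5)}
        sample = make_sample(cells)
        # both orientations collapse to one coordinate: no distinct site pair
        assert count_pair_events(sample, "A", "B", annotation=ann) == 0

    def test_matches_exhaustive_matching_enumeration(self):
        """Maximum-matching event counts equal brute-force enumeration
        on random bipartite instances with up to 6 sites per gene."""
        rng = np.random.default_rng(31)
        ann = _annotation({"A": (0, 600), "B": (1000, 1600)})
        for trial in range(100):
            n_a = int(rng.integers(1, 7))
            n_b = int(rng.integers(1, 7))
            a_sites = [site(int(p)) for p in rng.choice(600, n_a, replace=False)]
            b_sites = [site(1000 + int(p)) for p in rng.choice(600, n_b, replace=False)]
            cells = {}
            for c in range(int(rng.integers(1, 12))):
                held = {}
                for s in a_sites:
                    if rng.random() < 0.4:
                        held[s] = 15
                for s in b_sites:
                    if rng.random() < 0.4:
                        held[s] = 15
                if len(held) >= 2:
                    cells[f"c{c}"] = held
            if not cells:
                continue
            sample = make_sample(cells)
            edges = set()
            for cell in sample.cells:
                coords = {s.coordinate for s in cell.site_counts}
                for a in coords & {s.coordinate for s in a_sites}:
                    for b in coords & {s.coordinate for s in b_sites}:
                        edges.add((a, b))
            k = count_pair_events(sample, "A", "B", annotation=ann)
            assert k == _matching_oracle(edges), f"trial {trial}"


class TestPermuteSample:
    def _null_sample(self, rng, n_cells=30, n_ta=400, m=3):
        genome = Genome({"chr1": "TA" * n_ta})
        ta = build_ta_index(genome)
        cells = {}
        for c in range(n_cells):
            pos = rng.choice(n_ta, m, replace=False) * 2
            cells[f"c{c}"] = {site(int(p)): 15 for p in pos}
        return make_sample(cells), ta

    def test_structure_preserved_on_random_fixtures(self):
        """Per-cell multiplicities and incidence degree sequences survive
        the TA replacement, on 50 random fixtures."""
        rng = np.random.default_rng(12)
        for trial in range(50):
            sample, ta = self._null_sample(rng, n_cells=int(rng.integers(5, 40)))
            permuted = permute_sample(sample, ta, seed=trial)
            assert permuted.n_cells == sample.n_cells
            for before, after in zip(sample.cells, permuted.cells):
                assert before.cell_barcode == after.cell_barcode
                assert len(after.site_counts) == len(before.site_counts)
                assert sorted(after.site_counts.values()) == sorted(
                    before.site_counts.values()
                )
            # site-degree multiset (cells per site) is invariant
            def degrees(s):
                from collections import Counter
                d = Counter()
                for cell in s.cells:
                    for st in cell.site_counts:
                        d[st] += 1
                return sorted(d.values())
            assert degrees(permuted) == degrees(sample)
            # bijection: distinct sites stay distinct
            assert len(set(permuted.nonredundant_sites)) == len(
                set(sample.nonredundant_sites)
            )

    def test_all_replacement_sites_are_ta(self):
        rng = np.random.default_rng(3)
        sample, ta = self._null_sample(rng)
        permuted = permute_sample(sample, ta, seed=0)
        for s in permuted.nonredundant_sites:
            assert s.position % 2 == 0  # TA positions in the TA-repeat genome

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        sample, ta = self._null_sample(rng)
        a = permute_sample(sample, ta, seed=7)
        b = permute_sample(sample, ta, seed=7)
        assert a.nonredundant_sites == b.nonredundant_sites

    def test_too_few_ta_sites_rejected(self):
        rng = np.random.default_rng(3)
        sample, _ = self._null_sample(rng)
        tiny = build_ta_index(Genome({"chr1": "TATA"}))
        with pytest.raises(ValueError, match="fewer TA sites"):
            permute_sample(sample, tiny, seed=0)


class TestPermutationPvalues:
    def test_worked_example_rate(self):
        assert raw_pvalue(3, 10_000) == 0.0003
        assert raw_pvalue(3, 1_000) == 0.003
        assert raw_pvalue(10_000, 10_000) == 1.0
        assert raw_pvalue(0, 10_000) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            raw_pvalue(3, 0)
        with pytest.raises(ValueError):
            raw_pvalue(-1, 10)

    def test_counts_and_determinism(self):
        genome = Genome({"chr1": "TA" * 500})
        ta = build_ta_index(genome)
        ann = _annotation({"A": (0, 200), "B": (600, 800)})
        cells = {f"c{i}": {site(10): 15, site(650): 15} for i in range(10)}
        sample = make_sample(cells)
        res1 = permutation_pvalues(sample, [("A", "B")], ann, ta, n_iter=200, seed=5)
        res2 = permutation_pvalues(sample, [("A", "B")], ann, ta, n_iter=200, seed=5)
        pd.testing.assert_frame_equal(res1, res2)
        assert res1.loc[0, "p_raw"] == res1.loc[0, "c"] / 200 or res1.loc[0, "p_raw_is_bound"].item()

    def test_matches_slow_permute_and_count_path(self):
        """The vectorised trial loop agrees with explicitly permuting the
        sample and recounting events, trial by trial."""
        genome = Genome({"chr1": "TA" * 300})
        ta = build_ta_index(genome)
        ann = _annotation({"A": (0, 120), "B": (200, 360), "C": (400, 560)})
        rng = np.random.default_rng(9)
        cells = {}
        for c in range(15):
            pos = rng.choice(300, 3, replace=False) * 2
            cells[f"c{c}"] = {site(int(p)): 15 for p in pos}
        sample = make_sample(cells)
        pairs = [("A", "B"), ("A", "C"), ("B", "C")]
        n_iter, seed = 40, 3
        res = permutation_pvalues(sample, pairs, ann, ta, n_iter=n_iter, seed=seed)
        slow = np.zeros(len(pairs), dtype=int)
        for t in range(n_iter):
            trial_rng = np.random.default_rng([seed, t])
            permuted = permute_sample(sample, ta, trial_rng)
            gsmap = gene_site_map(permuted, ann)
            for i, (a, b) in enumerate(pairs):
                if count_pair_events(permuted, a, b, gsmap=gsmap) >= 1:
                    slow[i] += 1
        assert res["c"].tolist() == slow.tolist()

    def test_zero_count_reported_as_bound(self):
        genome = Genome({"chr1": "TA" * 2000})
        ta = build_ta_index(genome)
        # genes so small a null co-occurrence is (nearly) impossible
        ann = _annotation({"A": (0, 2), "B": (4000 - 2, 4000)})
        cells = {f"c{i}": {site(0): 15, site(3998): 15} for i in range(3)}
        sample = make_sample(cells)
        res = permutation_pvalues(sample, [("A", "B")], ann, ta, n_iter=50, seed=1)
        if res.loc[0, "c"] == 0:
            assert res.loc[0, "p_raw_is_bound"].item()
            assert res.loc[0, "p_raw"] == 1 / 50

    def test_n_iter_must_be_positive(self):
        genome = Genome({"chr1": "TA" * 50})
        ta = build_ta_index(genome)
        ann = _annotation({"A": (0, 10), "B": (20, 30)})
        sample = make_sample({"c": {site(0): 15, site(22): 15}})
        with pytest.raises(ValueError, match="n_iter"):
            permutation_pvalues(sample, [("A", "B")], ann, ta, n_iter=0, seed=1)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.003])[0] == pytest.approx(0.003)

    def test_hand_computed_step_up(self):
        got = bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(got, [0.03, 0.03, 0.03])

    def test_empty_family(self):
        assert bh_adjust([]).size == 0

    def test_matches_independent_step_up_oracle(self):
        def oracle(p):
            p = np.asarray(p, dtype=float)
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            return adj

        rng = np.random.default_rng(17)
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 40)))
            assert np.allclose(bh_adjust(p), oracle(p))

    def test_adjusted_at_least_raw_and_at_most_one(self):
        rng = np.random.default_rng(23)
        p = rng.random(100) * 0.2
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()


class TestEstimatedMultiP:
    def test_identity_for_single_event(self):
        assert estimated_multi_p(2.29e-03, 1) == pytest.approx(2.29e-03)

    @pytest.mark.parametrize("p_adj,k,expected", [
        (1.26e-03, 3, 2.00e-09),
        (6.59e-04, 2, 4.34e-07),
        (6.40e-04, 2, 4.10e-07),
    ])
    def test_published_examples(self, p_adj, k, expected):
        assert round_sig(estimated_multi_p(p_adj, k), 3) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            estimated_multi_p(0.5, 0)
        with pytest.raises(ValueError):
            estimated_multi_p(1.5, 1)
        with pytest.raises(ValueError):
            estimated_multi_p(0.0, 1)

    def test_reference_table_reproduced(self):
        """Every published row's estimated p recomputes from its adjusted p
        and event count; printed inputs are 3-s.f. rounded, so non-clean
        rows are checked against the rounding interval of the input."""
        for gene_a, gene_b, sample_id, k, p_adj, p_est in TABLE_ROWS:
            got = round_sig(estimated_multi_p(p_adj, k), 3)
            if (gene_a, gene_b, sample_id) in CLEAN:
                assert got == pytest.approx(p_est), (gene_a, gene_b, sample_id)
            else:
                step = 10 ** math.floor(math.log10(p_adj)) / 100  # half-ulp of input
                lo = round_sig((p_adj - step / 2) ** k, 3)
                hi = round_sig((p_adj + step / 2) ** k, 3)
                ulp_out = 10 ** math.floor(math.log10(p_est)) / 100
                assert lo - ulp_out <= p_est <= hi + ulp_out, (gene_a, gene_b, sample_id)


class TestRecurrentPairs:
    def _results(self):
        return pd.DataFrame([
            {"sample_id": "a", "gene_a": "NEDD4L", "gene_b": "BRAF", "k": 1},
            {"sample_id": "b", "gene_a": "NEDD4L", "gene_b": "BRAF", "k": 3},
            {"sample_id": "a", "gene_a": "MITF", "gene_b": "LPAR1", "k": 3},
            {"sample_id": "c", "gene_a": "PTPRD", "gene_b": "WWC3", "k": 1},
        ])

    def test_across_and_within_sample_flags(self):
        rep = find_recurrent_pairs(self._results()).set_index(["gene_a", "gene_b"])
        assert rep.loc[("NEDD4L", "BRAF"), "recurrent_across_samples"].item()
        assert not rep.loc[("MITF", "LPAR1"), "recurrent_across_samples"].item()
        assert rep.loc[("MITF", "LPAR1"), "recurrent_within_sample"].item()
        assert not rep.loc[("PTPRD", "WWC3"), "recurrent_across_samples"].item()
        assert not rep.loc[("PTPRD", "WWC3"), "recurrent_within_sample"].item()
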