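"""Overlap trimming, collapsing, diversity statistics and MSN, with
independent brute-force oracles on small instances."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapshift.haplotypes import (
    collapse_haplotypes,
    concordance,
    diversity_stats,
    extract_overlap,
    haplotype_diversity,
    minimum_spanning_network,
    nucleotide_diversity,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def pi_oracle(seqs):
    """Brute-force nucleotide diversity: explicit double loop over pairs."""
    n = len(seqs)
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += sum(a != b for a, b in zip(seqs[i], seqs[j]))
    return total / (n * (n - 1) / 2) / len(seqs[0])


def msn_oracle(ids, seqs):
    """Union of all minimum spanning trees by exhaustive enumeration."""
    n = len(ids)
    dist = {
        (i, j): sum(a != b for a, b in zip(seqs[i], seqs[j]))
        for i in range(n)
        for j in range(i + 1, n)
    }
    all_edges = list(dist)
    best_w, best_trees = None, []
    for tree in itertools.combinations(all_edges, n - 1):
        # connectivity check
        comp = list(range(n))

        def find(x):
            while comp[x] != x:
                x = comp[x]
            return x

        for i, j in tree:
            ri, rj = find(i), find(j)
            if ri != rj:
                comp[ri] = rj
        if len({find(i) for i in range(n)}) != 1:
            continue
        w = sum(dist[e] for e in tree)
        if best_w is None or w < best_w:
            best_w, best_trees = w, [tree]
        elif w == best_w:
            best_trees.append(tree)
    union = set()
    for tree in best_trees:
        union.update(frozenset((ids[i], ids[j])) for i, j in tree)
    return union


def random_seqs(rng, n, L):
    return ["".join("ACGT"[i] for i in rng.integers(0, 3, L)) for _ in range(n)]


# ---------------------------------------------------------------------------
# overlap extraction
# ---------------------------------------------------------------------------

class TestExtractOverlap:
    def _tissue(self, L=626, seed=0):
        rng = np.random.default_rng(seed)
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, L))
        return base, [("t1", base), ("t2", base[:-1] + ("A" if base[-1] != "A" else "C"))]

    def test_interior_edna_fragment_sets_window_length(self):
        base, tissue = self._tissue(626)
        edna = [("e1", base[200:391])]  # 191 bp interior fragment
        trimmed, (start, end) = extract_overlap(tissue, edna)
        assert (start, end) == (200, 391)
        assert all(len(s) == 191 for s in trimmed.values())

    def test_identical_sets_keep_full_window(self):
        base, tissue = self._tissue(300)
        trimmed, (start, end) = extract_overlap(tissue, [("e1", base)])
        assert (start, end) == (0, 300)

    def test_disjoint_fragments_error_names_sequences(self):
        base, _ = self._tissue(600)
        tissue = [("t1", base[:200] + "-" * 400)]
        edna = [("e1", base[400:])]
        with pytest.raises(ValueError, match="e1|t1"):
            extract_overlap(tissue, edna)

    def test_end_gap_padding_narrows_window(self):
        base, _ = self._tissue(400)
        tissue = [("t1", base), ("t2", "-" * 50 + base[50:])]
        edna = [("e1", base[40:340])]
        trimmed, (start, end) = extract_overlap(tissue, edna)
        assert start == 50 and end == 340


class TestCollapse:
    def test_exact_grouping_with_counts(self):
        hs = collapse_haplotypes([("a", "ACGT"), ("b", "ACGT"), ("c", "ACGA")])
        assert len(hs.haplotypes) == 2
        assert hs.counts.loc["H1", "all"] == 2
        assert hs.counts.loc["H2", "all"] == 1

    def test_ambiguous_sequences_discarded(self):
        hs = collapse_haplotypes([("a", "ACGT"), ("b", "ACNT")])
        assert hs.discarded == ["b"]
        assert len(hs.haplotypes) == 1

    def test_idempotent(self):
        records = [("a", "ACGT"), ("b", "ACGT"), ("c", "ACGA")]
        once = collapse_haplotypes(records)
        # re-collapsing the distinct haplotypes is a no-op on the set; carrying
        # the counts as weights also preserves the frequency ordering
        weights = {h: float(once.counts.loc[h, "all"]) for h, _ in once.haplotypes}
        again = collapse_haplotypes(once.haplotypes, weights=weights)
        assert [s for _, s in again.haplotypes] == [s for _, s in once.haplotypes]
        assert {s for _, s in collapse_haplotypes(once.haplotypes).haplotypes} == {
            s for _, s in once.haplotypes
        }


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

class TestDiversity:
    def test_pi_zero_iff_identical(self):
        assert nucleotide_diversity(["ACGT"] * 5) == 0.0

    def test_pi_hand_example(self):
        # {AAA, AAT, ATT}: pair diffs 1, 2, 1 -> mean 4/3; pi = (4/3)/3
        assert nucleotide_diversity(["AAA", "AAT", "ATT"]) == pytest.approx(4 / 9)

    def test_pi_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n, L = int(rng.integers(2, 9)), int(rng.integers(2, 11))
            seqs = random_seqs(rng, n, L)
            assert nucleotide_diversity(seqs) == pytest.approx(pi_oracle(seqs))

    def test_pi_requires_two_sequences(self):
        with pytest.raises(ValueError):
            nucleotide_diversity(["ACGT"])

    @pytest.mark.parametrize(
        "counts,expected",
        [([5], 0.0), ([2, 2], 2 / 3), ([1, 1], 1.0)],
    )
    def test_hd_formula(self, counts, expected):
        assert haplotype_diversity(counts) == pytest.approx(expected)

    def test_hd_bounds_property(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            counts = rng.integers(1, 20, size=rng.integers(1, 8))
            if counts.sum() < 2:
                continue
            hd = haplotype_diversity(counts)
            assert 0.0 <= hd <= 1.0

    @given(
        st.lists(st.text(alphabet="ACG", min_size=6, max_size=6), min_size=2, max_size=8)
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_pi_oracle_equivalence_property(self, seqs):
        assert nucleotide_diversity(seqs) == pytest.approx(pi_oracle(seqs))

    def test_diversity_stats_bundles_both(self):
        d = diversity_stats(["AAA", "AAT", "ATT"])
        assert d.n == 3 and d.L == 3 and d.pi > 0 and 0 < d.hd <= 1


# ---------------------------------------------------------------------------
# minimum spanning network
# ---------------------------------------------------------------------------

class TestMSN:
    def test_chain_topology(self):
        # AB=1, BC=1, AC=2 -> exactly the two unit edges
        g = minimum_spanning_network([("A", "AAA"), ("B", "AAT"), ("C", "ATT")])
        assert {frozenset(e) for e in g.edges} == {
            frozenset({"A", "B"}),
            frozenset({"B", "C"}),
        }

    def test_equilateral_triangle_keeps_all_edges(self):
        g = minimum_spanning_network([("A", "AAA"), ("B", "AAT"), ("C", "AAC")])
        assert g.number_of_edges() == 3

    def test_single_haplotype(self):
        g = minimum_spanning_network([("A", "ACGT")])
        assert g.number_of_nodes() == 1 and g.number_of_edges() == 0

    def test_matches_all_mst_union_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n, L = int(rng.integers(2, 7)), int(rng.integers(3, 11))
            seqs = random_seqs(rng, n, L)
            # de-duplicate: haplotypes are distinct by construction
            seqs = list(dict.fromkeys(seqs))
            if len(seqs) < 2:
                continue
            ids = [f"h{i}" for i in range(len(seqs))]
            g = minimum_spanning_network(list(zip(ids, seqs)))
            got = {frozenset(e) for e in g.edges}
            assert got == msn_oracle(ids, seqs)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(3)
        seqs = list(dict.fromkeys(random_seqs(rng, 6, 8)))
        ids = [f"h{i}" for i in range(len(seqs))]
        pairs = list(zip(ids, seqs))
        g1 = minimum_spanning_network(pairs)
        g2 = minimum_spanning_network(list(reversed(pairs)))
        assert {frozenset(e) for e in g1.edges} == {frozenset(e) for e in g2.edges}

    def test_contains_a_minimum_spanning_tree(self):
        import networkx as nx

        rng = np.random.default_rng(9)
        seqs = list(dict.fromkeys(random_seqs(rng, 6, 10)))
        ids = [f"h{i}" for i in range(len(seqs))]
        g = minimum_spanning_network(list(zip(ids, seqs)))
        full = nx.Graph()
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                w = sum(a != b for a, b in zip(seqs[i], seqs[j]))
                full.add_edge(ids[i], ids[j], weight=w)
        mst = nx.minimum_spanning_tree(full)
        mst_w = sum(d["weight"] for _, _, d in mst.edges(data=True))
        # the MSN must contain some spanning tree of that same minimal weight
        sub_mst = nx.minimum_spanning_tree(g)
        sub_w = sum(d["weight"] for _, _, d in sub_mst.edges(data=True))
        assert nx.is_connected(g)
        assert sub_w == mst_w


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

class TestConcordance:
    def _set(self, seqs, prefix):
        return collapse_haplotypes(
            [(f"{prefix}{i}", s) for i, s in enumerate(seqs)], prefix=prefix
        )

    def test_set_arithmetic(self):
        tissue = self._set(["AAAA", "CCCC", "GGGG"], "T")
        edna = self._set(["AAAA", "TTTT"], "E")
        shared, t_only, e_only, table = concordance(tissue, edna)
        assert (shared, t_only, e_only) == (1, 2, 1)
        assert set(table["status"]) == {"shared", "tissue_only", "edna_only"}

    def test_identical_sets(self):
        tissue = self._set(["AAAA", "CCCC"], "T")
        edna = self._set(["CCCC", "AAAA"], "E")
        assert concordance(tissue, edna)[:3] == (2, 0, 0)

    def test_empty_edna(self):
        tissue = self._set(["AAAA", "CCCC"], "T")
        edna = self._set([], "E")
        assert concordance(tissue, edna)[:3] == (0, 2, 0)

    def test_window_mismatch_rejected(self):
        tissue = self._set(["AAAA"], "T")
        edna = self._set(["AAA"], "E")
        with pytest.raises(ValueError):
            concordance(tissue, edna)
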