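"""Gene vectors, cosine similarity, clustering, and Newick serialization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_gene_matrix, brute_recurrence

from panrecur.io import Catalog, MutationKey
from panrecur.recurrence import recurrence_counts
from panrecur.similarity import (
    cosine_similarity_matrix,
    gene_donor_matrix,
    hierarchical_dendrogram,
    pan_recurrent_set,
    to_newick,
)
from panrecur.simulate import SimConfig, generate_catalog


def _row(donor, ctype, start, gene="G1"):
    return {"donor_id": donor, "cancer_type": ctype, "chromosome": "1",
            "start": start, "ref": "A", "alt": "T",
            "consequence": "missense_variant", "gene": gene}


class TestPanRecurrentSet:
    def test_keeps_only_multi_donor_keys(self, toy_catalog):
        table = recurrence_counts(toy_catalog, "PanCancer")
        assert pan_recurrent_set(table) == {MutationKey("7", 140453136, "A", "T")}

    def test_empty_when_nothing_recurs(self):
        cat = Catalog(pd.DataFrame([_row("d1", "T", 1), _row("d2", "T", 2)]))
        assert pan_recurrent_set(recurrence_counts(cat, "PanCancer")) == set()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_filter(self, seed):
        cfg = SimConfig(donors=40, burden_mean=10.0, shared_fraction=0.5,
                        shared_pool_size=60, seed=seed)
        cat = generate_catalog(cfg)
        got = pan_recurrent_set(recurrence_counts(cat, "PanCancer"))
        ref = {m for m, d in brute_recurrence(cat, "PanCancer").items()
               if len(d) >= 2}
        assert got == ref


class TestGeneDonorMatrix:
    def test_donor_counted_once_per_gene(self):
        rows = [
            _row("d1", "T", 10, "G"),
            _row("d2", "T", 10, "G"),
            _row("d2", "T", 20, "G"),
            _row("d3", "T", 20, "G"),
        ]
        cat = Catalog(pd.DataFrame(rows))
        recurrent = pan_recurrent_set(recurrence_counts(cat, "PanCancer"))
        m = gene_donor_matrix(cat, recurrent)
        assert m.loc["T", "G"] == 3  # d2 counted once despite two hits

    def test_gene_recurrent_only_in_one_type_is_zero_elsewhere(self):
        rows = [
            _row("d1", "U", 10, "GU"), _row("d2", "U", 10, "GU"),
            _row("d3", "V", 30, "GV"), _row("d4", "V", 30, "GV"),
        ]
        cat = Catalog(pd.DataFrame(rows))
        m = gene_donor_matrix(
            cat, pan_recurrent_set(recurrence_counts(cat, "PanCancer"))
        )
        assert m.loc["U", "GU"] == 2 and m.loc["V", "GU"] == 0

    def test_all_unlabeled_recurrent_calls_error(self):
        rows = [_row("d1", "T", 10, ""), _row("d2", "T", 10, "")]
        cat = Catalog(pd.DataFrame(rows))
        recurrent = pan_recurrent_set(recurrence_counts(cat, "PanCancer"))
        with pytest.raises(ValueError, match="gene label"):
            gene_donor_matrix(cat, recurrent)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_triple_loop(self, seed):
        cfgs = [
            SimConfig(cancer_type=t, donors=25, burden_mean=10.0,
                      shared_fraction=0.5, shared_pool_size=50,
                      genes=10, pool_label="pan")
            for t in ("TA", "TB", "TC")
        ]
        cat = generate_catalog(cfgs, seed=seed)
        recurrent = pan_recurrent_set(recurrence_counts(cat, "PanCancer"))
        m = gene_donor_matrix(cat, recurrent)
        ref = brute_gene_matrix(cat, recurrent)
        for (t, g), n in ref.items():
            assert m.loc[t, g] == n
        assert int(m.to_numpy().sum()) == sum(ref.values())


class TestCosineSimilarity:
    def test_closed_forms(self):
        m = pd.DataFrame(
            [[1, 2, 0], [2, 4, 0], [0, 0, 5], [1, 1, 0]],
            index=["A", "B", "C", "D"], columns=["g1", "g2", "g3"],
        )
        s = cosine_similarity_matrix(m)
        assert s.loc["A", "B"] == pytest.approx(1.0)
        assert s.loc["A", "C"] == pytest.approx(0.0)
        # (1,2,0) vs (1,1,0): 3/(sqrt(5)*sqrt(2))
        assert s.loc["A", "D"] == pytest.approx(3 / np.sqrt(10))
        m2 = pd.DataFrame([[1, 1], [1, 0]], index=["X", "Y"], columns=["a", "b"])
        assert cosine_similarity_matrix(m2).loc["X", "Y"] == pytest.approx(
            1 / np.sqrt(2)
        )

    def test_symmetric_unit_diagonal_in_unit_interval(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.integers(0, 9, size=(6, 11)).astype(float) + 0.01)
        s = cosine_similarity_matrix(m)
        v = s.to_numpy()
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 1.0)
        assert ((v >= 0) & (v <= 1)).all()

    def test_zero_row_names_the_type(self):
        m = pd.DataFrame([[1, 2], [0, 0]], index=["OK", "BAD"])
        with pytest.raises(ValueError, match="BAD"):
            cosine_similarity_matrix(m)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        row=st.integers(min_value=0, max_value=2),
    )
    def test_invariant_to_positive_rescaling(self, scale, row):
        m = pd.DataFrame(
            [[3.0, 1.0, 0.0], [1.0, 4.0, 2.0], [0.5, 0.5, 5.0]],
            index=list("ABC"),
        )
        scaled = m.copy()
        scaled.iloc[row] *= scale
        a = cosine_similarity_matrix(m).to_numpy()
        b = cosine_similarity_matrix(scaled).to_numpy()
        assert np.allclose(a, b, atol=1e-12)


class TestDendrogram:
    def _sim(self, values, labels):
        return pd.DataFrame(values, index=labels, columns=labels)

    def test_two_types_merge_at_one_minus_similarity(self):
        sim = self._sim([[1.0, 0.8], [0.8, 1.0]], ["A", "B"])
        d = hierarchical_dendrogram(sim)
        assert d.root.height == pytest.approx(0.2)
        assert d.leaves == ("A", "B")

    def test_three_types_hand_executed_average_linkage(self):
        sim = self._sim(
            [[1.0, 0.9, 0.1], [0.9, 1.0, 0.1], [0.1, 0.1, 1.0]], ["A", "B", "C"]
        )
        d = hierarchical_dendrogram(sim, "average")
        merges = d.merges()
        assert merges[0] == (("A",), ("B",), pytest.approx(0.1))
        assert merges[1] == (("A", "B"), ("C",), pytest.approx(0.9))

    def test_leaves_are_permutation_and_heights_monotone(self):
        rng = np.random.default_rng(3)
        labels = [f"T{i}" for i in range(7)]
        v = rng.random((7, 7))
        sim = (v + v.T) / 2
        np.fill_diagonal(sim, 1.0)
        d = hierarchical_dendrogram(self._sim(sim, labels))
        assert sorted(d.leaves) == sorted(labels)
        heights = [h for _, _, h in d.merges()]
        assert heights == sorted(heights)

    @pytest.mark.parametrize("seed", range(5))
    def test_cophenetic_matches_scipy_average_linkage(self, seed):
        # independent reference: scipy's agglomerative implementation
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(seed)
        n = 6
        v = rng.random((n, n))
        sim = (v + v.T) / 2
        np.fill_diagonal(sim, 1.0)
        labels = [f"T{i}" for i in range(n)]
        d = hierarchical_dendrogram(self._sim(sim, labels))
        ours = d.cophenetic().loc[labels, labels].to_numpy()
        z = linkage(squareform(1.0 - sim, checks=False), method="average")
        theirs = squareform(cophenet(z))
        assert np.allclose(ours, theirs, atol=1e-12)

    def test_fewer_than_two_types_rejected(self):
        sim = self._sim([[1.0]], ["A"])
        with pytest.raises(ValueError, match="at least 2"):
            hierarchical_dendrogram(sim)


class TestNewick:
    def test_two_leaf_height_halving(self):
        sim = pd.DataFrame([[1.0, 0.8], [0.8, 1.0]], index=["A", "B"],
                           columns=["A", "B"])
        d = hierarchical_dendrogram(sim)
        assert to_newick(d) == "(A:0.1,B:0.1);"

    def test_three_leaf_arithmetic(self):
        sim = pd.DataFrame(
            [[1.0, 0.9, 0.1], [0.9, 1.0, 0.1], [0.1, 0.1, 1.0]],
            index=["A", "B", "C"], columns=["A", "B", "C"],
        )
        assert to_newick(hierarchical_dendrogram(sim)) == \
            "((A:0.05,B:0.05):0.4,C:0.45);"

    def test_round_trip_topology_and_heights(self):
        import dendropy

        rng = np.random.default_rng(1)
        n = 5
        v = rng.random((n, n))
        sim = (v + v.T) / 2
        np.fill_diagonal(sim, 1.0)
        labels = [f"T{i}" for i in range(n)]
        d = hierarchical_dendrogram(pd.DataFrame(sim, index=labels, columns=labels))
        tree = dendropy.Tree.get(data=to_newick(d), schema="newick")
        assert sorted(l.taxon.label for l in tree.leaf_node_iter()) == labels
        pdm = tree.phylogenetic_distance_matrix()
        coph = d.cophenetic()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for a in labels:
            for b in labels:
                if a < b:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                        coph.loc[a, b], abs=1e-4
                    )

    def test_labels_with_special_characters_escaped(self):
        sim = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]],
                           index=["A B", "C(D)"], columns=["A B", "C(D)"])
        nwk = to_newick(hierarchical_dendrogram(sim))
        assert "'A B'" in nwk and "'C(D)'" in nwk
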