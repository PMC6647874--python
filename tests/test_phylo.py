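"""Distance models, neighbor joining, bootstrap, Newick round-trips."""

import math

import numpy as np
import pytest

from t3mine.phylo import (
    MSA,
    DistanceMatrix,
    SaturationError,
    bootstrap_support,

    jc_protein_distance,
    k80_distance,
    neighbor_joining,
    read_newick,
    write_newick,
)
from t3mine.simulate import generate_alignment, random_additive_tree, tree_distances


class TestDistances:
    def test_identical_sequences_are_zero(self):
        assert k80_distance("ACGTACGT", "ACGTACGT") == 0.0
        assert jc_protein_distance("MKTAY", "MKTAY") == 0.0

    def test_k80_single_transition_closed_form(self):
        # P = 0.1, Q = 0 -> -1/2 ln(0.8)
        d = k80_distance("AAAAAAAAAA", "GAAAAAAAAA")
        assert d == pytest.approx(-0.5 * math.log(0.8), abs=1e-12)
        assert d == pytest.approx(0.1116, abs=1e-4)

    def test_k80_saturation_boundary(self):
        # P = 0.4, Q = 0.2 makes 1 - 2P - Q = 0
        a = "A" * 10
        b = "G" * 4 + "C" * 2 + "A" * 4
        with pytest.raises(SaturationError):
            k80_distance(a, b)
        assert math.isinf(k80_distance(a, b, on_saturation="inf"))

    def test_jc_protein_closed_form(self):
        a = "A" * 1000
        b = "C" * 475 + "A" * 525
        assert jc_protein_distance(a, b) == pytest.approx(-0.95 * math.log(0.5), abs=1e-12)
        assert jc_protein_distance(a, b) == pytest.approx(0.6585, abs=1e-4)

    def test_jc_protein_saturation(self):
        with pytest.raises(SaturationError):
            jc_protein_distance("A" * 100, "C" * 95 + "A" * 5)

    def test_pairwise_deletion_skips_gaps_and_n(self):
        # comparable columns: positions 3..10 only
        a = "-NACGTACGT"
        b = "AAACGTACGA"
        d = k80_distance(a, b)
        # 8 comparable, 1 transversal difference (T vs A) -> P=0, Q=1/8
        q = 1 / 8
        assert d == pytest.approx(-0.5 * math.log(1 - q) - 0.25 * math.log(1 - 2 * q))

    def test_k80_reduces_to_jc_when_ts_equals_tv(self):
        """With transitions spread like transversions, K80 = JC69 distance."""
        # 12 sites: 1 transition + 2 transversions = p = 3/12, P = 1/12 = Q/2
        a = "AAAA" + "CCCC" + "GGGG"
        b = "GAAA" + "ACCC" + "TGGG"
        d = k80_distance(a, b)
        p = 3 / 12
        jc = -0.75 * math.log(1 - 4 * p / 3)
        assert d == pytest.approx(jc, rel=1e-9)


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> path-sum distances
        taxa = ("A", "B", "C", "D")
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(DistanceMatrix(taxa, d))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        tips = {t.name: t.length for t in tree.tree.tips()}
        recovered = tree_distances(tree)
        idx = [recovered.taxa.index(t) for t in taxa]
        assert np.allclose(recovered.d[np.ix_(idx, idx)], d, atol=1e-12)
        assert tips["A"] == pytest.approx(1.0)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(("A", "B", "C"), d))
        lengths = {t.name: t.length for t in tree.tree.tips()}
        assert lengths == {
            "A": pytest.approx(1.0),
            "B": pytest.approx(2.0),
            "C": pytest.approx(3.0),
        }

    def test_degenerate_equal_matrix_is_deterministic(self):
        d = np.ones((5, 5)) - np.eye(5)
        taxa = tuple("ABCDE")
        t1 = neighbor_joining(DistanceMatrix(taxa, d.copy()))
        t2 = neighbor_joining(DistanceMatrix(taxa, d.copy()))
        assert t1.to_newick() == t2.to_newick()

    def test_invalid_matrix_rejected(self):
        bad = np.array([[0, 1], [2, 0]], dtype=float)
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(("A", "B"), bad))
        nan = np.full((3, 3), np.nan)
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(("A", "B", "C"), nan))

    @pytest.mark.parametrize("seed", range(5))
    def test_random_additive_trees_recovered(self, seed):
        """NJ inverts path-sum distances of random trees (topology + lengths)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        true = random_additive_tree(n, rng)
        dm = tree_distances(true)
        nj = neighbor_joining(dm)
        assert nj.bipartitions() == true.bipartitions()
        back = tree_distances(nj)
        idx = [back.taxa.index(t) for t in dm.taxa]
        assert np.abs(back.d[np.ix_(idx, idx)] - dm.d).max() < 1e-9

    def test_nj_agrees_with_reference_implementation(self):
        """Cross-check topology against scikit-bio's independent NJ."""
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(99)
        true = random_additive_tree(8, rng)
        dm = tree_distances(true)
        ours = neighbor_joining(dm)
        theirs = sk_nj(SkDM(dm.d, ids=list(dm.taxa)))
        from t3mine.phylo import bipartitions

        assert bipartitions(theirs, dm.taxa) == ours.bipartitions()


class TestBootstrap:
    def two_clade_msa(self) -> MSA:
        """Within-clade identity, ~50% between-clade divergence."""
        rng = np.random.default_rng(0)
        n = 400
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
        other = "".join(
            "ACGT"[(i + 1 + rng.integers(3)) % 4] if rng.random() < 0.5 else "ACGT"[i]
            for i in (("ACGT".index(c)) for c in base)
        )
        return MSA(("A1", "A2", "B1", "B2"), (base, base, other, other))

    def test_central_split_fully_supported(self):
        tree = bootstrap_support(self.two_clade_msa(), n_replicates=100, seed=21)
        split = frozenset({"B1", "B2"})
        assert tree.supports[split] == 1.0
        assert tree.skipped_replicates == 0

    def test_same_seed_bitwise_identical(self):
        msa = self.two_clade_msa()
        t1 = bootstrap_support(msa, 50, "k80", seed=5)
        t2 = bootstrap_support(msa, 50, "k80", seed=5)
        assert t1.to_newick() == t2.to_newick()
        assert t1.supports == t2.supports

    def test_support_invariant_to_taxon_order(self):
        msa = self.two_clade_msa()
        perm = MSA(
            (msa.taxa[2], msa.taxa[0], msa.taxa[3], msa.taxa[1]),
            (msa.rows[2], msa.rows[0], msa.rows[3], msa.rows[1]),
        )
        t1 = bootstrap_support(msa, 50, seed=5)
        t2 = bootstrap_support(perm, 50, seed=5)
        split = frozenset({"B1", "B2"})
        assert t1.supports[split] == t2.supports[split] == 1.0

    def test_supports_within_percent_range(self):
        msa, _ = generate_alignment(
            "((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1,E:0.2);", length=300, seed=3
        )
        tree = bootstrap_support(msa, 50, seed=9)
        for node in tree.tree.non_tips():
            if node.name is not None:
                assert 0 <= int(node.name) <= 100

    def test_identical_sequences_give_tie_broken_full_support(self):
        """Star signal: the tie-broken topology is reproduced by every
        replicate, so its (arbitrary) splits carry 100% support."""
        msa = MSA(tuple("ABCD"), ("ACGT" * 25,) * 4)
        tree = bootstrap_support(msa, 20, seed=1)
        assert all(v == 1.0 for v in tree.supports.values())


class TestNewick:
    def test_three_taxon_string_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(("A", "B", "C"), d))
        nwk = tree.to_newick()
        assert nwk.startswith("(") and nwk.endswith(";")
        for label in ("A:1", "B:2", "C:3"):
            assert label in nwk

    def test_round_trip_topology_and_lengths(self, tmp_path):
        rng = np.random.default_rng(4)
        true = random_additive_tree(10, rng)
        nj = neighbor_joining(tree_distances(true))
        path = tmp_path / "t.nwk"
        write_newick(nj, path)
        back = read_newick(path)
        assert back.bipartitions() == nj.bipartitions()
        d1, d2 = tree_distances(nj), tree_distances(back)
        idx = [d2.taxa.index(t) for t in d1.taxa]
        assert np.allclose(d2.d[np.ix_(idx, idx)], d1.d, atol=1e-9)

    def test_label_with_comma_survives(self, tmp_path):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(("Taxon, odd", "B", "C"), d))
        path = tmp_path / "odd.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert "Taxon, odd" in back.taxa
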