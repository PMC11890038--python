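"""MinHash sketches, Mash distances, NJ trees and monophyly checks."""

import math
import warnings

import numpy as np
import pytest

import kmerpop as kp
from kmerpop.sketchdist import (
    read_sketch_json,
    sketch_from_fasta,
    write_sketch_json,
    _hash_kmer,
)

from _oracles import exact_jaccard, random_additive_tree


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestSketch:
    def test_deterministic(self, rng):
        seq = random_seq(rng, 500)
        params = kp.SketchParams(k=7, s=50)
        assert kp.sketch(seq, params).hashes == kp.sketch(seq, params).hashes

    def test_no_truncation_when_s_large(self, rng):
        seq = random_seq(rng, 300)
        params = kp.SketchParams(k=5, s=10_000, min_count=1)
        sk = kp.sketch(seq, params)
        profile = kp.count_kmers(seq, kp.KmerParams(5, 1))
        assert len(sk) == len(profile.counts)
        assert sk.hashes == sorted(sk.hashes)
        assert len(set(sk.hashes)) == len(sk.hashes)

    def test_filtered_kmers_only(self):
        params = kp.SketchParams(k=4, s=100, min_count=2)
        sk = kp.sketch("ACGTACGT", params)
        expected = sorted(_hash_kmer(km, 42) for km in ("ACGT", "CGTA"))
        assert sk.hashes == expected

    def test_empty_sketch_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            sk = kp.sketch("ACGTTTTT", kp.SketchParams(k=6, s=10, min_count=5))
        assert sk.hashes == []

    def test_json_roundtrip(self, tmp_path, rng):
        sk = kp.sketch(random_seq(rng, 200), kp.SketchParams(k=6, s=20))
        write_sketch_json(sk, tmp_path / "s.json")
        back = read_sketch_json(tmp_path / "s.json")
        assert back.params == sk.params and back.hashes == sk.hashes


class TestJaccard:
    def test_identical_sketches(self, rng):
        sk = kp.sketch(random_seq(rng, 400), kp.SketchParams(k=6, s=30))
        assert kp.jaccard(sk, sk) == 1.0

    def test_disjoint_sets(self):
        params = kp.SketchParams(k=3, s=10, min_count=1)
        a = kp.Sketch(params, [1, 2, 3], "a")
        b = kp.Sketch(params, [4, 5, 6], "b")
        assert kp.jaccard(a, b) == 0.0

    def test_symmetry(self, rng):
        params = kp.SketchParams(k=6, s=40, min_count=1)
        a = kp.sketch(random_seq(rng, 500), params, "a")
        b = kp.sketch(random_seq(rng, 500), params, "b")
        assert kp.jaccard(a, b) == kp.jaccard(b, a)

    def test_equals_exact_jaccard_when_s_exceeds_kmer_count(self, rng):
        params = kp.SketchParams(k=8, s=100_000, min_count=1)
        for _ in range(5):
            sa, sb_ = random_seq(rng, 2000), random_seq(rng, 2000)
            # share a chunk so the Jaccard is non-trivial
            sb = sb_[:1000] + sa[1000:]
            a = kp.sketch(sa, params, "a")
            b = kp.sketch(sb, params, "b")
            assert kp.jaccard(a, b) == pytest.approx(
                exact_jaccard(sa, sb, 8, 1), abs=1e-12
            )

    def test_param_mismatch_rejected(self, rng):
        a = kp.sketch(random_seq(rng, 100), kp.SketchParams(k=5, s=10))
        b = kp.sketch(random_seq(rng, 100), kp.SketchParams(k=6, s=10))
        with pytest.raises(ValueError, match="mismatch"):
            kp.jaccard(a, b)


class TestMashDistance:
    @pytest.mark.parametrize(
        "j,k,expected",
        [
            (1.0, 21, 0.0),
            (1.0, 9, 0.0),
            (0.0, 21, 1.0),
            (0.5, 21, -math.log(2 / 3) / 21),  # 0.0193088...
        ],
    )
    def test_examples(self, j, k, expected):
        assert kp.mash_distance(j, k) == pytest.approx(expected, abs=1e-12)

    def test_reference_value(self):
        # -(1/21) * ln(2*0.5 / 1.5) = ln(1.5)/21
        assert kp.mash_distance(0.5, 21) == pytest.approx(0.0193079, abs=1e-7)

    def test_strictly_decreasing_in_j(self):
        js = np.linspace(0.01, 1.0, 50)
        ds = [kp.mash_distance(j, 15) for j in js]
        assert all(a > b for a, b in zip(ds, ds[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            kp.mash_distance(1.2, 21)
        with pytest.raises(ValueError):
            kp.mash_distance(-0.1, 21)


class TestDistanceMatrix:
    def test_identical_sketches_zero_matrix(self, rng):
        params = kp.SketchParams(k=6, s=50)
        seq = random_seq(rng, 400)
        sks = [kp.sketch(seq, params, f"s{i}") for i in range(3)]
        dm = kp.distance_matrix(sks)
        assert np.allclose(dm.d, 0.0)

    def test_matches_elementwise_recomputation(self, rng):
        params = kp.SketchParams(k=6, s=30, min_count=1)
        sks = [kp.sketch(random_seq(rng, 300), params, f"s{i}") for i in range(4)]
        dm = kp.distance_matrix(sks)
        for i in range(4):
            for j in range(4):
                expected = (
                    0.0 if i == j else kp.mash_distance(kp.jaccard(sks[i], sks[j]), 6)
                )
                assert dm.d[i, j] == pytest.approx(expected)
        assert np.allclose(dm.d, dm.d.T)

    def test_input_permutation_permutes_matrix(self, rng):
        params = kp.SketchParams(k=6, s=30, min_count=1)
        sks = [kp.sketch(random_seq(rng, 300), params, f"s{i}") for i in range(5)]
        dm = kp.distance_matrix(sks)
        perm = [3, 0, 4, 1, 2]
        dm_p = kp.distance_matrix([sks[i] for i in perm])
        assert dm_p.names == [f"s{i}" for i in perm]
        assert np.allclose(dm_p.d, dm.d[np.ix_(perm, perm)])


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d_ab, d_ac, d_bc = 3.0, 4.0, 5.0
        dm = kp.DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, d_ab, d_ac], [d_ab, 0, d_bc], [d_ac, 0 + d_bc, 0]], float)
            * np.array(1.0),
        )
        dm.d[2, 1] = d_bc  # ensure symmetry
        tree = kp.nj_tree(dm)
        x = (d_ab + d_ac - d_bc) / 2  # branch to A
        y = (d_ab + d_bc - d_ac) / 2  # branch to B
        z = (d_ac + d_bc - d_ab) / 2  # branch to C
        tips = {t.name: t.length for t in tree.tips()}
        # branch lengths solve the three-point formulas (allow for the
        # basal trifurcation placing one length on an internal edge)
        dists = tree.tip_tip_distances()
        assert dists["A", "B"] == pytest.approx(d_ab)
        assert dists["A", "C"] == pytest.approx(d_ac)
        assert dists["B", "C"] == pytest.approx(d_bc)
        assert x + y == pytest.approx(d_ab) and z == pytest.approx(
            dists["A", "C"] - x
        )

    def test_additive_four_taxon_split_recovered(self):
        names = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 2, 5, 6], [2, 0, 5, 6], [5, 5, 0, 3], [6, 6, 3, 0]], float
        )
        tree = kp.nj_tree(kp.DistanceMatrix(names, d))
        assert kp.is_monophyletic(tree, ["A", "B"])
        assert kp.is_monophyletic(tree, ["C", "D"])
        dists = tree.tip_tip_distances()
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i < j:
                    assert dists[a, b] == pytest.approx(d[i, j], abs=1e-9)

    def test_random_additive_trees_reproduced(self, rng):
        for n_leaves in (4, 5, 6, 8):
            for _ in range(5):
                names, d = random_additive_tree(n_leaves, rng)
                tree = kp.nj_tree(kp.DistanceMatrix(names, d))
                dists = tree.tip_tip_distances()
                for i, a in enumerate(names):
                    for j, b in enumerate(names):
                        if i < j:
                            assert dists[a, b] == pytest.approx(d[i, j], abs=1e-9)

    def test_star_distances_zero_internal_branches(self):
        d = np.ones((4, 4)) - np.eye(4)
        tree = kp.nj_tree(kp.DistanceMatrix(["A", "B", "C", "D"], d))
        internal = [
            n.length for n in tree.traverse(include_self=False) if not n.is_tip()
        ]
        assert all(l == pytest.approx(0.0, abs=1e-12) for l in internal)

    def test_newick_terminated(self, rng):
        params = kp.SketchParams(k=5, s=20, min_count=1)
        sks = [kp.sketch(random_seq(rng, 200), params, f"s{i}") for i in range(4)]
        nwk = kp.tree_to_newick(kp.nj_tree(kp.distance_matrix(sks)))
        assert nwk.endswith(";")
        for i in range(4):
            assert f"s{i}" in nwk

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValueError, match="symmetric"):
            kp.nj_tree(kp.DistanceMatrix(["A", "B", "C"], d))


class TestMonophyly:
    @pytest.fixture()
    def four_leaf_tree(self):
        d = np.array(
            [[0, 1, 4, 4], [1, 0, 4, 4], [4, 4, 0, 1], [4, 4, 1, 0]], float
        )
        return kp.nj_tree(kp.DistanceMatrix(["A1", "A2", "B1", "B2"], d))

    def test_clade_is_monophyletic(self, four_leaf_tree):
        assert kp.is_monophyletic(four_leaf_tree, ["A1", "A2"])

    def test_mixed_group_is_not(self, four_leaf_tree):
        assert not kp.is_monophyletic(four_leaf_tree, ["A1", "B1"])

    def test_complement_of_clade_counts_on_unrooted_tree(self, four_leaf_tree):
        assert kp.is_monophyletic(four_leaf_tree, ["B1", "B2"])
        # property: group and complement agree for every 2-subset
        import itertools

        for pair in itertools.combinations(["A1", "A2", "B1", "B2"], 2):
            comp = [l for l in ["A1", "A2", "B1", "B2"] if l not in pair]
            assert kp.is_monophyletic(four_leaf_tree, pair) == kp.is_monophyletic(
                four_leaf_tree, comp
            )

    def test_trivial_groups(self, four_leaf_tree):
        assert kp.is_monophyletic(four_leaf_tree, ["A1"])
        assert kp.is_monophyletic(four_leaf_tree, ["A1", "A2", "B1", "B2"])

    def test_unknown_label_rejected(self, four_leaf_tree):
        with pytest.raises(ValueError, match="not in tree"):
            kp.is_monophyletic(four_leaf_tree, ["A1", "Z9"])


class TestMonophylySweep:
    def test_separated_demes_all_true(self, three_pop_manifest):
        grid = kp.monophyly_sweep(three_pop_manifest, ks=[9], ss=[500])
        assert len(grid) == 1
        row = grid.iloc[0]
        assert row["all_monophyletic"]
        assert row["pop1"] and row["pop2"] and row["pop3"]

    def test_interleaved_identical_sequences_not_monophyletic(self, tmp_path, rng):
        seq = random_seq(rng, 500)
        rows = ["sample_id\tpath\tlabel"]
        for i, lab in enumerate(["A", "B", "A", "B"]):
            (tmp_path / f"s{i}.fasta").write_text(f">s{i}\n{seq}\n")
            rows.append(f"s{i}\ts{i}.fasta\t{lab}")
        (tmp_path / "m.tsv").write_text("\n".join(rows) + "\n")
        grid = kp.monophyly_sweep(tmp_path / "m.tsv", ks=[5], ss=[50])
        assert not grid.iloc[0]["all_monophyletic"]

    def test_grid_shape(self, three_pop_manifest):
        grid = kp.monophyly_sweep(three_pop_manifest, ks=[7, 9], ss=[100, 500, 1000])
        assert len(grid) == 6
        assert set(zip(grid["k"], grid["s"])) == {
            (k, s) for k in (7, 9) for s in (100, 500, 1000)
        }

    def test_requires_labels(self, tmp_path, rng):
        (tmp_path / "s0.fasta").write_text(f">s0\n{random_seq(rng, 100)}\n")
        (tmp_path / "m.tsv").write_text("sample_id\tpath\ns0\ts0.fasta\n")
        with pytest.raises(ValueError, match="label"):
            kp.monophyly_sweep(tmp_path / "m.tsv", ks=[5], ss=[10])

    def test_sketch_from_fasta(self, three_pop_manifest, tmp_path):
        import pandas as pd

        df = pd.read_csv(three_pop_manifest, sep="\t")
        path = kp.read_manifest(three_pop_manifest)["path"][0]
        sk = sketch_from_fasta(path, kp.SketchParams(k=9, s=100))
        assert len(sk) == 100
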