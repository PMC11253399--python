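"""Clonal decomposition: CCF, EM clustering, pruning, trees."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ithkit.clones import (
    CloneModel,
    CountMatrix,
    _run_em,
    _vaf_factor,
    build_count_matrix,
    ccf,
    clone_mutations,
    cluster_mutations,
    infer_tree,
    observed_ccf,
    prune_clones,
    timepoint_prevalence,
)
from ithkit.io_formats import MutationKey, MutationRecord, Timepoint


def make_record(sample, pos, alt_count, depth, tumour="TUM1", ref="C", alt="A"):
    return MutationRecord(
        tumour_id=tumour,
        sample_id=sample,
        timepoint=Timepoint.PRE,
        region_label=sample,
        chrom="chr1",
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        alt_count=alt_count,
        depth=depth,
        cn_total=2,
        cn_major=1,
    )


class TestCcf:
    def test_clonal_heterozygous_diploid_pure(self):
        assert ccf(50, 100, purity=1.0, cn_total=2, cn_major=1) == pytest.approx(1.0)

    def test_half_purity_formula(self):
        # vaf 0.25, purity 0.5: copies = 0.25*(0.5*2+0.5*2)/0.5 = 1 -> ccf 1
        assert ccf(25, 100, purity=0.5, cn_total=2, cn_major=1) == pytest.approx(1.0)

    def test_zero_alt_is_zero(self):
        assert ccf(0, 80, purity=0.7) == pytest.approx(0.0)

    def test_zero_depth_is_missing(self):
        assert np.isnan(ccf(0, 0, purity=0.7))

    def test_multiplicity_clamped_by_major_copy_number(self):
        # vaf 0.5 at purity 1 with cn 4/2: copies=2, m=2 -> ccf 1
        assert ccf(50, 100, purity=1.0, cn_total=4, cn_major=2) == pytest.approx(1.0)


class TestBuildCountMatrix:
    def test_called_cells_equal_record_counts(self):
        records = [make_record("T1", 100, 20, 60), make_record("T2", 100, 30, 55)]
        m = build_count_matrix(records, purity={"T1": 0.8, "T2": 0.8})
        assert m.alt[0].tolist() == [20, 30]
        assert m.depth[0].tolist() == [60, 55]

    def test_uncalled_cell_zero_filled_from_pileup(self):
        records = [make_record("T1", 100, 20, 60)] + [make_record("T2", 200, 5, 50)]
        pileup = pd.DataFrame(
            [
                {"chrom": "chr1", "pos": 100, "ref_allele": "C", "alt_allele": "A",
                 "sample_id": "T2", "alt_count": 0, "depth": 40},
            ]
        )
        m = build_count_matrix(records, pileup, purity={"T1": 0.8, "T2": 0.8})
        i = m.keys.index(MutationKey("chr1", 100, "C", "A"))
        j = m.samples.index("T2")
        assert (m.alt[i, j], m.depth[i, j]) == (0, 40)
        assert not m.missing[i, j]
        # the (200, T1) cell was in neither calls nor pileup
        i2 = m.keys.index(MutationKey("chr1", 200, "C", "A"))
        assert m.missing[i2, m.samples.index("T1")]

    def test_fixture_union_matches_brute_force(self, rng):
        samples = ["T1", "T2", "P1"]
        cells = {}
        records = []
        for pos in range(100, 140):
            for s in samples:
                if rng.random() < 0.6:
                    a, d = int(rng.integers(0, 30)), int(rng.integers(30, 80))
                    cells[(pos, s)] = (a, d)
                    records.append(make_record(s, pos, a, d))
        pileup = pd.DataFrame(
            [
                {"chrom": "chr1", "pos": pos, "ref_allele": "C", "alt_allele": "A",
                 "sample_id": s, "alt_count": 0, "depth": 45}
                for pos in range(100, 140)
                for s in samples
            ]
        )
        m = build_count_matrix(records, pileup, purity={s: 0.9 for s in samples})
        for i, key in enumerate(m.keys):
            for j, s in enumerate(m.samples):
                expected = cells.get((key.pos, s), (0, 45))
                assert (m.alt[i, j], m.depth[i, j]) == expected

    def test_inconsistent_ref_alt_raises(self):
        records = [make_record("T1", 100, 5, 50, ref="C", alt="A"),
                   make_record("T2", 100, 5, 50, ref="C", alt="T")]
        with pytest.raises(ValueError, match="inconsistent"):
            build_count_matrix(records)


def simulate_matrix(centres, n_per_clone, depth, purity, rng):
    """Binomial draws from known per-sample CCF centres (diploid, m=1)."""
    centres = np.asarray(centres, dtype=float)
    K, S = centres.shape
    rows_alt, rows_depth, truth = [], [], []
    for k in range(K):
        vaf = centres[k] * np.asarray(purity) / 2.0
        for _ in range(n_per_clone):
            d = rng.poisson(depth, size=S)
            rows_alt.append(rng.binomial(d, vaf))
            rows_depth.append(d)
            truth.append(k)
    n = len(rows_alt)
    keys = [MutationKey("chr1", i + 1, "C", "A") for i in range(n)]
    matrix = CountMatrix(
        keys=keys,
        samples=[f"S{j}" for j in range(S)],
        alt=np.array(rows_alt),
        depth=np.array(rows_depth),
        purity=np.asarray(purity, dtype=float),
        cn_total=np.full((n, S), 2),
        cn_major=np.ones((n, S), dtype=int),
    )
    return matrix, np.array(truth)


class TestClusterMutations:
    def test_single_clone_at_ccf_one(self, rng):
        matrix, _ = simulate_matrix([[1.0, 1.0]], 100, 60, [0.8, 0.8], rng)
        model = cluster_mutations(matrix, max_clusters=10, restarts=20, seed=0)
        assert model.K == 1
        np.testing.assert_allclose(model.prevalence, 1.0, atol=0.05)

    def test_three_separated_clones_recovered(self, rng):
        """K=3, centres within 0.05, >=95% assignment accuracy at depth 60."""
        centres = [[1.0, 1.0], [0.6, 0.1], [0.15, 0.65]]
        matrix, truth = simulate_matrix(centres, 100, 60, [0.85, 0.85], rng)
        model = cluster_mutations(matrix, max_clusters=10, restarts=40, seed=3)
        assert model.K == 3
        # match fitted clones to planted centres by nearest distance
        fitted = model.prevalence
        order = [int(np.argmin(((fitted - np.array(c)) ** 2).sum(axis=1))) for c in centres]
        assert sorted(order) == [0, 1, 2]
        for c, k in zip(centres, order):
            np.testing.assert_allclose(fitted[k], c, atol=0.05)
        hard = np.array([model.assignment[key] for key in matrix.keys])
        accuracy = np.mean([order[t] == h for t, h in zip(truth, hard)])
        assert accuracy >= 0.95

    def test_pigeonhole_with_few_mutations(self, rng):
        matrix, _ = simulate_matrix([[1.0, 1.0]], 5, 60, [0.9, 0.9], rng)
        model = cluster_mutations(matrix, max_clusters=40, restarts=10, seed=1)
        assert model.K <= 5

    def test_deterministic_given_seed(self, rng):
        centres = [[1.0, 1.0], [0.4, 0.4]]
        matrix, _ = simulate_matrix(centres, 60, 60, [0.8, 0.8], rng)
        a = cluster_mutations(matrix, max_clusters=6, restarts=15, seed=9)
        b = cluster_mutations(matrix, max_clusters=6, restarts=15, seed=9)
        assert a.K == b.K and a.assignment == b.assignment
        np.testing.assert_array_equal(a.prevalence, b.prevalence)

    def test_empty_matrix_raises(self):
        matrix = CountMatrix(
            keys=[], samples=["S0"], alt=np.zeros((0, 1)), depth=np.zeros((0, 1)),
            purity=np.array([1.0]), cn_total=np.zeros((0, 1)), cn_major=np.zeros((0, 1)),
        )
        with pytest.raises(ValueError):
            cluster_mutations(matrix)

    def test_em_loglik_nondecreasing(self, rng):
        matrix, _ = simulate_matrix([[1.0, 1.0], [0.3, 0.6]], 80, 60, [0.8, 0.8], rng)
        q = _vaf_factor(matrix)
        init = np.array([[0.9, 0.9], [0.2, 0.7], [0.5, 0.2]])
        trace: list[float] = []
        _run_em(matrix.alt, matrix.depth, q, init, np.full(3, 1 / 3), 60, trace=trace)
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-6)


def toy_model(fractions, prevalence, samples=("S0", "S1")):
    K = len(fractions)
    keys, assignment = [], {}
    i = 0
    for k, f in enumerate(fractions):
        for _ in range(int(round(f * 1000))):
            key = MutationKey("chr1", i + 1, "C", "A")
            keys.append(key)
            assignment[key] = k
            i += 1
    return CloneModel(
        K=K,
        samples=list(samples),
        prevalence=np.asarray(prevalence, dtype=float),
        assignment=assignment,
        clone_fraction=np.asarray(fractions, dtype=float),
    )


class TestPruneClones:
    def test_half_percent_clone_removed(self):
        model = toy_model([0.795, 0.2, 0.005], [[1, 1], [0.4, 0.4], [0.1, 0.1]])
        pruned = prune_clones(model)
        assert pruned.K == 2
        assert len(pruned.unassigned) == 5
        np.testing.assert_allclose(pruned.clone_fraction.sum(), 1.0)
        np.testing.assert_allclose(pruned.original_fraction, model.clone_fraction)

    def test_all_above_threshold_unchanged(self):
        model = toy_model([0.7, 0.3], [[1, 1], [0.5, 0.5]])
        pruned = prune_clones(model)
        assert pruned.K == 2 and not pruned.unassigned

    def test_matches_brute_force_filter(self, rng):
        fr = rng.dirichlet(np.ones(6))
        model = toy_model(fr, rng.uniform(0, 1, size=(6, 2)))
        pruned = prune_clones(model, min_fraction=0.05)
        survivors = {k for k, f in enumerate(model.clone_fraction) if f >= 0.05}
        # brute force: every surviving clone keeps exactly its own mutations
        expected_sizes = sorted(
            sum(1 for c in model.assignment.values() if c == k) for k in survivors
        )
        got_sizes = sorted(
            sum(1 for c in pruned.assignment.values() if c == k) for k in range(pruned.K)
        )
        assert got_sizes == expected_sizes


class TestClonePartition:
    def test_partition_covers_and_disjoint(self):
        model = toy_model([0.6, 0.4], [[1, 1], [0.5, 0.5]])
        parts = clone_mutations(model)
        union = set().union(*parts.values())
        assert union == set(model.assignment)
        assert sum(len(p) for p in parts.values()) == len(union)

    def test_matches_assignment_map(self):
        model = toy_model([0.5, 0.3, 0.2], [[1, 1], [0.6, 0.1], [0.1, 0.6]])
        parts = clone_mutations(model)
        for key, cid in model.assignment.items():
            assert key in parts[cid]


class TestTimepointPrevalence:
    def test_identity_with_one_sample_per_timepoint(self):
        model = toy_model([1.0], [[0.8, 0.3]])
        table = timepoint_prevalence(model, {"S0": "pre", "S1": "post"})
        assert table.loc["C1", "pre"] == pytest.approx(0.8)
        assert table.loc["C1", "post"] == pytest.approx(0.3)

    def test_mean_within_timepoint(self):
        model = toy_model([1.0], [[0.2, 0.4]])
        table = timepoint_prevalence(model, {"S0": "pre", "S1": "pre"})
        assert table.loc["C1", "pre"] == pytest.approx(0.3)

    def test_matches_brute_force_mean(self, rng):
        prev = rng.uniform(0, 1, size=(3, 4))
        model = toy_model([0.4, 0.3, 0.3], prev, samples=["a", "b", "c", "d"])
        tps = {"a": "pre", "b": "pre", "c": "post", "d": "post"}
        table = timepoint_prevalence(model, tps)
        np.testing.assert_allclose(table["pre"], prev[:, :2].mean(axis=1))
        np.testing.assert_allclose(table["post"], prev[:, 2:].mean(axis=1))


class TestInferTree:
    def test_single_clone_root(self):
        model = toy_model([1.0], [[1.0, 1.0]])
        assert infer_tree(model) == {0: None}
        assert not model.flagged_forest

    def test_linear_chain_recovered(self):
        model = toy_model(
            [0.5, 0.3, 0.2], [[1.0, 1.0], [0.6, 0.6], [0.2, 0.2]]
        )
        assert infer_tree(model) == {0: None, 1: 0, 2: 1}

    def test_mutually_exclusive_subclones_attach_to_founder(self):
        # the two subclones sum to more than the smaller one allows as parent
        model = toy_model(
            [0.4, 0.3, 0.3], [[1.0, 1.0], [0.6, 0.35], [0.35, 0.6]]
        )
        tree = infer_tree(model)
        assert tree == {0: None, 1: 0, 2: 0}

    def test_forest_flagged_without_universal_founder(self):
        model = toy_model([0.5, 0.5], [[0.9, 0.1], [0.1, 0.9]])
        infer_tree(model)
        assert model.flagged_forest

    def test_label_permutation_leaves_shape_invariant(self, rng):
        prev = np.array([[1.0, 1.0], [0.6, 0.5], [0.25, 0.3], [0.1, 0.1]])
        fractions = [0.4, 0.3, 0.2, 0.1]
        model = toy_model(fractions, prev)
        tree = infer_tree(model)
        perm = rng.permutation(4)
        permuted = toy_model(
            [fractions[p] for p in perm], prev[perm]
        )
        tree_p = infer_tree(permuted)

        def depth_multiset(tree, model):
            def depth(k):
                d = 0
                while tree[k] is not None:
                    k = tree[k]
                    d += 1
                return d

            return sorted(depth(k) for k in range(model.K))

        assert depth_multiset(tree, model) == depth_multiset(tree_p, permuted)
        assert sorted(model.clone_fraction) == sorted(permuted.clone_fraction)
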