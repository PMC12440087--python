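"""Inverse Simpson clonality, rarefaction, and repertoire overlap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clonotrack.diversity import (
    clonality_with_replicates,
    downsample,
    inverse_simpson,
    jaccard,
    morisita_horn,
    overlap_matrix,
    shared_clones,
)
from tests.conftest import make_repertoire

counts_lists = st.lists(st.integers(min_value=1, max_value=500), min_size=1, max_size=30)


class TestInverseSimpson:
    def test_uniform_k_clones_equals_k(self):
        for k in (1, 4, 17):
            assert inverse_simpson([7] * k) == pytest.approx(k)

    def test_single_clone_is_one(self):
        assert inverse_simpson([42]) == pytest.approx(1.0)

    def test_hand_case_three_one(self):
        # p = (0.75, 0.25); 1 / (0.5625 + 0.0625) = 1.6
        assert inverse_simpson([3, 1]) == pytest.approx(1.6)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            inverse_simpson([])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(counts_lists)
    def test_scale_and_permutation_invariance(self, counts):
        base = inverse_simpson(counts)
        assert inverse_simpson([7 * c for c in counts]) == pytest.approx(base)
        assert inverse_simpson(list(reversed(counts))) == pytest.approx(base)
        assert 1.0 - 1e-9 <= base <= len(counts) + 1e-9


class TestDownsample:
    def test_identity_at_full_depth(self):
        rep = make_repertoire({"A": 3000, "B": 2000})
        out = downsample(rep, 5000, seed=0)
        assert out.clonotypes == rep.clonotypes

    def test_single_clone_keeps_depth(self):
        rep = make_repertoire({"A": 900})
        out = downsample(rep, 100, seed=0)
        assert out.total_reads == 100 and out.n_clones == 1

    def test_shallow_sample_flagged_not_rejected(self):
        rep = make_repertoire({"A": 10})
        out = downsample(rep, 5000, seed=0)
        assert out.clonotypes == rep.clonotypes
        assert out.meta["shallow"] is True

    def test_exact_depth_drawn(self, rng):
        rep = make_repertoire({"A": 500, "B": 300, "C": 200})
        for seed in range(5):
            assert downsample(rep, 123, seed=seed).total_reads == 123

    def test_hypergeometric_expectation(self):
        # minority clone 1000 / 10000; depth 100 -> expected drawn count 10
        rep = make_repertoire({"big": 9000, "small": 1000})
        small_key = [k for k in rep.clonotypes if k.cdr3 == "small"][0]
        n_seeds = 300
        draws = [downsample(rep, 100, seed=s).clonotypes.get(small_key, 0) for s in range(n_seeds)]
        var = 100 * 0.1 * 0.9 * (10000 - 100) / (10000 - 1)
        se = np.sqrt(var / n_seeds)
        assert abs(np.mean(draws) - 10.0) < 3 * se

    def test_reproducible_under_seed(self):
        rep = make_repertoire({"A": 500, "B": 300, "C": 200})
        assert downsample(rep, 100, seed=42).clonotypes == downsample(rep, 100, seed=42).clonotypes


class TestClonalityWithReplicates:
    def test_identical_uniform_replicates_exact(self):
        reps = [make_repertoire({c: 10 for c in "ABCDE"}) for _ in range(2)]
        res = clonality_with_replicates(reps, depth=50, n_iter=4, seed=0)
        assert res.inverse_simpson_mean == pytest.approx(5.0)
        assert np.std(res.per_iteration) == 0.0

    def test_shallow_replicate_flagged_full_depth(self):
        reps = [make_repertoire({"A": 5, "B": 5})]
        res = clonality_with_replicates(reps, depth=5000, n_iter=3, seed=0)
        assert res.shallow_replicates == 1
        assert res.inverse_simpson_mean == pytest.approx(2.0)

    def test_iteration_count_converges(self):
        rng = np.random.default_rng(1)
        rep = make_repertoire({f"c{i}": int(n) for i, n in
                               enumerate(rng.integers(1, 400, size=200))})
        a = clonality_with_replicates([rep], depth=2000, n_iter=1, seed=5).inverse_simpson_mean
        b = clonality_with_replicates([rep], depth=2000, n_iter=50, seed=6).inverse_simpson_mean
        assert abs(a - b) / b < 0.05


def brute_morisita(x, y):
    # independent evaluation on aligned abundance vectors
    x, y = np.asarray(x, float), np.asarray(y, float)
    p, q = x / x.sum(), y / y.sum()
    return 2 * float(p @ q) / float(p @ p + q @ q)


class TestMorisitaHorn:
    def test_identical_repertoires(self):
        rep = make_repertoire({"A": 5, "B": 2, "C": 1})
        assert morisita_horn(rep, rep) == pytest.approx(1.0)

    def test_disjoint_repertoires(self):
        assert morisita_horn(make_repertoire({"A": 5}), make_repertoire({"B": 5})) == 0.0

    def test_hand_case(self):
        # x=(2,0,1), y=(0,2,1) over clones A,B,C -> 0.2
        x = make_repertoire({"A": 2, "C": 1})
        y = make_repertoire({"B": 2, "C": 1})
        assert morisita_horn(x, y) == pytest.approx(0.2)

    def test_against_brute_force_on_random_vectors(self, rng):
        names = [f"c{i}" for i in range(12)]
        for _ in range(25):
            xv = rng.integers(0, 20, size=12)
            yv = rng.integers(0, 20, size=12)
            if xv.sum() == 0 or yv.sum() == 0:
                continue
            x = make_repertoire({n: int(v) for n, v in zip(names, xv) if v})
            y = make_repertoire({n: int(v) for n, v in zip(names, yv) if v})
            assert morisita_horn(x, y) == pytest.approx(brute_morisita(xv, yv))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(counts_lists, counts_lists)
    def test_symmetric_and_bounded(self, a, b):
        x = make_repertoire({f"s{i}": c for i, c in enumerate(a)})
        y = make_repertoire({f"t{i}": c for i, c in enumerate(b[: len(b) // 2])}
                            | {f"s{i}": c for i, c in enumerate(b[len(b) // 2:])})
        if y.n_clones == 0:
            return
        mh_xy, mh_yx = morisita_horn(x, y), morisita_horn(y, x)
        assert mh_xy == pytest.approx(mh_yx)
        assert -1e-12 <= mh_xy <= 1 + 1e-12


class TestSetOverlaps:
    def test_shared_and_jaccard(self):
        x = make_repertoire({"A": 1, "B": 1, "C": 1})
        y = make_repertoire({"B": 1, "C": 1, "D": 1})
        n, keys = shared_clones(x, y)
        assert n == 2 and len(keys) == 2
        assert jaccard(x, y) == pytest.approx(0.5)

    def test_identical_and_disjoint(self):
        x = make_repertoire({"A": 1, "B": 1})
        assert jaccard(x, x) == 1.0
        n, keys = shared_clones(x, make_repertoire({"C": 1}))
        assert n == 0 and keys == frozenset()


class TestOverlapMatrix:
    def test_disjoint_samples_zero_off_diagonal(self):
        samples = [make_repertoire({f"{i}_{j}": 2 for j in range(4)}, donor=f"D{i}")
                   for i in range(3)]
        om = overlap_matrix(samples, statistic="morisita_horn")
        vals = om.values.to_numpy()
        assert np.allclose(vals[~np.eye(3, dtype=bool)], 0.0)
        assert np.allclose(vals, vals.T)

    def test_duplicated_sample_pair_is_one(self):
        rep = make_repertoire({"A": 5, "B": 2}, donor="D1")
        twin = make_repertoire({"A": 5, "B": 2}, donor="D2")
        om = overlap_matrix([rep, twin], statistic="morisita_horn")
        assert om.values.iloc[0, 1] == pytest.approx(1.0)

    def test_unknown_statistic_raises(self):
        reps = [make_repertoire({"A": 1}), make_repertoire({"B": 1})]
        with pytest.raises(ValueError):
            overlap_matrix(reps, statistic="sorensen")
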