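"""Bray-Curtis dissimilarity, monotone regression and NMDS ordination."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from scipy.stats import rankdata

from abyssal.beta_diversity import (
    DissimilarityMatrix,
    abundance_matrix,
    bray_curtis,
    isotonic_fit,
    nmds,
    ordination_report,
)
from abyssal.zonation import ProvinceScheme, classify_province

from conftest import bd_sample


def euclid_dm(points):
    P = np.asarray(points, dtype=float)
    D = np.sqrt(((P[:, None] - P[None]) ** 2).sum(-1))
    return DissimilarityMatrix([f"p{i}" for i in range(len(P))], D, "none")


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        s = [bd_sample({"a": 100, "b": 100}, sample_id=f"s{i}") for i in range(2)]
        d = bray_curtis(s)
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_disjoint_samples_one(self):
        s = [
            bd_sample({"a": 200}, sample_id="s1"),
            bd_sample({"b": 200}, sample_id="s2"),
        ]
        assert bray_curtis(s).values[0, 1] == pytest.approx(1.0)

    def test_hand_computed_sqrt_case(self):
        # x={a:4,b:1}, y={a:1,b:4}: sqrt -> (2,1) vs (1,2) -> 2/6
        s = [
            bd_sample({"a": 4, "b": 1}, sample_id="s1"),
            bd_sample({"a": 1, "b": 4}, sample_id="s2"),
        ]
        assert bray_curtis(s, transform="sqrt").values[0, 1] == pytest.approx(
            1 / 3, abs=1e-12
        )

    def test_all_zero_sample_rejected(self):
        M = pd.DataFrame([[1.0, 2.0], [0.0, 0.0]], index=["a", "b"], columns=["x", "y"])
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(M)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.lists(st.integers(min_value=0, max_value=30), min_size=4, max_size=4),
            min_size=2,
            max_size=6,
        ).filter(lambda rows: all(sum(r) > 0 for r in rows))
    )
    def test_axioms_and_scipy_crosscheck(self, rows):
        """Range, symmetry, zero diagonal; values match scipy's Bray-Curtis
        on the transformed vectors (independent implementation)."""
        M = pd.DataFrame(rows, index=[f"s{i}" for i in range(len(rows))])
        d = bray_curtis(M, transform="sqrt")
        V = d.values
        assert np.allclose(V, V.T)
        assert np.allclose(np.diag(V), 0.0)
        assert (V >= -1e-12).all() and (V <= 1 + 1e-12).all()
        X = np.sqrt(np.asarray(rows, dtype=float))
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                assert V[i, j] == pytest.approx(scipy_braycurtis(X[i], X[j]), abs=1e-12)


class TestIsotonicFit:
    def brute_force(self, y):
        """Exact isotonic least squares by enumeration of level-set partitions."""
        n = len(y)
        best, best_sse = None, np.inf
        # enumerate compositions of n into contiguous blocks
        for mask in range(1 << (n - 1)):
            bounds = [0] + [i + 1 for i in range(n - 1) if mask >> i & 1] + [n]
            means = [np.mean(y[a:b]) for a, b in zip(bounds, bounds[1:])]
            if any(m2 < m1 for m1, m2 in zip(means, means[1:])):
                continue
            fit = np.concatenate(
                [np.full(b - a, m) for (a, b), m in zip(zip(bounds, bounds[1:]), means)]
            )
            sse = float(((np.asarray(y) - fit) ** 2).sum())
            if sse < best_sse - 1e-12:
                best, best_sse = fit, sse
        return best

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(min_value=-5, max_value=5, allow_nan=False), min_size=1, max_size=6))
    def test_matches_brute_force(self, y):
        y = np.asarray(y)
        fit = isotonic_fit(y)
        assert (np.diff(fit) >= -1e-9).all()
        assert fit == pytest.approx(self.brute_force(y), abs=1e-9)

    def test_matches_sklearn(self):
        from sklearn.isotonic import IsotonicRegression

        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.normal(size=rng.integers(2, 50))
            ref = IsotonicRegression().fit_transform(np.arange(y.size), y)
            assert isotonic_fit(y) == pytest.approx(ref, abs=1e-9)


class TestNMDS:
    def test_planted_square_recovery(self):
        d = euclid_dm([[0, 0], [1, 0], [1, 1], [0, 1]])
        o = nmds(d, n_restarts=20, max_iter=500, seed=0)
        assert o.stress < 0.01
        iu = np.triu_indices(4, 1)
        dhat = np.sqrt(
            ((o.coordinates[iu[0]] - o.coordinates[iu[1]]) ** 2).sum(-1)
        )
        # rank structure recovered: the four unit sides all shorter than the
        # two sqrt(2) diagonals (under primary tie treatment, ties impose no
        # within-group constraint, so this is exact rank identity)
        sides = dhat[d.values[iu] < 1.2]
        diags = dhat[d.values[iu] > 1.2]
        assert sides.max() < diags.min()

    def test_three_points_embed_exactly(self):
        rng = np.random.default_rng(3)
        P = rng.random((3, 2))
        o = nmds(euclid_dm(P), n_restarts=10, max_iter=500, seed=0)
        assert o.stress == pytest.approx(0.0, abs=1e-4)

    def test_deterministic_given_seed(self):
        d = euclid_dm([[0, 0], [1, 0], [1, 1], [0, 1]])
        a = nmds(d, n_restarts=5, seed=11)
        b = nmds(d, n_restarts=5, seed=11)
        assert np.array_equal(a.coordinates, b.coordinates)
        c = nmds(d, n_restarts=20, max_iter=500, seed=99)
        assert abs(c.stress - nmds(d, n_restarts=20, max_iter=500, seed=0).stress) < 1e-4

    def test_stress_non_increasing_within_restart(self):
        rng = np.random.default_rng(7)
        P = rng.random((9, 3))
        o = nmds(euclid_dm(P), n_restarts=3, max_iter=200, seed=1)
        assert (np.diff(o.stress_history) <= 1e-12).all()

    def test_coordinates_centred(self):
        rng = np.random.default_rng(8)
        P = rng.random((8, 2))
        o = nmds(euclid_dm(P), n_restarts=4, seed=2)
        assert o.coordinates.mean(axis=0) == pytest.approx([0, 0], abs=1e-9)

    def test_degenerate_equal_dissimilarities_warn(self):
        D = np.ones((4, 4)) - np.eye(4)
        d = DissimilarityMatrix(list("abcd"), D, "none")
        with pytest.warns(UserWarning, match="degenerate"):
            o = nmds(d, n_restarts=3, seed=0)
        assert np.isfinite(o.stress)


class TestOrdinationReport:
    def make(self):
        samples = [
            bd_sample({"a": 150, "b": 50}, sample_id="s1", depth=4100.0),
            bd_sample({"a": 90, "b": 110}, sample_id="s2", depth=4500.0),
            bd_sample({"b": 60, "c": 140}, sample_id="s3", depth=4900.0),
        ]
        o = nmds(bray_curtis(samples), n_restarts=4, seed=0)
        return samples, o

    def test_table_contents(self):
        samples, o = self.make()
        rep = ordination_report(o, samples)
        assert list(rep["province"]) == ["shallow", "transition", "deep"]
        assert len(rep) == 3
        assert {"nmds1", "nmds2", "mean_depth", "site"} <= set(rep.columns)

    def test_roundtrip_csv(self, tmp_path):
        samples, o = self.make()
        rep = ordination_report(o, samples)
        p = tmp_path / "ord.csv"
        rep.to_csv(p, index=False)
        back = pd.read_csv(p)
        assert back["nmds1"].to_numpy() == pytest.approx(rep["nmds1"].to_numpy())


def test_between_province_exceeds_within(default_run):
    """Programmed shallow/deep community turnover shows up as larger
    between-province than within-province Bray-Curtis dissimilarity."""
    bd = default_run["bd"]
    d = bray_curtis(bd)
    provs = np.array([classify_province(s.mean_depth) for s in bd])
    iu = np.triu_indices(len(bd), 1)
    same = provs[iu[0]] == provs[iu[1]]
    vals = d.values[iu]
    assert vals[~same].mean() > vals[same].mean()
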