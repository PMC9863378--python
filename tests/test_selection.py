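"""Scaling, network importance weighting and uncorrelated-set enumeration."""

import itertools

import numpy as np
import pandas as pd
import pytest

import qsarpt as q
from qsarpt.errors import MissingValueError, UnknownDescriptorError
from qsarpt.io import DescriptorEntry, DescriptorMatrix, DescriptorSchema
from qsarpt.selection import AnnConfig, _selection_from_weights

from conftest import make_clearance


def matrix_from(values, codes=None):
    values = np.asarray(values, dtype=float)
    codes = codes or [f"D{j + 1}" for j in range(values.shape[1])]
    schema = DescriptorSchema(tuple(DescriptorEntry(c, "physicochemical") for c in codes))
    return DescriptorMatrix([f"C{i + 1}" for i in range(values.shape[0])], schema, values)


class TestScaleMatrix:
    def test_arithmetic_sequence(self):
        Xs = q.scale_matrix(matrix_from([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(Xs.values[:, 0], [-1, 0, 1])

    def test_constant_column_dropped(self):
        Xs = q.scale_matrix(matrix_from([[4, 1], [4, 2], [4, 3]]))
        assert Xs.dropped == ("D1",)
        assert Xs.codes == ("D2",)

    def test_columns_standardised(self, bundle):
        Xs = q.scale_matrix(bundle.chromatographic)
        np.testing.assert_allclose(Xs.values.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Xs.values.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_missing_rejected(self):
        m = matrix_from([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(MissingValueError):
            q.scale_matrix(m)

    def test_single_compound_rejected(self):
        with pytest.raises(ValueError):
            q.scale_matrix(matrix_from([[1.0, 2.0]]))


def _planted_study(seed=1, n_desc=10, n_comp=15, n_reps=5, noise=0.02):
    """y = sigmoid(2 x3 - 2 x7) + replicate noise, descriptors standard normal."""
    rng = np.random.default_rng(seed)
    X = matrix_from(rng.normal(size=(n_comp, n_desc)))
    Xs = q.scale_matrix(X)
    lin = 2 * Xs.values[:, 2] - 2 * Xs.values[:, 6]
    mu = 1.0 / (1.0 + np.exp(-lin))
    rows = []
    for i in range(n_comp):
        for r in range(n_reps):
            rows.append(
                {
                    "compound_id": f"C{i + 1}",
                    "replicate_id": r + 1,
                    "ci": max(mu[i] + rng.normal(0, noise), 0.011),
                }
            )
    return Xs, q.ClearanceTable(pd.DataFrame(rows))


class TestAnnWeights:
    def test_planted_strong_descriptors_selected(self):
        Xs, y = _planted_study(seed=1)
        res = q.ann_weights(Xs, y, AnnConfig(restarts=5, seed=1))
        assert {"D3", "D7"} <= set(res.selected)

    def test_duplicate_informative_columns_agree(self):
        rng = np.random.default_rng(3)
        V = rng.normal(size=(15, 6))
        V[:, 1] = V[:, 0]  # exact duplicate of an informative column
        Xs = q.scale_matrix(matrix_from(V))
        mu = 1 / (1 + np.exp(-1.5 * Xs.values[:, 0]))
        y = make_clearance(Xs.compound_ids, mu, n_reps=5, noise=0.02, seed=3)
        res = q.ann_weights(Xs, y, AnnConfig(restarts=5, seed=3))
        both = [c in res.selected for c in ("D1", "D2")]
        assert both[0] == both[1]

    def test_selection_invariant_under_column_permutation(self):
        Xs, y = _planted_study(seed=5)
        res1 = q.ann_weights(Xs, y, AnnConfig(restarts=3, seed=5))
        perm = np.random.default_rng(0).permutation(len(Xs.codes))
        Xp = q.selection.ScaledMatrix(
            compound_ids=Xs.compound_ids,
            codes=tuple(np.asarray(Xs.codes)[perm]),
            values=Xs.values[:, perm],
            center=Xs.center[perm],
            scale=Xs.scale[perm],
        )
        res2 = q.ann_weights(Xp, y, AnnConfig(restarts=3, seed=5))
        # training is mathematically equivariant; float summation order can
        # differ with column order, so weights agree only to solver precision
        assert set(res1.selected) == set(res2.selected)
        for c in Xs.codes:
            assert res1.weight(c) == pytest.approx(res2.weight(c), abs=1e-6)

    def test_threshold_is_strict(self):
        weights = np.array([1.0, 1.0, 1.0, 2.0, 5.0])  # median 1, threshold 2
        res = _selection_from_weights(
            ("a", "b", "c", "d", "e"), weights, AnnConfig(), np.array([True])
        )
        assert res.selected == ("e",)  # weight exactly 2 x median excluded

    def test_too_few_descriptors_rejected(self):
        Xs = q.scale_matrix(matrix_from(np.random.default_rng(0).normal(size=(6, 2))))
        y = make_clearance(Xs.compound_ids, np.linspace(0.2, 0.8, 6), n_reps=2)
        with pytest.raises(ValueError, match="at least 3"):
            q.ann_weights(Xs, y, AnnConfig(seed=0))


def brute_force_mis(k, edges):
    """All maximal independent sets by exhaustive subset enumeration."""
    edge_set = {frozenset(e) for e in edges}
    independent = [
        frozenset(s)
        for r in range(k + 1)
        for s in itertools.combinations(range(k), r)
        if not any(frozenset(p) in edge_set for p in itertools.combinations(s, 2))
    ]
    return {s for s in independent if not any(s < t for t in independent)}


class TestEnumerateUncorrelated:
    def test_edgeless_graph_single_set(self):
        rng = np.random.default_rng(0)
        Xs = q.scale_matrix(matrix_from(rng.normal(size=(50, 4))))
        combos = q.enumerate_uncorrelated(Xs, Xs.codes, 0.5)
        assert combos.as_sorted_tuples() == [("D1", "D2", "D3", "D4")]

    def test_duplicate_pair_splits(self):
        rng = np.random.default_rng(1)
        V = rng.normal(size=(20, 3))
        V[:, 1] = V[:, 0]
        Xs = q.scale_matrix(matrix_from(V))
        combos = q.enumerate_uncorrelated(Xs, Xs.codes, 0.5)
        assert combos.as_sorted_tuples() == [("D1", "D3"), ("D2", "D3")]

    def test_chain_graph(self):
        # edges a-b and b-c but not a-c -> {{a,c},{b}}; built with exact
        # in-sample correlations: corr(a,c) = 0.55 (R^2 0.30, below the
        # threshold) and b = a + c (R^2 (1+rho)/2 = 0.775 with each)
        rng = np.random.default_rng(2)

        def std(v):
            v = v - v.mean()
            return v / v.std(ddof=1)

        a = std(rng.normal(size=300))
        e = rng.normal(size=300)
        e = std(e - a * (a @ e) / (a @ a))
        c = 0.55 * a + np.sqrt(1 - 0.55**2) * e
        b = a + c
        Xs = q.scale_matrix(matrix_from(np.column_stack([a, b, c]), ["a", "b", "c"]))
        r2 = np.corrcoef(Xs.values, rowvar=False) ** 2
        assert r2[0, 1] > 0.5 and r2[1, 2] > 0.5 and r2[0, 2] < 0.5
        combos = q.enumerate_uncorrelated(Xs, ("a", "b", "c"), 0.5)
        assert combos.as_sorted_tuples() == [("a", "c"), ("b",)]

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_brute_force_on_random_graphs(self, trial):
        rng = np.random.default_rng(trial)
        k = int(rng.integers(3, 13))
        Xs = q.scale_matrix(matrix_from(rng.normal(size=(8, k))))
        r2 = np.corrcoef(Xs.values, rowvar=False) ** 2
        edges = [
            (i, j) for i in range(k) for j in range(i + 1, k) if r2[i, j] > 0.5
        ]
        expected = {
            frozenset(Xs.codes[i] for i in s) for s in brute_force_mis(k, edges)
        }
        combos = q.enumerate_uncorrelated(Xs, Xs.codes, 0.5)
        assert set(combos.sets) == expected

    def test_empty_candidates(self, scaled):
        assert len(q.enumerate_uncorrelated(scaled, [], 0.5)) == 0

    def test_unknown_candidate(self, scaled):
        with pytest.raises(UnknownDescriptorError):
            q.enumerate_uncorrelated(scaled, ["NOPE9"], 0.5)
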