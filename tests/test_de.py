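"""Core statistics: EMD, rank test, BH, fold change, gate and subsampling."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from emdiff import (
    Contrast,
    EMDDifferentialExpression,
    bh_adjust,
    de_contrast,
    emd_1d,
    log2_fold_change,
    mwu_test,
    signed_emd,
    subsample_equal,
    summarize_deg_counts,
)
from emdiff.de import _emd_matrix


def emd_matching_oracle(x, y):
    """Min-cost perfect matching over permutations (equal sizes, brute force)."""
    best = np.inf
    for perm in itertools.permutations(range(len(y))):
        cost = sum(abs(x[i] - y[j]) for i, j in enumerate(perm))
        best = min(best, cost)
    return best / len(x)


samples = st.lists(st.integers(0, 10), min_size=1, max_size=6)


class TestEMD:
    @pytest.mark.parametrize("x,y,expected", [
        ([1, 2, 3], [1, 2, 3], 0.0),
        ([0, 1], [1, 2], 1.0),
        ([0, 2], [1, 1], 1.0),
        ([0, 0, 2, 2], [1, 1, 1, 1], 1.0),
    ])
    def test_worked_examples(self, x, y, expected):
        assert emd_1d(x, y) == pytest.approx(expected, abs=1e-12)

    def test_equal_size_matches_matching_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(1, 6)
            x = rng.integers(0, 10, n).astype(float)
            y = rng.integers(0, 10, n).astype(float)
            assert emd_1d(x, y) == pytest.approx(
                emd_matching_oracle(x, y), abs=1e-12)

    @given(x=samples, y=samples)
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_agrees_with_scipy_on_unequal_sizes(self, x, y):
        assert emd_1d(x, y) == pytest.approx(
            scipy.stats.wasserstein_distance(x, y), abs=1e-10)

    @given(x=samples, y=samples, z=samples,
           c=st.floats(-5, 5), a=st.floats(0.1, 4))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_metric_axioms_and_covariance(self, x, y, z, c, a):
        x, y, z = map(np.asarray, (x, y, z))
        dxy = emd_1d(x, y)
        assert dxy >= 0
        assert dxy == pytest.approx(emd_1d(y, x), abs=1e-12)
        assert emd_1d(x, x) == pytest.approx(0, abs=1e-12)
        assert dxy <= emd_1d(x, z) + emd_1d(z, y) + 1e-9
        assert emd_1d(x + c, y + c) == pytest.approx(dxy, abs=1e-9)
        assert emd_1d(a * x, a * y) == pytest.approx(a * dxy, rel=1e-9, abs=1e-9)

    def test_empty_sample_error(self):
        with pytest.raises(ValueError):
            emd_1d([], [1.0])

    def test_vectorized_matrix_matches_scalar(self):
        rng = np.random.default_rng(1)
        for n_ref, n_alt in [(10, 10), (7, 13)]:
            X = rng.poisson(4, (n_ref, 20)).astype(float)
            Y = rng.poisson(5, (n_alt, 20)).astype(float)
            vec = _emd_matrix(X, Y)
            ref = [emd_1d(X[:, g], Y[:, g]) for g in range(20)]
            np.testing.assert_allclose(vec, ref, atol=1e-12)


class TestSignedEMD:
    def test_direction_of_mean_change(self):
        assert signed_emd([0], [2]) == pytest.approx(2.0)
        assert signed_emd([2], [0]) == pytest.approx(-2.0)

    def test_pure_spread_change_has_sign_zero(self):
        # equal means: magnitude 1.0, sign 0
        assert emd_1d([0, 2], [1, 1]) == pytest.approx(1.0)
        assert signed_emd([0, 2], [1, 1]) == 0.0


def exact_mwu_p(x, y):
    """Exact two-sided p over all labelings of the pooled (tie-free) sample."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    center = len(x) * len(y) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        xs = pooled[list(combo)]
        ys = np.delete(pooled, list(combo))
        u = sum(1 for xi in xs for yj in ys if xi > yj)
        total += 1
        if abs(u - center) >= abs(u_obs - center):
            count += 1
    return count / total


class TestMWU:
    def test_identical_samples_no_separation(self):
        u, p = mwu_test([1, 2, 3], [1, 2, 3])
        assert p > 0.9

    def test_full_separation_example(self):
        u, p = mwu_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert abs(p - 0.1) < 0.05  # exact enumeration p = 2/20

    def test_interleaved_example(self):
        u, p = mwu_test([1, 3], [2, 4])
        assert u == 1.0
        assert abs(p - exact_mwu_p(np.array([1, 3]), np.array([2, 4]))) < 0.05

    def test_all_tied_degenerate(self):
        u, p = mwu_test([2, 2], [2, 2, 2])
        assert (u, p) == (3.0, 1.0)

    def test_u_matches_counting_definition(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            x = rng.normal(size=rng.integers(2, 8))
            y = rng.normal(size=rng.integers(2, 8))
            u, _ = mwu_test(x, y)
            assert u == sum(1.0 for xi in x for yj in y if xi > yj)


def bh_oracle(p):
    """Step-up definition: q_(i) = min_{j>=i} p_(j) * m / j, clipped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = min(running, 1.0)
    return q


class TestBHAdjust:
    @pytest.mark.parametrize("p,expected", [
        ([0.04], [0.04]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.005, 0.5], [0.01, 0.5]),
    ])
    def test_worked_examples(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_matches_step_up_oracle_and_dominates_raw(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 40))
            q = bh_adjust(p)
            np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)
            assert (q >= p - 1e-15).all() and (q <= 1 + 1e-15).all()

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestLog2FoldChange:
    def test_worked_examples(self):
        assert log2_fold_change([2, 2], [4, 4], pseudocount=0) == pytest.approx(1.0)
        assert log2_fold_change([3], [3]) == pytest.approx(0.0)
        assert log2_fold_change([0], [1], 0.01) == pytest.approx(
            np.log2(1.01 / 0.01), rel=1e-6)

    def test_negative_pseudocount_error(self):
        with pytest.raises(ValueError):
            log2_fold_change([1], [1], pseudocount=-1)


def toy_metadata(sizes):
    rows = []
    for g, n in sizes.items():
        for i in range(n):
            rows.append({"barcode": f"{g}{i}", "cell_type": "n",
                         "group": g, "sample": g})
    return pd.DataFrame(rows)


class TestSubsampleEqual:
    def test_min_rule(self):
        md = toy_metadata({"A": 100, "B": 80, "C": 120})
        keep = subsample_equal(md, "n", ["A", "B", "C"], seed=0)
        kept = md.iloc[keep]["group"].value_counts()
        assert set(kept) == {80}

    def test_equal_sizes_identity(self):
        md = toy_metadata({"A": 50, "B": 50})
        keep = subsample_equal(md, "n", ["A", "B"], seed=0)
        assert len(keep) == 100

    def test_seed_determinism(self):
        md = toy_metadata({"A": 100, "B": 60})
        a = subsample_equal(md, "n", ["A", "B"], seed=7)
        b = subsample_equal(md, "n", ["A", "B"], seed=7)
        c = subsample_equal(md, "n", ["A", "B"], seed=8)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_empty_group_error(self):
        md = toy_metadata({"A": 10})
        with pytest.raises(ValueError, match="'B'"):
            subsample_equal(md, "n", ["A", "B"], seed=0)


class TestDEContrast:
    def test_planted_shift_detected(self, small_expression, small_dataset):
        expr, metadata = small_expression
        _, cm, _, truth = small_dataset
        res = de_contrast(expr, metadata, Contrast("neuron", "WT", "MUT"))
        table = res.table.set_index("gene_id")
        shift_gene = truth.loc[truth["kind"] == "shift", "gene_id"].iloc[0]
        assert table.loc[shift_gene, "is_deg"]
        assert table.loc[shift_gene, "direction"] == "up"

    def test_scale_effect_emd_without_fold_change(self, small_expression,
                                                  small_dataset):
        expr, metadata = small_expression
        _, _, _, truth = small_dataset
        res = de_contrast(expr, metadata, Contrast("neuron", "WT", "MUT"))
        table = res.table.set_index("gene_id")
        scale_gene = truth.loc[truth["kind"] == "scale", "gene_id"].iloc[0]
        assert table.loc[scale_gene, "emd"] > 0
        assert abs(table.loc[scale_gene, "log2fc"]) < 0.2

    def test_small_group_is_skipped_with_warning(self, small_expression, caplog):
        expr, metadata = small_expression
        c = Contrast("neuron", "WT", "MUT", min_cells_per_group=1000)
        with caplog.at_level("WARNING"):
            res = de_contrast(expr, metadata, c)
        assert res is None
        assert "min_cells_per_group" in caplog.text

    def test_unknown_labels_error(self, small_expression):
        expr, metadata = small_expression
        with pytest.raises(ValueError, match="cell type"):
            de_contrast(expr, metadata, Contrast("nope", "WT", "MUT"))
        with pytest.raises(ValueError, match="group"):
            de_contrast(expr, metadata, Contrast("neuron", "WT", "nope"))

    def test_subsampled_fit_is_reproducible(self, small_expression):
        expr, metadata = small_expression
        c = Contrast("neuron", "WT", "MUT", subsample_seed=5)
        a = de_contrast(expr, metadata, c).table
        b = de_contrast(expr, metadata, c).table
        pd.testing.assert_frame_equal(a, b)

    def test_table_invariants(self, small_expression):
        expr, metadata = small_expression
        res = de_contrast(expr, metadata, Contrast("glia", "WT", "MUT"))
        t = res.table
        np.testing.assert_allclose(t["signed_emd"].abs(), t["emd"], atol=1e-12)
        assert (t["p_adj"] >= t["p_raw"] - 1e-15).all()
        assert (t["p_adj"] <= 1).all()
        gate = (t["p_adj"] < 0.01) & (t["emd"] >= 0.1)
        np.testing.assert_array_equal(t["is_deg"], gate)
        # sorted by descending |signed_emd|
        assert (np.diff(t["emd"]) <= 1e-12).all()

    def test_layer_mismatch_error(self, small_expression):
        expr, metadata = small_expression
        with pytest.raises(ValueError, match="layer"):
            EMDDifferentialExpression(
                expr, metadata, Contrast("neuron", "WT", "MUT", layer="imputed"))


class TestSummarize:
    def _mk(self, directions):
        table = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(len(directions))],
            "is_deg": [d != "none" for d in directions],
            "direction": directions,
        })
        res = type("R", (), {})()
        res.table = table
        res.contrast = Contrast("n", "WT", "MUT")
        res.deg_counts = lambda t=table: (
            int((t.loc[t.is_deg, "direction"] == "up").sum()),
            int((t.loc[t.is_deg, "direction"] == "down").sum()),
            int(t.is_deg.sum()),
        )
        return res

    def test_counts_and_permutation_invariance(self):
        res = self._mk(["up", "up", "down", "none"])
        out = summarize_deg_counts([res])
        assert out.loc[0, ["n_up", "n_down", "n_total"]].tolist() == [2, 1, 3]
        res2 = self._mk(["down", "none", "up", "up"])
        out2 = summarize_deg_counts([res2])
        assert out2.loc[0, "n_total"] == 3

    def test_no_degs(self):
        out = summarize_deg_counts([self._mk(["none", "none"])])
        assert out.loc[0, ["n_up", "n_down", "n_total"]].tolist() == [0, 0, 0]

    def test_skipped_contrasts_ignored(self):
        out = summarize_deg_counts([None, self._mk(["up"])])
        assert len(out) == 1
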