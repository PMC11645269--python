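import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.special import comb

from dissocsig import (
    NormalizedMatrix,
    ValidationError,
    differential_abundance,
    proportions,
    two_group_cell_de,
)

from conftest import make_annotations


def make_pt(per_sample_props, groups, n_cells=2000, seed=None):
    """ProportionTable from per-sample cluster proportion vectors."""
    rows = []
    for i, (props, g) in enumerate(zip(per_sample_props, groups)):
        props = np.asarray(props, dtype=float)
        if seed is not None:
            rng = np.random.default_rng(seed + i)
            counts = rng.multinomial(n_cells, props)
        else:
            counts = np.round(props * n_cells).astype(int)
        for k, c in enumerate(counts):
            rows.append(
                {"sample_id": f"s{i}", "group": g, "cluster": f"k{k}",
                 "count": int(c), "proportion": c / counts.sum()}
            )
    return pd.DataFrame(rows)


class TestProportions:
    def test_simple_counts(self):
        ann = make_annotations(["c1", "c2", "c3"], ["s1"] * 3, ["A"] * 3)
        labels = pd.Series({"c1": "A", "c2": "A", "c3": "B"})
        pt = proportions(ann, labels).set_index("cluster")
        assert pt.loc["A", "proportion"] == pytest.approx(2 / 3)
        assert pt.loc["B", "proportion"] == pytest.approx(1 / 3)

    def test_absent_cluster_recorded_as_zero(self):
        ann = make_annotations(
            ["c1", "c2", "c3"], ["s1", "s1", "s2"], ["A"] * 3
        )
        labels = pd.Series({"c1": "x", "c2": "y", "c3": "x"})
        pt = proportions(ann, labels)
        row = pt[(pt["sample_id"] == "s2") & (pt["cluster"] == "y")]
        assert len(row) == 1 and row["proportion"].iloc[0] == 0.0

    def test_unlabeled_cell_is_error(self):
        ann = make_annotations(["c1", "c2"], ["s1"] * 2, ["A"] * 2)
        with pytest.raises(ValidationError, match="c2"):
            proportions(ann, pd.Series({"c1": "x"}))

    def test_counts_reconstruct_sample_totals(self):
        rng = np.random.default_rng(0)
        n = 200
        samples = [f"s{i % 6}" for i in range(n)]
        ann = make_annotations(
            [f"c{i}" for i in range(n)], samples, ["A"] * n
        )
        labels = pd.Series(
            rng.choice(["x", "y", "z"], n), index=[f"c{i}" for i in range(n)]
        )
        pt = proportions(ann, labels)
        totals = pt.groupby("sample_id")["count"].sum()
        expected = pd.Series(samples).value_counts()
        for s in expected.index:
            assert totals[s] == expected[s]
        np.testing.assert_allclose(
            pt.groupby("sample_id")["proportion"].sum(), 1.0, atol=1e-9
        )


class TestDifferentialAbundance:
    def test_transformed_difference_closed_form(self):
        pt = make_pt(
            [[0.25, 0.75]] * 2 + [[0.5, 0.5]] * 2, ["A", "A", "B", "B"]
        )
        res = differential_abundance(pt, "A", "B").set_index("cluster")
        expected = np.arcsin(np.sqrt(0.5)) - np.arcsin(np.sqrt(0.25))
        assert res.loc["k0", "diff_transformed"] == pytest.approx(expected, abs=1e-12)

    def test_group_swap_symmetry(self):
        pt = make_pt(
            [[0.2, 0.8], [0.3, 0.7], [0.5, 0.5], [0.4, 0.6]],
            ["A", "A", "B", "B"], seed=1,
        )
        fwd = differential_abundance(pt, "A", "B")
        rev = differential_abundance(pt, "B", "A")
        np.testing.assert_allclose(fwd["p"], rev["p"], rtol=1e-12)
        np.testing.assert_allclose(
            fwd["diff_transformed"], -rev["diff_transformed"], rtol=1e-12
        )

    def test_single_sample_group_rejected(self):
        pt = make_pt([[0.5, 0.5]] * 3, ["A", "A", "B"])
        with pytest.raises(ValidationError, match="need >= 2"):
            differential_abundance(pt, "A", "B")

    def test_power_on_shifted_cluster(self):
        # one cluster moves from 10% to 35%; 4 vs 4 samples of 2,000 cells
        rng = np.random.default_rng(5)
        base = np.array([0.10, 0.30, 0.25, 0.20, 0.15])
        shifted = np.array([0.35, 0.30 - 0.125, 0.25 - 0.125, 0.20, 0.15])
        hits = 0
        reps = 200
        for _ in range(reps):
            rows = []
            for i in range(8):
                props = base if i < 4 else shifted
                counts = rng.multinomial(2000, props)
                for k, c in enumerate(counts):
                    rows.append(
                        {"sample_id": f"s{i}", "group": "A" if i < 4 else "B",
                         "cluster": f"k{k}", "count": int(c),
                         "proportion": c / 2000}
                    )
            res = differential_abundance(pd.DataFrame(rows), "A", "B")
            hits += res.set_index("cluster").loc["k0", "fdr"] < 0.05
        assert hits / reps >= 0.95

    def test_fdr_matches_brute_force_bh(self):
        pt = make_pt(
            [[0.2, 0.3, 0.5]] * 3 + [[0.3, 0.3, 0.4]] * 3,
            ["A"] * 3 + ["B"] * 3, seed=2,
        )
        res = differential_abundance(pt, "A", "B")
        p = res["p"].to_numpy()
        n = len(p)
        order = np.argsort(p)
        adj = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            adj[i] = running
        np.testing.assert_allclose(res["fdr"], adj, rtol=1e-12)


def make_norm_from(dense, barcodes):
    genes = [f"g{i}" for i in range(np.asarray(dense).shape[0])]
    return NormalizedMatrix(genes, barcodes, sp.csr_matrix(np.asarray(dense, float)))


class TestTwoGroupCellDE:
    def test_identical_values_give_p_one(self):
        dense = np.tile([[1.0, 2.0, 1.0, 2.0]], (3, 1))
        norm = make_norm_from(dense, ["a1", "a2", "b1", "b2"])
        t = two_group_cell_de(norm, ["a1", "a2"], ["b1", "b2"])
        np.testing.assert_array_equal(t["p"], 1.0)

    def test_exact_small_sample_p_value(self):
        # 4 vs 4, complete separation, no ties: two-sided p = 2 / C(8,4)
        a_vals = [5.0, 6.0, 7.0, 8.0]
        b_vals = [1.0, 2.0, 3.0, 4.0]
        dense = np.array([a_vals + b_vals])
        barcodes = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        norm = make_norm_from(dense, barcodes)
        t = two_group_cell_de(norm, barcodes[:4], barcodes[4:])
        expected = 2.0 / comb(8, 4)
        assert t["p"].iloc[0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0286, abs=5e-5)

    def test_bonferroni_identity(self):
        rng = np.random.default_rng(6)
        dense = rng.gamma(2.0, 1.0, size=(30, 40))
        barcodes = [f"c{i}" for i in range(40)]
        norm = make_norm_from(dense, barcodes)
        t = two_group_cell_de(norm, barcodes[:20], barcodes[20:])
        np.testing.assert_allclose(
            t["p_adj"], np.minimum(1.0, t["p"] * 30), rtol=1e-12
        )

    def test_overlapping_sets_rejected(self):
        norm = make_norm_from([[1.0, 2.0, 3.0]], ["c0", "c1", "c2"])
        with pytest.raises(ValidationError, match="overlap"):
            two_group_cell_de(norm, ["c0", "c1"], ["c1", "c2"])

    def test_detects_strong_shift_with_ties(self):
        rng = np.random.default_rng(7)
        a = rng.poisson(5.0, size=(1, 60)).astype(float)
        b = rng.poisson(1.0, size=(1, 60)).astype(float)
        dense = np.hstack([a, b])
        barcodes = [f"a{i}" for i in range(60)] + [f"b{i}" for i in range(60)]
        norm = make_norm_from(dense, barcodes)
        t = two_group_cell_de(norm, barcodes[:60], barcodes[60:])
        assert t["p"].iloc[0] < 1e-10
        assert t["log2fc"].iloc[0] > 0  # A over B
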