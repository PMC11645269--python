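import numpy as np
import pandas as pd
import pytest

from dissocsig import (
    FactorLoadings,
    GeneList,
    ModuleScorer,
    SimConfig,
    ValidationError,
    calibrate_cutoff,
    correlate_metadata,
    downsample_equal_classes,
    enrichment_fractions,
    intersect_universe,
    log_normalize,
    mad_outlier_threshold,
    module_score,
    random_gene_lists,
    run_calibration,
    select_factor_genes,
    simulate_dataset,
)
from dissocsig.calibration import null_thresholds
from dissocsig.scoring import ScoreVector

from conftest import make_annotations, make_counts


class TestUniverse:
    def test_pairwise_intersection(self):
        a = make_counts(np.ones((3, 1)), genes=["A", "B", "C"])
        b = make_counts(np.ones((3, 1)), genes=["B", "C", "D"])
        assert intersect_universe([a, b]) == ["B", "C"]

    def test_single_matrix_is_identity(self):
        a = make_counts(np.ones((3, 1)), genes=["A", "B", "C"])
        assert intersect_universe([a]) == ["A", "B", "C"]

    def test_matches_naive_repeated_intersection(self):
        rng = np.random.default_rng(7)
        pool = [f"g{i}" for i in range(60)]
        mats = []
        for _ in range(5):
            genes = list(rng.choice(pool, 40, replace=False))
            mats.append(make_counts(np.ones((40, 1)), genes=genes))
        naive = set(mats[0].genes)
        for m in mats[1:]:
            naive = naive & set(m.genes)
        result = intersect_universe(mats)
        assert set(result) == naive
        assert result == [g for g in mats[0].genes if g in naive]

    def test_empty_intersection_is_error(self):
        a = make_counts(np.ones((1, 1)), genes=["A"])
        b = make_counts(np.ones((1, 1)), genes=["B"])
        with pytest.raises(ValidationError, match="empty"):
            intersect_universe([a, b])


class TestDownsample:
    def _dataset(self, sizes):
        n = sum(sizes.values())
        barcodes, classes = [], []
        for c, k in sizes.items():
            for i in range(k):
                barcodes.append(f"{c}{i}")
                classes.append(c)
        m = make_counts(
            np.arange(2 * n).reshape(2, n), barcodes=barcodes
        )
        ann = make_annotations(barcodes, ["s1"] * n, ["A"] * n, classes)
        return m, ann

    def test_all_classes_reduced_to_minimum(self):
        m, ann = self._dataset({"x": 100, "y": 50, "z": 80})
        m2, ann2 = downsample_equal_classes(m, ann, seed=0)
        counts = ann2.df["cell_class"].value_counts()
        assert set(counts) == {50}

    def test_equal_classes_unchanged(self):
        m, ann = self._dataset({"x": 30, "y": 30})
        m2, _ = downsample_equal_classes(m, ann, seed=0)
        assert m2.barcodes == m.barcodes

    def test_no_duplicates_across_seeds(self):
        m, ann = self._dataset({"x": 40, "y": 25, "z": 31})
        for seed in range(20):
            m2, ann2 = downsample_equal_classes(m, ann, seed=seed)
            assert len(set(m2.barcodes)) == len(m2.barcodes)
            assert set(ann2.df["cell_class"].value_counts()) == {25}


class TestRandomLists:
    def test_sizes_and_uniqueness(self):
        universe = [f"g{i}" for i in range(50)]
        lists = random_gene_lists(universe, 38, n_lists=100, seed=1)
        assert len(lists) == 100
        for gl in lists:
            assert len(gl) == 38
            assert len(set(gl.symbols)) == 38

    def test_full_length_lists_are_permutations(self):
        universe = [f"g{i}" for i in range(10)]
        for gl in random_gene_lists(universe, 10, n_lists=5, seed=2):
            assert sorted(gl.symbols) == sorted(universe)

    def test_seed_determinism(self):
        universe = [f"g{i}" for i in range(30)]
        a = random_gene_lists(universe, 5, 10, seed=3)
        b = random_gene_lists(universe, 5, 10, seed=3)
        c = random_gene_lists(universe, 5, 10, seed=4)
        assert [x.symbols for x in a] == [x.symbols for x in b]
        assert [x.symbols for x in a] != [x.symbols for x in c]

    def test_oversized_length_rejected(self):
        with pytest.raises(ValidationError, match="universe"):
            random_gene_lists(["a", "b"], 3)


class TestMADThreshold:
    def test_hand_computation(self):
        assert mad_outlier_threshold([1, 2, 3, 4, 5]) == 6.0

    def test_constant_vector(self):
        assert mad_outlier_threshold([7.0] * 9) == 7.0

    def test_matches_literal_two_pass_median(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            x = rng.normal(size=rng.integers(3, 40))
            med = sorted(x)[len(x) // 2] if len(x) % 2 else (
                sorted(x)[len(x) // 2 - 1] + sorted(x)[len(x) // 2]
            ) / 2
            dev = sorted(abs(v - med) for v in x)
            mad = dev[len(x) // 2] if len(x) % 2 else (
                dev[len(x) // 2 - 1] + dev[len(x) // 2]
            ) / 2
            assert mad_outlier_threshold(x) == pytest.approx(med + 3 * mad, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            mad_outlier_threshold([])


class TestCutoff:
    def test_order_statistic_on_1_to_1000(self):
        assert calibrate_cutoff(np.arange(1, 1001), tail=0.025) == 975.0

    def test_constant_thresholds(self):
        assert calibrate_cutoff([4.2] * 100, tail=0.025) == 4.2

    def test_too_few_thresholds_rejected(self):
        with pytest.raises(ValidationError, match="at least"):
            calibrate_cutoff([1.0] * 10, tail=0.025)

    def test_monotone_in_one_minus_tail(self):
        rng = np.random.default_rng(9)
        thr = rng.normal(size=500)
        cutoffs = [calibrate_cutoff(thr, tail) for tail in (0.5, 0.25, 0.1, 0.05, 0.002)]
        assert cutoffs == sorted(cutoffs)

    def test_strict_exceedance_count(self):
        rng = np.random.default_rng(10)
        thr = rng.normal(size=1000)  # distinct with probability 1
        cut = calibrate_cutoff(thr, tail=0.025)
        assert (thr > cut).sum() == 25


class TestEnrichmentFractions:
    def _score(self, values, barcodes):
        return ScoreVector(
            "sig", pd.Series(values, index=barcodes), ["g"], []
        )

    def test_all_below_gives_zero(self):
        barcodes = [f"c{i}" for i in range(4)]
        ann = make_annotations(barcodes, ["s1", "s1", "s2", "s2"], ["A"] * 4)
        et = enrichment_fractions(self._score([0.1] * 4, barcodes), ann, cutoff=0.5)
        assert (et["fraction"] == 0).all()

    def test_half_above(self):
        barcodes = [f"c{i}" for i in range(4)]
        ann = make_annotations(barcodes, ["s1"] * 4, ["A"] * 4)
        et = enrichment_fractions(
            self._score([0.9, 0.8, 0.1, 0.2], barcodes), ann, cutoff=0.5
        )
        assert et["fraction"].iloc[0] == 0.5

    def test_boundary_score_not_enriched(self):
        barcodes = ["c0", "c1"]
        ann = make_annotations(barcodes, ["s1"] * 2, ["A"] * 2)
        et = enrichment_fractions(self._score([0.5, 0.6], barcodes), ann, cutoff=0.5)
        assert et["n_above"].iloc[0] == 1  # 0.5 is not strictly above

    def test_sample_without_class_cells_gets_missing_fraction(self):
        barcodes = ["c0", "c1", "c2"]
        ann = make_annotations(
            barcodes, ["s1", "s1", "s2"], ["A"] * 3, ["myeloid", "myeloid", "neuron"]
        )
        et = enrichment_fractions(
            self._score([1.0, 0.0, 1.0], barcodes), ann, 0.5, class_filter="myeloid"
        ).set_index("sample_id")
        assert et.loc["s2", "n_cells"] == 0
        assert np.isnan(et.loc["s2", "fraction"])

    def test_recovers_spiked_fraction(self, spiked_norm, spiked_sim):
        norm, ann = spiked_norm
        _, _, truth = spiked_sim
        calib = run_calibration(norm, ann, list_length=25, n_lists=200, seed=3,
                                n_bins=10, ctrl_per_gene=25)
        sig = GeneList("program", "mouse", list(truth.program_genes))
        sv = module_score(norm, sig, n_bins=10, ctrl_per_gene=25, seed=4)
        et = enrichment_fractions(sv, ann, calib.cutoff, class_filter="myeloid")
        by_group = et.groupby("group")["fraction"].mean()
        assert abs(by_group["DISS"] - 0.3) <= 0.10
        assert by_group["CTRL"] <= 0.05


class TestNullCalibrationEndToEnd:
    def test_null_enrichment_fraction_stays_low(self):
        # no activation anywhere: the calibrated cutoff should mark at most a
        # tiny fraction of cells per sample as enriched
        fractions = []
        for seed in range(10):
            cfg = SimConfig(
                seed=100 + seed, n_genes=900, groups=("CTRL",),
                samples_per_group=4, cells_per_sample=300, activated_fraction={},
            )
            m, ann, truth = simulate_dataset(cfg)
            norm = log_normalize(m)
            calib = run_calibration(norm, ann, list_length=25, n_lists=200,
                                    seed=seed, n_bins=10, ctrl_per_gene=25)
            sig = GeneList("program", "mouse", list(truth.program_genes))
            sv = module_score(norm, sig, n_bins=10, ctrl_per_gene=25, seed=seed)
            et = enrichment_fractions(sv, ann, calib.cutoff, class_filter="myeloid")
            fractions.extend(et["fraction"].tolist())
        assert np.median(fractions) <= 0.02


class TestFactorGenes:
    def test_threshold_selection_ordered(self):
        fl = FactorLoadings("f1", pd.Series({"g1": 0.9, "g2": 0.5, "g3": 0.1}))
        assert select_factor_genes(fl, 0.3).symbols == ["g1", "g2"]

    def test_threshold_above_max_warns_empty(self):
        fl = FactorLoadings("f1", pd.Series({"g1": 0.9}))
        with pytest.warns(UserWarning, match="no gene"):
            assert select_factor_genes(fl, 2.0) is None

    def test_constructed_38_gene_factor(self):
        loadings = pd.Series(
            {f"g{i:02d}": (1.0 - i * 0.01 if i < 38 else 0.05) for i in range(60)}
        )
        gl = select_factor_genes(FactorLoadings("microglia", loadings), 0.5)
        assert len(gl) == 38

    def test_ties_broken_by_symbol(self):
        fl = FactorLoadings("f", pd.Series({"b": 0.5, "a": 0.5, "c": 0.9}))
        assert select_factor_genes(fl, 0.1).symbols == ["c", "a", "b"]


class TestCorrelateMetadata:
    def _table(self, fractions, covariates):
        return pd.DataFrame({"fraction": fractions, "PMI": covariates})

    def test_perfect_monotone_gives_rho_one(self):
        et = self._table([0.1, 0.2, 0.35, 0.5], [10, 20, 30, 40])
        res = correlate_metadata(et, "PMI")
        assert res.rho == pytest.approx(1.0)
        assert res.n == 4

    def test_constant_fraction_is_error(self):
        et = self._table([0.2, 0.2, 0.2], [10, 20, 30])
        with pytest.raises(ValidationError, match="constant"):
            correlate_metadata(et, "PMI")

    def test_missing_rows_excluded_and_n_reported(self):
        et = self._table(
            [0.1, np.nan, 0.3, 0.5, 0.2], [10, 20, np.nan, 40, 15]
        )
        res = correlate_metadata(et, "PMI")
        assert res.n == 3

    def test_too_few_samples_is_error(self):
        et = self._table([0.1, np.nan, 0.3], [10, 20, np.nan])
        with pytest.raises(ValidationError, match=">= 3"):
            correlate_metadata(et, "PMI")

    def test_matches_naive_rank_pearson_oracle(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        et = self._table(y, x)
        res = correlate_metadata(et, "PMI")

        def average_ranks(v):
            order = np.argsort(v)
            ranks = np.empty(len(v))
            ranks[order] = np.arange(1, len(v) + 1)
            # average ties (none expected for continuous draws, but be literal)
            for val in np.unique(v):
                mask = v == val
                ranks[mask] = ranks[mask].mean()
            return ranks

        rx, ry = average_ranks(x), average_ranks(y)
        rho = np.corrcoef(rx, ry)[0, 1]
        assert res.rho == pytest.approx(rho, rel=1e-12)


def test_coverage_of_fresh_lists_near_tail(null_norm):
    # small-scale version of the calibration-coverage experiment: the
    # fraction of freshly drawn random-list thresholds exceeding the cutoff
    # should sit near the nominal tail mass
    norm, ann = null_norm
    norm2, _ = downsample_equal_classes(norm, ann, seed=1)
    scorer = ModuleScorer(norm2, n_bins=10, ctrl_per_gene=25)
    thr = null_thresholds(scorer, norm2.genes, 20, 400, list_seed=2, score_seed=3)
    cut = calibrate_cutoff(thr, tail=0.05)
    fresh = null_thresholds(scorer, norm2.genes, 20, 800, list_seed=4, score_seed=5)
    assert abs((fresh > cut).mean() - 0.05) < 0.03
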