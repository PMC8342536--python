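import numpy as np
import pandas as pd
import pytest

from glycodiff import glyco as gl
from glycodiff.glyco import GlycoMatrix

from conftest import make_glyco_records


def rec(sample, rt=20.0, auc=5000.0, protein="GP1", site="N100", glycan="N4H5"):
    return (sample, protein, site, glycan, rt, auc)


def toy_matrix(values, scale="raw", groups=None):
    """values: dict {(protein, site, glycan): [per-sample abundances]}"""
    idx = pd.MultiIndex.from_tuples(values.keys(),
                                    names=["protein", "glycosite", "glycan"])
    n = len(next(iter(values.values())))
    cols = [f"S{i+1}" for i in range(n)]
    data = pd.DataFrame(list(values.values()), index=idx, columns=cols, dtype=float)
    return GlycoMatrix(data=data, scale=scale, groups=groups)


class TestRTFilter:
    def test_hand_example(self):
        records = make_glyco_records(
            [rec(f"S{i}", rt=r) for i, r in enumerate([10.0, 10.1, 10.2, 10.3, 50.0])])
        kept, removed = gl.rt_outlier_filter(records)
        assert len(kept) == 4 and len(removed) == 1
        assert removed["rt"].iloc[0] == 50.0

    def test_identical_rts_kept(self):
        records = make_glyco_records([rec(f"S{i}", rt=12.5) for i in range(6)])
        kept, removed = gl.rt_outlier_filter(records)
        assert len(removed) == 0

    def test_small_groups_pass_through(self):
        records = make_glyco_records(
            [rec("S1", rt=10.0), rec("S2", rt=10.1), rec("S3", rt=99.0)])
        kept, removed = gl.rt_outlier_filter(records)
        assert len(kept) == 3 and len(removed) == 0

    def test_boundary_inclusive(self):
        # Q1=1.75, Q3=3.25 (type 7), IQR=1.5 -> bounds [-0.5, 5.5]
        rts = [1.0, 2.0, 3.0, 4.0, 5.5]
        records = make_glyco_records([rec(f"S{i}", rt=r) for i, r in enumerate(rts)])
        kept, _ = gl.rt_outlier_filter(records)
        assert len(kept) == 5

    def test_groups_independent(self):
        a = [rec(f"S{i}", rt=r, glycan="N4H5")
             for i, r in enumerate([10.0, 10.1, 10.2, 10.3, 50.0])]
        b = [rec(f"S{i}", rt=r, glycan="N4H5F1")
             for i, r in enumerate([49.9, 50.0, 50.1, 50.2])]
        kept, removed = gl.rt_outlier_filter(make_glyco_records(a + b))
        assert len(removed) == 1
        assert removed["glycan"].iloc[0] == "N4H5"

    def test_idempotent(self):
        records = make_glyco_records(
            [rec(f"S{i}", rt=r) for i, r in enumerate([10.0, 10.1, 10.2, 10.3, 50.0, 9.9])])
        kept1, _ = gl.rt_outlier_filter(records)
        kept2, removed2 = gl.rt_outlier_filter(kept1)
        pd.testing.assert_frame_equal(kept1, kept2)
        assert len(removed2) == 0


class TestAUCFilter:
    def test_strict_below(self):
        records = make_glyco_records([rec("S1", auc=999.9)])
        assert len(gl.auc_filter(records)) == 0

    def test_boundary_kept(self):
        records = make_glyco_records([rec("S1", auc=1000.0)])
        assert len(gl.auc_filter(records)) == 1

    def test_enumeration(self):
        aucs = [5, 999, 1000, 1500, 2000, 100, 9999.9, 1e6, 1234, 4321]
        records = make_glyco_records(
            [rec(f"S{i}", auc=a) for i, a in enumerate(aucs)])
        kept = gl.auc_filter(records)
        assert len(kept) == sum(a >= 1000 for a in aucs) == 7

    def test_idempotent(self):
        records = make_glyco_records(
            [rec(f"S{i}", auc=a) for i, a in enumerate([500, 1500, 2500])])
        once = gl.auc_filter(records)
        pd.testing.assert_frame_equal(gl.auc_filter(once), once)


class TestPresenceFilter:
    def test_sparse_row_dropped(self):
        vals = {("GP1", "N1", "N4H5"): [1.0] * 4 + [np.nan] * 8,
                ("GP1", "N1", "N4H5F1"): [1.0] * 12}
        m = gl.presence_filter(toy_matrix(vals), min_samples=5, min_glycopeptides=1)
        assert list(m.data.index.get_level_values("glycan")) == ["N4H5F1"]

    def test_dense_noop(self):
        vals = {("GP1", "N1", f"N4H{h}"): [1.0] * 20 for h in range(3, 10)}
        m0 = toy_matrix(vals)
        m = gl.presence_filter(m0, min_samples=5, min_glycopeptides=5)
        pd.testing.assert_frame_equal(m.data, m0.data)

    def test_toy_matches_enumeration(self, rng):
        # 12 glycopeptides x 8 samples with a designed missingness pattern
        data = rng.uniform(1e3, 1e5, size=(12, 8))
        mask = rng.random((12, 8)) < 0.45
        data[mask] = np.nan
        vals = {("GP1", f"N{i}", "N4H5"): data[i] for i in range(12)}
        m = toy_matrix(vals)
        min_s, min_g = 4, 5
        # brute-force oracle: rows first, then columns, once
        rows_keep = [i for i in range(12) if np.sum(~np.isnan(data[i])) >= min_s]
        sub = data[rows_keep]
        cols_keep = [j for j in range(8)
                     if np.sum(~np.isnan(sub[:, j])) >= min_g]
        got = gl.presence_filter(m, min_samples=min_s, min_glycopeptides=min_g)
        assert list(got.data.index.get_level_values("glycosite")) == [
            f"N{i}" for i in rows_keep]
        assert list(got.data.columns) == [f"S{j+1}" for j in cols_keep]

    def test_single_pass_not_fixpoint(self):
        # after dropping the sparse column, row r would fall below the row
        # threshold — a fixpoint iteration would remove it, a single pass must not
        vals = {
            ("GP1", "N1", "A2"): [1.0, 1.0, np.nan, np.nan],
            ("GP1", "N1", "A3"): [1.0, np.nan, 1.0, 1.0],
            ("GP1", "N1", "A4"): [1.0, np.nan, 1.0, 1.0],
        }
        idx = pd.MultiIndex.from_tuples(vals.keys(),
                                        names=["protein", "glycosite", "glycan"])
        data = pd.DataFrame(list(vals.values()), index=idx,
                            columns=["S1", "S2", "S3", "S4"], dtype=float)
        m = GlycoMatrix(data=data)
        got = gl.presence_filter(m, min_samples=2, min_glycopeptides=2)
        # column S2 has 1 glycopeptide -> dropped; row A2 keeps its seat
        assert "S2" not in got.data.columns
        assert ("GP1", "N1", "A2") in got.data.index

    def test_provenance_counts(self):
        vals = {("GP1", "N1", "N4H5"): [1.0, np.nan, np.nan],
                ("GP1", "N1", "N4H5F1"): [1.0, 1.0, 1.0]}
        m = gl.presence_filter(toy_matrix(vals), min_samples=2, min_glycopeptides=1)
        log = m.provenance[-1]
        assert log["glycopeptides_removed"] == 1

    def test_empty_result_error(self):
        vals = {("GP1", "N1", "N4H5"): [1.0, np.nan]}
        with pytest.raises(gl.EmptyMatrixError):
            gl.presence_filter(toy_matrix(vals), min_samples=5)

    def test_row_and_column_filters_each_idempotent(self, rng):
        # the glycopeptide-presence and sample-presence filters are separate
        # single-pass steps; each one is idempotent on its own
        data = rng.uniform(1e3, 1e5, size=(10, 8))
        data[rng.random((10, 8)) < 0.4] = np.nan
        vals = {("GP1", f"N{i}", "N4H5"): data[i] for i in range(10)}
        rows_once = gl.presence_filter(toy_matrix(vals), 4, 0)
        rows_twice = gl.presence_filter(rows_once, 4, 0)
        pd.testing.assert_frame_equal(rows_once.data, rows_twice.data)
        cols_once = gl.presence_filter(rows_once, 0, 4)
        cols_twice = gl.presence_filter(cols_once, 0, 4)
        pd.testing.assert_frame_equal(cols_once.data, cols_twice.data)


class TestNormalization:
    def test_identical_samples_unchanged_up_to_scale(self):
        col = [100.0, 200.0, 300.0, 400.0]
        m = toy_matrix({("GP1", "N1", f"G{i}"): [col[i], col[i]] for i in range(4)})
        got = gl.quotient_total_area_normalize(m)
        np.testing.assert_allclose(got.data["S1"], got.data["S2"])
        np.testing.assert_allclose(got.data["S1"], col)

    def test_proportional_columns_become_equal(self):
        base = np.array([120.0, 340.0, 560.0, 780.0])
        m = toy_matrix({("GP1", "N1", f"G{i}"):
                        [base[i], 2 * base[i], 0.5 * base[i]] for i in range(4)})
        got = gl.quotient_total_area_normalize(m)
        np.testing.assert_allclose(got.data["S1"], got.data["S2"], atol=1e-10)
        np.testing.assert_allclose(got.data["S1"], got.data["S3"], atol=1e-10)

    def test_single_sample_identity(self):
        m = toy_matrix({("GP1", "N1", f"G{i}"): [v] for i, v in
                        enumerate([10.0, 20.0, 30.0])})
        got = gl.quotient_total_area_normalize(m)
        np.testing.assert_allclose(got.data["S1"], [10.0, 20.0, 30.0])

    def test_all_missing_sample_error(self):
        m = toy_matrix({("GP1", "N1", "G1"): [1.0, np.nan],
                        ("GP1", "N1", "G2"): [2.0, np.nan]})
        with pytest.raises(ValueError, match="no quantified"):
            gl.quotient_total_area_normalize(m)

    def test_requires_raw_scale(self):
        m = toy_matrix({("GP1", "N1", "G1"): [1.0, 2.0]}, scale="log")
        with pytest.raises(ValueError):
            gl.quotient_total_area_normalize(m)


class TestLogTransform:
    def test_base2(self):
        m = toy_matrix({("GP1", "N1", "G1"): [8.0, 8.0]})
        got = gl.log_transform(gl.quotient_total_area_normalize(m), base=2)
        np.testing.assert_allclose(got.data.iloc[0], 3.0)

    def test_missing_stays_missing(self):
        m = toy_matrix({("GP1", "N1", "G1"): [8.0, np.nan],
                        ("GP1", "N1", "G2"): [4.0, 4.0]})
        got = gl.log_transform(m)
        assert np.isnan(got.data.loc[("GP1", "N1", "G1"), "S2"])

    def test_round_trip(self):
        vals = np.array([1.5, 8.0, 123.4])
        m = toy_matrix({("GP1", "N1", f"G{i}"): [v] for i, v in enumerate(vals)})
        got = gl.log_transform(m, base=2)
        np.testing.assert_allclose(2.0 ** got.data["S1"].to_numpy(), vals, atol=1e-12)

    def test_nonpositive_error(self):
        m = toy_matrix({("GP1", "N1", "G1"): [0.0, 1.0]})
        with pytest.raises(ValueError, match="non-positive"):
            gl.log_transform(m)


class TestSiteMetrics:
    def test_fucosylation_ratio(self):
        m = toy_matrix({("GP1", "N1", "N4H5F1"): [300.0],
                        ("GP1", "N1", "N4H5"): [100.0]})
        t = gl.site_metric_degrees(m)
        assert t["fucosylation"].iloc[0] == pytest.approx(0.75, abs=1e-12)

    def test_sialylation_two_glycoforms(self):
        m = toy_matrix({("GP1", "N1", "N4H5S1"): [100.0],
                        ("GP1", "N1", "N4H5"): [100.0]})
        t = gl.site_metric_degrees(m)
        assert t["sialylation"].iloc[0] == pytest.approx(0.25, abs=1e-12)

    def test_saturated_sialylation(self):
        m = toy_matrix({("GP1", "N1", "N4H5S2"): [5000.0]})
        t = gl.site_metric_degrees(m)
        assert t["sialylation"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_galactosylation(self):
        # H5 -> 2 gal on 2 antennae; H3 -> 0 gal
        m = toy_matrix({("GP1", "N1", "N4H5"): [100.0],
                        ("GP1", "N1", "N4H3"): [100.0]})
        t = gl.site_metric_degrees(m)
        assert t["galactosylation"].iloc[0] == pytest.approx(0.5, abs=1e-12)

    def test_rescaling_invariance(self, rng):
        vals = {("GP1", "N1", g): rng.uniform(1e3, 1e5, size=3)
                for g in ["N4H5", "N4H5F1", "N4H5S1", "N4H5S2F1"]}
        m = toy_matrix(vals)
        scaled = toy_matrix({k: v * np.array([1.0, 7.3, 0.2]) for k, v in vals.items()})
        pd.testing.assert_frame_equal(gl.site_metric_degrees(m),
                                      gl.site_metric_degrees(scaled))

    def test_missing_denominator_nan(self):
        # oligomannose only: no antennae -> sialylation/galactosylation NaN
        m = toy_matrix({("GP1", "N1", "N2H6"): [100.0]})
        t = gl.site_metric_degrees(m)
        assert np.isnan(t["sialylation"].iloc[0])
        assert np.isnan(t["galactosylation"].iloc[0])
        assert t["fucosylation"].iloc[0] == 0.0

    def test_rejects_log_matrix(self):
        m = toy_matrix({("GP1", "N1", "N4H5"): [3.0]}, scale="log")
        with pytest.raises(ValueError):
            gl.site_metric_degrees(m)

    def test_unknown_annotation_error(self):
        m = toy_matrix({("GP1", "N1", "N4H5"): [1.0]})
        with pytest.raises(KeyError):
            gl.site_metric_degrees(m, features={})


class TestDescriptors:
    def test_all_complex_type_ratio(self):
        m = toy_matrix({("GP1", "N1", "N4H5"): [100.0],
                        ("GP1", "N1", "N5H6F1"): [300.0]})
        d = gl.dataset_descriptors(m)
        assert d.type_ratio == {"complex": 1.0}
        assert d.fraction_complex == 1.0
        assert sum(d.branching_distribution.values()) == pytest.approx(1.0)

    def test_no_sialylation(self):
        m = toy_matrix({("GP1", "N1", "N4H5"): [100.0],
                        ("GP1", "N1", "N4H5F1"): [100.0]})
        d = gl.dataset_descriptors(m)
        assert d.average_antenna_sialylation == 0.0
        assert d.fraction_antennary_sialylated == 0.0
        assert d.average_fucosylation == pytest.approx(0.5)

    def test_type_ratio_sums_to_one(self, paper_like_cohort):
        _, glyco_df, meta, _ = paper_like_cohort
        kept = gl.auc_filter(gl.rt_outlier_filter(glyco_df)[0])
        m = gl.presence_filter(gl.records_to_matrix(kept))
        d = gl.dataset_descriptors(m)
        assert sum(d.type_ratio.values()) == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= d.average_fucosylation <= 1.0
        assert 0.0 <= d.average_antenna_sialylation <= 1.0


class TestDifferential:
    def test_two_group_spike_recovered(self, rng):
        n1, n2 = 46, 49
        base = np.vstack([rng.normal(0.47, 0.1, size=(1, n1 + n2))])
        spike = np.concatenate([rng.normal(0.47, 0.1, n1), rng.normal(0.83, 0.1, n2)])
        null = rng.normal(0.5, 0.1, size=(20, n1 + n2))
        data = pd.DataFrame(np.vstack([spike, base, null]),
                            index=[f"f{i}" for i in range(22)],
                            columns=[f"S{i}" for i in range(n1 + n2)])
        groups = pd.Series(["Normal"] * n1 + ["PCa"] * n2, index=data.columns)
        res, tukey, skipped = gl.differential(data, groups)
        row = res.set_index("feature").loc["f0"]
        assert row["significant"]
        est = row["mean_PCa"] - row["mean_Normal"]
        assert est == pytest.approx(0.36, abs=0.05)
        assert tukey.empty  # no Tukey for the two-group design

    def test_zero_variance_skipped(self):
        data = pd.DataFrame([[1.0] * 8], index=["flat"],
                            columns=[f"S{i}" for i in range(8)])
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=data.columns)
        res, _, skipped = gl.differential(data, groups)
        assert res.empty
        assert skipped[0]["feature"] == "flat"

    def test_insufficient_group_skipped(self):
        data = pd.DataFrame([[1.0, 2.0, np.nan, np.nan, 3.0, 4.0]], index=["f"],
                            columns=[f"S{i}" for i in range(6)])
        groups = pd.Series(["A", "A", "B", "B", "B", "B"], index=data.columns)
        res, _, skipped = gl.differential(data, groups)
        assert len(skipped) == 0 and len(res) == 1  # A still has 2 values
        data.iloc[0, 1] = np.nan
        res, _, skipped = gl.differential(data, groups)
        assert len(skipped) == 1

    def test_multigroup_emits_tukey_for_significant(self, rng):
        n = 12
        groups = pd.Series(sum([[g] * n for g in ["Normal", "G1", "G2", "G3"]], []),
                           index=[f"S{i}" for i in range(4 * n)])
        effect = np.concatenate([rng.normal(m, 0.3, n) for m in [0, 1, 2, 3]])
        flat = rng.normal(0, 0.3, 4 * n)
        data = pd.DataFrame([effect, flat], index=["hit", "null"],
                            columns=groups.index)
        res, tukey, _ = gl.differential(data, groups)
        res = res.set_index("feature")
        assert bool(res.loc["hit", "significant"])
        pairs = tukey[tukey["feature"] == "hit"]
        assert len(pairs) == 6
        big = pairs[(pairs["group_a"] == "Normal") & (pairs["group_b"] == "G3")]
        assert (big["p_adj"] < 0.05).all()
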