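"""Unit tests of the curation/normalization stages."""

import numpy as np
import pandas as pd
import pytest

from uromet import preprocess as pp
from uromet.preprocess import FilterConfig, LoessConfig

from conftest import make_meta, make_table


def _qc_blank_meta(n_qc=2, n_blank=2, n_study=0):
    rows = [{"injection_id": f"QC{i}", "type": "qc_pool"} for i in range(n_qc)]
    rows += [{"injection_id": f"BLK{i}", "type": "blank"} for i in range(n_blank)]
    rows += [{"injection_id": f"S{i}", "type": "study"} for i in range(n_study)]
    return make_meta(rows)


class TestBlankFilter:
    def test_ratio_rule(self):
        meta = _qc_blank_meta()
        table = make_table(
            {
                "clean": [100, 100, 0, 0],  # blank mean 0 -> kept
                "contam": [100, 100, 100, 100],  # ratio 1 >= 0.5 -> removed
                "border": [100, 100, 50, 50],  # ratio exactly 0.5 -> removed
                "low": [100, 100, 10, 10],  # ratio 0.1 -> kept
            },
            meta["injection_id"].tolist(),
        )
        filtered, removed = pp.filter_blank_features(table, meta)
        assert sorted(removed) == ["border", "contam"]
        assert list(filtered.index) == ["clean", "low"]

    def test_constructed_contaminants_exactly_removed(self):
        rng = np.random.default_rng(0)
        meta = _qc_blank_meta(n_qc=3, n_blank=3)
        inj = meta["injection_id"].tolist()
        values = {f"f{i}": list(rng.uniform(50, 150, 3)) + list(rng.uniform(0, 5, 3)) for i in range(30)}
        contaminants = {f"c{i}": list(rng.uniform(50, 150, 6)) for i in range(10)}
        table = make_table({**values, **contaminants}, inj)
        _, removed = pp.filter_blank_features(table, meta)
        assert sorted(removed) == sorted(contaminants)

    def test_no_blanks_is_an_error(self):
        meta = _qc_blank_meta(n_blank=0)
        table = make_table({"f": [1, 1]}, meta["injection_id"].tolist())
        with pytest.raises(ValueError, match="blank"):
            pp.filter_blank_features(table, meta)


class TestDilutionLinearity:
    def _series_meta(self, levels):
        return make_meta(
            [{"injection_id": f"D{i}", "type": "qc_dilution", "dilution_level": lv}
             for i, lv in enumerate(levels)]
        )

    def test_proportional_feature_kept_constant_removed(self):
        levels = [1, 2, 3, 4, 5]
        meta = self._series_meta(levels)
        table = make_table(
            {"prop": [10, 20, 30, 40, 50], "const": [7, 7, 7, 7, 7]},
            meta["injection_id"].tolist(),
        )
        filtered, removed = pp.filter_dilution_linearity(table, meta)
        assert removed == ["const"]
        assert list(filtered.index) == ["prop"]

    def test_pearson_matches_hand_oracle(self):
        levels = [1, 2, 3, 4, 5]
        values = [1.0, 2.1, 2.9, 4.2, 4.8]
        x, v = np.asarray(levels, float), np.asarray(values, float)
        r_hand = float(
            ((x - x.mean()) * (v - v.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((v - v.mean()) ** 2).sum())
        )
        meta = self._series_meta(levels)
        table = make_table({"f": values}, meta["injection_id"].tolist())
        filt = pp.DilutionLinearityFilter().fit(table.T, meta=meta)
        assert filt.r_["f"] == pytest.approx(r_hand, abs=1e-12)
        assert ("f" in filt.removed_ids_) == (r_hand < 0.6)

    def test_too_few_levels_is_an_error(self):
        meta = self._series_meta([1, 2])
        table = make_table({"f": [1, 2]}, meta["injection_id"].tolist())
        with pytest.raises(ValueError, match="3 dilution levels"):
            pp.filter_dilution_linearity(table, meta)


class TestPresenceFilter:
    @pytest.mark.parametrize("n_present, kept", [(67, True), (66, False), (99, True)])
    def test_strict_two_thirds_boundary(self, n_present, kept):
        meta = make_meta([{"injection_id": f"S{i}", "type": "study"} for i in range(99)])
        row = [1.0] * n_present + [np.nan] * (99 - n_present)
        table = make_table({"f": row}, meta["injection_id"].tolist())
        filtered, removed = pp.filter_presence(table, meta)
        assert ("f" in removed) == (not kept)


class TestLoess:
    def _batch_meta(self, n, qc_positions):
        rows = []
        for i in range(n):
            kind = "qc_pool" if i in qc_positions else "study"
            rows.append({"injection_id": f"I{i}", "type": kind, "batch": 1,
                         "injection_order": i + 1})
        return make_meta(rows)

    def test_constant_qc_leaves_table_unchanged(self):
        meta = self._batch_meta(12, {0, 3, 6, 9, 11})
        rng = np.random.default_rng(1)
        table = make_table({"f": [50.0] * 12, "g": list(rng.uniform(10, 20, 12))},
                           meta["injection_id"].tolist())
        table.loc["g", meta.loc[meta["type"] == "qc_pool", "injection_id"]] = 33.0
        corrected = pp.loess_drift_correct(table, meta)
        pd.testing.assert_frame_equal(corrected, table)

    def test_linear_drift_flattened(self):
        """A noiseless 2x linear drift across the batch is removed: the
        standardized slope of QC abundance vs order goes to ~0."""
        n = 21
        qc_pos = set(range(0, n, 4))
        meta = self._batch_meta(n, qc_pos)
        order = np.arange(1, n + 1, dtype=float)
        drift = 1.0 + (order - 1) / (n - 1)  # 1x -> 2x
        table = make_table({"f": (100.0 * drift).tolist()}, meta["injection_id"].tolist())
        corrected = pp.loess_drift_correct(table, meta)
        qc_cols = meta.loc[meta["type"] == "qc_pool", "injection_id"]
        qc_vals = corrected.loc["f", qc_cols].to_numpy(float)
        qc_order = meta.loc[meta["type"] == "qc_pool", "injection_order"].to_numpy(float)
        # relative fitted change across the batch: ~1.0 before, ~0 after
        slope = np.polyfit(qc_order, qc_vals, 1)[0] * np.ptp(qc_order) / qc_vals.mean()
        assert abs(slope) < 0.05

    def test_per_batch_correction_beats_global_fit(self):
        """Opposite drifts in two batches cancel only with per-batch fits."""
        rows, vals = [], []
        for b, sign in ((1, +1.0), (2, -1.0)):
            for i in range(16):
                kind = "qc_pool" if i % 3 == 0 else "study"
                rows.append({"injection_id": f"B{b}I{i}", "type": kind, "batch": b,
                             "injection_order": i + 1})
                t = i / 15
                vals.append(100.0 * (1.0 + sign * 0.8 * (t - 0.5)))
        meta = make_meta(rows)
        table = make_table({"f": vals}, meta["injection_id"].tolist())
        per_batch = pp.loess_drift_correct(table, meta, LoessConfig(min_qc_per_batch=4))
        global_fit = pp.loess_drift_correct(
            table, meta, LoessConfig(min_qc_per_batch=4, per_batch=False)
        )
        def qc_spread(tbl):
            qc = meta.loc[meta["type"] == "qc_pool", "injection_id"]
            v = tbl.loc["f", qc].to_numpy(float)
            return v.std() / v.mean()
        assert qc_spread(per_batch) < 0.01
        assert qc_spread(global_fit) > qc_spread(per_batch)

    def test_too_few_qcs_skips_batch(self, caplog):
        meta = self._batch_meta(6, {0, 5})
        table = make_table({"f": [10, 11, 12, 13, 14, 15]}, meta["injection_id"].tolist())
        with caplog.at_level("WARNING"):
            corrected = pp.loess_drift_correct(table, meta)
        assert "skipped" in caplog.text
        pd.testing.assert_frame_equal(corrected, table.astype(float))


class TestPQN:
    def _table(self):
        meta = make_meta(
            [{"injection_id": f"QC{i}", "type": "qc_pool"} for i in range(3)]
            + [{"injection_id": "S1", "type": "study"}]
        )
        rng = np.random.default_rng(5)
        base = rng.uniform(10, 100, 40)
        table = make_table(
            {f"f{i}": [base[i]] * 3 + [3.0 * base[i]] for i in range(40)},
            meta["injection_id"].tolist(),
        )
        return table, meta

    def test_scaled_injection_recovers_factor(self):
        table, meta = self._table()
        res = pp.pqn_normalize(table, meta)
        assert res.factors["S1"] == pytest.approx(3.0)
        assert res.factors["QC0"] == pytest.approx(1.0)
        np.testing.assert_allclose(res.normalized["S1"], res.reference, rtol=1e-12)

    def test_median_quotient_after_normalization_is_one(self):
        table, meta = self._table()
        res = pp.pqn_normalize(table, meta)
        for inj in table.columns:
            q = np.median(res.normalized[inj] / res.reference)
            assert q == pytest.approx(1.0, abs=1e-9)

    def test_too_few_shared_features_names_injection(self):
        meta = make_meta(
            [{"injection_id": "QC0", "type": "qc_pool"}, {"injection_id": "S1", "type": "study"}]
        )
        table = make_table({f"f{i}": [10.0, np.nan] for i in range(12)},
                           meta["injection_id"].tolist())
        with pytest.raises(ValueError, match="S1"):
            pp.pqn_normalize(table, meta)


class TestImputation:
    def test_draws_fall_in_low_window(self):
        meta = make_meta([{"injection_id": "S1", "type": "study"}])
        n_missing = 1000
        table = make_table(
            {"obs_min": [10.0], "obs_hi": [500.0],
             **{f"m{i}": [np.nan] for i in range(n_missing)}},
            ["S1"],
        )
        out = pp.impute_missing(table, seed=1)
        imputed = out.loc[[f"m{i}" for i in range(n_missing)], "S1"].to_numpy()
        assert ((imputed > 5.0) & (imputed < 10.0)).all()
        assert out.loc["obs_min", "S1"] == 10.0

    def test_seeded_reproducibility(self):
        meta = make_meta([{"injection_id": "S1", "type": "study"}])
        table = make_table({"a": [4.0], "b": [np.nan], "c": [np.nan]}, ["S1"])
        pd.testing.assert_frame_equal(pp.impute_missing(table, 7), pp.impute_missing(table, 7))
        assert not pp.impute_missing(table, 7).equals(pp.impute_missing(table, 8))

    def test_all_missing_injection_is_an_error(self):
        table = make_table({"a": [np.nan], "b": [np.nan]}, ["S1"])
        with pytest.raises(ValueError, match="S1"):
            pp.impute_missing(table, 0)


class TestReplicateAggregation:
    def test_mean_median_rules(self):
        rows = (
            [{"injection_id": f"A_r{i}", "type": "study", "replicate_group": "A"} for i in (1, 2)]
            + [{"injection_id": f"B_r{i}", "type": "study", "replicate_group": "B"} for i in (1, 2, 3)]
            + [{"injection_id": f"C_r{i}", "type": "study", "replicate_group": "C"} for i in (1, 2, 3, 4)]
            + [{"injection_id": "D_r1", "type": "study", "replicate_group": "D"}]
        )
        meta = make_meta(rows)
        table = make_table(
            {"f": [2, 4] + [1, 2, 9] + [1, 2, 3, 10] + [42]},
            meta["injection_id"].tolist(),
        )
        agg = pp.aggregate_replicates(table, meta)
        assert agg.loc["f", "A"] == 3.0  # mean of 2
        assert agg.loc["f", "B"] == 2.0  # median of 3
        assert agg.loc["f", "C"] == 2.5  # median of 4 = mean of middle two
        assert agg.loc["f", "D"] == 42.0  # identity


class TestPipeline:
    def test_filters_are_idempotent(self, small_cohort):
        table, meta, _ = small_cohort
        for fn in (pp.filter_blank_features, pp.filter_dilution_linearity, pp.filter_presence):
            once, removed1 = fn(table, meta)
            twice, removed2 = fn(once, meta)
            assert removed2 == []
            pd.testing.assert_frame_equal(once, twice)

    def test_output_is_clean_and_deterministic(self, small_cfg, small_cohort):
        table, meta, _ = small_cohort
        m1, log1 = pp.run_preprocessing(table, meta, seed=small_cfg.seed)
        m2, _ = pp.run_preprocessing(table, meta, seed=small_cfg.seed)
        pd.testing.assert_frame_equal(m1, m2)
        assert not m1.isna().any().any()
        assert (m1.to_numpy() >= 0).all()
        stages = [s["stage"] for s in log1.stages]
        assert stages == [
            "input", "blank_filter", "dilution_linearity_filter", "presence_filter",
            "loess_drift_correction", "pqn", "imputation", "replicate_aggregation",
        ]

    def test_qc_cv_not_increased_by_loess(self, small_cohort):
        """On drifting simulator data the median per-feature QC CV strictly
        decreases after correction."""
        table, meta, _ = small_cohort
        t, _ = pp.filter_blank_features(table, meta)
        t, _ = pp.filter_dilution_linearity(t, meta)
        t, _ = pp.filter_presence(t, meta)
        corrected = pp.loess_drift_correct(t, meta, LoessConfig(min_qc_per_batch=4))
        qc_cols = meta.loc[meta["type"] == "qc_pool", "injection_id"]

        def med_cv(tbl):
            qc = tbl[qc_cols]
            return float((qc.std(axis=1) / qc.mean(axis=1)).median())

        assert med_cv(corrected) < med_cv(t)

    def test_mode_merge_concatenates_features(self, small_cohort):
        table, meta, _ = small_cohort
        hilic = table.loc[[f for f in table.index if f.startswith("HILIC")]]
        rplc = table.loc[[f for f in table.index if f.startswith("RPLC")]]
        merged, log = pp.run_preprocessing(
            {"HILIC": (hilic, meta), "RPLC": (rplc, meta)}, seed=1
        )
        assert log.stages[-1]["stage"] == "mode_merge"
        assert any(f.startswith("HILIC") for f in merged.index)
        assert any(f.startswith("RPLC") for f in merged.index)
        assert not merged.index.duplicated().any()


def test_imputation_window_is_configurable():
    table = make_table({"a": [10.0], **{f"m{i}": [np.nan] for i in range(200)}}, ["S1"])
    out = pp._t(pp.LowValueImputer(seed=0, lower_fraction=0.8).transform(pp._t(table)))
    imputed = out.drop(index="a")["S1"].to_numpy()
    assert ((imputed > 8.0) & (imputed < 10.0)).all()
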