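"""Hourly triplets, standardization/imputation, derived indices, windows."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ventwatch.cohort import PatientStay, derive_vent_states
from ventwatch.featurize import (
    WindowConfig,
    WindowFeaturizer,
    add_derived_indices,
    aggregate_hourly,
    enumerate_windows,
    exclude_rare_features,
    fit_standardization,
    impute,
    measured_hour_counts,
    split_patients,
)
from ventwatch.synthetic import SimulationConfig, simulate_cohort

from conftest import brute_force_windows, make_events, random_vent_stay


def _stay(events, los=12.0, sid=1, vent=()):
    return PatientStay(stay_id=sid, los_hours=los, age=60.0, sex="male",
                       weight=80.0, height=175.0, events=events,
                       vent=np.array(vent).reshape(-1, 2))


class TestAggregateHourly:
    def test_hourly_mean_of_two_readings(self):
        hm = aggregate_hourly(
            _stay(make_events([("spo2", 3.2, 80.0), ("spo2", 3.8, 90.0)])), ["spo2"]
        )
        assert hm.value[3, 0] == 85.0
        assert hm.mask[3, 0] == 1
        assert hm.tsl[3, 0] == 0.0

    def test_never_measured_feature_all_masked_out(self):
        hm = aggregate_hourly(_stay(make_events([])), ["pao2"])
        assert (hm.mask == 0).all()
        assert np.isnan(hm.value).all()
        # before any measurement tsl counts hours since admission + 1
        assert hm.tsl[:, 0].tolist() == [h + 1 for h in range(hm.n_hours)]

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(3)
        feats = ["heart_rate", "spo2", "paco2"]
        rows = [
            (rng.choice(feats), float(rng.uniform(0, 23.99)), float(rng.normal()))
            for _ in range(300)
        ]
        stay = _stay(make_events(rows), los=24.0)
        hm = aggregate_hourly(stay, feats)
        for j, fid in enumerate(feats):
            last_measured = None
            for h in range(24):
                vals = [v for f, t, v in rows if f == fid and math.floor(t) == h]
                if vals:
                    assert hm.mask[h, j] == 1
                    assert hm.value[h, j] == pytest.approx(np.mean(vals))
                    assert hm.tsl[h, j] == 0
                    last_measured = h
                else:
                    assert hm.mask[h, j] == 0
                    assert np.isnan(hm.value[h, j])
                    expected = h - last_measured if last_measured is not None else h + 1
                    assert hm.tsl[h, j] == expected

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 11), st.floats(-5, 5)), max_size=30))
    def test_mask_iff_tsl_zero(self, meas):
        rows = [("spo2", h + 0.5, v) for h, v in meas]
        hm = aggregate_hourly(_stay(make_events(rows)), ["spo2"])
        assert ((hm.mask == 1) == (hm.tsl == 0)).all()
        # tsl rises by exactly one per unmeasured hour
        for h in range(1, hm.n_hours):
            if hm.mask[h, 0] == 0:
                assert hm.tsl[h, 0] == hm.tsl[h - 1, 0] + 1


class TestStandardizationImputation:
    def test_two_point_mean(self):
        rows = [("spo2", 0.5, 0.0), ("spo2", 5.5, 2.0)]
        params = fit_standardization([aggregate_hourly(_stay(make_events(rows)), ["spo2"])])
        assert params.mean[0] == pytest.approx(1.0)
        assert not params.constant[0]

    def test_transform_centers_and_scales_training_values(self):
        rng = np.random.default_rng(1)
        stays = [
            _stay(make_events([("spo2", h + 0.1, float(rng.normal(95, 3)))
                               for h in range(12)]), sid=i)
            for i in range(5)
        ]
        hms = [aggregate_hourly(s, ["spo2"]) for s in stays]
        params = fit_standardization(hms)
        zs = []
        for hm in hms:
            imp = impute(hm, params)
            zs.extend(imp.value[hm.mask[:, 0] == 1, 0].tolist())
        assert np.mean(zs) == pytest.approx(0.0, abs=1e-9)
        assert np.var(zs, ddof=1) == pytest.approx(1.0, rel=1e-9)

    def test_constant_feature_standardizes_to_zero(self):
        rows = [("spo2", h + 0.1, 95.0) for h in range(6)]
        hm = aggregate_hourly(_stay(make_events(rows)), ["spo2"])
        params = fit_standardization([hm])
        assert params.constant[0]
        assert (impute(hm, params).value == 0).all()

    def test_carry_forward_rule(self):
        rows = [("spo2", 0.5, 92.0)]
        hm = aggregate_hourly(_stay(make_events(rows), los=3.0), ["spo2"])
        params = fit_standardization(
            [aggregate_hourly(_stay(make_events([("spo2", 0.5, 90.0),
                                                 ("spo2", 1.5, 94.0)]),
                              los=3.0), ["spo2"])]
        )
        out = impute(hm, params)
        z = (92.0 - params.mean[0]) / params.sd[0]
        assert out.value[:, 0] == pytest.approx([z, z, z])
        assert out.tsl[:, 0].tolist() == [0.0, 1.0, 2.0]

    def test_unobserved_feature_imputes_prior_mean_zero(self):
        hm = aggregate_hourly(_stay(make_events([]), los=5.0), ["spo2"])
        params = fit_standardization(
            [aggregate_hourly(_stay(make_events([("spo2", 0.5, 90.0),
                                                 ("spo2", 1.5, 94.0)])), ["spo2"])]
        )
        out = impute(hm, params)
        assert (out.value == 0).all()
        assert (out.mask == 0).all()

    def test_imputation_idempotent(self):
        rng = np.random.default_rng(5)
        rows = [("spo2", float(rng.uniform(0, 12)), float(rng.normal(95, 2)))
                for _ in range(8)]
        hm = aggregate_hourly(_stay(make_events(rows)), ["spo2"])
        params = fit_standardization([hm])
        once = impute(hm, params)
        twice = impute(once, params)
        np.testing.assert_array_equal(once.value, twice.value)
        np.testing.assert_array_equal(once.tsl, twice.tsl)


class TestDerivedIndices:
    def test_rox_arithmetic(self):
        rows = [("spo2", 1.5, 92.0), ("fio2", 1.5, 0.4), ("resp_rate", 1.5, 23.0),
                ("pao2", 1.5, 80.0)]
        hm = add_derived_indices(
            aggregate_hourly(_stay(make_events(rows)), ["spo2", "fio2", "resp_rate", "pao2"])
        )
        j = hm.feature_ids.index("rox_index")
        assert hm.value[1, j] == pytest.approx((92.0 / 0.4) / 23.0)  # = 10.0
        assert hm.mask[1, j] == 1
        jsf = hm.feature_ids.index("spo2_fio2_ratio")
        assert hm.value[1, jsf] == pytest.approx(230.0)
        jpf = hm.feature_ids.index("pao2_fio2_ratio")
        assert hm.value[1, jpf] == pytest.approx(200.0)

    def test_missing_constituent_propagates_missingness(self):
        rows = [("spo2", 1.5, 92.0), ("resp_rate", 1.5, 23.0)]
        hm = add_derived_indices(
            aggregate_hourly(_stay(make_events(rows)), ["spo2", "fio2", "resp_rate", "pao2"])
        )
        j = hm.feature_ids.index("rox_index")
        assert hm.mask[1, j] == 0

    def test_zero_denominator_guarded(self):
        rows = [("spo2", 1.5, 92.0), ("fio2", 1.5, 0.4), ("resp_rate", 1.5, 0.0)]
        hm = add_derived_indices(
            aggregate_hourly(_stay(make_events(rows)), ["spo2", "fio2", "resp_rate", "pao2"])
        )
        j = hm.feature_ids.index("rox_index")
        assert hm.mask[1, j] == 0
        assert np.isnan(hm.value[1, j])


class TestEnumerateWindows:
    def _windows(self, stay, cfg):
        states = derive_vent_states(stay)
        ts, labels = enumerate_windows(states, cfg)
        return list(zip(ts.tolist(), labels.tolist()))

    def test_matches_oracle_on_100_random_stays_all_gaps(self):
        rng = np.random.default_rng(11)
        stays = [random_vent_stay(rng, i) for i in range(100)]
        for gap in (6, 12, 18, 24):
            cfg = WindowConfig(gap=gap)
            for stay in stays:
                assert self._windows(stay, cfg) == brute_force_windows(stay, cfg)

    def test_stay_entirely_on_imv_yields_nothing(self):
        stay = _stay(make_events([]), los=40.0, vent=[(0, 40)])
        assert self._windows(stay, WindowConfig()) == []

    def test_negative_count_for_vent_free_stay(self):
        stay = _stay(make_events([]), los=40.0)
        wins = self._windows(stay, WindowConfig(gap=6))
        assert len(wins) == 25  # 40 - 6 - 6 - 4 + 1
        assert all(lab == 0 for _, lab in wins)

    def test_short_stay_yields_no_samples(self):
        stay = _stay(make_events([]), los=15.0)
        assert self._windows(stay, WindowConfig()) == []

    def test_larger_gap_never_increases_sample_count(self):
        rng = np.random.default_rng(12)
        for i in range(30):
            stay = random_vent_stay(rng, i)
            counts = [len(self._windows(stay, WindowConfig(gap=g)))
                      for g in (6, 12, 18, 24)]
            assert counts == sorted(counts, reverse=True)

    def test_positive_labels_around_onset(self):
        # onset at hour 14, gap 6: labels positive iff onset in [t+6, t+10)
        stay = _stay(make_events([]), los=30.0, vent=[(14, 25)])
        wins = dict(self._windows(stay, WindowConfig(gap=6)))
        for t, lab in wins.items():
            assert lab == (t + 6 <= 14 < t + 10)


class TestRareFeaturesAndSplits:
    def test_min_count_boundary(self):
        counts = pd.Series({"a": 999, "b": 1000, "c": 5000})
        assert exclude_rare_features(counts, 1000) == ["b", "c"]

    def test_min_count_zero_is_identity(self):
        counts = pd.Series({"a": 0, "b": 3})
        assert exclude_rare_features(counts, 0) == ["a", "b"]

    def test_planted_sparse_feature_dropped(self, small_cohort):
        stays, _ = small_cohort
        from ventwatch.featurize import aggregate_hourly as agg

        counts = measured_hour_counts(
            agg(s, ["heart_rate", "tidal_volume_set"]) for s in stays
        )
        kept = exclude_rare_features(counts, 10)
        assert kept == ["heart_rate"]  # tidal_volume_set never simulated

    def test_split_sizes_disjoint_union(self, small_cohort):
        stays, _ = small_cohort
        a, b = split_patients(stays[:10], (0.8, 0.2), seed=0)
        assert len(a) == 8 and len(b) == 2
        assert set(a).isdisjoint(b)
        assert set(a) | set(b) == {s.stay_id for s in stays[:10]}

    def test_split_deterministic(self, small_cohort):
        stays, _ = small_cohort
        assert split_patients(stays, (0.7, 0.3), 5) == split_patients(stays, (0.7, 0.3), 5)

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            split_patients([], (0.5, 0.5), 0)

    def test_windows_of_one_stay_land_on_one_side(self, small_dataset, small_cohort):
        ftz, ds = small_dataset
        stays, _ = small_cohort
        a, b = split_patients(stays, (0.5, 0.5), seed=3)
        sa, sb = set(a), set(b)
        for sid in np.unique(ds.stay_ids):
            assert (sid in sa) != (sid in sb)


class TestFeaturizer:
    def test_manifest_shape_and_channels(self, small_dataset):
        ftz, ds = small_dataset
        W = ftz._window_cfg().feature_window
        assert len(ds.columns) == 3 * len(ftz.feature_list_) * W + 4
        assert ds.X.shape == (len(ds.y), len(ds.columns))
        # mask channels are 0/1
        mask_cols = [i for i, c in enumerate(ds.columns) if "|mask|" in c]
        assert np.isin(ds.X[:, mask_cols], [0.0, 1.0]).all()

    def test_no_leakage_params_differ_across_shifted_domains(self):
        from ventwatch.synthetic import covid_like_shift, shift_domain

        cfg = SimulationConfig(n_patients=60, seed=9)
        src = simulate_cohort(cfg).stays
        tgt = simulate_cohort(shift_domain(cfg, covid_like_shift())).stays
        f1 = WindowFeaturizer(min_count=5).fit(src)
        f2 = WindowFeaturizer(min_count=5).fit(tgt)
        i = f1.feature_list_.index("heart_rate")
        j = f2.feature_list_.index("heart_rate")
        assert abs(f1.standardization_.mean[i] - f2.standardization_.mean[j]) > 2.0

    def test_dataset_hdf5_round_trip(self, small_dataset, tmp_path):
        _, ds = small_dataset
        ds.save(tmp_path / "ds.h5")
        back = type(ds).load(tmp_path / "ds.h5")
        np.testing.assert_array_equal(ds.X, back.X)
        np.testing.assert_array_equal(ds.y, back.y)
        assert ds.columns == back.columns
        assert back.window == ds.window

    def test_featurizer_json_round_trip(self, small_dataset, small_cohort, tmp_path):
        ftz, ds = small_dataset
        stays, _ = small_cohort
        ftz.to_json(tmp_path / "f.json")
        back = WindowFeaturizer.from_json(tmp_path / "f.json")
        ds2 = back.make_samples(stays)
        np.testing.assert_array_equal(ds.X, ds2.X)
        assert ds.columns == ds2.columns

    def test_operational_toggle_shrinks_manifest(self, small_cohort):
        stays, _ = small_cohort
        f_on = WindowFeaturizer(min_count=50, include_operational=True).fit(stays)
        f_off = WindowFeaturizer(min_count=50, include_operational=False).fit(stays)
        ops = {"fio2_set", "peep_set"}
        assert ops & set(f_on.feature_list_)
        assert not ops & set(f_off.feature_list_)
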