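"""Plate-reader CSV parsing, path-length correction, replicate aggregation."""

import numpy as np
import pandas as pd
import pytest

from growthpeaks.errors import DegeneratePeakError, FormatError, InvalidInputError
from growthpeaks.model import GrowthParams
from growthpeaks.peaks import peak_shift
from growthpeaks.plate_io import (
    ConditionCurve,
    aggregate,
    analyze_condition,
    correct_od,
    load_plate_csv,
    load_wide_csv,
    subtract_blank,
)
from growthpeaks.synth import MeasurementModel, generate_dataset

INTERVAL = 1.0 / 6.0  # 10-min readings


def make_long_frame(n_wells=3, n_points=97, conditions=("control",)):
    """Programmatic long-form fixture: one OD and FL block per well."""
    rows = []
    times = np.arange(n_points) * INTERVAL
    for condition in conditions:
        for w in range(n_wells):
            well = f"{condition}-{w + 1}"
            od = 0.05 + 0.5 / (1.0 + np.exp(-(times - 5.0)))
            fl = 10.0 + times**2
            for channel, values in (("OD600", od), ("FL", fl)):
                for t, v in zip(times, values):
                    rows.append((well, condition, channel, t, v))
    return pd.DataFrame(rows, columns=["well", "condition", "channel", "time_hr", "value"])


@pytest.fixture()
def long_csv(tmp_path):
    path = tmp_path / "plate.csv"
    make_long_frame().to_csv(path, index=False)
    return path


class TestLoadPlateCsv:
    def test_fixture_loads_with_ten_minute_interval(self, long_csv):
        dataset = load_plate_csv(long_csv)
        assert dataset.interval == pytest.approx(INTERVAL)
        assert len(dataset.wells) == 3
        assert dataset.conditions == ("control",)

    def test_missing_time_point_is_format_error(self, tmp_path):
        frame = make_long_frame(n_points=20)
        frame = frame.drop(frame[(frame.well == "control-2") & (frame.time_hr > 1.0)].index[:1])
        path = tmp_path / "ragged.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(FormatError):
            load_plate_csv(path)

    def test_duplicate_reading_is_format_error(self, tmp_path):
        frame = make_long_frame(n_points=10)
        frame = pd.concat([frame, frame.iloc[[0]]])
        path = tmp_path / "dup.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(FormatError, match="duplicate"):
            load_plate_csv(path)

    def test_missing_columns_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(FormatError, match="missing columns"):
            load_plate_csv(path)

    def test_layout_map_reassigns_and_drops_unmapped(self, long_csv):
        layout = {"control-1": "treated", "control-2": "treated"}
        dataset = load_plate_csv(long_csv, layout_map=layout)
        assert set(dataset.wells) == {"control-1", "control-2"}
        assert dataset.conditions == ("treated",)
        assert dataset.data.attrs["unmapped_wells"] == ["control-3"]

    def test_synth_round_trip_is_lossless(self, tmp_path):
        dataset, _ = generate_dataset(meas=MeasurementModel(seed=7), n_replicates=2)
        path = tmp_path / "synth.csv"
        dataset.data.to_csv(path, index=False)
        loaded = load_plate_csv(path)
        pd.testing.assert_frame_equal(
            loaded.data.reset_index(drop=True), dataset.data.reset_index(drop=True)
        )

    def test_wide_reader(self, tmp_path):
        times = np.arange(20) * INTERVAL
        frame = pd.DataFrame(
            {"time_hr": times, "A1": times + 1.0, "A2": times + 2.0, "B1": times}
        )
        path = tmp_path / "wide.csv"
        frame.to_csv(path, index=False)
        dataset = load_wide_csv(path, {"A1": "control", "A2": "control"}, channel="OD600")
        assert set(dataset.wells) == {"A1", "A2"}
        curve = aggregate(dataset, "control", "OD600")
        assert np.allclose(curve.mean, times + 1.5)


class TestCorrectOd:
    def test_pathlength_factor_applied_to_od_only(self, long_csv):
        dataset = load_plate_csv(long_csv)
        corrected = correct_od(dataset, factor=2.39)
        raw_od = dataset.data[dataset.data.channel == "OD600"]["value"].to_numpy()
        cor_od = corrected.data[corrected.data.channel == "OD600"]["value"].to_numpy()
        assert np.allclose(cor_od, raw_od * 2.39)
        raw_fl = dataset.data[dataset.data.channel == "FL"]["value"].to_numpy()
        cor_fl = corrected.data[corrected.data.channel == "FL"]["value"].to_numpy()
        assert np.array_equal(cor_fl, raw_fl)
        assert corrected.pathlength_factor == pytest.approx(2.39)

    def test_single_value_example(self):
        assert 0.1 * 2.39 == pytest.approx(0.239)

    def test_identity_and_composition(self, long_csv):
        dataset = load_plate_csv(long_csv)
        assert np.array_equal(
            correct_od(dataset, 1.0).data["value"], dataset.data["value"]
        )
        twice = correct_od(correct_od(dataset, 2.0), 1.5)
        once = correct_od(dataset, 3.0)
        assert np.allclose(twice.data["value"], once.data["value"])
        assert twice.pathlength_factor == pytest.approx(once.pathlength_factor)

    def test_nonpositive_factor_rejected(self, long_csv):
        with pytest.raises(InvalidInputError):
            correct_od(load_plate_csv(long_csv), factor=0.0)

    def test_negative_od_flagged_not_clipped(self, tmp_path):
        frame = make_long_frame(n_wells=1, n_points=10)
        frame.loc[frame.channel == "OD600", "value"] -= 1.0
        path = tmp_path / "neg.csv"
        frame.to_csv(path, index=False)
        corrected = correct_od(load_plate_csv(path))
        assert corrected.negative_od_wells == ("control-1",)
        assert (corrected.data[corrected.data.channel == "OD600"]["value"] < 0).any()


class TestAggregate:
    def make_dataset(self, values_by_well):
        rows = []
        for well, values in values_by_well.items():
            for t, v in zip(np.arange(len(values)) * INTERVAL, values):
                rows.append((well, "c", "OD600", t, v))
        frame = pd.DataFrame(rows, columns=["well", "condition", "channel", "time_hr", "value"])
        from growthpeaks.plate_io import PlateDataset

        return PlateDataset(data=frame, interval=INTERVAL)

    def test_mean_and_sem_hand_computed(self):
        dataset = self.make_dataset({"w1": [1.0, 1.0], "w2": [2.0, 2.0], "w3": [3.0, 3.0]})
        curve = aggregate(dataset, "c", "OD600")
        assert np.allclose(curve.mean, 2.0)
        assert np.allclose(curve.sem, 1.0 / np.sqrt(3.0))  # SD of (1,2,3) is 1
        assert curve.n_replicates == 3

    def test_identical_replicates_have_zero_sem(self):
        dataset = self.make_dataset({"w1": [0.1, 0.2], "w2": [0.1, 0.2], "w3": [0.1, 0.2]})
        curve = aggregate(dataset, "c", "OD600")
        assert np.allclose(curve.sem, 0.0)

    def test_single_well_flagged(self):
        dataset = self.make_dataset({"w1": [0.1, 0.2, 0.3]})
        curve = aggregate(dataset, "c", "OD600")
        assert curve.single_replicate
        assert np.allclose(curve.sem, 0.0)

    def test_missing_condition_rejected(self):
        dataset = self.make_dataset({"w1": [0.1, 0.2]})
        with pytest.raises(InvalidInputError):
            aggregate(dataset, "other", "OD600")

    def test_aggregation_commutes_with_correction(self, long_csv):
        dataset = load_plate_csv(long_csv)
        first = aggregate(correct_od(dataset, 2.39), "control", "OD600")
        second = aggregate(dataset, "control", "OD600")
        assert np.allclose(first.mean, second.mean * 2.39)
        assert np.allclose(first.sem, second.sem * 2.39)

    def test_sem_shrinks_with_replicate_count(self):
        rng = np.random.default_rng(3)
        values = {f"w{i}": 1.0 + rng.normal(0, 0.1, 30) for i in range(12)}
        small = self.make_dataset({k: values[k] for k in list(values)[:3]})
        large = self.make_dataset(values)
        sem_small = aggregate(small, "c", "OD600").sem.mean()
        sem_large = aggregate(large, "c", "OD600").sem.mean()
        assert sem_large < sem_small
        # 1/sqrt(n) scaling within sampling slack
        assert sem_large == pytest.approx(sem_small / 2.0, rel=0.5)


class TestSubtractBlank:
    def test_blank_mean_removed(self, tmp_path):
        frame = make_long_frame(n_wells=2, n_points=12, conditions=("control", "blank"))
        path = tmp_path / "b.csv"
        frame.to_csv(path, index=False)
        dataset = load_plate_csv(path)
        cleaned = subtract_blank(dataset, "blank")
        assert "blank" not in cleaned.conditions
        od = aggregate(cleaned, "control", "OD600")
        assert np.allclose(od.mean, 0.0, atol=1e-12)  # identical wells cancel


class TestAnalyzeCondition:
    def test_recovers_known_lag_shift(self):
        meas = MeasurementModel(noise_cv=0.0, seed=0)
        control, truth_c = generate_dataset(
            GrowthParams(alpha=1.0), meas=meas, condition="control"
        )
        treated, truth_t = generate_dataset(
            GrowthParams(alpha=0.1), meas=meas, condition="treated"
        )
        results = []
        for dataset in (control, treated):
            dataset = correct_od(dataset)
            curve = aggregate(dataset, dataset.conditions[0], "OD600")
            results.append(analyze_condition(curve))
        measured = peak_shift(results[0].peak, results[1].peak).shift
        assert measured == pytest.approx(truth_t.tau_p - truth_c.tau_p, abs=2 * INTERVAL)

    def test_fluorescence_peak_lags_od_peak(self):
        dataset, _ = generate_dataset(meas=MeasurementModel(noise_cv=0.0, seed=0))
        dataset = correct_od(dataset)
        od = analyze_condition(aggregate(dataset, "condition", "OD600"))
        fl = analyze_condition(aggregate(dataset, "condition", "FL"))
        assert fl.peak.tau > od.peak.tau  # maturation delays the FL peak

    def test_flat_blank_is_degenerate(self):
        times = np.arange(30) * INTERVAL
        curve = ConditionCurve(
            condition="blank",
            channel="OD600",
            times=times,
            mean=np.full(30, 0.05),
            sem=np.zeros(30),
            n_replicates=3,
        )
        with pytest.raises(DegeneratePeakError):
            analyze_condition(curve, od_ceiling=None)

    def test_gompertz_fit_attached_for_od_channel(self):
        dataset, _ = generate_dataset(meas=MeasurementModel(noise_cv=0.0, seed=0))
        dataset = correct_od(dataset)
        analysis = analyze_condition(aggregate(dataset, "condition", "OD600"))
        assert analysis.gompertz is not None and analysis.gompertz.converged
        assert analysis.gompertz.lam > 0
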