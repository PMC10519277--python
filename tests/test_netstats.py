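"""Network statistics: per-vessel aggregates, nine-bin area histograms,
run comparisons, hot/cold spots, and time-signal metrics."""
import warnings

import numpy as np
import pandas as pd
import pytest

from capflow.netstats import (
    compare_runs,
    detect_spots,
    relative_histogram,
    rms_vs_diameter_fit,
    signal_metrics,
    time_signal_metrics,
    vessel_aggregate,
)
from capflow.wss.traction import TAWSSField, WSSGField


@pytest.fixture(scope="module")
def tube(straight_tube_surface):
    return straight_tube_surface


def _zero_g(n):
    return WSSGField(np.zeros(n), np.zeros(n))


class TestVesselAggregate:
    def test_uniform_field(self, tube):
        n = len(tube.vertices)
        df = vessel_aggregate(TAWSSField(np.full(n, 7.0)), _zero_g(n), tube)
        row = df.loc[0]
        assert row.tawss_mean == row.tawss_max == row.tawss_min == 7.0
        assert row.tawss_sigma == 0.0
        assert row.diameter == pytest.approx(8.0, rel=0.01)
        assert row.length == pytest.approx(40.0, rel=0.01)

    def test_two_level_field(self, tube):
        """Half the area at 10, half at 30: mean 20, sigma 10."""
        n = len(tube.vertices)
        field = np.where(tube.vertices[:, 2] < 20.0, 10.0, 30.0)
        df = vessel_aggregate(TAWSSField(field), _zero_g(n), tube)
        assert df.loc[0, "tawss_mean"] == pytest.approx(20.0, rel=0.01)
        assert df.loc[0, "tawss_sigma"] == pytest.approx(10.0, rel=0.01)

    def test_matches_brute_force(self, tube, rng):
        n = len(tube.vertices)
        field = rng.uniform(1.0, 50.0, n)
        gax = rng.standard_normal(n)
        df = vessel_aggregate(TAWSSField(field), WSSGField(gax, gax * 0.5), tube)
        w = tube.vertex_areas()
        mean = np.sum(w * field) / w.sum()
        assert df.loc[0, "tawss_mean"] == pytest.approx(mean, rel=1e-12)
        assert df.loc[0, "tawss_max"] == field.max()
        assert df.loc[0, "tawss_min"] == field.min()
        sigma = np.sqrt(np.sum(w * (field - mean) ** 2) / w.sum())
        assert df.loc[0, "tawss_sigma"] == pytest.approx(sigma, rel=1e-12)
        assert df.loc[0, "tawssg_axial"] == pytest.approx(
            np.sum(w * np.abs(gax)) / w.sum(), rel=1e-12
        )


class TestHistogram:
    def test_bimodal_extremes(self, tube):
        field = np.where(tube.vertices[:, 2] < 20.0, 1.0, 9.0)
        avg, _ = relative_histogram(field, tube.vertex_areas(), tube.vessel_label)
        assert avg[0] == pytest.approx(0.5, abs=0.02)
        assert avg[8] == pytest.approx(0.5, abs=0.02)
        assert avg[1:8].sum() < 1e-12

    def test_uniform_ramp_flat_histogram(self, tube):
        avg, per = relative_histogram(
            tube.vertices[:, 2], tube.vertex_areas(), tube.vessel_label
        )
        assert np.abs(avg - 1.0 / 9.0).max() < 0.02
        # fractions sum to one per vessel
        for frac in per.values():
            assert frac.sum() == pytest.approx(1.0, rel=1e-12)

    def test_single_vessel_average_is_itself(self, tube, rng):
        f = rng.uniform(0, 5, len(tube.vertices))
        avg, per = relative_histogram(f, tube.vertex_areas(), tube.vessel_label)
        assert np.allclose(avg, per[0])

    def test_degenerate_vessel_excluded(self, tube):
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            with pytest.raises(ValueError):
                relative_histogram(
                    np.full(len(tube.vertices), 3.0),
                    tube.vertex_areas(), tube.vessel_label,
                )
        assert any("uniform TAWSS" in str(x.message) for x in w)


class TestCompareRuns:
    def _stats(self, mean, grad):
        return pd.DataFrame(
            {
                "tawss_mean": [mean], "tawss_max": [mean * 2],
                "tawss_min": [mean / 2], "tawss_sigma": [mean / 4],
                "tawssg_axial": [grad], "tawssg_circ": [grad * 3],
            },
            index=pd.Index([0], name="vessel"),
        )

    def test_identical_runs_unity(self):
        a = self._stats(10.0, 2.0)
        r = compare_runs(a, a.copy(), "rbc_vs_plasma")
        assert np.allclose(r.to_numpy(), 1.0)

    def test_gamma_scaling_factor(self):
        r = compare_runs(self._stats(20.0, 4.0), self._stats(10.0, 2.0),
                         "gamma_scaling")
        assert np.allclose(r[["ratio_mean", "ratio_max", "ratio_min",
                              "ratio_sigma"]].to_numpy(), 2.0)

    def test_floor_masks_small_denominators(self):
        b = self._stats(1e-4, 2.0)  # below the 1e-3 dyne/cm^2 floor
        r = compare_runs(self._stats(1.0, 2.0), b, "rbc_vs_plasma")
        assert np.isnan(r["ratio_mean"]).all()

    def test_label_mismatch_rejected(self):
        a = self._stats(1.0, 1.0)
        b = self._stats(1.0, 1.0)
        b.index = pd.Index([5], name="vessel")
        with pytest.raises(ValueError, match="mismatch"):
            compare_runs(a, b, "rbc_vs_plasma")
        with pytest.raises(ValueError):
            compare_runs(a, a, "other_mode")


class TestSpots:
    def test_uniform_field_no_spots(self, tube):
        n = len(tube.vertices)
        g = _zero_g(n)
        s = detect_spots(TAWSSField(np.full(n, 5.0)), g, tube)
        assert s.table == []
        assert (s.spot_class == 0).all()

    def test_gaussian_bump_single_hot_spot(self, tube, tube_frames):
        """+30 dyne/cm^2 bump of ~2 um radius -> exactly one hot spot
        containing the peak vertex."""
        from capflow.wss import wss_gradients

        v = tube.vertices
        th = np.arctan2(v[:, 1], v[:, 0])
        d2 = (v[:, 2] - 20.0) ** 2 + (4.0 * th) ** 2
        field = 20.0 + 30.0 * np.exp(-d2 / (2 * 1.0**2))
        g = wss_gradients(TAWSSField(field), tube_frames, tube)
        s = detect_spots(TAWSSField(field), g, tube, threshold=10.0)
        hot = [t for t in s.table if t["kind"] == "hot"]
        assert len(hot) == 1 and len(s.table) == 1
        assert hot[0]["peak_vertex"] == int(np.argmax(field))

    def test_negated_bump_single_cold_spot(self, tube, tube_frames):
        from capflow.wss import wss_gradients

        v = tube.vertices
        th = np.arctan2(v[:, 1], v[:, 0])
        d2 = (v[:, 2] - 20.0) ** 2 + (4.0 * th) ** 2
        field = 50.0 - 30.0 * np.exp(-d2 / (2 * 1.0**2))
        g = wss_gradients(TAWSSField(field), tube_frames, tube)
        s = detect_spots(TAWSSField(field), g, tube, threshold=10.0)
        cold = [t for t in s.table if t["kind"] == "cold"]
        assert len(cold) == 1 and len(s.table) == 1
        assert cold[0]["peak_vertex"] == int(np.argmin(field))

    def test_threshold_validation(self, tube):
        n = len(tube.vertices)
        with pytest.raises(ValueError):
            detect_spots(TAWSSField(np.ones(n)), _zero_g(n), tube, threshold=0.0)


class TestTimeSignals:
    def test_sinusoid_closed_form(self):
        """s = A sin(2 pi t / T): timescale T, RMS A / sqrt(2)."""
        T, A, dt = 0.02, 4.0, 1e-3
        t = np.arange(80) * dt  # 4 full periods -> exact FFT bin
        m = signal_metrics(A * np.sin(2 * np.pi * t / T), dt)
        assert m.timescale == pytest.approx(T, rel=1e-12)
        assert m.rms == pytest.approx(A / np.sqrt(2), rel=1e-6)
        assert m.defined

    def test_constant_signal_undefined_timescale(self):
        m = signal_metrics(np.full(32, 5.0), 1e-3)
        assert m.rms == 0.0
        assert not m.defined and np.isnan(m.timescale)

    def test_two_tone_dominant_period(self):
        dt = 6.5e-4
        t = np.arange(160) * dt
        s = 3.0 * np.sin(2 * np.pi * t / 0.013) + 1.0 * np.sin(2 * np.pi * t / 0.052)
        m = signal_metrics(s, dt)
        assert m.timescale == pytest.approx(0.013, rel=1e-9)

    def test_requires_enough_samples_and_cadence(self):
        with pytest.raises(ValueError):
            signal_metrics(np.ones(8), 1e-3)
        with pytest.raises(ValueError):
            signal_metrics(np.ones(32), -1.0)

    def test_tidy_table(self):
        t = np.arange(64) * 1e-3
        sig = {1: {"mean": np.sin(2 * np.pi * t / 0.016)},
               2: {"mean": np.cos(2 * np.pi * t / 0.032)}}
        df = time_signal_metrics(sig, 1e-3)
        assert set(df["vessel"]) == {1, 2}
        assert df["timescale"].iloc[0] == pytest.approx(0.016, rel=1e-9)


class TestPowerLaw:
    @pytest.mark.parametrize("noise", [0.0, 0.02, 0.1])
    def test_recovers_planted_exponent(self, noise, rng):
        D = np.linspace(4.0, 30.0, 15)
        rms = 2.0 * D**-1.5 * np.exp(noise * rng.standard_normal(len(D)))
        expo, pref, r2 = rms_vs_diameter_fit(rms, D)
        tol = 0.01 if noise == 0 else 0.15
        assert expo == pytest.approx(-1.5, abs=tol)
        if noise == 0:
            assert pref == pytest.approx(2.0, rel=1e-6)
            assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self):
        D = np.array([5.0, 10.0, 20.0, 40.0])
        rms = 3.0 * D**-0.7
        e1, p1, _ = rms_vs_diameter_fit(rms, D)
        e2, p2, _ = rms_vs_diameter_fit(10.0 * rms, D)
        assert e1 == pytest.approx(e2)
        assert p2 == pytest.approx(10.0 * p1)

    def test_single_diameter_rejected(self):
        with pytest.raises(ValueError):
            rms_vs_diameter_fit([1.0, 2.0, 3.0], [8.0, 8.0, 8.0])

    def test_nonpositive_excluded_with_warning(self):
        D = np.linspace(4, 30, 10)
        rms = 2.0 * D**-1.0
        rms[3] = -1.0
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            expo, _, _ = rms_vs_diameter_fit(rms, D)
        assert any("excluded" in str(x.message) for x in w)
        assert expo == pytest.approx(-1.0, abs=0.05)
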