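import json

import numpy as np
import pytest

from accelalign import drift_model as dm
from accelalign import lag_estimation as le
from accelalign import preprocess as pp
from accelalign import synthetic_data as sd


class TestSpecs:
    def test_clock_sanity_bound(self):
        with pytest.raises(ValueError):
            sd.ClockSpec(skew_ppm=2000.0)

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            sd.ActivityScript([sd.Segment(0, 100, "walk"),
                               sd.Segment(50, 100, "walk")])

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            sd.Segment(0, 100, "swimming")

    def test_ground_truth_accumulated_drift(self):
        # a 20 ppm clock accumulates 12.096 s over 7 days; two devices at
        # +/-20 ppm accumulate 24.192 s relative to each other
        _, _, truth = sd.generate_pair(sd.ActivityScript([]),
                                       sd.ClockSpec(skew_ppm=20.0), days=0.001)
        assert abs(truth.accumulated_day7_s) == pytest.approx(12.096)
        rel = dm.relative_skew_ppm(-20.0, 20.0)
        _, _, truth2 = sd.generate_pair(sd.ActivityScript([]),
                                        sd.ClockSpec(skew_ppm=rel), days=0.001)
        assert abs(truth2.accumulated_day7_s) == pytest.approx(24.192)


class TestGeneratePair:
    def test_determinism(self):
        script = sd.ActivityScript([sd.Segment(30, 60, "walk", 0.4)])
        a = sd.generate_pair(script, sd.ClockSpec(20, 0.5), days=0.002, seed=9)
        b = sd.generate_pair(script, sd.ClockSpec(20, 0.5), days=0.002, seed=9)
        np.testing.assert_array_equal(a[0].samples, b[0].samples)
        np.testing.assert_array_equal(a[1].samples, b[1].samples)

    def test_sign_convention_positive_offset_gives_negative_lag(self):
        # the secondary clock reads ahead (offset_s > 0): its samples are
        # taken later in true time, so shared events sit EARLIER in its
        # stream -> negative lag, beta0 = -offset_s * fs
        script = sd.ActivityScript([sd.Segment(100, 300, "walk", 0.4)])
        ref, sec, truth = sd.generate_pair(script, sd.ClockSpec(0.0, 1.0),
                                           days=600 / 86400, seed=2)
        assert truth.beta0_samples == pytest.approx(-30.0)
        rp = pp.preprocess_stage1(ref)
        sp = pp.preprocess_stage1(sec)
        lag, corr = le.estimate_block_lag(rp.values, sp.values, max_lag=100)
        assert lag == pytest.approx(-30, abs=1)
        assert corr > 0.5

    def test_identical_clocks_give_zero_lag(self):
        script = sd.ActivityScript([sd.Segment(100, 300, "walk", 0.4)])
        ref, sec, _ = sd.generate_pair(script, sd.ClockSpec(0.0, 0.0),
                                       days=600 / 86400, seed=2)
        lag, _ = le.estimate_block_lag(pp.preprocess_stage1(ref).values,
                                       pp.preprocess_stage1(sec).values,
                                       max_lag=100)
        assert lag == 0

    def test_sedentary_hours_fail_activity_gate(self):
        ref, _, _ = sd.generate_pair(sd.ActivityScript([]), sd.ClockSpec(),
                                     days=0.01, seed=0)
        assert not le.block_is_active(pp.enmo(ref), 0.01)

    def test_unshared_block_produces_gross_outlier(self):
        # six active hours, one of them unshared: its lag observation
        # must sit far off the true line and be excluded by the fit
        segs = [sd.Segment(h * 3600 + 900, 600, "walk", 0.4) for h in range(5)]
        segs.append(sd.Segment(5 * 3600 + 900, 600, "unshared", 0.4))
        ref, sec, truth = sd.generate_pair(sd.ActivityScript(segs),
                                           sd.ClockSpec(100.0, 0.5),
                                           days=6 / 24, seed=5)
        obs = le.collect_lag_series(pp.preprocess_stage1(ref),
                                    pp.preprocess_stage1(sec),
                                    pp.enmo(ref), pp.enmo(sec))
        assert len(obs) == 6
        fit = dm.fit_drift(obs)
        assert 5 in [e.block_index for e in fit.excluded]
        resid = [abs(o.lag_samples - (truth.beta0_samples
                                      + truth.drift_samples_per_s * o.time_s))
                 for o in obs]
        assert resid[5] > 10 * max(resid[:5])

    def test_halt_shifts_post_halt_lag(self):
        # a 2 s sampling halt mid-recording shifts later lags by -60
        # samples on top of the clock line
        segs = [sd.Segment(h * 3600 + 900, 600, "walk", 0.4) for h in range(4)]
        ref, sec, _ = sd.generate_pair(sd.ActivityScript(segs), sd.ClockSpec(),
                                       days=4 / 24, seed=6, halt=(2 * 3600.0, 2.0))
        obs = le.collect_lag_series(pp.preprocess_stage1(ref),
                                    pp.preprocess_stage1(sec),
                                    pp.enmo(ref), pp.enmo(sec))
        lags = {o.block_index: o.lag_samples for o in obs}
        assert lags[0] == lags[1] == 0
        assert lags[2] == lags[3] == -60


class TestFixtureSuite:
    def test_smoke_fixture_deterministic_and_roundtrips(self, tmp_path):
        m1 = sd.write_fixture_suite(tmp_path / "a", seed=7, which=("smoke",))
        m2 = sd.write_fixture_suite(tmp_path / "b", seed=7, which=("smoke",))
        for name in ("smoke_ref.csv", "smoke_sec.csv", "fixtures.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()
        manifest = json.loads((tmp_path / "a" / "fixtures.json").read_text())
        truth = manifest["smoke"]["truth"]
        # the manifest's (beta0, beta1) line reproduces itself through
        # the two-mark arithmetic
        b0 = truth["initial_offset_s"] * truth["working_fs"]
        b1 = truth["drift_samples_per_s"]
        t1, t2 = 0.0, 300.0
        est = dm.reference_from_manual_marks(b0 + b1 * t1, b0 + b1 * t2, t1, t2)
        assert est.fit.beta0 == pytest.approx(b0, abs=1e-9)
        assert est.drift_samples_per_s == pytest.approx(b1, abs=1e-12)
        assert est.accumulated_day7_s == pytest.approx(
            truth["accumulated_day7_s"], abs=1e-9)

    def test_unknown_fixture_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            sd.write_fixture_suite(tmp_path, seed=0, which=("nope",))
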