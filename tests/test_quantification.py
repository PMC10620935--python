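import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from midpipe import quantification as q
from midpipe.data_model import ThresholdSet

from conftest import make_meta, make_table


def _meta_one_batch(samples, blanks=("b1", "b2", "b3")):
    rows = [(s, "TN", f"D{i+1}", "B1", False) for i, s in enumerate(samples)]
    rows += [(b, "", "", "B1", True) for b in blanks]
    return make_meta(rows)


class TestBlankThresholds:
    def test_mean_plus_two_sd(self):
        table = make_table(
            {("lac", 0): [500.0, 90.0, 100.0, 110.0]}, ["s1", "b1", "b2", "b3"]
        )
        meta = _meta_one_batch(["s1"])
        thr = q.compute_blank_thresholds(table, meta)
        row = thr.df.loc[("lac", 0, "B1")]
        assert row["blank_mean"] == pytest.approx(100.0)
        assert row["blank_sd"] == pytest.approx(10.0)
        assert row["threshold"] == pytest.approx(120.0)

    def test_all_zero_blanks_make_everything_quantifiable(self):
        table = make_table({("lac", 0): [5.0, 0.0, 0.0, 0.0]}, ["s1", "b1", "b2", "b3"])
        thr = q.compute_blank_thresholds(table, _meta_one_batch(["s1"]))
        assert thr.df.loc[("lac", 0, "B1"), "threshold"] == 0.0

    def test_single_blank_in_batch_is_an_error(self):
        table = make_table({("lac", 0): [5.0, 1.0]}, ["s1", "b1"])
        meta = _meta_one_batch(["s1"], blanks=("b1",))
        with pytest.raises(q.QuantificationError, match=">=2"):
            q.compute_blank_thresholds(table, meta)

    def test_batch_without_blanks_is_an_error(self):
        table = make_table({("lac", 0): [5.0]}, ["s1"])
        meta = make_meta([("s1", "TN", "D1", "B1", False)])
        with pytest.raises(q.QuantificationError):
            q.compute_blank_thresholds(table, meta)


def _threshold_set(mu, thr_value, rows=(("lac", 0),), batch="B1"):
    idx = pd.MultiIndex.from_tuples(
        [(m, k, batch) for m, k in rows], names=("metabolite", "shift", "batch")
    )
    return ThresholdSet(
        pd.DataFrame(
            {
                "blank_mean": mu,
                "blank_sd": (thr_value - mu) / 2.0,
                "threshold": thr_value,
            },
            index=idx,
        )
    )


class TestThresholdCorrection:
    @pytest.mark.parametrize(
        "x,expected",
        [(90.0, 0.0), (110.0, 60.0), (125.0, 125.0), (100.0, 0.0), (120.0, 120.0)],
    )
    def test_piecewise_linear_map(self, x, expected):
        # mu=100, T=120: below blank mean -> 0; band maps linearly onto [0, T]
        table = make_table({("lac", 0): [x]}, ["s1"])
        meta = make_meta([("s1", "TN", "D1", "B1", False)])
        out = q.apply_threshold_correction(table, _threshold_set(100.0, 120.0), meta)
        assert out.values.iloc[0, 0] == pytest.approx(expected)
        assert out.stage == "thresholded"

    def test_degenerate_threshold_equal_to_mean(self):
        table = make_table({("lac", 0): [40.0, 60.0]}, ["s1", "s2"])
        meta = make_meta(
            [("s1", "TN", "D1", "B1", False), ("s2", "TN", "D2", "B1", False)]
        )
        out = q.apply_threshold_correction(table, _threshold_set(50.0, 50.0), meta)
        assert out.values.iloc[0].tolist() == [0.0, 60.0]

    @given(
        mu=st.floats(0.0, 1e5),
        span=st.floats(0.0, 1e4),
        x=st.floats(0.0, 2e5),
        x2=st.floats(0.0, 2e5),
    )
    def test_map_contract(self, mu, span, x, x2):
        """Monotone, never exceeds input, continuous at T, idempotent."""
        thr = mu + span
        ts = _threshold_set(mu, thr)
        meta = make_meta([("s1", "TN", "D1", "B1", False)])

        def apply(t):
            return q.apply_threshold_correction(t, ts, meta)

        def f(v):
            t = make_table({("lac", 0): [v]}, ["s1"])
            return float(apply(t).values.iloc[0, 0])

        fx, fx2 = f(x), f(x2)
        if x <= x2:
            assert fx <= fx2 + 1e-9 * max(1.0, abs(fx))
        assert fx <= x + 1e-9 * max(1.0, x)
        # idempotent: re-applying the stage to its own output is a no-op
        once = apply(make_table({("lac", 0): [x]}, ["s1"]))
        twice = apply(once)
        assert float(twice.values.iloc[0, 0]) == fx
        assert f(thr) == pytest.approx(thr, rel=1e-12, abs=1e-12)  # identity at T
        if span > 1e-9 * max(thr, 1.0):  # wide enough for float arithmetic
            # the band is linear with slope T/span and reaches exactly T at
            # its right end, which is continuity at T
            eps = span / 2.0
            assert f(thr - eps) == pytest.approx(thr - eps * thr / span, rel=1e-9, abs=1e-9)

    def test_missing_values_stay_missing(self):
        table = make_table({("lac", 0): [np.nan]}, ["s1"])
        meta = make_meta([("s1", "TN", "D1", "B1", False)])
        out = q.apply_threshold_correction(table, _threshold_set(100.0, 120.0), meta)
        assert np.isnan(out.values.iloc[0, 0])


class TestTestability:
    def _setup(self, values):
        table = make_table({("lac", 0): values}, ["s1", "s2", "s3"], stage="thresholded")
        meta = make_meta([(f"s{i}", "TN", f"D{i}", "B1", False) for i in (1, 2, 3)])
        return table, _threshold_set(100.0, 120.0), meta

    @pytest.mark.parametrize(
        "values,expected",
        [
            ([125.0, 130.0, 60.0], True),   # two replicates above T
            ([125.0, 60.0, 60.0], False),   # only one above
            ([0.0, 0.0, 0.0], False),       # nothing above
        ],
    )
    def test_two_replicates_above_threshold(self, values, expected):
        table, ts, meta = self._setup(values)
        assert bool(q.flag_testable(table, ts, meta).iloc[0]) is expected


class TestGroupCleaning:
    def _setup(self, values, n=3):
        samples = [f"s{i}" for i in range(1, n + 1)]
        table = make_table({("lac", 0): values}, samples, stage="thresholded")
        meta = make_meta([(s, "TN", f"D{i}", "B1", False) for i, s in enumerate(samples)])
        return table, _threshold_set(100.0, 120.0), meta

    def test_exactly_one_third_below_is_kept(self):
        table, ts, meta = self._setup([125.0, 130.0, 60.0])
        out = q.clean_groups(table, ts, meta)
        assert not out.values.isna().any().any()

    def test_more_than_one_third_below_removes_the_group(self):
        table, ts, meta = self._setup([125.0, 60.0, 60.0])
        out = q.clean_groups(table, ts, meta)
        assert out.values.loc[("lac", 0)].isna().all()

    def test_group_of_four_all_above_untouched(self):
        table, ts, meta = self._setup([125.0, 130.0, 140.0, 150.0], n=4)
        out = q.clean_groups(table, ts, meta)
        pd.testing.assert_frame_equal(out.values, table.values)

    def test_missing_counts_as_below_threshold(self):
        table, ts, meta = self._setup([125.0, np.nan, np.nan])
        out = q.clean_groups(table, ts, meta)
        assert out.values.loc[("lac", 0)].isna().all()

    def test_never_converts_missing_to_present(self):
        table, ts, meta = self._setup([125.0, 130.0, np.nan])
        out = q.clean_groups(table, ts, meta)
        assert np.isnan(out.values.loc[("lac", 0), "s3"])

    def test_mask_applies_to_target_table(self):
        table, ts, meta = self._setup([125.0, 60.0, 60.0])
        target = make_table(
            {("lac", 0): [1.0, 2.0, 3.0]}, ["s1", "s2", "s3"], stage="normalized"
        )
        out = q.clean_groups(table, ts, meta, target=target)
        assert out.values.loc[("lac", 0)].isna().all()
        # membership judged on the thresholded table, not on the target
        assert not table.values.isna().any().any()
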