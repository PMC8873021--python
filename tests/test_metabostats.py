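"""Detection thresholds, imputation and differential statistics against
hand-computed oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from enviromics.metabostats import (
    ALPHA_DEFAULT,
    DetectionThresholds,
    apply_detection,
    bh_fdr,
    cluster_order,
    compute_thresholds,
    differential,
    results_frame,
    volcano_table,
)

from conftest import make_corrected, make_intensity_matrix


def _matrix(heights_dict, blanks, groups=None):
    df = pd.DataFrame(heights_dict)
    roles = {c: ("blank" if c in blanks else "sample") for c in df.columns}
    return make_intensity_matrix(df, roles, groups)


class TestThresholds:
    def test_blank_mean_below_floor_uses_floor(self):
        m = _matrix({"b1": [1000.0], "s1": [5e5]}, blanks={"b1"})
        thr = compute_thresholds(m)
        assert thr.thresholds.iloc[0] == 10_000.0

    def test_three_times_blank_mean(self):
        m = _matrix({"b1": [20_000.0], "b2": [20_000.0], "s1": [5e5]},
                    blanks={"b1", "b2"})
        thr = compute_thresholds(m)
        assert thr.thresholds.iloc[0] == 60_000.0

    def test_all_zero_blanks_gives_floor(self):
        m = _matrix({"b1": [0.0], "s1": [5e5]}, blanks={"b1"})
        assert compute_thresholds(m).thresholds.iloc[0] == 10_000.0

    def test_blank_mean_averages_blanks_only(self):
        m = _matrix({"b1": [10_000.0], "b2": [30_000.0], "s1": [9e9]},
                    blanks={"b1", "b2"})
        assert compute_thresholds(m).thresholds.iloc[0] == 60_000.0

    def test_no_blanks_rejected(self):
        m = _matrix({"s1": [5e5]}, blanks=set())
        with pytest.raises(ValueError, match="blank"):
            compute_thresholds(m)

    def test_container_enforces_floor(self):
        with pytest.raises(ValueError):
            DetectionThresholds(pd.Series([5000.0]), floor=10_000.0)


class TestDetection:
    def test_at_threshold_counts_as_detected(self):
        m = _matrix({"b1": [0.0], "s1": [10_000.0], "s2": [9_999.9]},
                    blanks={"b1"})
        corr = apply_detection(m, compute_thresholds(m))
        assert bool(corr.detected.loc[0, "s1"]) is True
        assert bool(corr.detected.loc[0, "s2"]) is False

    def test_non_detection_imputed_with_threshold(self):
        m = _matrix({"b1": [20_000.0], "s1": [30_000.0]}, blanks={"b1"})
        corr = apply_detection(m, compute_thresholds(m))
        assert corr.values.loc[0, "s1"] == 60_000.0
        assert corr.provenance().loc[0, "s1"] == "imputed"

    def test_detected_values_pass_through(self):
        m = _matrix({"b1": [0.0], "s1": [123_456.0]}, blanks={"b1"})
        corr = apply_detection(m, compute_thresholds(m))
        assert corr.values.loc[0, "s1"] == 123_456.0
        assert corr.provenance().loc[0, "s1"] == "measured"

    def test_missing_threshold_rows_rejected(self):
        m = _matrix({"b1": [0.0], "s1": [1.0]}, blanks={"b1"})
        thr = DetectionThresholds(pd.Series({99: 10_000.0}))
        with pytest.raises(ValueError, match="missing"):
            apply_detection(m, thr)


def _corr(values, detected, thr, groups):
    vdf = pd.DataFrame(values, index=["m"])
    ddf = pd.DataFrame(detected, index=["m"])
    return make_corrected(vdf, ddf, pd.Series({"m": thr}), groups)


class TestDifferential:
    def test_worked_example(self):
        """control {10,12,11,13}, group {20,22,21,23}: log2fc 0.9028,
        pooled t = 10.9545 on 6 df, p = 3.4364e-5."""
        cols = [f"c{i}" for i in range(4)] + [f"g{i}" for i in range(4)]
        vals = {c: [v] for c, v in zip(cols, [10, 12, 11, 13, 20, 22, 21, 23])}
        det = {c: [True] for c in cols}
        groups = {c: ("ctrl" if c.startswith("c") else "trt") for c in cols}
        corr = _corr(vals, det, 1.0, groups)
        (r,) = differential(corr, "trt", control="ctrl")
        assert r.log2fc == pytest.approx(math.log2(21.5 / 11.5), rel=1e-12)
        assert r.log2fc == pytest.approx(0.90279, rel=1e-4)
        assert r.p_value == pytest.approx(3.4364e-5, rel=1e-3)
        assert r.significant and r.inf_reason == "none"

    def test_control_all_undetected_gives_plus_inf(self):
        cols = ["c0", "c1", "g0", "g1"]
        vals = {c: [10_000.0] for c in cols}
        vals["g0"] = [5e5]
        vals["g1"] = [6e5]
        det = {"c0": [False], "c1": [False], "g0": [True], "g1": [True]}
        groups = {"c0": "ctrl", "c1": "ctrl", "g0": "trt", "g1": "trt"}
        (r,) = differential(_corr(vals, det, 10_000.0, groups), "trt", "ctrl")
        assert r.log2fc == math.inf
        assert r.inf_reason == "control_undetected"
        assert math.isfinite(r.p_value)

    def test_group_all_undetected_gives_minus_inf(self):
        vals = {"c0": [5e5], "c1": [6e5], "g0": [10_000.0], "g1": [10_000.0]}
        det = {"c0": [True], "c1": [True], "g0": [False], "g1": [False]}
        groups = {"c0": "ctrl", "c1": "ctrl", "g0": "trt", "g1": "trt"}
        (r,) = differential(_corr(vals, det, 10_000.0, groups), "trt", "ctrl")
        assert r.log2fc == -math.inf
        assert r.inf_reason == "group_undetected"

    def test_identical_arms_p_is_one(self):
        vals = {"c0": [5.0], "c1": [5.0], "g0": [5.0], "g1": [5.0]}
        det = {c: [True] for c in vals}
        groups = {"c0": "ctrl", "c1": "ctrl", "g0": "trt", "g1": "trt"}
        (r,) = differential(_corr(vals, det, 1.0, groups), "trt", "ctrl")
        assert r.p_value == 1.0 and r.log2fc == 0.0 and not r.significant

    def test_single_sample_arm_warns_and_nan(self):
        vals = {"c0": [5.0], "g0": [6.0], "g1": [7.0]}
        det = {c: [True] for c in vals}
        groups = {"c0": "ctrl", "g0": "trt", "g1": "trt"}
        with pytest.warns(UserWarning, match="undefined"):
            (r,) = differential(_corr(vals, det, 1.0, groups), "trt", "ctrl")
        assert math.isnan(r.p_value) and not r.significant

    def test_missing_group_rejected(self):
        vals = {"c0": [5.0]}
        det = {"c0": [True]}
        (corr,) = [_corr(vals, det, 1.0, {"c0": "ctrl"})]
        with pytest.raises(ValueError):
            differential(corr, "trt", "ctrl")


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    blank_scale=st.floats(0.0, 1e5),
    heights=st.lists(st.floats(0.0, 1e6), min_size=4, max_size=4),
)
def test_raising_blanks_never_increases_detections(blank_scale, heights):
    cols = ["s0", "s1", "s2", "s3"]
    base = _matrix(
        {"b1": [1000.0], **{c: [h] for c, h in zip(cols, heights)}},
        blanks={"b1"},
    )
    raised = _matrix(
        {"b1": [1000.0 + blank_scale], **{c: [h] for c, h in zip(cols, heights)}},
        blanks={"b1"},
    )
    det_base = apply_detection(base, compute_thresholds(base)).detected
    det_raised = apply_detection(raised, compute_thresholds(raised)).detected
    assert int(det_raised.to_numpy().sum()) <= int(det_base.to_numpy().sum())


def test_imputed_values_never_below_threshold():
    rng = np.random.default_rng(5)
    cols = [f"s{i}" for i in range(6)]
    m = _matrix(
        {"b1": [8000.0, 0.0, 50_000.0],
         **{c: list(rng.uniform(0, 1e5, 3)) for c in cols}},
        blanks={"b1"},
    )
    corr = apply_detection(m, compute_thresholds(m))
    thr = corr.thresholds
    assert (corr.values.ge(thr, axis=0)).to_numpy().all()


class TestClusterOrder:
    def test_one_dimensional_toy(self):
        """Rows at 0, 1 and 10: the outlier row ends up at one edge."""
        vals = pd.DataFrame(
            {"s1": [0.0, 1.0, 10.0], "s2": [0.0, 1.0, 10.0]},
            index=["a", "b", "far"],
        )
        det = vals.astype(bool) | True
        corr = make_corrected(vals, det, pd.Series(1.0, index=vals.index),
                              {"s1": "x", "s2": "x"})
        rows, cols = cluster_order(corr)
        assert set(rows) == {"a", "b", "far"}
        assert rows[0] == "far" or rows[-1] == "far"
        assert {rows.index("a"), rows.index("b")} in ({0, 1}, {1, 2})

    def test_constant_matrix_warns(self):
        vals = pd.DataFrame(np.ones((3, 3)), index=list("abc"),
                            columns=["s1", "s2", "s3"])
        with pytest.warns(UserWarning, match="constant"):
            cluster_order(vals)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            cluster_order(pd.DataFrame({"s1": [1.0]}))


class TestVolcano:
    def _results(self, corr_groups):
        return differential(*corr_groups)

    def test_boundary_p_not_significant(self):
        """p exactly alpha must not be significant (strict inequality)."""
        from enviromics.metabostats import DifferentialResult

        r = DifferentialResult("m", "g", 1.0, ALPHA_DEFAULT, False, "none")
        df = volcano_table([r])
        assert not df.loc[0, "significant"]

    def test_infinite_fc_gets_signed_sentinel(self):
        from enviromics.metabostats import DifferentialResult

        rs = [
            DifferentialResult("up", "g", math.inf, 0.01, True,
                               "control_undetected"),
            DifferentialResult("down", "g", -math.inf, 0.01, True,
                               "group_undetected"),
        ]
        df = volcano_table(rs).set_index("analyte")
        assert df.loc["up", "log2fc"] == 10.0
        assert df.loc["down", "log2fc"] == -10.0
        assert df["infinite_fc"].all()

    def test_sorted_by_significance(self):
        from enviromics.metabostats import DifferentialResult

        rs = [
            DifferentialResult("weak", "g", 0.1, 0.5, False, "none"),
            DifferentialResult("strong", "g", 1.0, 1e-6, True, "none"),
        ]
        df = volcano_table(rs)
        assert df.loc[0, "analyte"] == "strong"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            volcano_table([])


class TestFdr:
    def test_monotone_and_bounded(self):
        p = np.array([0.001, 0.01, 0.03, 0.5, 0.9])
        adj = bh_fdr(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        assert (np.diff(adj[np.argsort(p)]) >= -1e-15).all()

    def test_textbook_example(self):
        adj = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_results_frame_has_fdr(self):
        from enviromics.metabostats import DifferentialResult

        rs = [DifferentialResult("m", "g", 0.5, 0.02, True, "none")]
        df = results_frame(rs)
        assert "fdr" in df.columns and df.loc[0, "fdr"] == 0.02
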