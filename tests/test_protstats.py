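"""Quantile normalization invariants, complete-case filtering, ANOVA and
post-hoc machinery for the protein matrix."""

import numpy as np
import pandas as pd
import pytest

from enviromics.design import StudyDesign
from enviromics.metabostats import differential as metab_differential
from enviromics.protstats import (
    ProteinMatrix,
    anova_posthoc,
    complete_case_filter,
    differential_counts,
    log2_quantile_normalize,
    pairwise_vs_control,
    qc_report,
    quantile_normalize,
)
from enviromics.synthetic.proteome import gen_protein_matrix

from conftest import make_corrected


def _pm(values, groups, donors=None):
    df = pd.DataFrame(values)
    cols = list(df.columns)
    return ProteinMatrix(
        intensities=df,
        groups=pd.Series({c: groups[c] for c in cols}),
        donors=pd.Series({c: (donors or {}).get(c, "d1") for c in cols}),
    )


class TestQuantileNormalize:
    def test_two_by_two_exact(self):
        """[[1,4],[3,2]] -> [[1.5,3.5],[3.5,1.5]] (frozen worked example)."""
        df = pd.DataFrame({"a": [1.0, 3.0], "b": [4.0, 2.0]})
        out = quantile_normalize(df)
        expect = pd.DataFrame({"a": [1.5, 3.5], "b": [3.5, 1.5]})
        pd.testing.assert_frame_equal(out, expect)

    def test_sorted_columns_identical_after(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.lognormal(3, 1, size=(50, 6)),
                          columns=[f"s{i}" for i in range(6)])
        out = quantile_normalize(df).to_numpy()
        sorted_cols = np.sort(out, axis=0)
        assert np.abs(sorted_cols - sorted_cols[:, :1]).max() <= 1e-9

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(40, 5)))
        once = quantile_normalize(df)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice.to_numpy(), once.to_numpy(),
                                   atol=1e-12)

    def test_rank_order_preserved_within_column(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(30, 4)))
        out = quantile_normalize(df)
        for c in df.columns:
            a = df[c].to_numpy()
            b = out[c].to_numpy()
            assert (np.argsort(a) == np.argsort(b)).all()

    def test_ties_get_mean_of_tied_reference(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(df)
        ref = np.mean(np.sort(df.to_numpy(), axis=0), axis=1)
        assert out["a"].iloc[0] == out["a"].iloc[1] == pytest.approx(
            (ref[0] + ref[1]) / 2
        )


class TestCompleteCase:
    def test_keeps_only_fully_observed(self):
        rng = np.random.default_rng(6)
        vals = rng.lognormal(3, 1, size=(10, 4))
        vals[2, 1] = np.nan
        vals[7, 3] = np.nan
        vals[7, 0] = np.nan
        df = pd.DataFrame(vals, index=[f"p{i}" for i in range(10)],
                          columns=list("wxyz"))
        pm = _pm(df, {c: "g" for c in "wxyz"})
        kept = complete_case_filter(pm)
        assert kept.intensities.shape[0] == 8
        assert "p2" not in kept.intensities.index
        assert "p7" not in kept.intensities.index

    def test_all_missing_rejected(self):
        df = pd.DataFrame({"a": [np.nan], "b": [1.0]})
        pm = _pm(df, {"a": "g", "b": "g"})
        with pytest.raises(ValueError, match="complete"):
            complete_case_filter(pm)

    def test_normalize_refuses_incomplete(self):
        df = pd.DataFrame({"a": [np.nan, 2.0], "b": [1.0, 3.0]})
        pm = _pm(df, {"a": "g", "b": "g"})
        with pytest.raises(ValueError, match="complete"):
            log2_quantile_normalize(pm)


class TestQC:
    def test_cv_recovers_generator_noise(self):
        """donor_sd=0, noise_cv=5%: median within-group CV comes out ~5%."""
        design = StudyDesign(groups=("vehicle", "WIN"), donors_per_group=6,
                             blanks=0, seed=21)
        matrix, groups, donors, _ = gen_protein_matrix(
            design, n_proteins=400, n_affected=0, noise_cv=0.05,
            missing_rate=0.0, donor_sd=0.0,
        )
        pm = ProteinMatrix(matrix, groups, donors)
        rep = qc_report(pm)
        for g in ("vehicle", "WIN"):
            assert rep.group_median_cv[g] == pytest.approx(0.05, rel=0.15)

    def test_identical_samples_r2_one(self):
        col = np.array([10.0, 20.0, 40.0, 80.0])
        df = pd.DataFrame({"a": col, "b": col, "c": col * 2})
        pm = _pm(df, {"a": "g", "b": "g", "c": "g"})
        rep = qc_report(pm)
        assert rep.r2.loc["a", "b"] == pytest.approx(1.0)

    def test_singleton_group_rejected(self):
        df = pd.DataFrame({"a": [1.0], "b": [1.0]})
        pm = _pm(df, {"a": "g1", "b": "g2"})
        with pytest.raises(ValueError, match="fewer than 2"):
            qc_report(pm)


class TestAnovaPosthoc:
    def test_anova_worked_example(self):
        """{1,2,3} vs {4,5,6}: F = 13.5 on (1, 4) df, p = 0.02131."""
        df = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]],
            index=["p"], columns=[f"s{i}" for i in range(6)],
        )
        groups = pd.Series(
            {f"s{i}": ("vehicle" if i < 3 else "trt") for i in range(6)}
        )
        out = anova_posthoc(df, groups)
        assert out.loc["p", "anova_p"] == pytest.approx(0.021312, rel=1e-3)
        assert bool(out.loc["p", "diff_trt"])
        assert out.loc["p", "dir_trt"] == 1

    def test_spiked_protein_detected_null_mostly_not(self):
        rng = np.random.default_rng(8)
        n = 60
        cols = [f"v{i}" for i in range(4)] + [f"t{i}" for i in range(4)]
        groups = pd.Series(
            {c: ("vehicle" if c.startswith("v") else "trt") for c in cols}
        )
        base = rng.normal(20, 0.1, size=(n, 8))
        base[0, 4:] += 1.0  # +1 log2 spike in the treated arm
        df = pd.DataFrame(base, index=[f"p{i}" for i in range(n)],
                          columns=cols)
        out = anova_posthoc(df, groups)
        assert bool(out.loc["p0", "diff_trt"]) and out.loc["p0", "dir_trt"] == 1
        null_calls = out.loc[out.index != "p0", "diff_trt"].sum()
        assert null_calls <= 6  # ~alpha-level false positives on 59 nulls

    def test_posthoc_skipped_when_omnibus_fails(self):
        df = pd.DataFrame([[5.0, 5.1, 4.9, 5.0, 5.05, 4.95]], index=["p"],
                          columns=[f"s{i}" for i in range(6)])
        groups = pd.Series(
            {f"s{i}": ("vehicle" if i < 3 else "trt") for i in range(6)}
        )
        out = anova_posthoc(df, groups)
        if out.loc["p", "anova_p"] >= 0.05:
            assert np.isnan(out.loc["p", "p_trt"])
            assert out.loc["p", "dir_trt"] == 0

    def test_constant_rows_use_degenerate_convention(self):
        df = pd.DataFrame([[5.0] * 6, [1.0, 1.0, 1.0, 2.0, 2.0, 2.0]],
                          index=["flat", "step"],
                          columns=[f"s{i}" for i in range(6)])
        groups = pd.Series(
            {f"s{i}": ("vehicle" if i < 3 else "trt") for i in range(6)}
        )
        out = anova_posthoc(df, groups)
        assert out.loc["flat", "anova_p"] == 1.0
        assert out.loc["step", "anova_p"] == 0.0

    def test_singleton_group_rejected(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], columns=["a", "b", "c"])
        groups = pd.Series({"a": "vehicle", "b": "vehicle", "c": "trt"})
        with pytest.raises(ValueError, match="2 samples"):
            anova_posthoc(df, groups)


class TestPairwise:
    def test_alpha_boundary_is_strict(self):
        df = pd.DataFrame(
            np.random.default_rng(9).normal(size=(20, 6)),
            columns=[f"s{i}" for i in range(6)],
        )
        groups = pd.Series(
            {f"s{i}": ("vehicle" if i < 3 else "trt") for i in range(6)}
        )
        out = pairwise_vs_control(df, groups, "trt")
        assert (out["called"] == (out["p_value"] < 0.05)).all()

    def test_counts_match_pairwise_calls(self):
        rng = np.random.default_rng(10)
        cols = [f"{g}{i}" for g in "vab" for i in range(3)]
        groups = pd.Series(
            {c: {"v": "vehicle", "a": "ga", "b": "gb"}[c[0]] for c in cols}
        )
        df = pd.DataFrame(rng.normal(size=(30, 9)), columns=cols)
        counts = differential_counts(df, groups)
        for g in ("ga", "gb"):
            expect = int(pairwise_vs_control(df, groups, g)["called"].sum())
            assert counts[g] == expect

    def test_consistent_with_metabolite_differential(self):
        """The protein pairwise t-test and the metabolite differential use
        the same test, so on identical numbers the p-values agree."""
        cols = ["c0", "c1", "c2", "g0", "g1", "g2"]
        vals = [10.0, 12.0, 11.0, 20.0, 22.0, 21.0]
        df = pd.DataFrame([vals], index=["x"], columns=cols)
        groups = pd.Series(
            {c: ("vehicle" if c.startswith("c") else "trt") for c in cols}
        )
        prot = pairwise_vs_control(df, groups, "trt")

        corr = make_corrected(
            df, df.astype(bool) | True, pd.Series({"x": 1.0}),
            {c: ("vehicle" if c.startswith("c") else "trt") for c in cols},
        )
        (metab,) = metab_differential(corr, "trt", control="vehicle")
        assert prot.loc["x", "p_value"] == pytest.approx(metab.p_value,
                                                         rel=1e-12)


class TestProteinMatrixContainer:
    def test_label_coverage_enforced(self):
        df = pd.DataFrame({"a": [1.0]})
        with pytest.raises(ValueError, match="cover"):
            ProteinMatrix(df, pd.Series(dtype=object), pd.Series(dtype=object))

    def test_nonpositive_rejected(self):
        df = pd.DataFrame({"a": [0.0]})
        with pytest.raises(ValueError, match="positive"):
            ProteinMatrix(df, pd.Series({"a": "g"}), pd.Series({"a": "d"}))
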