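import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdmr import DMPThresholds, classify_dmps
from tdmr.dmp_stats import (
    DegenerateDesignError,
    UndefinedTestError,
    bonferroni_alpha,
    mean_sum_of_squares,
    tissue_f_test,
    tissue_f_test_mixed,
)


class TestTissueFTest:
    def test_worked_four_sample_design(self):
        """Explicit nested least-squares RSS on a 2x2 tissue/individual design."""
        fit = tissue_f_test(
            [0.1, 0.2, 0.5, 0.8], ["A", "A", "B", "B"], ["1", "2", "1", "2"]
        )
        assert fit.rss_reduced == pytest.approx(0.26, rel=1e-12)
        assert fit.rss_full == pytest.approx(0.01, rel=1e-9)
        assert fit.f_statistic == pytest.approx(25.0, rel=1e-9)
        # F(1,1): p = 2/pi * atan(1/sqrt(F))
        assert fit.p_value == pytest.approx(2 / math.pi * math.atan(0.2), rel=1e-9)
        assert (fit.df_num, fit.df_den, fit.n_obs) == (1, 1, 4)

    def test_constant_betas_give_f_zero_p_one(self):
        fit = tissue_f_test([0.5] * 4, ["A", "A", "B", "B"], ["1", "2", "1", "2"])
        assert fit.f_statistic == 0.0
        assert fit.p_value == 1.0

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(0)
        y = rng.random(12)
        t = np.repeat(["A", "B", "C"], 4)
        i = np.tile(["1", "2", "3", "4"], 3)
        ref = tissue_f_test(y, t, i)
        perm = rng.permutation(12)
        fit = tissue_f_test(y[perm], t[perm], i[perm])
        assert fit.f_statistic == pytest.approx(ref.f_statistic, rel=1e-12)
        assert fit.p_value == pytest.approx(ref.p_value, rel=1e-12)

    def test_single_tissue_raises(self):
        with pytest.raises(UndefinedTestError):
            tissue_f_test([0.1, 0.2], ["A", "A"], ["1", "2"])

    def test_saturated_design_raises(self):
        with pytest.raises(DegenerateDesignError):
            tissue_f_test([0.1, 0.2], ["A", "B"], ["1", "1"])

    def test_missing_values_dropped_per_probe(self):
        full = tissue_f_test(
            [0.1, 0.2, 0.5, 0.8, 0.3, 0.4],
            ["A", "A", "B", "B", "C", "C"],
            ["1", "2", "1", "2", "1", "2"],
        )
        with_nan = tissue_f_test(
            [0.1, 0.2, 0.5, 0.8, 0.3, 0.4, np.nan],
            ["A", "A", "B", "B", "C", "C", "A"],
            ["1", "2", "1", "2", "1", "2", "3"],
        )
        assert with_nan.n_obs == full.n_obs
        assert with_nan.f_statistic == pytest.approx(full.f_statistic, rel=1e-12)

    def test_matches_brute_force_least_squares(self):
        """RSS pair agrees with independent lstsq fits on random designs."""
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 150:
            nt, ni = rng.integers(2, 5), rng.integers(2, 6)
            keep = rng.random((nt, ni)) < 0.85
            t_lab, i_lab = np.nonzero(keep)
            if len(np.unique(t_lab)) < 2:
                continue
            y = rng.random(len(t_lab))

            def design(with_tissue):
                cols = [np.ones(len(y))]
                if with_tissue:
                    cols += [(t_lab == v).astype(float) for v in np.unique(t_lab)[1:]]
                cols += [(i_lab == v).astype(float) for v in np.unique(i_lab)[1:]]
                return np.column_stack(cols)

            Xf = design(True)
            if len(y) - np.linalg.matrix_rank(Xf) <= 0:
                continue
            fit = tissue_f_test(y, t_lab, i_lab)
            for X, got in ((Xf, fit.rss_full), (design(False), fit.rss_reduced)):
                beta = np.linalg.lstsq(X, y, rcond=None)[0]
                resid = y - X @ beta
                assert got == pytest.approx(resid @ resid, rel=1e-10, abs=1e-12)
            checked += 1

    def test_balanced_design_equals_mixed_model(self):
        """Blocked-ANOVA F equals the REML mixed-model Wald F when balanced."""
        rng = np.random.default_rng(2)
        T, M = 3, 5
        t = np.repeat(np.arange(T), M)
        i = np.tile(np.arange(M), T)
        for _ in range(5):
            y = (
                0.4
                + 0.1 * (t == 1)
                + rng.normal(0, 0.05, M)[i]
                + rng.normal(0, 0.03, T * M)
            )
            fa = tissue_f_test(y, t, i)
            fm = tissue_f_test_mixed(y, t, i)
            assert fm.f_statistic == pytest.approx(fa.f_statistic, rel=1e-3)
            assert (fm.df_num, fm.df_den) == (fa.df_num, fa.df_den)


class TestEffectSize:
    @pytest.mark.parametrize(
        "means, expected",
        [
            ({"a": 0.40, "b": 0.60}, 0.01),  # a 20% two-tissue split
            ({"a": 0.5, "b": 0.5, "c": 0.5}, 0.0),
            ({"a": 0.2, "b": 0.4, "c": 0.6}, (0.04 + 0.0 + 0.04) / 3),
        ],
    )
    def test_worked_values(self, means, expected):
        assert mean_sum_of_squares(means).mss == pytest.approx(expected, rel=1e-9)

    def test_empty_or_single_tissue_rejected(self):
        with pytest.raises(ValueError):
            mean_sum_of_squares({})
        with pytest.raises(ValueError):
            mean_sum_of_squares({"a": 0.5})

    @given(
        means=st.lists(st.floats(0.05, 0.6), min_size=2, max_size=6),
        shift=st.floats(0.0, 0.35),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_invariant_to_labels_and_constant_shift(self, means, shift):
        base = {f"t{k}": m for k, m in enumerate(means)}
        shifted = {f"u{k}": m + shift for k, m in enumerate(means)}
        assert mean_sum_of_squares(base).mss == pytest.approx(
            mean_sum_of_squares(shifted).mss, rel=1e-9, abs=1e-15
        )
        assert mean_sum_of_squares(base).mss >= 0


class TestBonferroni:
    def test_truncated_threshold_for_half_million_probes(self):
        assert bonferroni_alpha(471_000) == 1e-7

    def test_raw_mode(self):
        assert bonferroni_alpha(471_000, truncate=False) == pytest.approx(
            0.05 / 471_000
        )


class TestClassifyDmps:
    def test_threshold_conjunction(self, toy_matrix):
        """Calling requires both the significance and the effect-size cut."""
        out = classify_dmps(toy_matrix, DMPThresholds(alpha=1e-7, mss_min=0.01))
        assert set(out["probe_id"]) == {"p1", "p2", "p3"}
        assert not out["is_dmp"].any()  # tiny n: nothing is genome-wide significant
        relaxed = classify_dmps(toy_matrix, DMPThresholds(alpha=0.5, mss_min=0.01))
        by = relaxed.set_index("probe_id")
        assert by.loc["p1", "is_dmp"] and by.loc["p2", "is_dmp"]
        assert not by.loc["p3", "is_dmp"]  # constant probe: mss = 0
        # high mss but failing p: not a DMP
        strict = classify_dmps(toy_matrix, DMPThresholds(alpha=1e-3, mss_min=0.01))
        assert not strict.set_index("probe_id").loc["p1", "is_dmp"]

    def test_matches_single_probe_path(self, small_dataset):
        out = classify_dmps(small_dataset.matrix)
        sheet = small_dataset.matrix.samples
        rng = np.random.default_rng(5)
        for idx in rng.choice(len(out), size=10, replace=False):
            row = out.iloc[int(idx)]
            y = small_dataset.matrix.values.loc[row["probe_id"]].to_numpy()
            fit = tissue_f_test(
                y, sheet.table["tissue"].to_numpy(), sheet.table["individual"].to_numpy()
            )
            assert row["p_value"] == pytest.approx(fit.p_value, rel=1e-9)

    def test_output_sorted_and_complete(self, small_dataset):
        out = classify_dmps(small_dataset.matrix)
        assert len(out) == small_dataset.matrix.n_probes
        key = out[["chromosome", "position"]]
        assert key.equals(key.sort_values(["chromosome", "position"]).reset_index(drop=True))

    def test_degenerate_probe_flagged_untested(self, toy_matrix):
        vals = toy_matrix.values.copy()
        vals.loc["p1", ["s3", "s4"]] = np.nan  # only one tissue left
        from tdmr import BetaMatrix

        m = BetaMatrix(values=vals, manifest=toy_matrix.manifest, samples=toy_matrix.samples)
        out = classify_dmps(m).set_index("probe_id")
        assert not out.loc["p1", "tested"]
        assert np.isnan(out.loc["p1", "p_value"])
        assert not out.loc["p1", "is_dmp"]
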