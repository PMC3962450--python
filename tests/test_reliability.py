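import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from oracles import brute_force_anova

from dtiretest import (
    PairedSeries,
    bland_altman,
    icc,
    icc_ci_delta,
    outlier_sensitivity,
    reliability_result,
    reliability_summary,
    reliability_table,
    simulate_paired_series,
    variance_components,
    voxelwise_icc,
)


class TestVarianceComponents:
    def test_identical_repeats(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [4.0, 4.0]])
        var_b, var_w = variance_components(x)
        assert var_w == 0.0
        # between = variance of subject means relative to MSB/k with MSW = 0
        assert var_b == pytest.approx(np.var([1, 2, 4], ddof=1))

    def test_pure_within_truncates_between_to_zero(self):
        x = np.array([[0.0, 1.0], [0.0, 1.0], [0.0, 1.0]])
        var_b, var_w = variance_components(x)
        assert var_b == 0.0
        assert var_w == pytest.approx(0.5)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            n = rng.integers(3, 31)
            x = rng.normal(size=(n, 2)) * rng.uniform(0.1, 10)
            got = variance_components(x)
            want = brute_force_anova(x)
            assert got[0] == pytest.approx(want[0], rel=1e-10, abs=1e-12)
            assert got[1] == pytest.approx(want[1], rel=1e-10, abs=1e-12)

    def test_matches_pingouin_icc1(self, rng):
        """Independent published implementation of ICC(1,1) agrees."""
        pingouin = pytest.importorskip("pingouin")
        x = simulate_paired_series(15, 0.8, 0.2, rng=rng)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(15), 2),
                "rater": np.tile([1, 2], 15),
                "score": x.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            data=df, targets="subject", raters="rater", ratings="score"
        )
        icc1 = ref.loc[ref["Type"].isin(["ICC1", "ICC(1,1)"]), "ICC"].iloc[0]
        var_b, var_w = variance_components(x)
        assert icc(var_b, var_w) == pytest.approx(icc1, abs=1e-9)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            variance_components(np.array([[1.0, 2.0]]))

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            variance_components(np.array([[1.0, np.nan], [2.0, 3.0]]))

    def test_components_sum_to_anova_total(self):
        # deterministic table with dominant between-subject spread (no truncation)
        x = np.array([[0.0, 0.1], [1.0, 1.1], [2.0, 2.3], [3.0, 2.9]])
        var_b, var_w = variance_components(x)
        n, k = x.shape
        rm = x.mean(1)
        msw = ((x - rm[:, None]) ** 2).sum() / (n * (k - 1))
        msb = k * ((rm - x.mean()) ** 2).sum() / (n - 1)
        assert msb > msw
        assert var_b + var_w == pytest.approx((msb + msw) / k, rel=1e-12)


class TestIcc:
    @pytest.mark.parametrize(
        "vb,vw,expected", [(1.0, 0.0, 1.0), (0.0, 1.0, 0.0), (3.0, 1.0, 0.75)]
    )
    def test_point_values(self, vb, vw, expected):
        assert icc(vb, vw) == expected

    def test_undefined_when_no_variance(self):
        assert math.isnan(icc(0.0, 0.0))

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            icc(-1.0, 1.0)

    @given(
        vb=st.floats(0.1, 10), vw=st.floats(0.1, 10),
        shift=st.floats(-10, 10), scale=st.floats(0.1, 10),
    )
    def test_shift_and_scale_invariance(self, vb, vw, shift, scale):
        rng = np.random.default_rng(42)
        x = simulate_paired_series(12, vb, vw, rng=rng)
        rho0 = icc(*variance_components(x))
        rho1 = icc(*variance_components(x * scale + shift))
        assert rho1 == pytest.approx(rho0, abs=1e-12)


class TestDeltaCi:
    def test_perfect_icc_zero_width(self):
        assert icc_ci_delta(1.0, 12) == (1.0, 1.0)
        assert icc_ci_delta(1.0, 12, transform="identity") == (1.0, 1.0)

    def test_zero_icc_identity_width_and_truncation(self):
        lo, hi = icc_ci_delta(0.0, 13, transform="identity")
        # V = 2/(2*12) at rho=0 -> half-width 1.96*sqrt(1/12), floor at 0
        half = 1.959963984540054 * math.sqrt(2.0 / (2.0 * 12.0))
        assert lo == 0.0
        assert hi == pytest.approx(half, rel=1e-9)

    def test_fisher_z_half_width_is_constant_on_z_scale(self):
        # for k=2 the delta-method se on the arctanh scale is 1/sqrt(n-1)
        for rho in (0.0, 0.3, 0.8):
            lo, hi = icc_ci_delta(rho, 10)
            z = 1.959963984540054 / 3.0
            assert math.atanh(hi) - math.atanh(rho) == pytest.approx(z, rel=1e-9)

    def test_identity_width_scales_as_inverse_sqrt_n(self):
        # n chosen large enough that no truncation occurs at either size
        rho = 0.5
        w1 = np.diff(icc_ci_delta(rho, 33, transform="identity"))[0]
        w2 = np.diff(icc_ci_delta(rho, 65, transform="identity"))[0]
        assert w2 == pytest.approx(w1 / math.sqrt(2), rel=1e-9)

    def test_fisher_z_width_scales_on_transformed_scale(self):
        rho = 0.6
        z1 = math.atanh(icc_ci_delta(rho, 9)[1]) - math.atanh(icc_ci_delta(rho, 9)[0])
        z2 = math.atanh(icc_ci_delta(rho, 17)[1]) - math.atanh(icc_ci_delta(rho, 17)[0])
        assert z2 == pytest.approx(z1 / math.sqrt(2), rel=1e-9)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            icc_ci_delta(0.5, 2)

    def test_bounds_contain_estimate(self):
        for rho in (0.0, 0.25, 0.5, 0.9, 1.0):
            lo, hi = icc_ci_delta(rho, 12)
            assert lo <= rho <= hi


class TestBlandAltman:
    def test_identical_repeats(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        ba = bland_altman(x)
        assert ba.mean_diff == 0.0
        assert ba.sd_diff == 0.0
        assert ba.loa_low == ba.loa_high == 0.0

    def test_constant_offset(self):
        x = np.column_stack([np.arange(5.0), np.arange(5.0) - 0.1])
        ba = bland_altman(x)
        assert ba.mean_diff == pytest.approx(0.1)
        assert ba.sd_diff == pytest.approx(0.0, abs=1e-15)

    def test_hand_arithmetic(self):
        ba = bland_altman(np.array([[1.0, 2.0], [2.0, 2.0], [3.0, 5.0]]))
        assert ba.mean_diff == pytest.approx(-1.0)
        assert ba.sd_diff == pytest.approx(1.0)
        assert ba.loa_low == pytest.approx(-1.0 - 1.96)
        assert ba.loa_high == pytest.approx(-1.0 + 1.96)

    def test_limits_cover_95pct_of_gaussian_diffs(self, rng):
        x = simulate_paired_series(10_000, 1.0, 0.5, rng=rng)
        ba = bland_altman(x)
        diffs = x[:, 0] - x[:, 1]
        frac = np.mean((diffs >= ba.loa_low) & (diffs <= ba.loa_high))
        assert 0.92 <= frac <= 0.98

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(np.array([[1.0, 2.0]]))


class TestReliabilityTable:
    @staticmethod
    def _table(rng, n=8, groups=("control", "hd")):
        rows = []
        for group in groups:
            for region in ("r1", "r2"):
                for metric in ("FA", "MD"):
                    x = simulate_paired_series(n, 0.8, 0.2, mean=1.0, rng=rng)
                    for i in range(n):
                        for rep in (1, 2):
                            rows.append(
                                {
                                    "subject_id": f"{group}_{i}",
                                    "group": group,
                                    "repeat": rep,
                                    "region": region,
                                    "metric": metric,
                                    "value": x[i, rep - 1],
                                }
                            )
        return pd.DataFrame(rows)

    def test_one_row_per_cell(self, rng):
        df = self._table(rng)
        rel = reliability_table(df)
        assert len(rel) == 2 * 2 * 2
        assert set(rel["group"]) == {"control", "hd"}
        assert (rel["n"] == 8).all()

    def test_identical_groups_identical_results(self, rng):
        df = self._table(rng, groups=("control",))
        clone = df.copy()
        clone["group"] = "hd"
        clone["subject_id"] = clone["subject_id"].str.replace("control", "hd")
        rel = reliability_table(pd.concat([df, clone], ignore_index=True))
        a = rel[rel["group"] == "control"].drop(columns="group").reset_index(drop=True)
        b = rel[rel["group"] == "hd"].drop(columns="group").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_row_order_invariance(self, rng):
        df = self._table(rng)
        rel0 = reliability_table(df)
        rel1 = reliability_table(df.sample(frac=1.0, random_state=1))
        pd.testing.assert_frame_equal(rel0, rel1)

    def test_summary_counts(self):
        iccs = [0.9] * 40 + [0.5] * 8  # 40 of 48 at or above 0.8
        table = pd.DataFrame(
            {
                "region": [f"r{i}" for i in range(48)],
                "metric": "FA",
                "group": "control",
                "n": 12,
                "icc": iccs,
                "ci_low": 0.0,
                "ci_high": 1.0,
                "var_within": 0.1,
                "var_between": 0.9,
            }
        )
        summ = reliability_summary(table)
        row = summ.iloc[0]
        assert row["n_regions"] == 48
        assert row["n_icc_ge_0.8"] == 40
        assert row["pct_icc_ge_0.8"] == pytest.approx(100 * 40 / 48)
        assert row["mean_icc"] == pytest.approx(np.mean(iccs))

    def test_parameter_recovery_large_n(self, rng):
        """With n = 200 and true ICC 0.9, estimates land within ±0.03
        for at least 95% of independent regions."""
        hits = 0
        n_regions = 200
        for _ in range(n_regions):
            x = simulate_paired_series(200, 0.9, 0.1, rng=rng)
            rho = icc(*variance_components(x))
            hits += abs(rho - 0.9) <= 0.03
        assert hits / n_regions >= 0.95

    def test_undefined_written_as_na(self, tmp_path):
        table = pd.DataFrame(
            {
                "region": ["r"], "metric": ["FA"], "group": ["control"], "n": [5],
                "icc": [float("nan")], "ci_low": [float("nan")],
                "ci_high": [float("nan")], "var_within": [0.0], "var_between": [0.0],
            }
        )
        path = tmp_path / "rel.tsv"
        table.to_csv(path, sep="\t", index=False, na_rep="NA")
        assert "NA" in path.read_text()


class TestVoxelwiseIcc:
    def test_identical_streams_give_one(self, rng):
        stack = rng.normal(1.0, 0.3, size=(6, 3, 3, 3))
        icc_map, n_undef = voxelwise_icc(stack, stack.copy())
        assert np.allclose(icc_map, 1.0)
        assert n_undef == 0

    def test_matches_plain_loop(self, rng):
        """Vectorized map equals the scalar pipeline voxel by voxel on 5³."""
        a = rng.normal(1.0, 0.3, size=(8, 5, 5, 5))
        b = a + rng.normal(0, 0.1, size=a.shape)
        icc_map, _ = voxelwise_icc(a, b)
        for idx in np.ndindex(5, 5, 5):
            series = np.column_stack([a[(slice(None),) + idx], b[(slice(None),) + idx]])
            var_b, var_w = variance_components(series)
            assert icc_map[idx] == var_b / (var_b + var_w)

    def test_recovers_regional_ordering(self, rng):
        """Voxels simulated at true ICC 0.8 average higher than ICC 0.4 ones."""
        n = 30
        shape = (4, 4, 2)
        a = np.empty((n,) + shape)
        b = np.empty((n,) + shape)
        half = shape[0] // 2
        for idx in np.ndindex(shape):
            rho = 0.8 if idx[0] < half else 0.4
            x = simulate_paired_series(n, rho, 1 - rho, rng=rng)
            a[(slice(None),) + idx] = x[:, 0]
            b[(slice(None),) + idx] = x[:, 1]
        icc_map, _ = voxelwise_icc(a, b)
        assert icc_map[:half].mean() > icc_map[half:].mean()

    def test_zero_variance_voxels_counted(self):
        a = np.ones((4, 2, 2, 1))
        icc_map, n_undef = voxelwise_icc(a, a.copy())
        assert n_undef == 4
        assert not icc_map.any()

    def test_subject_order_mismatch_rejected(self, rng):
        a = rng.normal(size=(3, 2, 2, 1))
        with pytest.raises(ValueError, match="order"):
            voxelwise_icc(a, a, subject_ids1=["s1", "s2", "s3"],
                          subject_ids2=["s2", "s1", "s3"])


class TestOutlierSensitivity:
    @staticmethod
    def _series(rng, n=10):
        x = simulate_paired_series(n, 1.0, 0.05, rng=rng)
        return PairedSeries(x, tuple(f"s{i}" for i in range(n)))

    def test_discordant_outlier_lowers_icc(self, rng):
        series = self._series(rng)
        vals = series.values.copy()
        spread = np.abs(vals[:, 0] - vals[:, 1]).max()
        vals[0] = [vals[0, 0], vals[0, 0] + 10 * max(spread, 1.0)]
        outlier = PairedSeries(vals, series.subject_ids)
        before, after = outlier_sensitivity(outlier, "s0")
        assert after.icc > before.icc

    def test_drop_then_readd_is_identity(self, rng):
        series = self._series(rng)
        dropped = series.drop("s3")
        restored = PairedSeries(
            np.vstack([dropped.values, series.values[3]]),
            dropped.subject_ids + ("s3",),
        )
        rho0 = reliability_result(series).icc
        rho1 = reliability_result(restored).icc
        assert rho1 == pytest.approx(rho0, abs=1e-12)

    def test_after_matches_direct_recompute(self, rng):
        series = self._series(rng)
        _, after = outlier_sensitivity(series, "s5")
        direct = reliability_result(series.drop("s5"))
        assert after.icc == pytest.approx(direct.icc, abs=1e-15)
        assert after.n == series.n - 1

    def test_too_small_series_rejected(self, rng):
        series = self._series(rng, n=3)
        with pytest.raises(ValueError):
            outlier_sensitivity(series, "s0")
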