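"""Rate estimation, bootstrap CIs, extrapolation, annotation OR, regressions."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from strdnm.rates import (
    annotation_overrepresentation,
    attribute_regression,
    bootstrap_rate_ci,
    estimate_rates,
    extrapolate_expected,
    step_bias_summary,
)


def _elig(rows):
    return pd.DataFrame(rows, columns=["child_id", "motif_length", "n_eligible"])


class TestEstimateRates:
    def test_toy_rate(self):
        calls = pd.DataFrame({"motif_length": [2, 2]})
        elig = _elig([("t1", 2, 60), ("t2", 2, 40)])
        table = estimate_rates(calls, elig).set_index("motif_length")
        assert table.loc[2, "rate"] == pytest.approx(0.02)
        assert table.loc["all", "rate"] == pytest.approx(0.02)

    def test_zero_calls(self):
        table = estimate_rates(pd.DataFrame(), _elig([("t1", 1, 100)]))
        assert (table["rate"] == 0).all()

    def test_dnm_total_preserved_and_order_invariant(self, zero_noise_cohort):
        res = zero_noise_cohort["result"]
        t1 = estimate_rates(res["calls"], res["eligibility"])
        t2 = estimate_rates(
            res["calls"].sample(frac=1.0, random_state=0),
            res["eligibility"].sample(frac=1.0, random_state=1),
        )
        pd.testing.assert_frame_equal(t1, t2)
        assert t1.set_index("motif_length").loc["all", "dnms"] == len(res["calls"])


class TestBootstrap:
    def test_identical_markers_collapse_ci(self):
        mt = pd.DataFrame({"tested_trios": [100] * 20, "dnm_count": [2] * 20})
        out = bootstrap_rate_ci(mt, seed=0)
        assert out["ci_low"] == out["ci_high"] == pytest.approx(0.02)

    def test_seed_reproducibility(self):
        mt = pd.DataFrame(
            {"tested_trios": np.full(50, 100), "dnm_count": np.arange(50) % 3}
        )
        a = bootstrap_rate_ci(mt, seed=42)
        b = bootstrap_rate_ci(mt, seed=42)
        assert (a["ci_low"], a["ci_high"]) == (b["ci_low"], b["ci_high"])

    def test_single_marker_degenerates_with_warning(self):
        mt = pd.DataFrame({"tested_trios": [100], "dnm_count": [3]})
        with pytest.warns(UserWarning):
            out = bootstrap_rate_ci(mt, seed=0)
        assert out["ci_low"] == out["ci_high"] == pytest.approx(0.03)


class TestExtrapolation:
    def test_single_length(self):
        table = pd.DataFrame({"motif_length": [2], "rate": [1e-4]})
        assert extrapolate_expected(table, {2: 100_000}) == pytest.approx(10.0)

    def test_zero_rates(self):
        table = pd.DataFrame({"motif_length": [1, 2], "rate": [0.0, 0.0]})
        assert extrapolate_expected(table, {1: 10, 2: 10}) == 0.0

    def test_homopolymer_exclusion(self):
        table = pd.DataFrame({"motif_length": [1, 2], "rate": [1e-3, 1e-4]})
        n = {1: 1000, 2: 1000}
        assert extrapolate_expected(table, n) == pytest.approx(1.1)
        assert extrapolate_expected(table, n, exclude_homopolymers=True) == pytest.approx(0.1)

    def test_missing_census_rejected(self):
        table = pd.DataFrame({"motif_length": [3], "rate": [1e-4]})
        with pytest.raises(KeyError):
            extrapolate_expected(table, {2: 10})


class TestAnnotationOR:
    def _calls(self, positions):
        return pd.DataFrame({"chrom": "chr1", "start": positions})

    def test_equal_density_is_one(self):
        ann = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        calls = self._calls([100, 500, 1100, 1500])
        assert annotation_overrepresentation(calls, ann, 2000)["odds_ratio"] == pytest.approx(1.0)

    def test_triple_density(self):
        ann = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        calls = self._calls([10, 20, 30, 1500])
        assert annotation_overrepresentation(calls, ann, 2000)["odds_ratio"] == pytest.approx(3.0)

    def test_scale_invariance(self):
        ann = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        calls = self._calls([10, 20, 1500])
        base = annotation_overrepresentation(calls, ann, 4000)["odds_ratio"]
        ann10 = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10_000]})
        calls10 = self._calls([10, 20, 15_000] * 10)
        scaled = annotation_overrepresentation(calls10, ann10, 40_000)["odds_ratio"]
        assert scaled == pytest.approx(base)

    def test_no_outside_calls_infinite(self):
        ann = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        out = annotation_overrepresentation(self._calls([10]), ann, 2000)
        assert np.isinf(out["odds_ratio"])

    def test_zero_annotated_span_rejected(self):
        ann = pd.DataFrame(columns=["chrom", "start", "end"])
        with pytest.raises(ValueError):
            annotation_overrepresentation(self._calls([10]), ann, 2000)


class TestAttributeRegression:
    @staticmethod
    def _table(rng, n=400, rrt_slope=0.04):
        rrt = rng.integers(10, 100, size=n)
        purity = rng.uniform(0.7, 1.0, size=n)
        tested = rng.integers(100, 300, size=n)
        rate = np.exp(-8 + rrt_slope * rrt)
        counts = rng.poisson(rate * tested)
        return pd.DataFrame(
            {
                "motif_length": rng.integers(1, 7, size=n),
                "rrt_length": rrt,
                "gc_content": rng.uniform(0, 1, size=n),
                "purity": purity,
                "tested_trios": tested,
                "dnm_count": counts,
            }
        )

    def test_recovers_positive_rrt_effect(self):
        table = self._table(np.random.default_rng(0))
        out = attribute_regression(table).set_index("term")
        assert out.loc["rrt_length", "estimate"] > 0
        assert out.loc["rrt_length", "p_value"] < 1e-6

    def test_null_slopes_near_zero(self):
        table = self._table(np.random.default_rng(1), rrt_slope=0.0)
        out = attribute_regression(table).set_index("term")
        est, se = out.loc["rrt_length", ["estimate", "std_err"]]
        assert abs(est) < 4 * se

    def test_offset_invariance(self):
        table = self._table(np.random.default_rng(2))
        doubled = table.assign(
            tested_trios=table["tested_trios"] * 2, dnm_count=table["dnm_count"] * 2
        )
        a = attribute_regression(table).set_index("term")["estimate"]
        b = attribute_regression(doubled).set_index("term")["estimate"]
        assert np.allclose(a, b, atol=1e-6)


class TestStepBias:
    def test_pure_expansion(self):
        calls = pd.DataFrame(
            {
                "phase": ["paternal"] * 10,
                "motif_length": 2,
                "step_bp": 2,
                "step_motifs": 1.0,
                "rrt_length": 30,
            }
        )
        out = step_bias_summary(calls)
        row = out["per_motif_length"].iloc[0]
        assert row["mean_abs_motifs_paternal"] == 1.0
        assert (out["per_rrt_bin"]["expansion_fraction"] == 1.0).all()

    def test_maternal_step_inflation_detected(self):
        rng = np.random.default_rng(3)
        n = 5000
        pat = rng.geometric(0.8, size=n)
        mat = rng.geometric(0.55, size=n)
        calls = pd.DataFrame(
            {
                "phase": ["paternal"] * n + ["maternal"] * n,
                "motif_length": 2,
                "step_motifs": np.concatenate([pat, mat]).astype(float),
                "step_bp": np.concatenate([pat, mat]) * 2,
                "rrt_length": rng.integers(10, 100, size=2 * n),
            }
        )
        out = step_bias_summary(calls)["per_motif_length"].iloc[0]
        assert out["mean_abs_motifs_maternal"] > out["mean_abs_motifs_paternal"]
        assert out["mannwhitney_p"] < 0.05
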