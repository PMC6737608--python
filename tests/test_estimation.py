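"""Estimation-layer tests: logistic fits, distributions, PAF composition,
bootstrap intervals."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pafkit
from pafkit import estimation
from pafkit.estimation import CaseControlDataset, ExposureSpec
from pafkit.exceptions import (
    BootstrapFailureError,
    DegenerateLevelError,
    InvalidArgumentError,
)
from pafkit.simulate import SimulationConfig, sample_case_control, simulate_cohort

from conftest import make_2x2


class TestDataset:
    def test_missing_rows_dropped(self):
        df = pd.DataFrame(
            {"y": [1, 1, 0, 0, None], "a": [1, 0, 1, 0, 1], "c": [1, 2, 3, None, 5]}
        )
        ds = CaseControlDataset.from_dataframe(
            df, "y", {"a": ExposureSpec("binary", 0)}, ["c"]
        )
        assert len(ds.df) == 3

    def test_outcome_must_be_binary(self):
        df = pd.DataFrame({"y": [1, 2, 0], "a": [0, 1, 0]})
        with pytest.raises(InvalidArgumentError):
            CaseControlDataset.from_dataframe(df, "y", {"a": ExposureSpec("binary")})

    def test_reference_must_occur(self):
        df = pd.DataFrame({"y": [1, 0], "a": [1, 1]})
        with pytest.raises(InvalidArgumentError):
            CaseControlDataset.from_dataframe(
                df, "y", {"a": ExposureSpec("binary", reference=0)}
            )

    def test_need_both_outcome_groups(self):
        df = pd.DataFrame({"y": [1, 1], "a": [0, 1]})
        with pytest.raises(InvalidArgumentError):
            CaseControlDataset.from_dataframe(df, "y", {"a": ExposureSpec("binary")})


class TestFitExposureModel:
    def test_matches_2x2_closed_form(self, toy_2x2):
        model = pafkit.fit_exposure_model(toy_2x2, "a")
        assert model.betas[1] == pytest.approx(math.log(27 / 7), abs=1e-8)
        assert model.betas[0] == 0.0

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        a=st.integers(5, 200), b=st.integers(5, 200),
        c=st.integers(5, 200), d=st.integers(5, 200),
    )
    def test_unadjusted_fit_equals_closed_form_over_random_tables(self, a, b, c, d):
        ds = make_2x2(a, b, c, d)
        model = pafkit.fit_exposure_model(ds, "a")
        assert model.betas[1] == pytest.approx(
            math.log(a * d / (b * c)), abs=1e-8
        )

    def test_null_association_estimate_near_zero(self):
        rng = np.random.default_rng(42)
        n = 10_000
        df = pd.DataFrame(
            {"y": rng.integers(0, 2, n), "a": rng.integers(0, 2, n)}
        )
        ds = CaseControlDataset.from_dataframe(df, "y", {"a": ExposureSpec("binary", 0)})
        model = pafkit.fit_exposure_model(ds, "a")
        assert abs(model.betas[1]) < 3 * model.beta_se[1]

    def test_recovers_generating_beta_with_confounder_adjustment(self):
        cfg = SimulationConfig.from_dict(
            {**SimulationConfig().to_dict(), "betas": (0.0, 0.5), "seed": 1}
        )
        cohort = simulate_cohort(cfg)
        ds = sample_case_control(cohort, 5000, 5000, seed=1)
        model = pafkit.fit_exposure_model(ds, "a", confounders=["c"])
        assert abs(model.betas[1] - 0.5) < 3 * model.beta_se[1]

    def test_degenerate_level_reported_by_name(self):
        df = pd.DataFrame(
            {
                "y": [1] * 6 + [0] * 6,
                "a": [0, 0, 1, 1, 2, 2, 0, 0, 0, 1, 1, 1],  # level 2 absent in controls
            }
        )
        ds = CaseControlDataset.from_dataframe(
            df, "y", {"a": ExposureSpec("multicategory", 0)}
        )
        with pytest.raises(DegenerateLevelError, match="2"):
            pafkit.fit_exposure_model(ds, "a")


def _continuous_dataset(curve, n=6000, seed=3, x_dist="normal"):
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, n) if x_dist == "normal" else rng.uniform(-2, 2, n)
    p = 1.0 / (1.0 + np.exp(-(-1.2 + curve(x))))
    y = (rng.random(n) < p).astype(int)
    df = pd.DataFrame({"y": y, "x": x})
    return CaseControlDataset.from_dataframe(df, "y", {"x": ExposureSpec("continuous")})


class TestReferenceSelection:
    def test_increasing_curve_picks_lower_trim_quantile(self):
        ds = _continuous_dataset(lambda x: 0.8 * x)
        model = pafkit.fit_exposure_model(ds, "x")
        j0 = pafkit.select_reference_level(model, trim=(0.01, 0.99))
        lo = np.quantile(ds.df["x"], 0.01)
        assert j0 == pytest.approx(lo, abs=1e-9)
        assert float(model.curve(np.array([j0]))[0]) == pytest.approx(0.0, abs=1e-9)

    def test_interior_minimum_of_quadratic_curve(self):
        ds = _continuous_dataset(lambda x: 0.5 * (x - 0.3) ** 2, n=20_000, seed=5)
        model = pafkit.fit_exposure_model(ds, "x")
        j0 = pafkit.select_reference_level(model)
        assert abs(j0 - 0.3) < 0.35  # spline fit + grid resolution

    def test_wrong_kind_rejected(self, toy_2x2):
        model = pafkit.fit_exposure_model(toy_2x2, "a")
        with pytest.raises(InvalidArgumentError):
            pafkit.select_reference_level(model)


class TestDistributions:
    def test_discrete_counting(self, toy_2x2):
        dist = pafkit.control_case_distributions(toy_2x2, "a")
        assert dist.levels == (0, 1)
        assert dist.control_probs == pytest.approx((0.9, 0.1))
        assert dist.case_probs == pytest.approx((0.7, 0.3))

    def test_degenerate_controls_flagged(self):
        df = pd.DataFrame({"y": [1, 1, 0, 0], "a": [0, 1, 0, 0]})
        ds = CaseControlDataset.from_dataframe(
            df, "y", {"a": ExposureSpec("binary", 0)}
        )
        dist = pafkit.control_case_distributions(ds, "a")
        assert dist.degenerate

    def test_continuous_sample_lengths(self):
        ds = _continuous_dataset(lambda x: 0.3 * x, n=500)
        dist = pafkit.control_case_distributions(ds, "x")
        assert len(dist.control_values) == ds.n_controls
        assert len(dist.case_values) == ds.n_cases


class TestEstimatePaf:
    def test_toy_2x2_exact_and_approx(self, toy_2x2):
        r = pafkit.estimate_paf(toy_2x2, "a")
        assert r.exact_paf == pytest.approx(0.3 * (1 - 7 / 27), abs=1e-10)
        assert r.exact_paf == pytest.approx(0.22222, abs=5e-6)
        assert r.approx_paf == pytest.approx(0.1 * math.log(27 / 7), abs=1e-10)
        assert r.approx_paf == pytest.approx(0.13499, abs=5e-6)
        assert r.or_ave == pytest.approx(math.exp(r.beta_ave), abs=1e-12)

    def test_null_data_estimates_near_zero(self):
        rng = np.random.default_rng(7)
        n = 8000
        df = pd.DataFrame({"y": rng.integers(0, 2, n), "a": rng.integers(0, 2, n)})
        ds = CaseControlDataset.from_dataframe(df, "y", {"a": ExposureSpec("binary", 0)})
        r = pafkit.estimate_paf(ds, "a")
        assert abs(r.exact_paf) < 0.05
        assert abs(r.approx_paf) < 0.05

    def test_summary_only_entry_path(self):
        df = pd.DataFrame(
            {"factor": ["Lack of physical activity"], "prevalence": [0.837],
             "beta_ave": [0.501]}
        )
        (r,) = pafkit.frame_to_results(df)
        assert r.approx_paf == pytest.approx(0.41934, abs=5e-6)
        assert round(100 * r.approx_paf, 1) == 41.9

    def test_multicategory_to_binary_recoding_preserves_prevalence(self):
        rng = np.random.default_rng(11)
        n = 4000
        a = rng.choice([0, 1, 2], size=n, p=[0.5, 0.3, 0.2])
        logits = -1.0 + np.array([0.0, 0.4, 0.8])[a]
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
        df = pd.DataFrame({"y": y, "a": a})
        multi = CaseControlDataset.from_dataframe(
            df, "y", {"a": ExposureSpec("multicategory", 0)}
        )
        binary = CaseControlDataset.from_dataframe(
            df.assign(a=(df["a"] > 0).astype(int)), "y",
            {"a": ExposureSpec("binary", 0)},
        )
        r_multi = pafkit.estimate_paf(multi, "a")
        r_binary = pafkit.estimate_paf(binary, "a")
        assert r_multi.control_prevalence == pytest.approx(
            r_binary.control_prevalence, abs=1e-12
        )

    def test_continuous_pipeline_recovers_linear_beta_ave(self):
        """Data generated with a linear log-odds curve: the spline pipeline's
        averaged log-OR matches the analytic value slope * E[x - q01(x) | control]."""
        slope = 0.4
        errors = []
        for seed in range(5):
            ds = _continuous_dataset(lambda x: slope * x, n=10_000, seed=seed)
            r = pafkit.estimate_paf(ds, "x")
            assert r.control_prevalence == 1.0
            assert r.exact_paf < 1.0
            controls = ds.df.loc[ds.df["y"] == 0, "x"]
            target = slope * float(
                (controls - np.quantile(ds.df["x"], 0.01)).mean()
            )
            errors.append(r.beta_ave - target)
        # single-seed MC SE is about 0.14 (anchor noise at the 1% quantile);
        # 3 SE of the 5-seed mean is about 0.2
        assert abs(np.mean(errors)) < 0.2


class TestBootstrap:
    def test_same_seed_reproducible(self, toy_2x2):
        ci1 = pafkit.bootstrap_ci(toy_2x2, "a", n_reps=99, level=0.95, seed=5)
        ci2 = pafkit.bootstrap_ci(toy_2x2, "a", n_reps=99, level=0.95, seed=5)
        assert ci1.exact == ci2.exact
        assert ci1.approx == ci2.approx

    def test_levels_are_nested_for_same_stream(self, toy_2x2):
        wide = pafkit.bootstrap_ci(toy_2x2, "a", n_reps=199, level=0.99, seed=3)
        narrow = pafkit.bootstrap_ci(toy_2x2, "a", n_reps=199, level=0.95, seed=3)
        assert wide.exact[0] <= narrow.exact[0] <= narrow.exact[1] <= wide.exact[1]
        assert wide.approx[0] <= narrow.approx[0] <= narrow.approx[1] <= wide.approx[1]

    def test_separated_data_raises_bootstrap_failure(self):
        # exposure identical within each outcome group: the logistic MLE
        # does not exist (perfect separation), so every refit fails
        df = pd.DataFrame({"y": [1] * 20 + [0] * 20, "a": [1] * 20 + [0] * 20})
        ds = CaseControlDataset.from_dataframe(
            df, "y", {"a": ExposureSpec("binary", 0)}
        )
        from pafkit.exceptions import FitFailureError

        with pytest.raises(
            (BootstrapFailureError, FitFailureError, DegenerateLevelError)
        ):
            pafkit.bootstrap_ci(ds, "a", n_reps=20, seed=0)

    def test_invalid_settings_rejected(self, toy_2x2):
        with pytest.raises(InvalidArgumentError):
            pafkit.bootstrap_ci(toy_2x2, "a", n_reps=1, seed=0)
        with pytest.raises(InvalidArgumentError):
            pafkit.bootstrap_ci(toy_2x2, "a", n_reps=10, level=1.2, seed=0)

    def test_estimate_paf_attaches_interval(self, toy_2x2):
        r = pafkit.estimate_paf(toy_2x2, "a", n_boot=99, ci_level=0.95, seed=2)
        assert r.ci_lower is not None and r.ci_upper is not None
        assert r.ci_lower <= r.exact_paf <= r.ci_upper


class TestSummaryIO:
    def test_round_trip_ranked_by_approx_paf(self, tmp_path, stroke_results):
        path = tmp_path / "summary.csv"
        pafkit.write_summary_csv(stroke_results, path)
        df = pafkit.read_summary_csv(path)
        assert list(df.columns) == estimation.SUMMARY_COLUMNS
        assert (df["approx_paf"].diff().dropna() <= 1e-12).all()

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("factor,prevalence,beta_ave\n")
        with pytest.raises(InvalidArgumentError, match="no rows"):
            pafkit.read_summary_csv(path)

    def test_missing_columns_named(self):
        with pytest.raises(InvalidArgumentError, match="beta_ave"):
            pafkit.frame_to_results(pd.DataFrame({"factor": ["x"], "prevalence": [0.5]}))
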