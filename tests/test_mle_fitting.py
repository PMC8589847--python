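import numpy as np
import pytest

import pollenflow as pf
from pollenflow.mle_fitting import auto_init, threefold_partition
from pollenflow.models import DispersalModelSpec

from conftest import make_dataset

# reference truths for simulation studies: posterior-mean estimates of the
# four ZIP variants; Poisson variants share the kernel parameters
RECOVERY_TRUTHS = {
    "ZExpoB": {"K_e": 0.6760, "a1": 0.6073, "a2": 0.0506, "D": 2.8480,
               "k": 0.3552, "b1": 2.7621, "b2": 0.0275},
    "ZExpoN": {"K_e": 0.8318, "a1": 0.6823, "a2": 0.0781, "D": 3.3954,
               "b1": 2.5743, "b2": 0.0086},
    "ZCauchyB": {"beta": 1.1000, "c1": 0.2832, "k": 0.0632, "D": 3.5803,
                 "b1": 2.7795, "b2": 0.0266},
    "ZCauchyN": {"beta": 1.3608, "c1": 0.1467, "D": 2.4030,
                 "b1": 3.0979, "b2": 0.0927},
}
for _z, _p in [("ZExpoB", "PExpoB"), ("ZExpoN", "PExpoN"),
               ("ZCauchyB", "PCauchyB"), ("ZCauchyN", "PCauchyN")]:
    RECOVERY_TRUTHS[_p] = {
        k: v for k, v in RECOVERY_TRUTHS[_z].items() if k not in ("b1", "b2")
    }

# parameters whose truth carries no usable signal at this design and are
# therefore excluded from the recovery bound: ZExpoN's logistic slope
# (0.0086/m) moves q_s by < 0.15 over the whole 60 m transect, i.e. the
# likelihood is nearly flat in b2
WEAKLY_IDENTIFIED = {("ZExpoN", "b2")}


class TestFitMle:
    def test_metric_identities(self, small_suite_zexpob_fit):
        fit = small_suite_zexpob_fit
        assert fit.deviance == pytest.approx(-2 * fit.log_likelihood, rel=1e-12)
        assert fit.aic == pytest.approx(fit.deviance + 2 * fit.spec.n_params, rel=1e-12)
        assert fit.spec.n_params == 7  # ZExpoB: K_e, a1, a2, D, k, b1, b2

    def test_refit_from_optimum_is_fixed_point(self, small_suite, small_suite_zexpob_fit):
        refit = pf.fit_mle(
            small_suite, "ZExpoB", init=small_suite_zexpob_fit.estimates, n_starts=1
        )
        assert refit.log_likelihood >= small_suite_zexpob_fit.log_likelihood - 1e-4

    def test_truth_likelihood_not_above_optimum(self, small_suite, small_suite_zexpob_fit):
        from pollenflow.synthetic_data import SUITE_TRUTH_PARAMS

        spec = DispersalModelSpec.from_code("ZExpoB")
        ll_truth = pf.log_likelihood(small_suite, spec, SUITE_TRUTH_PARAMS)
        assert small_suite_zexpob_fit.log_likelihood >= ll_truth

    def test_empty_dataset_errors(self):
        ds = make_dataset([("A", "g1", 1.0, 0.0, 1)]).subset([])
        with pytest.raises(ValueError):
            pf.fit_mle(ds, "PExpoN")

    def test_unknown_code_errors(self, toy_dataset):
        with pytest.raises(ValueError, match="model code"):
            pf.fit_mle(toy_dataset, "ZExpoX")

    def test_auto_init_covers_all_parameters(self, small_suite):
        for code in pf.MODEL_CODES:
            spec = DispersalModelSpec.from_code(code)
            init = auto_init(small_suite, spec)
            assert set(spec.param_names) <= set(init)
            packed = spec.pack(init)
            assert np.all(np.isfinite(spec.to_unconstrained(packed)))


class TestFitMetrics:
    def test_r_squared_one_for_perfect_prediction(self, small_suite, small_suite_zexpob_fit):
        """Replace observations with their model predictions: R^2 -> 1."""
        fit = small_suite_zexpob_fit
        pred = fit.spec.mean_counts(small_suite, fit.estimates)
        perfect = small_suite.df.copy()
        perfect["cp_grains"] = np.round(pred).astype(int)
        # rounding leaves sub-grain discrepancies only
        ds = pf.Dataset(df=perfect, k_grains=small_suite.k_grains)
        _, _, r2 = pf.fit_metrics(fit, ds)
        assert r2 == pytest.approx(1.0, abs=5e-3)

    def test_r_squared_none_for_constant_observations(self, small_suite_zexpob_fit):
        ds = make_dataset(
            [("A", f"g{i}", 1.0 + i, 0.0, 7) for i in range(4)]
        )
        _, _, r2 = pf.fit_metrics(small_suite_zexpob_fit, ds)
        assert r2 is None


class TestPredictiveR:
    def _fit(self, small_suite_zexpob_fit):
        return small_suite_zexpob_fit

    def test_perfect_predictions_give_r_one(self, small_suite, small_suite_zexpob_fit):
        fit = small_suite_zexpob_fit
        pred = fit.spec.mean_counts(small_suite, fit.estimates)
        perfect = small_suite.df.copy()
        perfect["cp_grains"] = np.round(pred).astype(int)
        ds = pf.Dataset(df=perfect, k_grains=small_suite.k_grains)
        assert pf.predictive_r(fit, ds) == pytest.approx(1.0, abs=1e-3)

    def test_affine_invariance(self, small_suite, small_suite_zexpob_fit):
        """r is unchanged by an affine (positive-slope) map of the data."""
        fit = small_suite_zexpob_fit
        pred = fit.spec.mean_counts(small_suite, fit.estimates)
        df = small_suite.df.copy()
        df["cp_grains"] = np.round(10 + 0.5 * pred).astype(int)
        ds = pf.Dataset(df=df, k_grains=small_suite.k_grains)
        assert pf.predictive_r(fit, ds) == pytest.approx(1.0, abs=1e-3)

    def test_needs_three_grids(self, small_suite, small_suite_zexpob_fit):
        two_grids = small_suite.subset(range(8))  # 2 grids x 4 cobs
        with pytest.raises(ValueError, match="3 validation grids"):
            pf.predictive_r(small_suite_zexpob_fit, two_grids)


class TestThreefoldPartition:
    def _nine_obs(self):
        rows = []
        for g, dist in enumerate([1.0, 2.0, 3.0]):
            for c in range(3):
                rows.append(("A", f"g{g}", dist, 0.0, c))
        return make_dataset(rows)

    def test_balanced_groups_split_one_per_fold(self):
        ds = self._nine_obs()
        folds = threefold_partition(ds, seed=5)
        for fold in folds:
            assert len(fold) == 3
            # one observation from each distance group
            assert sorted(ds.df.iloc[fold]["distance_m"]) == [1.0, 2.0, 3.0]

    def test_folds_partition_the_dataset(self, small_suite):
        folds = threefold_partition(small_suite, seed=1)
        union = np.concatenate(folds)
        assert len(union) == len(small_suite)
        assert len(np.unique(union)) == len(small_suite)

    def test_seed_determinism(self, small_suite):
        a = threefold_partition(small_suite, seed=3)
        b = threefold_partition(small_suite, seed=3)
        c = threefold_partition(small_suite, seed=4)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert any(not np.array_equal(x, y) for x, y in zip(a, c))

    def test_small_group_errors(self):
        ds = make_dataset(
            [("A", "g1", 1.0, 0.0, 1), ("A", "g1", 1.0, 0.0, 2), ("A", "g2", 2.0, 0.0, 0)]
        )
        with pytest.raises(ValueError, match="fewer than 3"):
            threefold_partition(ds, seed=0)


@pytest.fixture(scope="module")
def report(small_suite):
    return pf.crossval_threefold(small_suite, "ZExpoB", seed=7, n_starts=2)


class TestCrossval:
    def test_three_folds_with_metrics(self, report):
        assert len(report.per_fold) == 3
        for fold in report.per_fold:
            assert fold["aic"] == pytest.approx(
                fold["deviance"] + 2 * report.spec.n_params
            )
            assert -1 <= fold["r_validation"] <= 1

    def test_summary_shape(self, report):
        s = report.summary
        assert set(s["metric"]) == {"aic", "deviance", "r_squared", "r_validation"}
        assert np.all(np.isfinite(s["mean"]))
        assert np.all(s["sd"] >= 0)

    def test_validation_recovers_truth_signal(self, report):
        # data simulated from the fitted family: held-out r should be high
        assert report.mean("r_validation") > 0.8


class TestParameterRecovery:
    """Simulation-based recovery for every model variant.

    Each variant is simulated under its own reference truth at a design
    comparable to the emulated field study (every 2nd row, 10 cobs per
    grid) and refitted; the median relative error over 20 seeded
    replicates must stay within 15% for every identifiable parameter.
    """

    @pytest.mark.parametrize("code", pf.MODEL_CODES)
    def test_median_relative_error(self, code):
        spec = DispersalModelSpec.from_code(code)
        truth = RECOVERY_TRUTHS[code]
        errors = {name: [] for name in spec.param_names}
        for rep in range(20):
            parts = pf.paper_scale_suite(
                seed=1000 + rep, truth_spec=spec, truth_params=truth,
                row_stride=2, cobs_per_grid=10,
            )
            ds = parts[0].concat(parts[1]).concat(parts[2])
            fit = pf.fit_mle(ds, spec, seed=rep, n_starts=2)
            for name in spec.param_names:
                errors[name].append(
                    abs(fit.estimates[name] - truth[name]) / abs(truth[name])
                )
        medians = {name: float(np.median(v)) for name, v in errors.items()}
        for name, med in medians.items():
            if (code, name) in WEAKLY_IDENTIFIED:
                continue
            assert med <= 0.15, f"{code} {name}: median rel. error {med:.3f}"
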