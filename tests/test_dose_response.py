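"""Normalization, truncation and multistart logistic fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corspec.dose_response import (
    FitConfig,
    FoldActivationSeries,
    Logistic3Params,
    Logistic4Params,
    estimate_ec50,
    eval_logistic3,
    eval_logistic4,
    fit_dose_response,
    fit_measurement_table,
    normalize_to_vehicle,
    truncate_at_max_mean,
)
from corspec.errors import (
    DegenerateBaselineError,
    InputError,
    MissingBaselineError,
    NoActivationError,
)
from corspec.simulate import DoseResponseSimConfig, simulate_dose_response


def _raw(construct="r", rows=()):
    return pd.DataFrame(
        [(construct, lig, d, i + 1, v) for i, (lig, d, v) in enumerate(rows)],
        columns=["construct", "ligand", "dose_molar", "replicate", "luminescence"],
    )


def _series(doses, reps_per_dose, construct="r", ligand="l"):
    return FoldActivationSeries(
        construct=construct,
        ligand=ligand,
        points=tuple((d, tuple(r)) for d, r in zip(doses, reps_per_dose)),
    )


class TestNormalize:
    def test_division_by_vehicle_mean(self):
        raw = _raw(rows=[("veh", 0, 95), ("veh", 0, 105), ("aldo", 1e-8, 300), ("aldo", 1e-8, 330)])
        (series,) = normalize_to_vehicle(raw)
        assert series.points == ((1e-8, (3.0, 3.3)),)

    def test_treatment_equal_to_baseline_gives_fold_one(self):
        raw = _raw(rows=[("veh", 0, 100), ("x", 1e-9, 100)])
        (series,) = normalize_to_vehicle(raw)
        assert series.points[0][1] == (1.0,)

    def test_vehicle_rows_consumed_and_mean_fold_one_when_self_normalized(self):
        cfg = DoseResponseSimConfig(noise_cv=0, seed=0)
        raw = simulate_dose_response(cfg)
        series = normalize_to_vehicle(raw)
        assert all(s.ligand != "vehicle" for s in series)
        # vehicle luminescence / vehicle mean == 1 by construction
        veh = raw.loc[raw["dose_molar"] == 0, "luminescence"]
        assert np.isclose((veh / veh.mean()).mean(), 1.0)

    def test_missing_vehicle_rows_raise(self):
        with pytest.raises(MissingBaselineError):
            normalize_to_vehicle(_raw(rows=[("aldo", 1e-8, 300)]))

    def test_nonpositive_vehicle_mean_raises(self):
        with pytest.raises(DegenerateBaselineError):
            normalize_to_vehicle(_raw(rows=[("veh", 0, 0.0), ("aldo", 1e-8, 300)]))

    def test_multiple_constructs_rejected(self):
        df = pd.concat([_raw("a", [("v", 0, 1), ("x", 1e-9, 2)]),
                        _raw("b", [("v", 0, 1), ("x", 1e-9, 2)])])
        with pytest.raises(InputError, match="one construct"):
            normalize_to_vehicle(df)


class TestTruncate:
    def test_doses_above_maximum_mean_are_excluded(self):
        s = _series([1e-10, 1e-9, 1e-8, 1e-7], [(1.2,), (2.0,), (6.0,), (5.1,)])
        out, d_max, excluded = truncate_at_max_mean(s)
        assert d_max == 1e-8
        assert excluded == (1e-7,)
        assert [d for d, _ in out.points] == [1e-10, 1e-9, 1e-8]

    def test_monotone_series_passes_through(self):
        s = _series([1e-10, 1e-9, 1e-8], [(1.0,), (2.0,), (3.0,)])
        out, d_max, excluded = truncate_at_max_mean(s)
        assert out == s and d_max == 1e-8 and excluded == ()

    def test_tied_maximum_keeps_both_tied_doses(self):
        s = _series([1e-10, 1e-9, 1e-8], [(1.0,), (5.0,), (5.0,)])
        out, d_max, excluded = truncate_at_max_mean(s)
        assert d_max == 1e-8 and excluded == ()
        assert len(out.points) == 3

    def test_idempotence_and_subset(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            doses = np.sort(rng.choice(np.logspace(-11, -6, 12), size=6, replace=False))
            s = _series(doses, [tuple(rng.uniform(0.5, 8, size=3)) for _ in doses])
            once, d1, _ = truncate_at_max_mean(s)
            twice, d2, excl2 = truncate_at_max_mean(once)
            assert set(once.points) <= set(s.points)
            assert twice == once and d1 == d2 and excl2 == ()


class TestLogisticForms:
    def test_midpoint_and_baseline_and_arithmetic(self):
        p = Logistic3Params(beta1=5, beta2=1e-9, beta3=1)
        assert eval_logistic3(p, 1e-9) == pytest.approx(3.0)
        assert eval_logistic3(p, 0.0) == 1.0
        assert eval_logistic3(p, 3e-9) == pytest.approx(5 + (1 - 5) / (1 + 3))

    @given(
        beta1=st.floats(0.1, 50),
        beta2=st.floats(1e-12, 1e-4),
        beta3=st.floats(0.05, 10),
    )
    def test_zero_dose_response_fixed_at_one(self, beta1, beta2, beta3):
        assert eval_logistic3(Logistic3Params(beta1, beta2, beta3), 0.0) == 1.0

    def test_four_parameter_form(self):
        p = Logistic4Params(beta0=2, beta1=8, beta2=1e-8, beta3=2)
        assert eval_logistic4(p, 0.0) == 2.0
        assert eval_logistic4(p, 1e-8) == pytest.approx(5.0)  # (beta0+beta1)/2

    @given(
        beta1=st.floats(0.1, 50),
        beta2=st.floats(1e-12, 1e-4),
        beta3=st.floats(0.05, 10),
        dose=st.floats(0, 1e-5),
    )
    def test_4pl_with_unit_baseline_nests_3pl(self, beta1, beta2, beta3, dose):
        p3 = Logistic3Params(beta1, beta2, beta3)
        p4 = Logistic4Params(1.0, beta1, beta2, beta3)
        assert eval_logistic4(p4, dose) == eval_logistic3(p3, dose)


def _noiseless_series(beta1, beta2, beta3, n_reps=3, beta0=1.0):
    cfg = DoseResponseSimConfig(
        beta0=beta0, beta1=beta1, beta2=beta2, beta3=beta3, noise_cv=0, n_reps=n_reps
    )
    (series,) = normalize_to_vehicle(simulate_dose_response(cfg))
    return series


class TestFit:
    def test_noiseless_3pl_recovery_to_1e6_relative(self):
        true = (6.0, 5e-9, 1.2)
        series = _noiseless_series(*true)
        fit = fit_dose_response(series)
        p = fit.params
        assert p.beta1 == pytest.approx(true[0], rel=1e-6)
        assert p.beta2 == pytest.approx(true[1], rel=1e-6)
        assert p.beta3 == pytest.approx(true[2], rel=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_4pl_recovery(self):
        series = _noiseless_series(6.0, 2e-8, 1.0, beta0=1.5)
        fit = fit_dose_response(series, model_kind="4PL")
        p = fit.params
        assert p.beta0 == pytest.approx(1.5, rel=1e-4)
        assert p.beta2 == pytest.approx(2e-8, rel=1e-4)

    def test_4pl_with_near_unit_baseline_matches_3pl(self):
        series = _noiseless_series(6.0, 5e-9, 1.2)
        ec3 = estimate_ec50(fit_dose_response(series, "3PL"))
        ec4 = estimate_ec50(fit_dose_response(series, "4PL"))
        assert ec4 == pytest.approx(ec3, rel=1e-3)

    def test_flat_series_flags_no_activation(self):
        s = _series([1e-10, 1e-9, 1e-8, 1e-7], [(1.0, 1.0)] * 4)
        fit = fit_dose_response(s)
        assert fit.no_activation and not fit.converged
        with pytest.raises(NoActivationError):
            estimate_ec50(fit)

    def test_best_of_starts_rss_dominance(self):
        rng = np.random.default_rng(2)
        cfg = DoseResponseSimConfig(beta1=6, beta2=5e-9, beta3=1.2, noise_cv=0.15)
        (series,) = normalize_to_vehicle(simulate_dose_response(cfg, rng=rng))
        exact = FitConfig(rss_tie_rel=0.0)
        multi = fit_dose_response(series, config=exact)
        max_mean = series.mean_by_dose().max()
        for b1 in (2.0, max_mean, 2 * max_mean):
            for q in (0.25, 0.5, 0.75):
                for b3 in (0.5, 1.0, 2.0):
                    single = FitConfig(
                        beta1_starts=(b1,), beta2_quantiles=(q,), beta3_starts=(b3,),
                        rss_tie_rel=0.0,
                    )
                    one = fit_dose_response(series, config=single)
                    assert multi.rss <= one.rss + 1e-9

    def test_ec50_unit_conversion(self):
        series = _noiseless_series(6.0, 2e-10, 1.0)
        fit = fit_dose_response(series)
        assert estimate_ec50(fit, unit="nM") == pytest.approx(0.20, rel=1e-5)
        assert estimate_ec50(fit, unit="molar") == pytest.approx(2e-10, rel=1e-5)

    def test_too_few_observations_rejected(self):
        s = _series([1e-9, 1e-8], [(2.0,), (5.0,)])
        with pytest.raises(InputError, match="observations"):
            fit_dose_response(s)

    def test_fit_means_option(self):
        series = _noiseless_series(6.0, 5e-9, 1.2)
        fit = fit_dose_response(series, config=FitConfig(fit_means=True))
        assert fit.params.beta2 == pytest.approx(5e-9, rel=1e-6)


class TestFitTable:
    def test_end_to_end_table_with_truncation(self):
        frames = []
        for ligand, ec50 in [("aldosterone", 2e-10), ("cortisol", 2e-9)]:
            cfg = DoseResponseSimConfig(
                construct="mouse_MR", ligand=ligand, beta2=ec50, noise_cv=0,
                tox_dose=5e-7, tox_shape=3,
            )
            frames.append(simulate_dose_response(cfg))
        raw = pd.concat(frames, ignore_index=True).drop_duplicates(
            subset=["construct", "ligand", "dose_molar", "replicate"]
        )
        table, results = fit_measurement_table(raw)
        assert set(table["ligand"]) == {"aldosterone", "cortisol"}
        aldo = table.set_index("ligand").loc["aldosterone"]
        assert aldo["ec50_nM"] == pytest.approx(0.20, rel=0.05)
        # the cytotoxic decline at the top dose triggers the exclusion rule
        assert any(r.excluded_doses for r in results)

    def test_vehicle_only_table_rejected(self):
        raw = _raw(rows=[("veh", 0, 100), ("veh", 0, 101)])
        with pytest.raises(InputError, match="treatment"):
            fit_measurement_table(raw)
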