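"""Calibrated Kd inference and the equilibrium oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from curlikin import (
    TitrationReplicate,
    abundance_ratio,
    aggregate_kd,
    equilibrium_complex,
    estimate_kd,
    fit_response_calibration,
    generate_titration_dataset,
    kd_from_ratio,
)
from curlikin.binding import ResponseCalibrator
from curlikin.errors import CalibrationError, MassBalanceError, SaturationError
from curlikin.synth import NoiseModel


class TestResponseCalibration:
    def test_exact_line_through_origin(self):
        cal = fit_response_calibration([(5, 1000), (10, 2000), (20, 4000), (40, 8000)])
        assert cal.slope == pytest.approx(200.0)
        assert cal.r_squared == pytest.approx(1.0)

    def test_all_zero_abundances_rejected(self):
        with pytest.raises(CalibrationError):
            fit_response_calibration([(5, 0), (10, 0), (20, 0)])

    def test_too_few_points_rejected(self):
        with pytest.raises(CalibrationError):
            fit_response_calibration([(5, 1000), (10, 2000)])

    def test_correction_equalizes_equal_concentrations(self):
        # two proteins, slopes 200 and 100: same true concentration maps to
        # the same corrected abundance
        cal_a = fit_response_calibration([(c, 200 * c) for c in (5, 10, 20)])
        cal_b = fit_response_calibration([(c, 100 * c) for c in (5, 10, 20)])
        assert cal_a.to_concentration(200 * 15.0) == pytest.approx(
            cal_b.to_concentration(100 * 15.0)
        )

    def test_free_intercept_mode(self):
        est = ResponseCalibrator(fit_intercept=True).fit(
            [5, 10, 20, 40], [1100, 2100, 4100, 8100]
        )
        assert est.slope_ == pytest.approx(200.0)
        assert est.intercept_ == pytest.approx(100.0)


class TestAbundanceRatio:
    def test_plain_division(self):
        assert abundance_ratio(4990.0, 100.0) == pytest.approx(100.0 / 4990.0)

    def test_zero_free_p1_saturation_error(self):
        with pytest.raises(SaturationError):
            abundance_ratio(0.0, 10.0)

    def test_calibration_cancels_when_complex_uses_p1_response(self):
        cal = fit_response_calibration([(c, 321 * c) for c in (5, 10, 20)])
        raw_ratio = abundance_ratio(500.0, 25.0)
        assert abundance_ratio(500.0, 25.0, cal) == pytest.approx(raw_ratio)


class TestKdFromRatio:
    @pytest.mark.parametrize(
        "kd,p1,p2", [(489.0, 10.0, 10.0), (429.0, 20.0, 20.0)]
    )
    def test_reproduces_replicate_kds_through_inversion(self, kd, p1, p2):
        """Forward ratio from the equilibrium oracle returns the printed Kd."""
        cx, p1_eq, _ = equilibrium_complex(kd, p1, p2)
        r = cx / p1_eq
        assert kd_from_ratio(r, p1, p2) == pytest.approx(kd, abs=0.5)

    def test_first_replicate_worked_ratio(self):
        # (10, 10) uM at Kd 489: complex ~ 0.1965 uM, R ~ 0.020048
        cx, p1_eq, _ = equilibrium_complex(489.0, 10.0, 10.0)
        assert cx == pytest.approx(0.1965, abs=5e-4)
        assert cx / p1_eq == pytest.approx(0.020048, abs=5e-6)

    def test_tight_binding_limit(self):
        assert kd_from_ratio(1e9, 10.0, 10.0) == pytest.approx(0.0, abs=1e-6)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            kd_from_ratio(0.0, 10.0, 10.0)

    def test_mass_balance_violation_named(self):
        # R so large that implied complex exceeds available P2
        with pytest.raises(MassBalanceError):
            kd_from_ratio(50.0, 100.0, 10.0)

    def test_monotone_decreasing_in_r(self):
        rs = np.linspace(0.005, 0.5, 40)
        kds = [kd_from_ratio(r, 10.0, 10.0) for r in rs]
        assert all(a > b for a, b in zip(kds, kds[1:]))

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        kd=st.floats(min_value=1.0, max_value=1e4),
        conc=st.sampled_from([(10.0, 10.0), (20.0, 20.0)]),
    )
    def test_round_trip_is_exact(self, kd, conc):
        """equilibrium -> R -> kd_from_ratio is an algebraic identity."""
        p1_0, p2_0 = conc
        cx, p1_eq, _ = equilibrium_complex(kd, p1_0, p2_0)
        r = cx / p1_eq
        assert kd_from_ratio(r, p1_0, p2_0) == pytest.approx(kd, rel=1e-9)


class TestEquilibriumComplex:
    def test_zero_kd_binds_limiting_protein_fully(self):
        cx, p1_eq, p2_eq = equilibrium_complex(0.0, 10.0, 20.0)
        assert cx == pytest.approx(10.0)
        assert p1_eq == pytest.approx(0.0, abs=1e-12)
        assert p2_eq == pytest.approx(10.0)

    def test_weak_binding_limit(self):
        cx, _, _ = equilibrium_complex(1e12, 10.0, 10.0)
        assert cx == pytest.approx(0.0, abs=1e-6)

    def test_mass_balance_holds(self):
        cx, p1_eq, p2_eq = equilibrium_complex(100.0, 15.0, 25.0)
        assert cx + p1_eq == pytest.approx(15.0)
        assert cx + p2_eq == pytest.approx(25.0)
        assert p1_eq * p2_eq / cx == pytest.approx(100.0)


class TestAggregateKd:
    def test_table_replicate_arithmetic(self):
        # five replicate Kds: plain mean 435.8, sample SD ~ 94.54
        est = aggregate_kd([489, 298, 429, 551, 412])
        assert est.mean == pytest.approx(435.8)
        assert est.sd == pytest.approx(94.476, abs=0.01)
        assert est.n == 5

    def test_single_value(self):
        est = aggregate_kd([489.0])
        assert est.mean == 489.0
        assert math.isnan(est.sd)

    def test_identical_values_zero_sd(self):
        assert aggregate_kd([400.0] * 3).sd == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_kd([])


class TestTitrationRoundTrip:
    def test_noiseless_unit_response_recovers_kd_exactly(self):
        ds = generate_titration_dataset(true_kd=416.0)
        reps = [
            TitrationReplicate(r.p1_0_uM, r.p2_0_uM, r.ab_p1, r.ab_complex)
            for r in ds.table.itertuples()
        ]
        est = estimate_kd(reps)
        assert est.mean == pytest.approx(416.0, rel=1e-12)
        assert est.sd == pytest.approx(0.0, abs=1e-9)

    def test_response_factors_cancel_after_calibration(self):
        """2:1 response, corrected through a fitted calibration, gives the
        same R (hence Kd) as unit response."""
        ds = generate_titration_dataset(true_kd=300.0, response={"p1": 2.0, "p2": 1.0})
        cal = fit_response_calibration([(c, 2.0 * c) for c in (5, 10, 20, 40)])
        row = ds.table.iloc[0]
        r_cal = abundance_ratio(row.ab_p1, row.ab_complex, cal)
        ds_unit = generate_titration_dataset(true_kd=300.0)
        row_u = ds_unit.table.iloc[0]
        r_unit = abundance_ratio(row_u.ab_p1, row_u.ab_complex)
        assert r_cal == pytest.approx(r_unit, rel=1e-12)

    def test_kd_invariant_to_global_response_rescaling(self):
        for c in (0.5, 1.0, 7.3):
            ds = generate_titration_dataset(
                true_kd=500.0, response={"p1": 2.0 * c, "p2": 1.0 * c}
            )
            reps = [
                TitrationReplicate(r.p1_0_uM, r.p2_0_uM, r.ab_p1, r.ab_complex)
                for r in ds.table.itertuples()
            ]
            assert estimate_kd(reps).mean == pytest.approx(500.0, rel=1e-12)

    def test_seeded_dataset_reproducible(self):
        noise = NoiseModel.multiplicative(0.05, seed=42)
        a = generate_titration_dataset(true_kd=416.0, noise=noise)
        b = generate_titration_dataset(true_kd=416.0, noise=noise)
        assert a.table.equals(b.table)

    def test_noisy_recovery_within_15_percent(self):
        """5% multiplicative abundance noise, 3 replicates x 2 pairs."""
        ds = generate_titration_dataset(
            true_kd=416.0, noise=NoiseModel.multiplicative(0.05, seed=7)
        )
        reps = [
            TitrationReplicate(r.p1_0_uM, r.p2_0_uM, r.ab_p1, r.ab_complex)
            for r in ds.table.itertuples()
        ]
        est = estimate_kd(reps)
        assert abs(est.mean - 416.0) / 416.0 < 0.15

    def test_nonpositive_kd_rejected(self):
        with pytest.raises(ValueError):
            generate_titration_dataset(true_kd=0.0)
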