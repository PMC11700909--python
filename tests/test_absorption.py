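"""Saturable absorption model: closed form vs root-finder, monotonicity, limits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zincabs import (
    CovariateSpec,
    IntakeRecord,
    ModelParams,
    Sex,
    absorb_cohort,
    absorb_frame,
    absorb_record,
    effective_params,
    faz,
    taz_closed_form,
    validate_covariate_spec,
)
from zincabs.intake import records_to_frame

positive = st.floats(0.01, 10.0)


def bisect_taz(tdz: float, tdp: float, p: ModelParams, tol: float = 1e-12) -> float:
    """Independent oracle: bisection on the equilibrium quadratic.

    g(a) = a^2 - B a + a_max * tdz has g(0) >= 0 and g(min(a_max, tdz)) <= 0,
    so the physical (lower) root is bracketed by [0, min(a_max, tdz)].
    """
    b = p.a_max + tdz + p.k_r * (1.0 + tdp / p.k_p)
    lo, hi = 0.0, min(p.a_max, tdz)
    g = lambda a: a * a - b * a + p.a_max * tdz
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


class TestClosedForm:
    def test_zero_intake_absorbs_nothing(self, unit_params):
        assert taz_closed_form(0.0, 0.0, unit_params) == 0.0
        assert taz_closed_form(0.0, 5.0, unit_params) == 0.0

    def test_unit_parameter_value(self, unit_params):
        expected = 0.5 * (3.0 - np.sqrt(5.0))  # 0.381966...
        assert taz_closed_form(1.0, 0.0, unit_params) == pytest.approx(expected, abs=1e-12)

    def test_saturation_approaches_a_max(self, unit_params):
        assert taz_closed_form(1000.0, 0.0, unit_params) == pytest.approx(0.999, abs=1e-3)
        taz = taz_closed_form(1e4 * unit_params.a_max, 0.0, unit_params)
        assert abs(taz - unit_params.a_max) / unit_params.a_max < 1e-3

    def test_matches_bisection_oracle_on_grid(self, rng):
        """Closed form equals an independent root-finder to 1e-9 mmol."""
        tdz_grid = np.linspace(0.001, 2.0, 50)
        tdp_grid = np.linspace(0.0, 5.0, 50)
        for _ in range(20):
            p = ModelParams(*rng.uniform(0.02, 2.0, size=3))
            for tdz in tdz_grid[::7]:
                for tdp in tdp_grid[::7]:
                    assert taz_closed_form(tdz, tdp, p) == pytest.approx(
                        bisect_taz(tdz, tdp, p), abs=1e-9
                    )
            # full grid vectorised against the oracle at a coarser tolerance
            zz, pp = np.meshgrid(tdz_grid, tdp_grid)
            closed = taz_closed_form(zz, pp, p)
            oracle = np.vectorize(lambda a, b: bisect_taz(a, b, p))(zz, pp)
            assert np.max(np.abs(closed - oracle)) < 1e-9

    def test_bounds_hold_everywhere(self, rng):
        p = ModelParams(0.13, 0.10, 1.2)
        tdz = rng.uniform(0, 3, 1000)
        tdp = rng.uniform(0, 10, 1000)
        taz = taz_closed_form(tdz, tdp, p)
        assert np.all(taz >= 0)
        assert np.all(taz <= np.minimum(p.a_max, tdz) + 1e-12)

    def test_negative_inputs_rejected(self, unit_params):
        with pytest.raises(ValueError):
            taz_closed_form(-0.1, 0.0, unit_params)
        with pytest.raises(ValueError):
            taz_closed_form(0.1, -0.1, unit_params)

    @pytest.mark.parametrize("bad", [0.0, -1.0, np.nan, np.inf])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelParams(a_max=bad, k_r=1.0, k_p=1.0)


class TestMonotonicity:
    def test_random_triples(self, rng):
        """TAZ rises with zinc, falls with phytate; FAZ falls with both."""
        n = 10_000
        for _ in range(5):
            p = ModelParams(*rng.uniform(0.02, 2.0, size=3))
            tdz = rng.uniform(0.001, 3.0, n)
            tdp = rng.uniform(0.0, 8.0, n)
            dz, dp = 1e-4, 1e-4
            taz0 = taz_closed_form(tdz, tdp, p)
            assert np.all(taz_closed_form(tdz + dz, tdp, p) > taz0)
            assert np.all(taz_closed_form(tdz, tdp + dp, p) < taz0)
            faz0 = faz(tdz, tdp, p)
            assert np.all(faz(tdz + dz, tdp, p) < faz0)
            assert np.all(faz(tdz, tdp + dp, p) < faz0)


class TestFractionalAbsorption:
    def test_zero_intake_limits(self, unit_params):
        assert faz(0.0, 0.0, unit_params) == pytest.approx(0.5, abs=1e-12)
        assert faz(0.0, 1.0, unit_params) == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_limit_is_continuous(self, unit_params):
        """FAZ at tdz -> 0 converges to the analytic limit."""
        assert faz(1e-9, 2.5, unit_params) == pytest.approx(
            faz(0.0, 2.5, unit_params), abs=1e-6
        )

    def test_saturation_makes_fraction_vanish(self, unit_params):
        tdz = 1000.0 * unit_params.a_max
        assert faz(tdz, 0.0, unit_params) == pytest.approx(unit_params.a_max / tdz, rel=1e-2)

    @given(tdz=positive, tdp=st.floats(0.0, 10.0))
    @settings(deadline=None)
    def test_fraction_in_unit_interval(self, tdz, tdp):
        p = ModelParams(0.13, 0.10, 1.2)
        value = faz(tdz, tdp, p)
        assert 0.0 < value < 1.0


class TestCovariateAdjustment:
    def test_bivariate_is_identity(self, unit_params):
        spec = CovariateSpec(mode="bivariate")
        assert effective_params(80.0, 10.0, unit_params, spec) is unit_params

    def test_null_trivariate_is_identity(self, unit_params):
        spec = CovariateSpec(
            mode="trivariate",
            coefficients={"log_a_max_per_g_protein": 0.0, "log_k_p_per_mmol_calcium": 0.0},
        )
        adjusted = effective_params(80.0, 10.0, unit_params, spec)
        assert adjusted == unit_params

    def test_calcium_multiplier_on_log_scale(self, unit_params):
        spec = CovariateSpec(
            mode="trivariate", coefficients={"log_k_p_per_mmol_calcium": -0.01}
        )
        adjusted = effective_params(0.0, 10.0, unit_params, spec)
        assert adjusted.k_p == pytest.approx(unit_params.k_p * np.exp(-0.1), rel=1e-12)
        assert adjusted.a_max == unit_params.a_max

    def test_direction_probe_accepts_physiological_spec(self, unit_params):
        spec = CovariateSpec(
            mode="trivariate",
            coefficients={"log_a_max_per_g_protein": 0.002,
                          "log_k_p_per_mmol_calcium": -0.01},
        )
        validate_covariate_spec(spec, unit_params)

    @pytest.mark.parametrize(
        "coefficients, message",
        [
            ({"log_a_max_per_g_protein": -0.002}, "protein"),
            ({"log_k_p_per_mmol_calcium": 0.01}, "calcium"),
        ],
    )
    def test_direction_probe_rejects_wrong_sign(self, unit_params, coefficients, message):
        spec = CovariateSpec(mode="trivariate", coefficients=coefficients)
        with pytest.raises(ValueError, match=message):
            validate_covariate_spec(spec, unit_params)

    def test_unknown_coefficient_rejected(self):
        with pytest.raises(ValueError, match="unknown covariate"):
            CovariateSpec(mode="trivariate", coefficients={"iron": 1.0})


class TestCohortAbsorption:
    def _record(self):
        return IntakeRecord(
            id="1", sex=Sex.MALE, age_years=25, zinc_mg=8.1,
            phytate_mg=590.6, protein_g=59.9, calcium_mg=317.3,
        )

    def test_single_record_matches_scalar_composition(self, reference_model):
        params, spec = reference_model
        record = self._record()
        [result] = absorb_cohort([record], params, spec)
        scalar = absorb_record(record, params, spec)
        assert result == scalar
        # and the vectorised frame path agrees with the scalar path
        frame = absorb_frame(records_to_frame([record]), params, spec)
        assert frame["taz_mg"].iloc[0] == pytest.approx(scalar.taz_mg, rel=1e-12)
        assert frame["faz"].iloc[0] == pytest.approx(scalar.faz, rel=1e-12)

    def test_trivariate_frame_matches_scalar(self, reference_model):
        params, _ = reference_model
        spec = CovariateSpec(
            mode="trivariate",
            coefficients={"log_a_max_per_g_protein": 0.002,
                          "log_k_p_per_mmol_calcium": -0.01},
        )
        record = self._record()
        scalar = absorb_record(record, params, spec)
        frame = absorb_frame(records_to_frame([record]), params, spec)
        assert frame["taz_mg"].iloc[0] == pytest.approx(scalar.taz_mg, rel=1e-12)
        assert frame["faz"].iloc[0] == pytest.approx(scalar.faz, rel=1e-12)

    def test_empty_cohort(self, unit_params):
        assert absorb_cohort([], unit_params) == []

    def test_identical_records_identical_results(self, reference_model):
        params, spec = reference_model
        results = absorb_cohort([self._record()] * 5, params, spec)
        assert len(set(results)) == 1

    def test_taz_never_exceeds_intake(self, reference_model, rng):
        params, spec = reference_model
        records = [
            IntakeRecord(
                id=str(i), sex=Sex.FEMALE, age_years=30,
                zinc_mg=float(z), phytate_mg=float(p),
                protein_g=50.0, calcium_mg=300.0,
            )
            for i, (z, p) in enumerate(zip(rng.uniform(0.1, 30, 200), rng.uniform(0, 3000, 200)))
        ]
        for record, result in zip(records, absorb_cohort(records, params, spec)):
            assert 0.0 < result.taz_mg <= record.zinc_mg
            assert 0.0 < result.faz < 1.0
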