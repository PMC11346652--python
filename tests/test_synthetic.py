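import numpy as np
import pandas as pd
import pytest

from stcr import (
    MODE_NPK_ALONE,
    MODE_NPK_FYM,
    NutrientTriple,
    SoilTest,
    VerificationTreatment,
    calibrate,
    default_design,
    default_truth,
    derive_equation,
    simulate_gradient,
    simulate_main_experiment,
    simulate_verification,
)

_NUTRIENTS = ("n", "p", "k")


class TestDesign:
    def test_default_layout(self):
        d = default_design()
        assert d.n_plots == 72
        zero = [t for t in d.npk_subplot_doses if t.total == 0]
        assert len(zero) == 1  # one absolute control per block
        n_levels = {round(t.n) for t in d.npk_subplot_doses}
        assert n_levels <= {0, 75, 150, 225}
        p2o5 = {round(t.p * 2.29, 1) for t in d.npk_subplot_doses}
        assert p2o5 <= {0, 37.5, 75.0, 112.5}

    def test_requires_single_control(self):
        from stcr import DesignSpec

        with pytest.raises(ValueError, match="all-zero"):
            DesignSpec(npk_subplot_doses=(NutrientTriple(75, 16, 15),))


class TestGradient:
    def test_determinism(self):
        truth = default_truth()
        a = simulate_gradient(truth, default_design(), seed=7)
        b = simulate_gradient(truth, default_design(), seed=7)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_gradient(truth, default_design(), seed=8)
        assert not a.equals(c)

    def test_zero_spread_degenerate(self):
        truth = default_truth(stv_spread_cv=0.0)
        g = simulate_gradient(truth, default_design(), seed=1)
        for i, strip in enumerate(("S1", "S2", "S3")):
            sub = g[g.strip == strip]
            assert (sub.soil_n == truth.strip_stv_means[i].sn).all()

    def test_monotone_strip_gradient_and_mean_recovery(self):
        """Strip sample means track the configured means within 3%."""
        truth = default_truth()
        means = {s: [] for s in ("S1", "S2", "S3")}
        for seed in range(100):
            g = simulate_gradient(truth, default_design(), seed=seed)
            for s in means:
                means[s].append(g[g.strip == s].soil_n.mean())
        for i, s in enumerate(("S1", "S2", "S3")):
            assert np.mean(means[s]) == pytest.approx(
                truth.strip_stv_means[i].sn, rel=0.03
            )
        assert np.mean(means["S1"]) < np.mean(means["S2"]) < np.mean(means["S3"])


class TestMainExperiment:
    def test_determinism(self, fym_truth):
        a = simulate_main_experiment(fym_truth, default_design(), seed=5)
        b = simulate_main_experiment(fym_truth, default_design(), seed=5)
        pd.testing.assert_frame_equal(a.to_dataframe(), b.to_dataframe())

    def test_noiseless_decomposition_conservation(self, fym_truth):
        """Each plot's uptake is exactly the sum of soil, fertilizer and
        manure contributions."""
        table = simulate_main_experiment(fym_truth, default_design(), seed=2)
        for r in table:
            for x in _NUTRIENTS:
                expected = (
                    fym_truth.cs_frac[x] * r.soil_test[x]
                    + fym_truth.cf_frac[x] * r.fert_dose[x]
                    + fym_truth.com_pct[x] / 100.0 * r.fym_rate * 1000.0
                )
                assert r.uptake[x] == pytest.approx(expected, rel=1e-12)

    def test_noiseless_control_uptake_is_soil_term(self, alone_truth):
        table = simulate_main_experiment(alone_truth, default_design(), seed=2)
        for r in table.select(role="control"):
            assert r.uptake.n == pytest.approx(
                alone_truth.cs_frac["n"] * r.soil_test.sn, rel=1e-12
            )

    def test_consistency_rescales_and_preserves_decomposition(self, alone_truth):
        table = simulate_main_experiment(
            alone_truth, default_design(), seed=2, per_nutrient_consistency=True
        )
        for r in table:
            for x in ("p", "k"):
                assert r.uptake[x] == pytest.approx(
                    alone_truth.nr[x] * r.cob_yield, rel=1e-12
                )
                assert r.uptake[x] == pytest.approx(
                    alone_truth.cs_frac[x] * r.soil_test[x]
                    + alone_truth.cf_frac[x] * r.fert_dose[x],
                    rel=1e-12,
                )

    def test_consistency_impossible_under_large_manure_credit(self, fym_truth):
        """Mass-basis manure credits leave no non-negative soil-test P; the
        generator refuses rather than emitting an inconsistent table."""
        with pytest.raises(ValueError, match="inconsistent option combination"):
            simulate_main_experiment(
                fym_truth, default_design(), seed=2, per_nutrient_consistency=True
            )

    def test_estimator_consistency_as_noise_vanishes(self):
        """Calibration bias shrinks toward zero with the noise CV."""
        design = default_design()
        max_err = []
        for cv in (10.0, 1.0, 0.0):
            truth = default_truth(
                MODE_NPK_FYM, uptake_noise_cv=cv, yield_noise_cv=cv, stv_spread_cv=10.0
            )
            errs = []
            for seed in range(20):
                bp = calibrate(
                    simulate_main_experiment(truth, design, seed=seed), MODE_NPK_FYM
                )
                for x in _NUTRIENTS:
                    errs.append(abs(bp[x].cs_pct / (100 * truth.cs_frac[x]) - 1))
                    errs.append(abs(bp[x].cf_pct / (100 * truth.cf_frac[x]) - 1))
            max_err.append(float(np.mean(errs)))
        assert max_err[0] > max_err[1] > max_err[2]
        assert max_err[2] == pytest.approx(0, abs=1e-12)


class TestVerification:
    def _equation(self, truth):
        table = simulate_main_experiment(
            truth, default_design(), seed=1, per_nutrient_consistency=True
        )
        bp = calibrate(table, MODE_NPK_ALONE)
        return derive_equation(bp, slope_oxide_conversion=False)

    def test_noiseless_round_trip_hits_target(self, alone_truth):
        eq = self._equation(alone_truth)
        stv = alone_truth.strip_stv_means[1]
        outs = simulate_verification(
            alone_truth,
            eq,
            [
                VerificationTreatment("T1", target_t=25.0),
                VerificationTreatment("C", doses=NutrientTriple(0, 0, 0)),
            ],
            stv,
            seed=4,
        )
        assert outs[0].cob_yield == pytest.approx(25.0, rel=0.005)

    def test_control_yield_is_soil_supply_only(self, alone_truth):
        stv = alone_truth.strip_stv_means[0]
        outs = simulate_verification(
            alone_truth,
            None,
            [VerificationTreatment("C", doses=NutrientTriple(0, 0, 0))],
            stv,
            seed=4,
        )
        expected = alone_truth.cs_frac["n"] * stv.sn / alone_truth.nr["n"]
        assert outs[0].cob_yield == pytest.approx(expected, rel=1e-12)

    def test_requires_control(self, alone_truth):
        with pytest.raises(ValueError, match="control"):
            simulate_verification(
                alone_truth,
                None,
                [VerificationTreatment("X", doses=NutrientTriple(75, 16, 15))],
                alone_truth.strip_stv_means[0],
                seed=4,
            )

    def test_determinism(self, alone_truth):
        eq = self._equation(alone_truth)
        stv = alone_truth.strip_stv_means[1]
        treatments = [
            VerificationTreatment("T1", target_t=22.0),
            VerificationTreatment("C", doses=NutrientTriple(0, 0, 0)),
        ]
        a = simulate_verification(alone_truth, eq, treatments, stv, seed=9)
        b = simulate_verification(alone_truth, eq, treatments, stv, seed=9)
        assert a[0].cob_yield == b[0].cob_yield
        assert a[0].uptake.k == b[0].uptake.k
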