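import math
import random

import numpy as np
import pytest

from stcr import (
    MODE_NPK_ALONE,
    MODE_NPK_FYM,
    NutrientTriple,
    PlotRecord,
    PlotTable,
    SoilTest,
    calibrate,
    default_design,
    simulate_main_experiment,
    strip_summary,
    yield_dose_uptake_correlation,
)
from stcr.calibration import (
    fertilizer_contribution,
    manure_contribution,
    nutrient_requirement,
    soil_contribution,
)

_NUTRIENTS = ("n", "p", "k")


def make_plot(
    pid="p1",
    strip="S1",
    dose=(0, 0, 0),
    fym=0.0,
    stv=(200, 40, 90),
    cob=20.0,
    uptake=(117, 15, 80),
):
    return PlotRecord(
        plot_id=pid,
        strip=strip,
        fym_block="F0" if fym == 0 else "F1",
        fert_dose=NutrientTriple(*dose),
        fym_rate=fym,
        soil_test=SoilTest(*stv),
        cob_yield=cob,
        stover_yield=cob * 1.5,
        uptake=NutrientTriple(*uptake),
    )


class TestEstimators:
    def test_nr_forced_ratio(self):
        nr = nutrient_requirement([make_plot(dose=(150, 30, 30))])
        assert nr["n"] == pytest.approx(117 / 20)  # 5.85 kg/t

    def test_nr_zero_yield_guard(self):
        with pytest.raises(ValueError, match="cob_yield"):
            nutrient_requirement([make_plot(dose=(150, 30, 30), cob=0.0)])

    def test_cs_forced_ratio(self):
        cs = soil_contribution([make_plot(uptake=(59.06, 3, 40))])
        assert cs["n"] == pytest.approx(29.53)

    def test_cs_rejects_non_control(self):
        with pytest.raises(ValueError, match="expected control"):
            soil_contribution([make_plot(dose=(75, 0, 0))])

    def test_cf_forced_arithmetic(self):
        cs = {"n": 29.53, "p": 0.0, "k": 0.0}
        plot = make_plot(dose=(150, 30, 30), uptake=(120, 10, 60))
        cf = fertilizer_contribution([plot], cs)
        assert cf["n"] == pytest.approx(100 * (120 - 200 * 29.53 / 100) / 150)

    def test_cf_zero_when_uptake_equals_soil_credit(self):
        cs = {"n": 50.0, "p": 50.0, "k": 50.0}
        plot = make_plot(dose=(150, 30, 30), uptake=(100, 20, 45))
        assert fertilizer_contribution([plot], cs)["n"] == pytest.approx(0.0)

    def test_cf_zero_dose_guard(self):
        with pytest.raises(ValueError, match="zero n dose"):
            fertilizer_contribution([make_plot(dose=(0, 30, 30))], {"n": 0, "p": 0, "k": 0})

    def test_com_forced_ratio(self):
        # net uptake above soil credit of 87.1 kg/ha over 10 t manure -> 0.871%
        cs = {"n": 0.0, "p": 0.0, "k": 0.0}
        plot = make_plot(dose=(0, 0, 0), fym=10, uptake=(87.1, 10, 40))
        assert manure_contribution([plot], cs)["n"] == pytest.approx(0.871)

    def test_com_requires_fym_only_role(self):
        with pytest.raises(ValueError, match="expected fym_only"):
            manure_contribution([make_plot(dose=(75, 0, 0))], {"n": 0, "p": 0, "k": 0})

    def test_empty_selection(self):
        with pytest.raises(ValueError, match="empty"):
            nutrient_requirement([])


class TestCalibrate:
    def test_noiseless_alone_exact(self, alone_table, alone_truth):
        bp = calibrate(alone_table, MODE_NPK_ALONE)
        for x in _NUTRIENTS:
            assert bp[x].nr == pytest.approx(alone_truth.nr[x], rel=1e-9)
            assert bp[x].cs_pct == pytest.approx(100 * alone_truth.cs_frac[x], rel=1e-9)
            assert bp[x].cf_pct == pytest.approx(100 * alone_truth.cf_frac[x], rel=1e-9)

    def test_noiseless_fym_exact(self, fym_table, fym_truth):
        bp = calibrate(fym_table, MODE_NPK_FYM)
        assert bp["n"].nr == pytest.approx(fym_truth.nr["n"], rel=1e-9)
        for x in _NUTRIENTS:
            assert bp[x].cs_pct == pytest.approx(100 * fym_truth.cs_frac[x], rel=1e-9)
            assert bp[x].cf_pct == pytest.approx(100 * fym_truth.cf_frac[x], rel=1e-9)
            assert bp[x].com_pct == pytest.approx(fym_truth.com_pct[x], rel=1e-9)

    def test_cf_k_above_100_preserved(self, alone_table):
        # fertilizer K contribution exceeds 100% (native-K priming); kept as-is
        bp = calibrate(alone_table, MODE_NPK_ALONE)
        assert bp["k"].cf_pct > 100

    def test_no_controls_error(self, fym_table):
        treated = PlotTable(records=[r for r in fym_table if r.role != "control"])
        with pytest.raises(ValueError, match="no control plots"):
            calibrate(treated, MODE_NPK_FYM)

    def test_order_and_strip_label_invariance(self, fym_table):
        bp = calibrate(fym_table, MODE_NPK_FYM)
        rng = random.Random(5)
        shuffled = list(fym_table.records)
        rng.shuffle(shuffled)
        relabel = {"S1": "west", "S2": "mid", "S3": "east"}
        renamed = [
            PlotRecord(
                plot_id=r.plot_id,
                strip=relabel[r.strip],
                fym_block=r.fym_block,
                fert_dose=r.fert_dose,
                fym_rate=r.fym_rate,
                soil_test=r.soil_test,
                cob_yield=r.cob_yield,
                stover_yield=r.stover_yield,
                uptake=r.uptake,
            )
            for r in shuffled
        ]
        bp2 = calibrate(PlotTable(records=renamed), MODE_NPK_FYM)
        for x in _NUTRIENTS:
            assert bp2[x].cs_pct == pytest.approx(bp[x].cs_pct, rel=1e-12)
            assert bp2[x].cf_pct == pytest.approx(bp[x].cf_pct, rel=1e-12)
            assert bp2[x].com_pct == pytest.approx(bp[x].com_pct, rel=1e-12)

    def test_scaling_invariances(self, fym_table):
        """CS is invariant to jointly scaling uptakes and soil tests; CF to
        jointly scaling uptakes, soil tests and doses."""
        c = 1.7
        bp = calibrate(fym_table, MODE_NPK_FYM)
        scaled = [
            PlotRecord(
                plot_id=r.plot_id,
                strip=r.strip,
                fym_block=r.fym_block,
                fert_dose=NutrientTriple(
                    c * r.fert_dose.n, c * r.fert_dose.p, c * r.fert_dose.k
                ),
                fym_rate=c * r.fym_rate,
                soil_test=SoilTest(
                    c * r.soil_test.sn, c * r.soil_test.sp, c * r.soil_test.sk
                ),
                cob_yield=r.cob_yield,
                stover_yield=r.stover_yield,
                uptake=NutrientTriple(c * r.uptake.n, c * r.uptake.p, c * r.uptake.k),
            )
            for r in fym_table
        ]
        bp2 = calibrate(PlotTable(records=scaled), MODE_NPK_FYM)
        for x in _NUTRIENTS:
            assert bp2[x].cs_pct == pytest.approx(bp[x].cs_pct, rel=1e-12)
            assert bp2[x].cf_pct == pytest.approx(bp[x].cf_pct, rel=1e-12)

    def test_single_noisy_replicate_close(self, fym_truth):
        from stcr import default_truth

        truth = default_truth(MODE_NPK_FYM, uptake_noise_cv=1.0, yield_noise_cv=1.0)
        table = simulate_main_experiment(truth, default_design(), seed=3)
        bp = calibrate(table, MODE_NPK_FYM)
        for x in _NUTRIENTS:
            assert bp[x].cs_pct == pytest.approx(100 * truth.cs_frac[x], rel=0.05)
            assert bp[x].cf_pct == pytest.approx(100 * truth.cf_frac[x], rel=0.05)


class TestStripSummary:
    def test_forced_values(self):
        plots = [
            make_plot(pid=f"p{i}", cob=v, dose=(75, 0, 0)) for i, v in enumerate([10, 20, 30])
        ]
        (s,) = strip_summary(PlotTable(records=plots), "cob_yield")
        assert s.mean == pytest.approx(20)
        assert s.sd == pytest.approx(10)
        assert s.cv_pct == pytest.approx(50)

    def test_symmetric_skewness_zero(self):
        plots = [
            make_plot(pid=f"p{i}", cob=v, dose=(75, 0, 0))
            for i, v in enumerate([1, 2, 3, 4, 5])
        ]
        (s,) = strip_summary(PlotTable(records=plots), "cob_yield")
        assert s.skewness == pytest.approx(0, abs=1e-12)
        assert s.iqr == pytest.approx(2)

    def test_matches_brute_force_oracle(self, fym_table):
        """Summary equals an independent one-pass recomputation."""
        for var, getter in [
            ("soil_n", lambda r: r.soil_test.sn),
            ("uptake_k", lambda r: r.uptake.k),
            ("cob_yield", lambda r: r.cob_yield),
        ]:
            for s in strip_summary(fym_table, var):
                vals = sorted(getter(r) for r in fym_table if r.strip == s.strip)
                n = len(vals)
                mean = sum(vals) / n
                sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
                assert s.n == n
                assert s.mean == pytest.approx(mean, rel=1e-12)
                assert s.sd == pytest.approx(sd, rel=1e-12)
                assert s.min == vals[0] and s.max == vals[-1]
                # linear-interpolation quartiles
                def quantile(p):
                    h = (n - 1) * p
                    lo = math.floor(h)
                    return vals[lo] + (h - lo) * (vals[min(lo + 1, n - 1)] - vals[lo])
                assert s.iqr == pytest.approx(quantile(0.75) - quantile(0.25), rel=1e-12)
                # adjusted Fisher-Pearson skewness (0 for a constant column;
                # summation round-off can leave sd at ~1e-14 of the mean)
                if sd > 1e-9 * abs(mean):
                    m2 = sum((v - mean) ** 2 for v in vals) / n
                    m3 = sum((v - mean) ** 3 for v in vals) / n
                    g1 = m3 / m2**1.5
                    adj = g1 * math.sqrt(n * (n - 1)) / (n - 2)
                    assert s.skewness == pytest.approx(adj, rel=1e-9, abs=1e-9)
                else:
                    assert s.skewness == 0.0

    def test_unknown_variable(self, fym_table):
        with pytest.raises(KeyError):
            strip_summary(fym_table, "nope")


class TestYieldCorrelation:
    def test_perfect_linear_r2(self):
        plots = [
            make_plot(pid=f"p{i}", cob=y, dose=(75, 16, 15), uptake=(6 * y + 3, 5, 5))
            for i, y in enumerate([10, 14, 18, 22, 26])
        ]
        corr = yield_dose_uptake_correlation(PlotTable(records=plots))
        assert corr.loc["uptake_n", "r2"] == pytest.approx(1.0)

    def test_constant_regressor_flagged(self):
        plots = [
            make_plot(pid=f"p{i}", cob=y, dose=(75, 16, 15), uptake=(6 * y, 5, 5))
            for i, y in enumerate([10, 14, 18])
        ]
        corr = yield_dose_uptake_correlation(PlotTable(records=plots))
        assert np.isnan(corr.loc["dose_n", "r2"])  # all doses identical

    def test_two_point_guard(self):
        plots = [make_plot(pid=f"p{i}", dose=(75, 16, 15)) for i in range(2)]
        with pytest.raises(ValueError, match=">=3"):
            yield_dose_uptake_correlation(PlotTable(records=plots))

    def test_independent_uptake_r2_near_zero(self, fym_table):
        """Permuting uptakes against yields drives r2 to its null level."""
        rng = np.random.default_rng(21)
        base = list(fym_table.records)
        r2s = []
        for _ in range(100):
            perm = rng.permutation(len(base))
            shuffled = [
                PlotRecord(
                    plot_id=f"q{i}",
                    strip=r.strip,
                    fym_block=r.fym_block,
                    fert_dose=r.fert_dose,
                    fym_rate=r.fym_rate,
                    soil_test=r.soil_test,
                    cob_yield=base[perm[i]].cob_yield,
                    stover_yield=r.stover_yield,
                    uptake=r.uptake,
                )
                for i, r in enumerate(base)
            ]
            corr = yield_dose_uptake_correlation(PlotTable(records=shuffled))
            r2s.append(corr.loc["uptake_n", "r2"])
        assert np.mean(r2s) < 0.05
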