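import math

import numpy as np
import pytest

import oracles
from conftest import make_series, random_walk_series
from glucovar.gv import (
    RangeThresholds,
    adrr,
    conga,
    glucose_risk,
    gmi,
    grade,
    gv_report,
    j_index,
    lbgi_hbgi,
    li,
    m_value,
    mag,
    mage,
    modd,
    sd_roc,
    time_in_ranges,
)

RISK_NEUTRAL = math.exp(5.381 ** (1 / 1.084))  # ~112.44 mg/dL


class TestTimeInRanges:
    def test_constant_in_range(self):
        assert time_in_ranges(make_series([100] * 10)) == (0.0, 100.0, 0.0)

    def test_equal_halves_below_and_above(self):
        tbr, tir, tar = time_in_ranges(make_series([60] * 5 + [200] * 5))
        assert (tbr, tir, tar) == (50.0, 0.0, 50.0)

    def test_threshold_values_count_in_range(self):
        tbr, tir, tar = time_in_ranges(make_series([70, 180, 100]))
        assert tir == 100.0

    def test_conservation_on_random_windows(self, rng):
        for _ in range(50):
            s = random_walk_series(rng, int(rng.integers(10, 300)))
            tbr, tir, tar = time_in_ranges(s)
            assert abs(tbr + tir + tar - 100.0) < 1e-9


class TestRiskIndices:
    def test_symmetry_point_near_112(self):
        rl, rh = glucose_risk(RISK_NEUTRAL)
        assert rl < 1e-9 and rh < 1e-9
        rl, rh = glucose_risk(112.5)
        assert rl + rh < 1e-2

    def test_low_and_high_branches(self):
        assert glucose_risk(50)[0] > 0 and glucose_risk(50)[1] == 0
        assert glucose_risk(300)[1] > 0 and glucose_risk(300)[0] == 0

    def test_lbgi_hbgi_on_constants(self):
        lbgi, hbgi = lbgi_hbgi(make_series([112.5] * 10))
        assert lbgi < 0.01 and hbgi < 0.01
        lbgi, hbgi = lbgi_hbgi(make_series([50] * 10))
        assert lbgi > 0 and hbgi == 0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            glucose_risk(0.0)

    def test_hbgi_monotone_under_pointwise_increase(self, rng):
        base = 130 + np.abs(rng.normal(0, 30, size=200))
        s1 = make_series(base)
        s2 = make_series(base + 10)
        assert lbgi_hbgi(s2)[1] >= lbgi_hbgi(s1)[1]


class TestClosedForms:
    @pytest.mark.parametrize(
        "mean,expected", [(147.94, 6.85), (98.42, 5.66), (152.71, 6.96)]
    )
    def test_gmi_reference_values(self, mean, expected):
        assert round(gmi(mean), 2) == expected

    @pytest.mark.parametrize(
        "mean,sd,expected",
        [(147.94, 60.27, 43.35), (98.42, 33.3, 17.35), (100.0, 0.0, 10.0)],
    )
    def test_j_index_reference_values(self, mean, sd, expected):
        assert round(j_index(mean, sd), 2) == expected

    def test_gmi_j_index_strictly_increase_in_mean(self):
        means = np.linspace(80, 250, 50)
        g = [gmi(m) for m in means]
        j = [j_index(m, 20.0) for m in means]
        assert all(b > a for a, b in zip(g, g[1:]))
        assert all(b > a for a, b in zip(j, j[1:]))

    def test_m_value_closed_forms(self):
        assert m_value(make_series([120] * 10)) == 0.0
        assert m_value(make_series([240] * 10)) == pytest.approx(27.28, abs=0.005)

    def test_grade_minimum_near_90(self):
        assert grade(make_series([90.0] * 10)) < 0.01

    def test_grade_at_clamp_ceiling_below_cap(self):
        # the per-reading cap of 50 binds only above ~600 mg/dL
        val = grade(make_series([400.0] * 10))
        assert val == pytest.approx(35.54, abs=0.01)
        assert grade(make_series([700.0] * 10)) == 50.0

    def test_grade_domain_error_names_sample(self):
        s = make_series([100, 36, 100] * 100)
        with pytest.raises(ValueError, match="36"):
            grade(s)


class TestDifferenceMetrics:
    def test_constant_series_zeros(self):
        s = make_series([110.0] * (2 * 288))
        assert conga(s) == 0.0
        assert modd(s) == 0.0
        assert mage(s) == 0.0
        assert mag(s) == 0.0
        assert sd_roc(s) == 0.0
        assert li(s) == 0.0

    def test_conga_hourly_alternation(self):
        # alternate a,b every hour: differences at 1 h lag are +/-(b-a)
        blocks = []
        for i in range(49):  # 48 hourly transitions -> equal +/- split
            blocks += [100.0 if i % 2 == 0 else 140.0] * 12
        s = make_series(blocks)
        d = 40.0
        n = len(blocks) - 12
        expected = d * math.sqrt(n / (n - 1))
        assert conga(s) == pytest.approx(expected, rel=1e-12)

    def test_modd_constant_daily_step(self):
        # base + k per day: every 24-h difference is exactly k
        days, k = 3, 7.0
        vals = np.concatenate([np.full(288, 100.0 + k * d) for d in range(days)])
        assert modd(make_series(vals)) == pytest.approx(k)

    def test_modd_24h_periodic_is_zero(self):
        t = np.arange(2 * 288)
        s = make_series(130 + 30 * np.sin(2 * np.pi * t / 288))
        assert modd(s) == pytest.approx(0.0, abs=1e-9)

    def test_modd_requires_more_than_a_day(self):
        with pytest.raises(ValueError):
            modd(make_series([100.0] * 288))

    def test_mage_sinusoid_recovers_double_amplitude(self):
        A = 40.0
        t = np.arange(3 * 288)
        s = make_series(140 + A * np.sin(2 * np.pi * t / 288))
        assert mage(s) == pytest.approx(2 * A, rel=0.02)

    def test_mage_direction_selection(self):
        t = np.arange(2 * 288)
        s = make_series(140 + 40 * np.sin(2 * np.pi * t / 288))
        assert mage(s, "asc") > 0
        assert mage(s, "desc") > 0
        both = mage(s, "both")
        assert min(mage(s, "asc"), mage(s, "desc")) <= both <= max(
            mage(s, "asc"), mage(s, "desc")
        )

    def test_mag_telescoping_monotone_rise(self):
        # 100 mg/dL rise over 10 h
        vals = np.linspace(100, 200, 121)  # 120 x 5-min steps = 10 h
        assert mag(make_series(vals)) == pytest.approx(10.0)

    def test_sd_roc_linear_series_zero(self):
        assert sd_roc(make_series(np.linspace(100, 160, 100))) == pytest.approx(0.0, abs=1e-12)

    def test_sd_roc_alternating_rates(self):
        vals = [100.0, 110.0] * 200 + [100.0]  # 400 rates, equal +/- split
        r = 2.0  # +/-10 mg/dL per 5 min
        n = len(vals) - 1
        expected = math.sqrt(n / (n - 1)) * r
        assert sd_roc(make_series(vals)) == pytest.approx(expected, rel=1e-9)

    def test_li_weekly_staircase(self):
        # 1 mmol/L per hour for one week: 167 unit steps over 1 week
        vals = np.repeat(np.arange(168) * 18.016 + 50.0, 12)
        assert li(make_series(vals)) == pytest.approx(167.0, rel=1e-6)

    def test_adrr_constant_risk(self):
        s = make_series([112.5] * (2 * 288))
        assert adrr(s) < 0.01
        s50 = make_series([50.0] * (2 * 288))
        assert adrr(s50) == pytest.approx(oracles.risk_oracle(50.0)[0], rel=1e-12)

    def test_adrr_needs_complete_day(self):
        import pandas as pd

        # spans 25 h but straddles midnight: 75% + 29% complete days only
        s = make_series([100.0] * 300, start=pd.Timestamp("2021-03-01T06:00:00Z"))
        with pytest.raises(ValueError, match="complete day"):
            adrr(s)


ORACLE_CASES = [
    ("conga", lambda s: conga(s), lambda s: oracles.conga_oracle(s)),
    ("modd", lambda s: modd(s), lambda s: oracles.modd_oracle(s)),
    ("mage", lambda s: mage(s), lambda s: oracles.mage_oracle(s)),
    ("adrr", lambda s: adrr(s), lambda s: oracles.adrr_oracle(s)),
    ("lbgi_hbgi", lambda s: lbgi_hbgi(s), lambda s: oracles.lbgi_hbgi_oracle(s)),
    ("m_value", lambda s: m_value(s), lambda s: oracles.m_value_oracle(s)),
    ("mag", lambda s: mag(s), lambda s: oracles.mag_oracle(s)),
    ("li", lambda s: li(s), lambda s: oracles.li_oracle(s)),
    ("sd_roc", lambda s: sd_roc(s), lambda s: oracles.sd_roc_oracle(s)),
    ("grade", lambda s: grade(s), lambda s: oracles.grade_oracle(s)),
]


@pytest.mark.parametrize("name,impl,oracle", ORACLE_CASES, ids=[c[0] for c in ORACLE_CASES])
def test_oracle_equivalence_on_random_windows(name, impl, oracle, rng):
    """Vectorised metrics match naive loop implementations to 1e-9 relative
    on 100 random 1-3-day windows (with and without missing slots)."""
    for k in range(100):
        n_days = 1 + (k % 3)
        nan_frac = 0.0 if k % 2 == 0 else 0.05
        s = random_walk_series(rng, n_days * 288 + 2, nan_frac=nan_frac)
        a, b = impl(s), oracle(s)
        np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-12)


class TestGvReport:
    def test_48h_window_all_metrics_populated(self):
        s = random_walk_series(np.random.default_rng(5), 576)
        rep = gv_report(s)
        for name in rep.metric_names():
            assert getattr(rep, name) is not None, name
        assert rep.absent == {}
        assert len(rep.metric_names()) == 19

    def test_12h_window_reports_absences_with_reason(self):
        s = random_walk_series(np.random.default_rng(6), 144)
        rep = gv_report(s)
        assert rep.modd is None and "24" in rep.absent["modd"]
        assert rep.adrr is None
        assert rep.mean is not None and rep.tir is not None

    def test_constant_window_composition(self):
        rep = gv_report(make_series([112.5] * 576))
        assert rep.tir == 100.0
        assert rep.lbgi < 0.01 and rep.hbgi < 0.01
        assert rep.mage == 0.0

    def test_custom_thresholds(self):
        rep = gv_report(make_series([100.0] * 576), RangeThresholds(90, 110))
        assert rep.tir == 100.0
        with pytest.raises(ValueError):
            RangeThresholds(180, 70)
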