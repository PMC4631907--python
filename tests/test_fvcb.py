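"""FvCB forward model and A/Ci fitting."""

import numpy as np
import pytest

from leafgx.fvcb import (
    SPECIES_KINETICS,
    FitError,
    FitOptions,
    FvCBParams,
    KineticConstants,
    ResponseCurve,
    fit_aci,
    net_assimilation,
    rubisco_limited_rate,
    rubp_limited_rate,
    vcmax_slope_estimate,
)
from leafgx.synthetic import NoiseModel, simulate_aci_curve

QS = SPECIES_KINETICS["Quercus spinosa"]


def _params(vcmax=58.26, jmax=118.0, rd=1.21):
    return FvCBParams(vcmax=vcmax, jmax=jmax, rd=rd)


class TestBranchRates:
    def test_rubisco_compensation_point(self):
        p = _params()
        assert rubisco_limited_rate(QS.gamma_star, p, QS) == pytest.approx(-p.rd)

    def test_rubisco_asymptote(self):
        p = _params()
        assert rubisco_limited_rate(1e9, p, QS) == pytest.approx(
            p.vcmax - p.rd, rel=1e-5
        )

    def test_rubisco_hand_value(self):
        # independent arithmetic of Vcmax(Cc-G*)/(Cc+Kc(1+O/Ko)) - Rd
        km = 404.9 * (1.0 + 210.0 / 278.4)
        expected = 58.26 * (124.0 - 52.513) / (124.0 + km) - 1.21
        p = _params()
        assert rubisco_limited_rate(124.0, p, QS) == pytest.approx(expected, rel=1e-12)

    def test_rubp_compensation_point(self):
        assert rubp_limited_rate(52.513, 118.1, 52.513, 1.21) == pytest.approx(-1.21)

    def test_rubp_asymptote(self):
        assert rubp_limited_rate(1e9, 118.1, 52.513, 1.21) == pytest.approx(
            118.1 / 4.0 - 1.21, rel=1e-5
        )

    def test_rubp_hand_value(self):
        expected = 118.1 * (300.0 - 52.513) / (4 * 300.0 + 8 * 52.513) - 1.21
        assert rubp_limited_rate(300.0, 118.1, 52.513, 1.21) == pytest.approx(
            expected, rel=1e-12
        )

    def test_rubisco_strictly_increasing_above_gamma_star(self):
        p = _params()
        cc = np.linspace(QS.gamma_star, 2000, 200)
        vals = np.asarray(rubisco_limited_rate(cc, p, QS))
        assert np.all(np.diff(vals) > 0)


class TestNetAssimilation:
    def test_compensation_point_exact(self):
        for vcmax, jmax, rd in [(30, 60, 0.5), (58.26, 236.7, 1.21), (102, 300, 3.4)]:
            p = _params(vcmax, jmax, rd)
            assert net_assimilation(QS.gamma_star, p, QS) == pytest.approx(
                -rd, rel=1e-12
            )

    def test_low_cc_is_rubisco_limited(self):
        p = _params(vcmax=60, jmax=120, rd=1.2)
        cc = np.linspace(60, 200, 20)
        np.testing.assert_allclose(
            net_assimilation(cc, p, QS), rubisco_limited_rate(cc, p, QS)
        )

    def test_high_cc_is_rubp_limited(self):
        p = _params(vcmax=60, jmax=120, rd=1.2)
        cc = np.linspace(1200, 2000, 20)
        np.testing.assert_allclose(
            net_assimilation(cc, p, QS),
            rubp_limited_rate(cc, p.jmax, QS.gamma_star, p.rd),
        )

    def test_nondecreasing_on_measured_range(self):
        rng = np.random.default_rng(3)
        cc = np.linspace(QS.gamma_star, 2000, 300)
        for _ in range(20):
            p = _params(
                vcmax=rng.uniform(20, 120),
                jmax=rng.uniform(40, 480),
                rd=rng.uniform(0.2, 4),
            )
            vals = np.asarray(net_assimilation(cc, p, QS))
            assert np.all(np.diff(vals) >= -1e-9)

    def test_below_gamma_star_bounded_efflux(self):
        # the photorespiratory branch below the compensation point must not
        # blow up with Jmax: the Rubisco gross rate is the active (smaller)
        # branch there for realistic parameters
        p_small = _params(vcmax=60, jmax=120, rd=1.2)
        p_big = _params(vcmax=60, jmax=1200, rd=1.2)
        a_small = net_assimilation(40.0, p_small, QS)
        a_big = net_assimilation(40.0, p_big, QS)
        assert a_big == pytest.approx(a_small, rel=1e-12)

    def test_amax_never_exceeds_rubp_ceiling(self):
        p = _params(vcmax=80, jmax=200, rd=1.5)
        assert net_assimilation(2000.0, p, QS) <= p.jmax / 4 - p.rd + 1e-9


class TestResponseCurveValidation:
    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            ResponseCurve("x", "Quercus spinosa", 2500, [50, 100, 200], [1, 2, 3], [48, 95, 190])

    def test_non_monotone_setpoints_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            ResponseCurve(
                "x", "Quercus spinosa", 2500,
                [50, 100, 90, 200, 300], [1, 2, 3, 4, 5], [48, 95, 85, 190, 280],
            )


def _noiseless_curve(vcmax, jmax, rd, scenario, cfg):
    rng = np.random.default_rng(0)
    draw = {
        "vcmax": vcmax, "jmax": jmax, "jmax_vcmax": jmax / vcmax, "rn": rd,
        "gs": 0.2, "gm": 0.2, "sla": 100.0, "narea": 1.5, "delta13c": -28.0,
    }
    curve, params = simulate_aci_curve(
        scenario, "low", cfg.sites["low"], rng,
        noise=NoiseModel(0.0, 0.0), draw=draw,
    )
    return curve, params


class TestFitAci:
    def test_noiseless_recovery_identifiable_pair(self, quiet_campaign):
        sc = quiet_campaign.scenarios[0]
        curve, p = _noiseless_curve(80.85, 2.2 * 80.85, 1.83, sc, quiet_campaign)
        fit = fit_aci(curve, sc.kinetics(), FitOptions(rd=1.83))
        assert fit.params.vcmax == pytest.approx(80.85, rel=1e-3)
        assert fit.params.jmax == pytest.approx(2.2 * 80.85, rel=1e-3)
        assert fit.jmax_identified and fit.vcmax_identified

    def test_latent_jmax_reported_as_lower_bound(self, quiet_campaign):
        # published-style ratio ~4: the whole measured range is Rubisco
        # limited, Jmax is unidentifiable and must come back flagged, at the
        # deterministic identifiability boundary, with Vcmax still exact
        sc = quiet_campaign.scenarios[0]
        curve, p = _noiseless_curve(58.26, 236.7, 1.21, sc, quiet_campaign)
        fit = fit_aci(curve, sc.kinetics(), FitOptions(rd=1.21))
        assert fit.params.vcmax == pytest.approx(58.26, rel=1e-3)
        assert not fit.jmax_identified
        assert fit.params.jmax < 236.7  # lower bound, not the latent truth
        # boundary value: Jmax where the RuBP branch touches the Rubisco one
        km = sc.kinetics().km_effective
        g = sc.kinetics().gamma_star
        jb = 58.26 * np.max((4 * curve.ci + 8 * g) / (curve.ci + km))
        assert fit.params.jmax == pytest.approx(jb, rel=1e-3)

    def test_flat_curve_rejected(self):
        with pytest.raises(FitError, match="flat"):
            curve = ResponseCurve(
                "flat", "Quercus spinosa", 2500,
                [50, 100, 200, 400, 800], [5, 5, 5, 5, 5], [48, 95, 190, 380, 760],
            )
            fit_aci(curve, QS, FitOptions(rd=1.0))

    def test_missing_rd_rejected(self, quiet_campaign):
        sc = quiet_campaign.scenarios[0]
        curve, _ = _noiseless_curve(60, 130, 1.2, sc, quiet_campaign)
        with pytest.raises(FitError, match="rd"):
            fit_aci(curve, sc.kinetics(), FitOptions())

    def test_cofit_rd_recovers_on_noiseless_curve(self, quiet_campaign):
        sc = quiet_campaign.scenarios[0]
        curve, _ = _noiseless_curve(60, 130, 1.7, sc, quiet_campaign)
        fit = fit_aci(curve, sc.kinetics(), FitOptions(fit_rd=True))
        assert fit.params.vcmax == pytest.approx(60, rel=1e-2)
        assert fit.params.rd == pytest.approx(1.7, rel=0.05)

    def test_fit_is_deterministic(self, quiet_campaign):
        sc = quiet_campaign.scenarios[0]
        rng = np.random.default_rng(11)
        curve, _ = simulate_aci_curve(
            sc, "low", quiet_campaign.sites["low"], rng, noise=NoiseModel(0.5, 0.0)
        )
        f1 = fit_aci(curve, sc.kinetics(), FitOptions(rd=1.21))
        f2 = fit_aci(curve, sc.kinetics(), FitOptions(rd=1.21))
        assert f1.params.vcmax == f2.params.vcmax
        assert f1.params.jmax == f2.params.jmax

    def test_amax_respects_rubp_ceiling(self, quiet_campaign):
        sc = quiet_campaign.scenarios[0]
        curve, _ = _noiseless_curve(80, 180, 1.5, sc, quiet_campaign)
        fit = fit_aci(curve, sc.kinetics(), FitOptions(rd=1.5))
        assert fit.params.amax <= fit.params.amax_ceiling + 1e-6

    def test_ratio_property_exact(self, quiet_campaign):
        sc = quiet_campaign.scenarios[0]
        curve, _ = _noiseless_curve(70, 150, 1.0, sc, quiet_campaign)
        fit = fit_aci(curve, sc.kinetics(), FitOptions(rd=1.0))
        assert fit.params.jmax_vcmax_ratio == fit.params.jmax / fit.params.vcmax


class TestVcmaxSlopeEstimate:
    def test_exact_recovery_on_rubisco_window(self, quiet_campaign):
        sc = quiet_campaign.scenarios[0]
        curve, _ = _noiseless_curve(58.26, 236.7, 1.21, sc, quiet_campaign)
        est = vcmax_slope_estimate(curve, sc.kinetics(), rd=1.21)
        assert est == pytest.approx(58.26, rel=1e-3)

    def test_too_few_window_points_rejected(self):
        curve = ResponseCurve(
            "w", "Quercus spinosa", 2500,
            [300, 500, 800, 1200, 2000],
            [10, 14, 17, 19, 20],
            [295, 492, 790, 1190, 1985],
        )
        with pytest.raises(FitError, match="slope window"):
            vcmax_slope_estimate(curve, QS, rd=1.0)

    def test_rubp_contamination_biases_low_and_is_flagged(self, quiet_campaign):
        # a low-Jmax leaf is RuBP-limited inside the 40-200 window; the slope
        # estimate must come out below the generating Vcmax and the full fit
        # must flag the divergence
        sc = quiet_campaign.scenarios[0]
        curve, _ = _noiseless_curve(80.0, 80.0, 1.2, sc, quiet_campaign)
        est = vcmax_slope_estimate(curve, sc.kinetics(), rd=1.2)
        assert est < 80.0 * 0.95
        fit = fit_aci(curve, sc.kinetics(), FitOptions(rd=1.2))
        assert fit.slope_estimate_divergent
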