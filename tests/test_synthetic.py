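"""Synthetic campaign generator: structure, determinism, estimator consistency."""

import numpy as np
import pandas as pd
import pytest

from leafgx.conductance import electron_transport, gm_variable_j, phi_psii
from leafgx.fvcb import SPECIES_KINETICS, FitOptions, fit_aci
from leafgx.io import _curves_from_frame
from leafgx.synthetic import (
    CampaignConfig,
    NoiseModel,
    SpeciesScenario,
    default_paper_scenario,
    reported_group_means,
    simulate_aci_curve,
    simulate_campaign,
    simulate_leaf_point,
)


class TestDefaultScenario:
    def test_published_group_means_carried(self):
        cfg = default_paper_scenario()
        by_name = {s.name: s for s in cfg.scenarios}
        assert by_name["Quercus spinosa"].quantities["low"]["vcmax"][0] == 58.26
        assert by_name["Rumex dentatus"].quantities["high"]["gm"][0] == 0.44
        assert all(s.n_leaves == 6 for s in cfg.scenarios)

    def test_site_pco2_matches_study_range(self):
        cfg = default_paper_scenario()
        assert cfg.sites["low"].p_co2_pa == pytest.approx(27.7, abs=0.01)
        assert cfg.sites["high"].p_co2_pa == pytest.approx(24.6, abs=0.01)

    def test_species_gamma_star_presets(self):
        assert SPECIES_KINETICS["Quercus spinosa"].gamma_star == 52.513
        assert SPECIES_KINETICS["Salix atopantha"].gamma_star == 54.145
        assert SPECIES_KINETICS["Rumex dentatus"].gamma_star == 52.512

    def test_cv_cap_invariant(self):
        cfg = default_paper_scenario()
        for sc in cfg.scenarios:
            for band in ("low", "high"):
                for par, (mean, sd) in sc.quantities[band].items():
                    assert sd <= 0.5 * abs(mean) + 1e-12

    def test_reported_means_table_shape(self):
        df = reported_group_means()
        assert set(df["species"]) == {
            "Quercus spinosa", "Salix atopantha", "Rumex dentatus"
        }
        assert len(df) == len(df.drop_duplicates(["species", "parameter"]))


class TestConfigValidation:
    def test_empty_scenarios_rejected(self):
        cfg = default_paper_scenario()
        with pytest.raises(ValueError, match="at least one"):
            CampaignConfig(scenarios=(), sites=cfg.sites)

    def test_short_ladder_rejected(self):
        cfg = default_paper_scenario()
        with pytest.raises(ValueError, match="10 steps"):
            CampaignConfig(
                scenarios=cfg.scenarios, sites=cfg.sites, ladder=(50, 100, 200)
            )

    def test_negative_scenario_mean_rejected(self):
        with pytest.raises(ValueError, match="mean"):
            SpeciesScenario(
                name="X", gamma_star=50.0, ppfd=1200.0,
                quantities={"low": {"vcmax": (-5.0, 1.0)}, "high": {}},
            )


class TestLeafPoint:
    def test_noiseless_variable_j_roundtrip(self, quiet_campaign):
        # the emitted fluorescence must encode exactly the electron transport
        # that lets the variable-J estimator recover the drawn Gm
        rng = np.random.default_rng(5)
        for sc in quiet_campaign.scenarios:
            rec, leaf = simulate_leaf_point(
                sc, "low", quiet_campaign.sites["low"], rng,
                noise=NoiseModel(0.0, 0.0),
            )
            phi = phi_psii(rec.f, rec.fm_prime)
            j = electron_transport(phi, rec.ppfd, quiet_campaign.calibration)
            gm = gm_variable_j(
                rec.a, rec.ci, j, sc.kinetics().gamma_star, rec.rn
            )
            assert gm == pytest.approx(leaf["gm"], rel=1e-6)

    def test_fick_consistency_of_record(self, quiet_campaign):
        rng = np.random.default_rng(6)
        sc = quiet_campaign.scenarios[1]
        rec, leaf = simulate_leaf_point(
            sc, "high", quiet_campaign.sites["high"], rng, noise=NoiseModel(0.0, 0.0)
        )
        assert rec.ci == pytest.approx(rec.ca - rec.a / leaf["gs"], rel=1e-12)

    def test_fixed_seed_reproducible(self, quiet_campaign):
        sc = quiet_campaign.scenarios[0]
        r1, _ = simulate_leaf_point(sc, "low", quiet_campaign.sites["low"],
                                    np.random.default_rng(9))
        r2, _ = simulate_leaf_point(sc, "low", quiet_campaign.sites["low"],
                                    np.random.default_rng(9))
        assert r1 == r2

    def test_high_conductance_limit_ci_approaches_ca(self, quiet_campaign):
        sc = quiet_campaign.scenarios[0]
        draw = {
            "vcmax": 58.0, "jmax": 236.0, "jmax_vcmax": 236 / 58.0, "rn": 1.2,
            "gs": 1e5, "gm": 1e5, "sla": 93.0, "narea": 1.9, "delta13c": -28.0,
        }
        rec, _ = simulate_leaf_point(
            sc, "low", quiet_campaign.sites["low"], np.random.default_rng(1),
            noise=NoiseModel(0.0, 0.0), draw=draw,
        )
        assert rec.ci == pytest.approx(rec.ca, rel=1e-4)


class TestAciCurveGeneration:
    def test_generator_is_the_fitting_oracle(self, quiet_campaign):
        rng = np.random.default_rng(2)
        sc = quiet_campaign.scenarios[1]  # S. atopantha
        draw = {
            "vcmax": 80.85, "jmax": 2.0 * 80.85, "jmax_vcmax": 2.0, "rn": 1.83,
            "gs": 0.2, "gm": 0.2, "sla": 146.0, "narea": 1.7, "delta13c": -28.0,
        }
        curve, params = simulate_aci_curve(
            sc, "high", quiet_campaign.sites["high"], rng,
            noise=NoiseModel(0.0, 0.0), draw=draw,
        )
        fit = fit_aci(curve, sc.kinetics(), FitOptions(rd=1.83))
        assert fit.params.vcmax == pytest.approx(80.85, rel=1e-3)
        assert fit.params.jmax == pytest.approx(161.7, rel=1e-3)

    def test_same_seed_identical_curves(self, quiet_campaign):
        sc = quiet_campaign.scenarios[0]
        c1, _ = simulate_aci_curve(sc, "low", quiet_campaign.sites["low"],
                                   np.random.default_rng(3))
        c2, _ = simulate_aci_curve(sc, "low", quiet_campaign.sites["low"],
                                   np.random.default_rng(3))
        np.testing.assert_array_equal(c1.a, c2.a)

    def test_different_seeds_differ(self, default_campaign):
        sc = default_campaign.scenarios[0]
        c1, _ = simulate_aci_curve(sc, "low", default_campaign.sites["low"],
                                   np.random.default_rng(3))
        c2, _ = simulate_aci_curve(sc, "low", default_campaign.sites["low"],
                                   np.random.default_rng(4))
        assert not np.array_equal(c1.a, c2.a)


class TestCampaign:
    def test_structure_three_species_two_elevations_six_leaves(self, quiet_campaign):
        result = simulate_campaign(quiet_campaign)
        counts = result.points.groupby(["species", "elevation_m"]).size()
        assert len(counts) == 6
        assert (counts == 6).all()
        assert len(result.curves) == 36 * len(quiet_campaign.ladder)
        assert len(result.traits) == 36

    def test_byte_identical_output_for_same_seed(self, quiet_campaign):
        r1 = simulate_campaign(quiet_campaign)
        r2 = simulate_campaign(quiet_campaign)
        assert r1.points.to_csv(index=False) == r2.points.to_csv(index=False)
        assert r1.curves.to_csv(index=False) == r2.curves.to_csv(index=False)
        assert r1.traits.to_csv(index=False) == r2.traits.to_csv(index=False)

    def test_large_n_group_means_converge_to_scenario(self):
        from dataclasses import replace

        cfg = default_paper_scenario(seed=0, noise=NoiseModel(0.0, 0.0))
        big = replace(
            cfg,
            scenarios=tuple(
                replace(
                    s,
                    n_leaves=1000,
                    quantities={
                        band: {p: (m, 0.0) for p, (m, sd) in qs.items()}
                        for band, qs in s.quantities.items()
                    },
                )
                for s in cfg.scenarios[:1]
            ),
        )
        rng = np.random.default_rng(0)
        sc = big.scenarios[0]
        draws = [
            simulate_leaf_point(sc, "low", big.sites["low"], rng,
                                noise=NoiseModel(0.0, 0.0))[1]["gs"]
            for _ in range(200)
        ]
        assert np.mean(draws) == pytest.approx(
            sc.quantities["low"]["gs"][0], rel=1e-3
        )

    def test_sample_cv_tracks_configured_cv(self):
        from leafgx.synthetic import _draw_leaf

        cfg = default_paper_scenario(seed=0)
        sc = cfg.scenarios[2]  # R. dentatus: moderate CVs, little truncation
        rng = np.random.default_rng(1)
        draws = np.array([_draw_leaf(sc, "low", rng)["vcmax"] for _ in range(1000)])
        mean, sd = sc.quantities["low"]["vcmax"]
        assert draws.std() == pytest.approx(sd, rel=0.2)

    def test_curves_roundtrip_into_response_curves(self, quiet_campaign):
        result = simulate_campaign(quiet_campaign)
        curves = _curves_from_frame(result.curves)
        assert len(curves) == 36
        assert all(len(c) == len(quiet_campaign.ladder) for c in curves)
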