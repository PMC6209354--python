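"""Site choice, calibration, participation, and elasticities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from baytrips.config import BAYS, BaseSeasonTable, CatchWeights, ChoiceCoefficients
from baytrips.demand import (
    DistanceVector,
    base_catch_rates,
    base_participation,
    calibrate_distance_vector,
    delta_trip_probability,
    estimate_choice_coefficients,
    expected_catch,
    inclusive_value,
    lambda_from_wtp,
    site_choice_probs,
    trip_elasticity,
)


class TestBaseCatchRates:
    def test_galveston_high_season_rate(self, base_tables):
        rates = base_catch_rates(base_tables["high"])
        assert rates["red_drum"][0] == pytest.approx(30997 / 191165)
        assert rates["red_drum"][0] == pytest.approx(0.1621, abs=5e-4)

    def test_rates_times_trips_reproduce_harvest(self, base_tables):
        for season, base in base_tables.items():
            rates = base_catch_rates(base)
            for sp in ("red_drum", "spotted_seatrout"):
                np.testing.assert_allclose(rates[sp] * base.trips, base.harvest(sp))

    def test_zero_harvest_gives_zero_rate(self):
        base = BaseSeasonTable(
            season="high", trips=np.full(7, 10.0),
            harvest_red_drum=np.zeros(7), harvest_spotted_seatrout=np.ones(7),
        )
        assert np.all(base_catch_rates(base)["red_drum"] == 0)


class TestSiteChoice:
    def test_identical_bays_uniform(self, coefs):
        catch = {"red_drum": np.full(7, 0.2), "spotted_seatrout": np.full(7, 0.5)}
        p = site_choice_probs(catch, np.full(7, 100.0), coefs)
        np.testing.assert_allclose(p, 1 / 7)

    def test_translation_invariance_in_distance(self, coefs):
        rng = np.random.default_rng(0)
        catch = {"red_drum": rng.uniform(0, 1, 7), "spotted_seatrout": rng.uniform(0, 1, 7)}
        d = rng.uniform(50, 150, 7)
        p1 = site_choice_probs(catch, d, coefs)
        p2 = site_choice_probs(catch, d + 37.0, coefs)
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_probs_sum_to_one_and_positive(self, coefs):
        rng = np.random.default_rng(1)
        for _ in range(20):
            catch = {"red_drum": rng.uniform(0, 2, 7),
                     "spotted_seatrout": rng.uniform(0, 2, 7)}
            p = site_choice_probs(catch, rng.uniform(10, 500, 7), coefs)
            assert p.sum() == pytest.approx(1.0)
            assert np.all(p > 0)

    def test_base_inputs_reproduce_trip_shares(self, base_tables, coefs):
        base = base_tables["high"]
        dv = calibrate_distance_vector(base, coefs)
        p = site_choice_probs(base_catch_rates(base), dv, coefs)
        np.testing.assert_allclose(p, base.trips / base.trips.sum(), atol=1e-10)
        assert p[0] == pytest.approx(191165 / 631950, abs=1e-6)


class TestCalibrateDistances:
    def test_high_season_matches_published_vector(self, base_tables, coefs):
        dv = calibrate_distance_vector(base_tables["high"], coefs)
        np.testing.assert_allclose(
            dv.miles, [100.0, 112.0, 114.6, 107.5, 112.8, 111.8, 114.0], atol=0.05
        )

    def test_low_season_matches_published_vector(self, base_tables, coefs):
        dv = calibrate_distance_vector(base_tables["low"], coefs)
        np.testing.assert_allclose(
            dv.miles, [100.0, 106.9, 113.4, 99.4, 103.7, 103.0, 105.7], atol=0.05
        )

    def test_equal_bays_collapse_to_anchor(self, coefs):
        base = BaseSeasonTable(
            season="high", trips=np.full(7, 100.0),
            harvest_red_drum=np.full(7, 20.0), harvest_spotted_seatrout=np.full(7, 30.0),
        )
        np.testing.assert_allclose(calibrate_distance_vector(base, coefs).miles, 100.0)

    def test_zero_beta_d_unsolvable(self, base_tables):
        class Degenerate:
            beta_d = 0.0
            beta_cR = 0.1
            beta_cS = 0.1
        with pytest.raises(ValueError, match="unsolvable"):
            calibrate_distance_vector(base_tables["high"], Degenerate())

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 100_000))
    def test_round_trip_reproduces_shares_property(self, coefs, seed):
        rng = np.random.default_rng(seed)
        base = BaseSeasonTable(
            season="high",
            trips=rng.uniform(1e3, 1e5, 7),
            harvest_red_drum=rng.uniform(0, 2e4, 7),
            harvest_spotted_seatrout=rng.uniform(0, 5e4, 7),
        )
        dv = calibrate_distance_vector(base, coefs)
        p = site_choice_probs(base_catch_rates(base), dv, coefs)
        np.testing.assert_allclose(p, base.trips / base.trips.sum(), atol=1e-10)


class TestExpectedCatch:
    W = CatchWeights(distance_decay=0.05, wave_weight=0.5, year_weight=0.3)

    def test_observations_at_base_leave_expectation_at_base(self):
        base = np.array([0.2, 0.4, 0.6])
        out = expected_catch(base.copy(), base, self.W)
        np.testing.assert_allclose(out, base)

    def test_own_site_only_returns_observation(self):
        base = np.array([0.2, 0.4])
        obs = np.array([0.5, 0.1])
        out = expected_catch(obs, base, self.W)  # no distance matrix: own history only
        np.testing.assert_allclose(out, obs)

    def test_two_sites_two_periods_hand_computed(self):
        base = np.array([1.0, 2.0])
        obs = np.array([1.5, 2.5])
        prev = np.array([0.5, 1.5])
        dist = np.array([[0.0, 10.0], [10.0, 0.0]])
        w = CatchWeights(distance_decay=0.1, wave_weight=0.5, year_weight=0.0)
        out = expected_catch(obs, base, w, site_distances=dist, prev_wave=prev)
        neighbour_w = 0.9**10
        # site 0: anomalies +0.5 (own, w=1), +0.5 (other, w=0.9^10),
        #         -0.5 (own prev, w=0.5), -0.5 (other prev, w=0.5*0.9^10)
        num = 0.5 * 1 + 0.5 * neighbour_w - 0.5 * 0.5 - 0.5 * 0.5 * neighbour_w
        den = (1 + neighbour_w) * 1.5
        assert out[0] == pytest.approx(1.0 + num / den)


class TestLambdaAndParticipation:
    def test_lambda_published_values(self):
        assert lambda_from_wtp(-0.082, 30, 1.0) == pytest.approx(2.46)
        assert lambda_from_wtp(-0.082, 30, 2.0) == pytest.approx(1.23)
        assert lambda_from_wtp(-0.082, 30, 0.5) == pytest.approx(4.92)

    def test_lambda_zero_wtp_and_bad_cost(self):
        assert lambda_from_wtp(-0.082, 0.0, 1.0) == 0.0
        with pytest.raises(ValueError):
            lambda_from_wtp(-0.082, 30, 0.0)

    def test_published_seasonal_probabilities(self, base_tables):
        hi, lo = base_participation(
            float(base_tables["high"].trips.sum()),
            float(base_tables["low"].trips.sum()),
        )
        assert hi == pytest.approx(0.0749, abs=1e-4)
        assert lo == pytest.approx(0.0332, abs=1e-4)

    def test_symmetric_split(self):
        hi, lo = base_participation(1000, 1000, days_high=182.5, days_low=182.5)
        assert hi == pytest.approx(20 / 365)
        assert lo == pytest.approx(20 / 365)

    @pytest.mark.parametrize("th,tl", [(1000, 500), (631950, 261250), (10, 90)])
    def test_annual_rate_conserved(self, th, tl):
        hi, lo = base_participation(th, tl)
        assert (lo * 176 + hi * 189) / 365 == pytest.approx(20 / 365, abs=1e-12)


class TestDeltaTripProbability:
    def test_no_change_at_base(self):
        assert delta_trip_probability(1.5, 1.5, 0.07, 2.46) == 0.0

    def test_hand_computed_linear_update(self):
        d = delta_trip_probability(1.51, 1.50, 0.0749, 2.46)
        assert d == pytest.approx(2.46 * (1 - 0.0749) * 0.0749 * 0.01, abs=1e-12)

    def test_exact_mode_agrees_to_first_order(self):
        gaps = []
        for div in (1e-2, 1e-3, 1e-4):
            lin = delta_trip_probability(1.0 + div, 1.0, 0.05, 2.0)
            exact = delta_trip_probability(1.0 + div, 1.0, 0.05, 2.0, exact=True)
            gaps.append(abs(lin - exact) / abs(lin))
        assert gaps[2] < gaps[1] < gaps[0]
        assert gaps[2] < 1e-3


class TestElasticity:
    def test_zero_catch_or_zero_beta_gives_zero(self, coefs):
        total, *_ = trip_elasticity(coefs, 2.46, 0.07, 0.3, 0.0, "red_drum")
        assert total == 0.0
        flat = ChoiceCoefficients(beta_d=-0.08, beta_cR=0.0, beta_cS=0.3)
        total, *_ = trip_elasticity(flat, 2.46, 0.07, 0.3, 0.5, "red_drum")
        assert total == 0.0

    def test_components_additive(self, coefs):
        total, part, site = trip_elasticity(coefs, 2.46, 0.0749, 0.3, 0.54, "spotted_seatrout")
        assert total == pytest.approx(part + site)

    @pytest.mark.parametrize("species,j", [("red_drum", 0), ("spotted_seatrout", 3)])
    def test_matches_finite_difference_oracle(self, base_tables, coefs, species, j):
        """Eq-by-construction check: elasticity equals d ln(PT*Pj) / d ln cj
        computed through the choice probabilities and the exact logistic."""
        base = base_tables["high"]
        rates = base_catch_rates(base)
        dv = calibrate_distance_vector(base, coefs)
        lam = lambda_from_wtp(coefs.beta_d, 30, 1.0)
        pt0 = 0.0749
        shares = base.trips / base.trips.sum()
        cj = float(rates[species][j])
        total, _, _ = trip_elasticity(coefs, lam, pt0, float(shares[j]), cj, species)

        iv0 = inclusive_value(rates, dv, coefs)
        alpha = np.log(pt0 / (1 - pt0)) - lam * iv0

        def log_pjt(c):
            catch = {k: v.copy() for k, v in rates.items()}
            catch[species][j] = c
            iv = inclusive_value(catch, dv, coefs)
            pt = 1 / (1 + np.exp(-(alpha + lam * iv)))
            pj = site_choice_probs(catch, dv, coefs)[j]
            return np.log(pt * pj)

        h = 1e-6
        fd = (log_pjt(cj * (1 + h)) - log_pjt(cj * (1 - h))) / (2 * h)
        assert total == pytest.approx(fd, rel=1e-5)


class TestInclusiveValue:
    def test_single_site_is_utility(self, coefs):
        u = coefs.beta_d * 50 + coefs.beta_cR * 0.3
        iv = inclusive_value({"red_drum": np.array([0.3])}, np.array([50.0]), coefs)
        assert iv == pytest.approx(u)

    def test_identical_sites_add_log_j(self, coefs):
        catch = {"red_drum": np.full(5, 0.3), "spotted_seatrout": np.full(5, 0.6)}
        u = coefs.beta_d * 80 + coefs.beta_cR * 0.3 + coefs.beta_cS * 0.6
        iv = inclusive_value(catch, np.full(5, 80.0), coefs)
        assert iv == pytest.approx(u + np.log(5))

    def test_matches_direct_summation(self, base_tables, coefs):
        base = base_tables["high"]
        rates = base_catch_rates(base)
        dv = calibrate_distance_vector(base, coefs)
        u = (coefs.beta_d * dv.miles + coefs.beta_cR * rates["red_drum"]
             + coefs.beta_cS * rates["spotted_seatrout"])
        assert inclusive_value(rates, dv, coefs) == pytest.approx(np.log(np.exp(u).sum()))


class TestEstimateChoiceCoefficients:
    def _sites(self, base_tables, coefs):
        base = base_tables["high"]
        rates = base_catch_rates(base)
        dv = calibrate_distance_vector(base, coefs)
        return pd.DataFrame({
            "distance": dv.miles,
            "catch_red_drum": rates["red_drum"],
            "catch_spotted_seatrout": rates["spotted_seatrout"],
        })

    def test_recovery_within_3se(self, base_tables, coefs):
        from baytrips.synthetic import gen_choice_dataset
        truth = ChoiceCoefficients(beta_d=-0.08, beta_cR=0.17, beta_cS=0.35)
        recs = gen_choice_dataset(truth, self._sites(base_tables, coefs),
                                  n_records=3000, seed=3)
        est = estimate_choice_coefficients(recs)
        assert abs(est.beta_d - truth.beta_d) < 3 * est.se_d
        assert abs(est.beta_cR - truth.beta_cR) < 3 * est.se_cR
        assert abs(est.beta_cS - truth.beta_cS) < 3 * est.se_cS

    def test_doubling_distances_halves_beta_d(self, base_tables, coefs):
        from baytrips.synthetic import gen_choice_dataset
        truth = ChoiceCoefficients(beta_d=-0.08, beta_cR=0.17, beta_cS=0.35)
        sites = self._sites(base_tables, coefs)
        recs = gen_choice_dataset(truth, sites, n_records=1500, seed=9)
        doubled = recs.copy()
        doubled["distance"] = 2.0 * doubled["distance"]
        est1 = estimate_choice_coefficients(recs)
        est2 = estimate_choice_coefficients(doubled)
        # agreement limited by optimizer tolerance, not the identity itself
        assert est2.beta_d == pytest.approx(est1.beta_d / 2, rel=1e-4)

    def test_no_catch_variation_errors(self, base_tables, coefs):
        sites = self._sites(base_tables, coefs)
        from baytrips.synthetic import gen_choice_dataset
        recs = gen_choice_dataset(
            ChoiceCoefficients(beta_d=-0.08, beta_cR=0.2, beta_cS=0.3),
            sites, n_records=100, seed=1, catch_jitter=0.0,
        )
        recs["catch_red_drum"] = 0.5
        recs["catch_spotted_seatrout"] = 0.5
        with pytest.raises(ValueError, match="inestimable"):
            estimate_choice_coefficients(recs)
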