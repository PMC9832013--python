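"""Return-time estimators: closed forms, first passage, curves, discovery."""

import math

import numpy as np
import pytest

from islert.data_model import MainlandPool, RateSet, ValidationError
from islert.ert import (
    ERTQuery,
    equilibrium_diversity,
    ert_vs_loss_curve,
    estimate_ert,
    expected_trajectory_crossing,
    first_passage_ert,
)


class TestEquilibrium:
    def test_sink_equilibrium_value(self, preferred_rates, study_pool):
        eq = equilibrium_diversity(preferred_rates["bat"], study_pool, "bat")
        assert eq.equilibrium
        assert eq.value == pytest.approx(7.48 / 0.13, rel=1e-9)
        assert int(eq.value) == 57

    def test_non_equilibrium_flagged(self, preferred_rates, study_pool):
        eq = equilibrium_diversity(preferred_rates["nonvolant"], study_pool,
                                   "nonvolant")
        assert not eq.equilibrium
        assert math.isinf(eq.value)

    def test_zero_inflow(self, study_pool):
        eq = equilibrium_diversity(RateSet(0, 0.1, 0, 0.3), study_pool, "bat")
        assert eq.value == 0.0


class TestExpectedTrajectory:
    def test_start_equals_target(self, preferred_rates, study_pool):
        res = expected_trajectory_crossing(preferred_rates["bat"], study_pool,
                                           "bat", 44, 44)
        assert res.estimate == 0.0

    def test_zero_growth_linear_accumulation(self):
        pool = MainlandPool(M=220, p_guild2=1.0, island_age=88.0)
        r = RateSet(7.5 / 220, 0.2, 0.0, 0.2)  # lambda_c == mu
        res = expected_trajectory_crossing(r, pool, "bat", 0, 2)
        assert res.estimate == pytest.approx(2 / 7.5, rel=1e-9)

    def test_headline_crossings(self, preferred_rates, study_pool):
        cases = [
            ("bat", 44, 46, 1.2295),
            ("bat", 39, 44, 2.4178),
            ("bat", 29, 44, 5.7363),
            ("nonvolant", 175, 203, 3.5763),
            ("nonvolant", 52, 175, 28.162),
            ("nonvolant", 44, 175, 31.806),
        ]
        for g, s, t, expect in cases:
            res = expected_trajectory_crossing(preferred_rates[g], study_pool,
                                               g, s, t)
            assert res.estimate == pytest.approx(expect, rel=1e-3)

    def test_unreachable_above_equilibrium(self, preferred_rates, study_pool):
        res = expected_trajectory_crossing(preferred_rates["bat"], study_pool,
                                           "bat", 10, 80)  # above ~57.5
        assert not res.reachable
        assert res.censored == 1

    def test_deficit_monotonicity(self, preferred_rates, study_pool):
        r = preferred_rates["nonvolant"]
        erts = [expected_trajectory_crossing(r, study_pool, "nonvolant",
                                             s, 203).estimate
                for s in range(202, 150, -5)]
        assert all(b > a for a, b in zip(erts, erts[1:]))

    def test_finite_K_rejected(self, study_pool):
        with pytest.raises(ValidationError):
            expected_trajectory_crossing(RateSet(0.01, 0.1, 0.1, 0.2, K=40),
                                         study_pool, "bat", 10, 20)


class TestFirstPassage:
    def test_start_equals_target(self, preferred_rates, study_pool):
        res = first_passage_ert(preferred_rates["bat"], study_pool, "bat",
                                35, 9, 44, n_reps=50, seed=0)
        assert res.estimate == 0.0
        assert res.censored == 0

    def test_erlang_sum_of_exponentials(self):
        """Pure immigration at rate 7.5: time to gain 2 species is
        Erlang(2, 7.5)."""
        pool = MainlandPool(M=220, p_guild2=1.0, island_age=88.0)
        r = RateSet(7.5 / 220, 0, 0, 0)
        res = first_passage_ert(r, pool, "bat", 0, 0, 2, n_reps=20000, seed=3)
        assert res.estimate == pytest.approx(2 / 7.5, rel=0.03)
        assert res.values.var() == pytest.approx(2 / 7.5 ** 2, rel=0.08)

    def test_matches_expected_trajectory_at_large_n(self, preferred_rates,
                                                    study_pool):
        """Near-deterministic regime: mean first passage within 10% of the
        deterministic crossing for the large non-volant recovery."""
        det = expected_trajectory_crossing(
            preferred_rates["nonvolant"], study_pool, "nonvolant", 52, 175)
        sim = first_passage_ert(preferred_rates["nonvolant"], study_pool,
                                "nonvolant", 52, 0, 175, n_reps=400, seed=5)
        assert sim.estimate == pytest.approx(det.estimate, rel=0.10)

    def test_all_censored_raises(self, study_pool):
        with pytest.raises(ValidationError):
            first_passage_ert(RateSet(0, 0, 0, 0.5), study_pool, "bat",
                              5, 0, 10, n_reps=20, horizon=5.0, seed=1)

    def test_global_endemic_counts_only_endemics(self, study_pool):
        """With speciation off, colonization alone never raises global
        diversity; anagenesis does."""
        no_ana = RateSet(0.05, 0, 0, 0)
        with pytest.raises(ValidationError):
            first_passage_ert(no_ana, study_pool, "bat", 2, 0, 4,
                              diversity_kind="global_endemic", n_reps=30,
                              horizon=30.0, seed=2)
        with_ana = RateSet(0.05, 0, 2.0, 0)
        res = first_passage_ert(with_ana, study_pool, "bat", 2, 0, 4,
                                diversity_kind="global_endemic", n_reps=200,
                                horizon=200.0, seed=2)
        assert res.estimate > 0

    def test_query_dispatch(self, preferred_rates, study_pool):
        q = ERTQuery(guild="bat", start_endemic=35, start_non_endemic=9,
                     target_total=46, estimator="expected_trajectory")
        res = estimate_ert(q, preferred_rates["bat"], study_pool)
        assert res.estimate == pytest.approx(1.2295, rel=1e-3)


class TestLossCurves:
    def test_zero_loss_zero_ert(self, preferred_rates, study_pool):
        tab = ert_vs_loss_curve(preferred_rates["bat"], study_pool, "bat",
                                46, n_draws=300, seed=0)
        zero = tab[tab["lost"] == 0]
        assert (zero["ert"] == 0).all()

    def test_nonvolant_per_species_cost_shrinks_at_high_diversity(
            self, preferred_rates, study_pool):
        """Supercritical guild: recovering one extra species is cheaper
        when diversity is already high (concave-decelerating curve)."""
        r = preferred_rates["nonvolant"]
        target = 203
        inc = [expected_trajectory_crossing(r, study_pool, "nonvolant", s,
                                            target).estimate
               - expected_trajectory_crossing(r, study_pool, "nonvolant",
                                              s + 1, target).estimate
               for s in (60, 120, 180)]
        assert inc[0] > inc[1] > inc[2]

    def test_bat_per_species_cost_grows_near_plateau(self, preferred_rates,
                                                     study_pool):
        """Sink-equilibrium guild: marginal species get ever slower to
        recover approaching the plateau."""
        r = preferred_rates["bat"]
        target = 46
        inc = [expected_trajectory_crossing(r, study_pool, "bat", s,
                                            target).estimate
               - expected_trajectory_crossing(r, study_pool, "bat", s + 1,
                                              target).estimate
               for s in (5, 25, 42)]
        assert inc[0] < inc[1] < inc[2]

    def test_curve_table_schema(self, preferred_rates, study_pool):
        tab = ert_vs_loss_curve(preferred_rates["bat"], study_pool, "bat",
                                46, n_draws=150, seed=1)
        assert set(tab.columns) == {"start", "lost", "endemic_start", "ert"}
        assert len(tab) == 150
        assert (tab["start"] + tab["lost"] == 46).all()


class TestDiscoveryPerturbation:
    DISC_RATES = {
        "nonvolant": RateSet(0.0008, 0.40, 1.0, 0.25),
        "bat": RateSet(0.034, 0.33, 1.0, 0.46),
    }

    @pytest.fixture()
    def small_sim_dataset(self):
        from islert.simulator import prune_to_observed, simulate_island
        pool = MainlandPool(M=400, p_guild2=0.3, island_age=25.0)
        return prune_to_observed(simulate_island(self.DISC_RATES, pool,
                                                 seed=9))

    def test_no_discoveries_degenerate_at_baseline(self, small_sim_dataset):
        from islert.ert import discovery_perturbation
        from islert.inference import model_registry
        baseline = {"bat": (15, 20), "nonvolant": (10, 16)}
        out = discovery_perturbation(
            small_sim_dataset, {"bat": 0, "nonvolant": 0}, "all_threatened",
            model_registry()["M26"], baseline, n_reps=2, n_starts=1, seed=1,
            maxfev=250, restart=False)
        by_rep = out.groupby("guild")["ert"].nunique()
        assert (by_rep == 1).all()

    def test_discoveries_raise_fitted_rates(self, small_sim_dataset):
        """Extra clade members push the cladogenesis estimate up in the
        median replicate."""
        from islert.ert import discovery_perturbation
        from islert.inference import model_registry
        spec = model_registry()["M26"]
        baseline = {"bat": (15, 20)}
        base = discovery_perturbation(
            small_sim_dataset, {"bat": 0}, "all_threatened", spec, baseline,
            n_reps=1, n_starts=1, seed=2, maxfev=300, restart=False)
        pert = discovery_perturbation(
            small_sim_dataset, {"bat": 6}, "all_threatened", spec, baseline,
            n_reps=3, n_starts=1, seed=2, maxfev=300, restart=False)
        lam_base = base["lambda_c"].iloc[0]
        lam_new = pert.groupby("rep")["lambda_c"].first().median()
        assert lam_new > lam_base

    def test_guild_contrast_in_ert_shift(self, small_sim_dataset):
        """The same number of discoveries moves the sink guild's return
        time much more than the growing guild's."""
        from islert.ert import discovery_perturbation
        from islert.inference import ModelSpec
        # the generative rates are held fixed except anagenesis (which the
        # expected-trajectory ERT does not involve), isolating the
        # scenario accounting from refit noise
        roles = {}
        for p in ("gamma", "lambda_c", "mu"):
            roles[p] = {g: ("fixed", getattr(self.DISC_RATES[g], p))
                        for g in ("nonvolant", "bat")}
        roles["lambda_a"] = {"nonvolant": "free", "bat": "shared"}
        roles["K"] = {g: ("fixed", math.inf) for g in ("nonvolant", "bat")}
        spec = ModelSpec(model_id="la_only", roles=roles)
        baseline = {"bat": (15, 20), "nonvolant": (10, 16)}
        base = discovery_perturbation(
            small_sim_dataset, {"bat": 0, "nonvolant": 0}, "all_extinct",
            spec, baseline, n_reps=1, n_starts=1, seed=3, maxfev=150,
            restart=False)
        pert = discovery_perturbation(
            small_sim_dataset, {"bat": 5, "nonvolant": 5}, "all_extinct",
            spec, baseline, n_reps=2, n_starts=1, seed=3, maxfev=150,
            restart=False)
        rel = {}
        for g in ("bat", "nonvolant"):
            e0 = base[base["guild"] == g]["ert"].iloc[0]
            e1 = pert[pert["guild"] == g]["ert"].median()
            rel[g] = abs(e1 - e0) / e0
        assert rel["nonvolant"] < rel["bat"]

    def test_empty_guild_rejected(self, preferred_rates, study_pool):
        from islert.data_model import IslandDataset
        from islert.ert import discovery_perturbation
        from islert.inference import model_registry
        ds = IslandDataset(pool=study_pool)
        with pytest.raises(ValidationError):
            discovery_perturbation(ds, {"bat": 1}, "all_threatened",
                                   model_registry()["M26"],
                                   {"bat": (1, 2)}, n_reps=1)
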