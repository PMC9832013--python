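"""Likelihood module: closed forms, route agreement, simulator equivalence."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from islert._bd import bd_mean, p0, q1
from islert.data_model import (
    ColonistRecord,
    IslandDataset,
    MainlandPool,
    RateSet,
    ValidationError,
)
from islert.likelihood import (
    LikelihoodSettings,
    ShiftedRates,
    TruncationError,
    clade_loglik,
    dataset_loglik,
    guild_colonization_rate,
    lineage_state_probabilities,
)
from islert.simulator import simulate_lineage_final_states


class TestBirthDeathPrimitives:
    def test_p0_limits(self):
        assert p0(0.3, 0.0, 5.0) == 0.0
        assert float(p0(0.0, 0.3, 5.0)) == pytest.approx(1 - math.exp(-1.5))

    def test_q1_is_exact_one_descendant_probability(self):
        # against the geometric distribution of descendant counts
        lam, mu, t = 0.4, 0.25, 6.0
        P0 = float(p0(lam, mu, t))
        eta = lam * P0 / mu
        assert float(q1(lam, mu, t)) == pytest.approx((1 - P0) * (1 - eta))

    def test_q1_critical_case(self):
        lam = 0.3
        assert float(q1(lam, lam, 4.0)) == pytest.approx(
            1.0 / (1 + lam * 4.0) ** 2)

    def test_bd_mean_zero_growth(self):
        assert float(bd_mean(7.5, 0.0, 2.0)) == pytest.approx(15.0)


class TestLineageStateProbabilities:
    def test_all_rates_zero(self):
        d = lineage_state_probabilities(RateSet(0, 0, 0, 0), 88.0)
        assert d.p_empty == pytest.approx(1.0)

    def test_no_extinction_empty_iff_never_colonized(self):
        d = lineage_state_probabilities(RateSet(0.01, 0, 0, 0), 88.0)
        assert d.p_empty == pytest.approx(math.exp(-0.88), rel=1e-8)

    def test_probabilities_sum_to_one(self, generic_rates):
        d = lineage_state_probabilities(generic_rates, 20.0)
        assert d.prob.sum() == pytest.approx(1.0, abs=1e-7)

    def test_truncation_error_advises(self):
        with pytest.raises(TruncationError, match="n_max"):
            lineage_state_probabilities(
                RateSet(1.0, 2.0, 0.0, 0.01), 50.0,
                LikelihoodSettings(n_max=10))

    def test_matches_gillespie_frequency(self):
        """P(empty) agrees with simulation within 3 MC standard errors."""
        r = RateSet(0.02, 0.0, 0.0, 0.1)
        d = lineage_state_probabilities(r, 20.0)
        n = 40000
        sim = simulate_lineage_final_states(r, 20.0, n, seed=7)
        f = (sim.sum(axis=1) == 0).mean()
        se = math.sqrt(d.p_empty * (1 - d.p_empty) / n)
        assert abs(f - d.p_empty) < 3 * se


def _tv(rates, T, n_sims, seed):
    d = lineage_state_probabilities(rates, T)
    sim = simulate_lineage_final_states(rates, T, n_sims, seed)
    emp = {}
    for b, e in sim:
        emp[(b, e)] = emp.get((b, e), 0) + 1
    tv = 0.0
    seen = set(emp)
    for b in (0, 1):
        for e in range(d.prob.shape[1]):
            seen.add((b, e))
    for key in seen:
        b, e = key
        p_th = d.prob[b, e] if e < d.prob.shape[1] else 0.0
        tv += abs(emp.get(key, 0) / n_sims - p_th)
    return tv / 2


@pytest.mark.parametrize("rates", [
    RateSet(0.3, 0.2, 0.1, 0.15),
    RateSet(0.5, 0.4, 0.0, 0.3, K=4),
    RateSet(0.2, 0.0, 0.5, 0.1),
    RateSet(0.1, 0.6, 0.2, 0.5, K=10),
])
def test_state_distribution_matches_simulation(rates):
    """Master equation vs Gillespie: total variation below 0.02."""
    assert _tv(rates, 5.0, 30000, seed=11) < 0.02


class TestCladeLoglik:
    T = 20.0
    rates = RateSet(gamma=0.02, lambda_c=0.3, lambda_a=0.5, mu=0.2)
    # effectively diversity-independent, but routed through the master
    # equation: an independent check of the analytic formulas
    rates_bigK = RateSet(gamma=0.02, lambda_c=0.3, lambda_a=0.5, mu=0.2,
                         K=1e9)

    def test_impossible_without_colonization(self):
        rec = ColonistRecord("x", "bat", "max_age", 10.0, (), "non_endemic")
        assert clade_loglik(rec, RateSet(0, 0.1, 0.1, 0.1), self.T) == -math.inf

    def test_max_age_non_endemic_closed_form(self):
        """With no extinction, presence <=> colonized at least once."""
        rec = ColonistRecord("x", "bat", "max_age", 88.0, (), "non_endemic")
        ll = clade_loglik(rec, RateSet(0.01, 0, 0, 0), 88.0)
        assert ll == pytest.approx(math.log(1 - math.exp(-0.88)), rel=1e-6)

    def test_precise_non_endemic_closed_form(self):
        """Pure colonization: waiting-time density with censoring."""
        rec = ColonistRecord("x", "bat", "precise", 6.0, (), "non_endemic")
        ll = clade_loglik(rec, RateSet(0.01, 0, 0, 0), 10.0)
        assert ll == pytest.approx(math.log(0.01) - 0.01 * 4.0, rel=1e-6)

    @pytest.mark.parametrize("rec", [
        ColonistRecord("a", "bat", "precise", 8.0, (5.0, 2.5, 1.0), "endemic"),
        ColonistRecord("b", "bat", "precise", 8.0, (), "endemic"),
        ColonistRecord("c", "bat", "max_age", 8.0, (5.0, 1.0), "endemic"),
        ColonistRecord("d", "bat", "precise", 8.0, (), "non_endemic"),
        ColonistRecord("e", "bat", "max_age", 8.0, (), "non_endemic"),
        ColonistRecord("f", "bat", "precise", 8.0, (5.0,),
                       "endemic_and_non_endemic"),
        ColonistRecord("g", "bat", "max_age", 8.0, (5.0,),
                       "endemic_and_non_endemic"),
    ])
    def test_analytic_and_master_equation_routes_agree(self, rec):
        la = clade_loglik(rec, self.rates, self.T)
        lo = clade_loglik(rec, self.rates_bigK, self.T)
        assert la == pytest.approx(lo, abs=5e-7)

    def test_missing_species_marginalize_placements(self):
        """One missing species equals the brute-force marginal over its
        attachment time and lineage (negligible recolonization)."""
        r = RateSet(gamma=1e-8, lambda_c=0.25, lambda_a=0.4, mu=0.3)
        T, tc = 8.0, 5.0

        def dens(bts):
            return math.exp(clade_loglik(
                ColonistRecord("x", "bat", "precise", tc, bts, "endemic"),
                r, T))

        I1, _ = quad(lambda x: dens((x,)), 1e-6, tc - 1e-6, limit=100)
        via = math.exp(clade_loglik(
            ColonistRecord("x", "bat", "precise", tc, (), "endemic", 1), r, T))
        assert via == pytest.approx(2.0 * I1, rel=1e-3)

        I2a, _ = quad(lambda y: dens((2.5, y)), 1e-6, 2.5 - 1e-9, limit=200)
        I2b, _ = quad(lambda y: dens((y, 2.5)), 2.5 + 1e-9, tc - 1e-6,
                      limit=200)
        via2 = math.exp(clade_loglik(
            ColonistRecord("x", "bat", "precise", tc, (2.5,), "endemic", 1),
            r, T))
        assert via2 == pytest.approx(2.0 * I2a + I2b, rel=1e-3)

    def test_max_age_window_shrinks_to_precise_density(self):
        """Integrated likelihood ~ precise density x window width."""
        x2, eps = 3.0, 1e-4
        rec_w = ColonistRecord("x", "bat", "max_age", x2 + eps, (x2,),
                               "endemic")
        rec_p = ColonistRecord("x", "bat", "precise", x2 + eps / 2, (x2,),
                               "endemic")
        lw = clade_loglik(rec_w, self.rates, self.T)
        lp = clade_loglik(rec_p, self.rates, self.T)
        assert lw == pytest.approx(lp + math.log(eps), abs=1e-3)

    def test_density_matches_binned_simulation(self):
        """2-species endemic clade: exp(loglik) equals the Monte-Carlo
        density of (colonization time, branching time) in a bin."""
        from numpy.random import SeedSequence, default_rng
        from islert.simulator import prune_to_observed, simulate_island
        from islert.data_model import Status

        r = RateSet(gamma=0.15, lambda_c=0.25, lambda_a=0.4, mu=0.3)
        pool = MainlandPool(M=1, p_guild2=0.0, island_age=8.0)
        n = 40000
        hits = []
        for ss in SeedSequence(42).spawn(n):
            ds = prune_to_observed(simulate_island(
                {"nonvolant": r, "bat": RateSet(0, 0, 0, 0)}, pool,
                default_rng(ss)))
            if ds.n_colonists() == 1:
                rec = ds.colonists[0]
                if (rec.status is Status.ENDEMIC
                        and len(rec.branching_times) == 1
                        and rec.n_missing == 0):
                    hits.append((rec.col_time, rec.branching_times[0]))
        hits = np.asarray(hits)
        tc0, x0, w = 5.0, 2.0, 0.4
        inbin = int(((np.abs(hits[:, 0] - tc0) < w / 2)
                     & (np.abs(hits[:, 1] - x0) < w / 2)).sum())
        dens_mc = inbin / n / w ** 2
        se = math.sqrt(inbin) / n / w ** 2
        rec = ColonistRecord("x", "nonvolant", "precise", tc0, (x0,),
                             "endemic")
        dens_th = math.exp(clade_loglik(rec, r, 8.0))
        assert abs(dens_mc - dens_th) < 3 * se


class TestDatasetLoglik:
    def test_empty_dataset_zero_gamma(self):
        pool = MainlandPool(M=10, p_guild2=0.5, island_age=88.0)
        ds = IslandDataset(pool=pool)
        z = RateSet(0, 0, 0, 0)
        assert dataset_loglik(ds, {"nonvolant": z, "bat": z}) == pytest.approx(0.0)

    def test_empty_island_additivity(self):
        """Independence across mainland lineages: 10 x (-gamma T)."""
        pool = MainlandPool(M=10, p_guild2=0.0, island_age=88.0)
        ds = IslandDataset(pool=pool)
        r = RateSet(0.01, 0, 0, 0)
        ll = dataset_loglik(ds, {"nonvolant": r, "bat": r})
        assert ll == pytest.approx(-8.8, rel=1e-6)

    def test_additivity_over_identical_records(self, generic_rates):
        pool = MainlandPool(M=50, p_guild2=0.0, island_age=20.0)
        rec = ColonistRecord("a", "nonvolant", "max_age", 6.0, (),
                             "non_endemic")
        rec2 = ColonistRecord("b", "nonvolant", "max_age", 6.0, (),
                              "non_endemic")
        r = {"nonvolant": generic_rates, "bat": generic_rates}
        l0 = dataset_loglik(IslandDataset(pool=pool), r)
        l1 = dataset_loglik(IslandDataset(pool=pool, colonists=(rec,)), r)
        l2 = dataset_loglik(IslandDataset(pool=pool, colonists=(rec, rec2)), r)
        per_clade = clade_loglik(rec, generic_rates, 20.0)
        background = l0 / 50.0
        assert l1 == pytest.approx(per_clade + 49 * background, rel=1e-6)
        assert l2 == pytest.approx(2 * per_clade + 48 * background, rel=1e-6)

    def test_invariant_to_record_order(self, small_dataset, generic_rates):
        r = {"nonvolant": generic_rates, "bat": generic_rates}
        fwd = dataset_loglik(small_dataset, r)
        rev = dataset_loglik(
            small_dataset.with_colonists(small_dataset.colonists[::-1]), r)
        assert fwd == pytest.approx(rev, rel=1e-12)

    def test_invariant_to_guild_rate_object_identity(self, small_dataset,
                                                     generic_rates):
        twin = RateSet(**{k: getattr(generic_rates, k)
                          for k in ("gamma", "lambda_c", "lambda_a", "mu", "K")})
        a = dataset_loglik(small_dataset,
                           {"nonvolant": generic_rates, "bat": generic_rates})
        b = dataset_loglik(small_dataset,
                           {"nonvolant": generic_rates, "bat": twin})
        assert a == pytest.approx(b, rel=1e-12)

    def test_missing_guild_rates_raise(self, small_dataset, generic_rates):
        with pytest.raises(ValidationError):
            dataset_loglik(small_dataset, {"nonvolant": generic_rates})

    def test_conditioning_reduces_loglik_of_observed_data(self, generic_rates):
        pool = MainlandPool(M=20, p_guild2=0.0, island_age=20.0)
        rec = ColonistRecord("a", "nonvolant", "max_age", 6.0, (),
                             "non_endemic")
        ds = IslandDataset(pool=pool, colonists=(rec,))
        r = {"nonvolant": generic_rates, "bat": generic_rates}
        plain = dataset_loglik(ds, r)
        cond = dataset_loglik(
            ds, r, LikelihoodSettings(conditioning="at_least_one_colonization"))
        assert cond > plain  # dividing by P(>=1 colonization) < 1

    def test_normalization_over_outcome_partition(self):
        """For one mainland lineage the record-type probabilities and the
        empty outcome sum to one (max-age records are state probabilities)."""
        r = RateSet(gamma=0.1, lambda_c=0.0, lambda_a=0.3, mu=0.2)
        T = 10.0
        d = lineage_state_probabilities(r, T)
        # with lambda_c = 0: outcomes are empty / lone non-endemic /
        # endemic singletons (anagenesis, no splitting)
        p_ne = math.exp(clade_loglik(
            ColonistRecord("x", "bat", "max_age", T, (), "non_endemic"), r, T))
        assert p_ne == pytest.approx(d.prob[1, 0], rel=1e-6)
        total = d.prob.sum()
        assert total == pytest.approx(1.0, abs=1e-7)


class TestShiftedRates:
    def test_shift_reduces_to_constant_when_equal(self, generic_rates):
        rec = ColonistRecord("a", "bat", "precise", 8.0, (5.0,), "endemic")
        sh = ShiftedRates(rates=generic_rates, tau_shift=10.0,
                          gamma_before=generic_rates.gamma)
        assert clade_loglik(rec, sh, 20.0) == pytest.approx(
            clade_loglik(rec, generic_rates, 20.0), rel=1e-8)

    def test_shift_changes_colonization_era_weight(self, generic_rates):
        # colonization rate zero before the shift: old colonizations
        # impossible
        sh = ShiftedRates(rates=generic_rates, tau_shift=6.0, gamma_before=0.0)
        old = ColonistRecord("a", "bat", "precise", 8.0, (), "endemic")
        young = ColonistRecord("a", "bat", "precise", 4.0, (), "endemic")
        assert clade_loglik(old, sh, 20.0) == -math.inf
        assert clade_loglik(young, sh, 20.0) > -math.inf


class TestGuildColonizationRate:
    def test_printed_rates(self, study_pool):
        assert guild_colonization_rate(
            RateSet(0.00036, 0.33, 1.47, 0.29), study_pool, "nonvolant"
        ) == pytest.approx(0.2808)
        assert guild_colonization_rate(
            RateSet(0.034, 0.33, 1.47, 0.46), study_pool, "bat"
        ) == pytest.approx(7.48)

    def test_zero(self, study_pool):
        assert guild_colonization_rate(RateSet(0, 0, 0, 0), study_pool,
                                       "bat") == 0.0
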