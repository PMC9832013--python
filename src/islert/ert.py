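"""Evolutionary return times: how long until island diversity recovers.

Under the fitted CES rates with infinite ``K``, a guild's expected local
diversity obeys the linear immigration-birth-death equation
``dN/dt = Gamma + r N`` with total colonization inflow
``Gamma = gamma * M_guild`` and net diversification ``r = lambda_c - mu``.
The expected-trajectory estimator returns the crossing time

    t* = (1/r) * ln((target + Gamma/r) / (start + Gamma/r))      (r != 0)
    t* = (target - start) / Gamma                                 (r == 0)

When ``r < 0`` diversity tends to the sink equilibrium ``Gamma / (mu -
lambda_c)`` maintained by immigration; targets above it are unreachable.
The first-passage estimator instead simulates stochastic trajectories
forward and records when each first reaches the target, either in local
diversity (every island species) or in global-endemic diversity (only new
endemic species count: anagenesis and cladogenesis increment it,
colonization does not).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data_model import (
    Guild,
    IslandDataset,
    MainlandPool,
    RateSet,
    Status,
    ValidationError,
)
from .inference import ModelSpec, fit_model
from .likelihood import LikelihoodSettings, ShiftedRates

__all__ = [
    "ERTQuery",
    "ERTResult",
    "EquilibriumResult",
    "equilibrium_diversity",
    "expected_trajectory_crossing",
    "first_passage_ert",
    "estimate_ert",
    "ert_vs_loss_curve",
    "discovery_perturbation",
]


def _base(rates) -> RateSet:
    return rates.rates if isinstance(rates, ShiftedRates) else rates


@dataclass(frozen=True)
class ERTQuery:
    """A return-time question for one guild."""

    guild: str
    start_endemic: int
    start_non_endemic: int
    target_total: int
    diversity_kind: str = "local"            # or "global_endemic"
    estimator: str = "expected_trajectory"   # or "first_passage"
    n_reps: int = 1000
    horizon: float | None = None
    seed: int = 0

    @property
    def start_total(self) -> int:
        return self.start_endemic + self.start_non_endemic


@dataclass
class ERTResult:
    estimate: float            # Myr (mean over uncensored replicates)
    p2_5: float
    p97_5: float
    censored: int = 0
    n_reps: int = 1
    reachable: bool = True
    values: np.ndarray | None = None


@dataclass(frozen=True)
class EquilibriumResult:
    value: float
    equilibrium: bool


def equilibrium_diversity(rates, pool: MainlandPool, guild) -> EquilibriumResult:
    """Sink-equilibrium diversity ``Gamma / (mu - lambda_c)``.

    Flagged non-equilibrium (infinite value) when ``mu <= lambda_c``: the
    guild's diversity then grows without bound instead of saturating.
    """
    r = _base(rates)
    G = r.gamma * pool.guild_size(guild)
    if r.mu <= r.lambda_c:
        return EquilibriumResult(value=math.inf, equilibrium=False)
    return EquilibriumResult(value=G / (r.mu - r.lambda_c), equilibrium=True)


def expected_trajectory_crossing(rates, pool: MainlandPool, guild,
                                 start_total: float, target_total: float
                                 ) -> ERTResult:
    """Deterministic crossing time of the expected-diversity trajectory."""
    rs = _base(rates)
    if not math.isinf(rs.K):
        raise ValidationError(
            "expected-trajectory estimator requires infinite K; "
            "use the first-passage estimator for diversity-dependent rates")
    G = rs.gamma * pool.guild_size(guild)
    r = rs.lambda_c - rs.mu
    if target_total <= start_total:
        return ERTResult(0.0, 0.0, 0.0)
    if abs(r) < 1e-12:
        if G <= 0:
            return ERTResult(math.inf, math.inf, math.inf, censored=1,
                             reachable=False)
        t = (target_total - start_total) / G
        return ERTResult(t, t, t)
    a = target_total + G / r
    b = start_total + G / r
    if r < 0 and target_total >= G / (-r):
        return ERTResult(math.inf, math.inf, math.inf, censored=1,
                         reachable=False)
    if r > 0 and b <= 0:
        return ERTResult(math.inf, math.inf, math.inf, censored=1,
                         reachable=False)
    t = math.log(a / b) / r
    return ERTResult(t, t, t)


def first_passage_ert(rates, pool: MainlandPool, guild,
                      start_endemic: int, start_non_endemic: int,
                      target: int, diversity_kind: str = "local",
                      n_reps: int = 1000, horizon: float | None = None,
                      seed: int = 0) -> ERTResult:
    """Stochastic first-passage time to the target diversity.

    Simulates the guild's community forward (aggregate counts; with
    infinite ``K`` clade identity is dynamically irrelevant).  Replicates
    not reaching the target by the horizon are censored and excluded from
    the mean, with their count reported.
    """
    rs = _base(rates)
    if diversity_kind not in ("local", "global_endemic"):
        raise ValidationError(f"unknown diversity kind {diversity_kind!r}")
    G = rs.gamma * pool.guild_size(guild)
    lam, mu, la = rs.lambda_c, rs.mu, rs.lambda_a
    if horizon is None:
        try:
            det = expected_trajectory_crossing(
                rates, pool, guild, start_endemic + start_non_endemic, target)
            horizon = 10.0 * det.estimate if math.isfinite(det.estimate) \
                and det.estimate > 0 else 500.0
        except ValidationError:
            horizon = 500.0
    rng = np.random.default_rng(seed)
    ne = np.full(n_reps, start_non_endemic, dtype=float)
    en = np.full(n_reps, start_endemic, dtype=float)
    t = np.zeros(n_reps)
    hit = np.full(n_reps, np.nan)

    def metric():
        return (ne + en) if diversity_kind == "local" else en

    done = metric() >= target
    hit[done] = 0.0
    active = ~done
    while active.any():
        N = ne + en
        if math.isinf(rs.K):
            A = 1.0
        else:
            A = np.maximum(0.0, 1.0 - N / rs.K)
        w_col = G * A * np.ones_like(N) if np.ndim(A) else G * A
        w_col = np.broadcast_to(np.asarray(w_col, dtype=float), N.shape).copy()
        w_cla = lam * N * A
        w_ext = mu * N
        w_ana = la * ne
        tot = w_col + w_cla + w_ext + w_ana
        stuck = active & (tot <= 0)
        active = active & ~stuck
        if not active.any():
            break
        dt = rng.exponential(1.0, size=n_reps) / np.where(tot > 0, tot, 1.0)
        t = np.where(active, t + dt, t)
        u = rng.uniform(0.0, 1.0, size=n_reps) * tot
        is_col = u < w_col
        is_cla = ~is_col & (u < w_col + w_cla)
        is_ext = ~is_col & ~is_cla & (u < w_col + w_cla + w_ext)
        is_ana = ~is_col & ~is_cla & ~is_ext
        pick_ne = rng.uniform(0.0, 1.0, size=n_reps) * np.maximum(N, 1.0) < ne
        ne = np.where(active & is_col, ne + 1, ne)
        en = np.where(active & is_cla & pick_ne, en + 2, en)
        ne = np.where(active & is_cla & pick_ne, ne - 1, ne)
        en = np.where(active & is_cla & ~pick_ne, en + 1, en)
        ne = np.where(active & is_ext & pick_ne, ne - 1, ne)
        en = np.where(active & is_ext & ~pick_ne, en - 1, en)
        ne = np.where(active & is_ana, ne - 1, ne)
        en = np.where(active & is_ana, en + 1, en)
        reached = active & (metric() >= target)
        hit[reached] = t[reached]
        active = active & ~reached & (t < horizon)

    ok = np.isfinite(hit)
    censored = int(n_reps - ok.sum())
    if not ok.any():
        raise ValidationError(
            "all replicates censored; increase the horizon or n_reps")
    vals = hit[ok]
    return ERTResult(
        estimate=float(vals.mean()),
        p2_5=float(np.percentile(vals, 2.5)),
        p97_5=float(np.percentile(vals, 97.5)),
        censored=censored, n_reps=n_reps, values=vals)


def estimate_ert(query: ERTQuery, rates, pool: MainlandPool) -> ERTResult:
    """Dispatch an :class:`ERTQuery` to the configured estimator."""
    if query.estimator == "expected_trajectory":
        if query.diversity_kind != "local":
            raise ValidationError(
                "the expected-trajectory estimator applies to local diversity")
        return expected_trajectory_crossing(
            rates, pool, query.guild, query.start_total, query.target_total)
    if query.estimator == "first_passage":
        return first_passage_ert(
            rates, pool, query.guild, query.start_endemic,
            query.start_non_endemic, query.target_total,
            diversity_kind=query.diversity_kind, n_reps=query.n_reps,
            horizon=query.horizon, seed=query.seed)
    raise ValidationError(f"unknown estimator {query.estimator!r}")


def ert_vs_loss_curve(rates, pool: MainlandPool, guild, target_total: int,
                      n_draws: int = 10000, seed: int = 0,
                      estimator: str = "expected_trajectory") -> pd.DataFrame:
    """Return time as a function of the number of species to recover.

    Draws ``n_draws`` random start diversities uniform on ``{0..target}``
    with a uniform random endemic proportion (non-endemics capped at the
    guild's mainland pool), computes the ERT for each, and returns a tidy
    table with columns ``start``, ``lost``, ``endemic_start``, ``ert``.
    """
    if n_draws < 100:
        raise ValidationError("n_draws must be >= 100")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, target_total + 1, size=n_draws)
    p_end = rng.uniform(0.0, 1.0, size=n_draws)
    cap = pool.guild_size(guild)
    rows = []
    for s, pe in zip(starts, p_end):
        n_end = int(round(s * pe))
        n_ne = min(int(s) - n_end, cap)
        n_end = int(s) - n_ne
        if estimator == "expected_trajectory":
            res = expected_trajectory_crossing(rates, pool, guild, s, target_total)
        else:
            res = first_passage_ert(rates, pool, guild, n_end, n_ne,
                                    target_total, n_reps=200,
                                    seed=int(rng.integers(2**31)))
        rows.append({"start": int(s), "lost": int(target_total - s),
                     "endemic_start": n_end, "ert": res.estimate})
    return pd.DataFrame(rows)


def discovery_perturbation(dataset: IslandDataset, n_new_by_guild: dict,
                           fate: str, spec: ModelSpec,
                           baseline: dict, n_reps: int = 100,
                           n_starts: int = 2, seed: int = 0,
                           settings: LikelihoodSettings | None = None,
                           maxfev: int = 2000,
                           restart: bool = True) -> pd.DataFrame:
    """Impact of future species discoveries on the return time.

    Per replicate, each newly discovered species is appended as a missing
    species to a uniformly chosen existing colonist clade of its guild
    (discoveries enter the data regardless of fate, mirroring the
    anthropogenic-extinction convention), the model is refitted, and the
    ERT is recomputed with the target raised by the number of discoveries
    (``fate`` ``all_threatened`` / ``half_threatened_half_extinct`` /
    ``all_extinct``; discovered extant-threatened species join the target
    community but not the start).

    ``baseline`` maps guild -> (start_total, target_total).
    Returns a tidy frame: one row per replicate x guild with the fitted
    rates and the ERT.
    """
    if fate not in ("all_threatened", "half_threatened_half_extinct",
                    "all_extinct"):
        raise ValidationError(f"unknown fate {fate!r}")
    for gname, m in n_new_by_guild.items():
        if m > 0 and not dataset.guild_records(gname):
            raise ValidationError(
                f"guild {gname} has no clades to receive discoveries")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_reps):
        recs = list(dataset.colonists)
        for gname, m in n_new_by_guild.items():
            # lone non-endemic populations cannot host unplaced clade
            # members; discoveries join island clades
            idxs = [i for i, r in enumerate(recs)
                    if r.guild is Guild(gname)
                    and r.status is not Status.NON_ENDEMIC]
            if m > 0 and not idxs:
                raise ValidationError(
                    f"guild {gname} has no island clades to receive "
                    "discoveries")
            for _ in range(int(m)):
                i = idxs[int(rng.integers(len(idxs)))]
                recs[i] = replace(recs[i], n_missing=recs[i].n_missing + 1)
        ds = dataset.with_colonists(recs)
        fit = fit_model(ds, spec, n_starts=n_starts,
                        seed=int(rng.integers(2**31)), settings=settings,
                        maxfev=maxfev, restart=restart)
        for gname, (start, target) in baseline.items():
            m = int(n_new_by_guild.get(gname, 0))
            res = expected_trajectory_crossing(
                fit.rates_by_guild[Guild(gname).value], dataset.pool, gname,
                start, target + m)
            rows.append({
                "rep": rep, "guild": Guild(gname).value, "fate": fate,
                "gamma": fit.param("gamma", Guild(gname).value),
                "lambda_c": fit.param("lambda_c", Guild(gname).value),
                "lambda_a": fit.param("lambda_a", Guild(gname).value),
                "mu": fit.param("mu", Guild(gname).value),
                "loglik": fit.loglik, "ert": res.estimate,
            })
    return pd.DataFrame(rows)
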