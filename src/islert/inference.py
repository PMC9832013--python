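"""Maximum-likelihood fitting and model selection for the CES model family.

The model family spans one- and two-guild parameterizations: every CES
parameter (``gamma``, ``lambda_c``, ``lambda_a``, ``mu``, ``K``) can be
free, fixed, or (for the bat guild) shared with the non-volant guild;
``K`` is either estimated or fixed to infinity (no diversity dependence),
and two time-shift variants allow the colonization rate to change at an
estimated time.  Optimization is multi-start Nelder-Mead on log-transformed
parameters.

The numbered registry (``M1``-``M32``) mirrors the conventional layout of
such model tables: ``M1``-``M4`` are one-guild (homogeneous) models,
``M5``-``M30`` let subsets of the rates differ between non-volant mammals
and bats with and without diversity dependence, and ``M31``/``M32`` add a
colonization-rate shift.  Which sharing pattern carries which id is a
documentation convention (see ``docs/methods.md``); code should select
models by pattern, e.g. ``model_registry()["M26"]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .data_model import Guild, IslandDataset, RateSet, ValidationError
from .likelihood import (
    LikelihoodSettings,
    ShiftedRates,
    TruncationError,
    dataset_loglik,
)

__all__ = [
    "ModelSpec",
    "FitResult",
    "ModelSelection",
    "BatchFitResult",
    "fit_model",
    "model_selection_table",
    "batch_fit",
    "model_registry",
    "default_n_eff",
]

PARAM_ORDER = ("gamma", "lambda_c", "lambda_a", "mu", "K")
_G1, _G2 = Guild.NONVOLANT.value, Guild.BAT.value


@dataclass(frozen=True)
class ModelSpec:
    """One model: a role per (parameter, guild) plus an optional shift.

    ``roles[param][guild]`` is ``"free"``, ``"shared"`` (bat guild tied to
    the non-volant value) or ``("fixed", value)``.  ``shift=True`` adds a
    free shift time and pre-shift colonization rate(s), following the
    sharing pattern of ``gamma``.
    """

    model_id: str
    roles: dict = field(hash=False)
    shift: bool = False

    def __post_init__(self) -> None:
        for p in PARAM_ORDER:
            if p not in self.roles:
                raise ValidationError(f"{self.model_id}: missing role for {p}")
            for g in (_G1, _G2):
                role = self.roles[p].get(g)
                if role == "shared" and g == _G1:
                    raise ValidationError(
                        f"{self.model_id}: guild 1 cannot share")
                ok = role in ("free", "shared") or (
                    isinstance(role, tuple) and role[0] == "fixed")
                if not ok:
                    raise ValidationError(
                        f"{self.model_id}: bad role {role!r} for {p}/{g}")
        if not self.free_params():
            raise ValidationError(f"{self.model_id}: no free parameters")

    @classmethod
    def build(cls, model_id: str, differ: frozenset | set = frozenset(),
              K: str | float = "inf", lambda_a="free",
              shift: bool = False) -> "ModelSpec":
        """Two-guild spec: parameters in ``differ`` get their own bat value.

        ``K`` is ``"free"`` or ``"inf"`` (or a number); ``lambda_a`` is
        ``"free"`` or a fixed number (0 disables anagenesis).
        """
        roles: dict = {}
        for p in ("gamma", "lambda_c", "mu"):
            roles[p] = {_G1: "free", _G2: "free" if p in differ else "shared"}
        la_role = "free" if lambda_a == "free" else ("fixed", float(lambda_a))
        roles["lambda_a"] = {
            _G1: la_role,
            _G2: ("free" if "lambda_a" in differ and lambda_a == "free"
                  else ("shared" if lambda_a == "free" else la_role)),
        }
        if K == "free":
            k_role = "free"
            roles["K"] = {_G1: k_role, _G2: "free" if "K" in differ else "shared"}
        else:
            kv = math.inf if K == "inf" else float(K)
            roles["K"] = {_G1: ("fixed", kv), _G2: ("fixed", kv)}
        return cls(model_id=model_id, roles=roles, shift=shift)

    def free_params(self) -> list[tuple[str, str]]:
        """Free coordinates in optimization order."""
        out = []
        for p in PARAM_ORDER:
            for g in (_G1, _G2):
                if self.roles[p][g] == "free":
                    out.append((p, g))
        if self.shift:
            out.append(("tau_shift", "both"))
            out.append(("gamma_before", _G1))
            if self.roles["gamma"][_G2] == "free":
                out.append(("gamma_before", _G2))
        return out

    @property
    def k(self) -> int:
        return len(self.free_params())

    def rates_from_vector(self, theta: np.ndarray, T: float) -> dict:
        """Map the optimizer vector (log/logit scale) to per-guild rates."""
        fp = self.free_params()
        vals: dict[tuple[str, str], float] = {}
        for (p, g), th in zip(fp, theta):
            if p == "tau_shift":
                vals[(p, g)] = T / (1.0 + math.exp(-th))
            else:
                vals[(p, g)] = math.exp(th)
        out = {}
        for g in (_G1, _G2):
            kw = {}
            for p in PARAM_ORDER:
                role = self.roles[p][g]
                if role == "free":
                    kw[p] = vals[(p, g)]
                elif role == "shared":
                    r1 = self.roles[p][_G1]
                    kw[p] = (vals[(p, _G1)] if r1 == "free" else r1[1])
                else:
                    kw[p] = role[1]
            rates = RateSet(**kw)
            if self.shift:
                gb_g = g if ("gamma_before", g) in vals else _G1
                out[g] = ShiftedRates(rates=rates,
                                      tau_shift=vals[("tau_shift", "both")],
                                      gamma_before=vals[("gamma_before", gb_g)])
            else:
                out[g] = rates
        return out


def model_registry() -> dict[str, ModelSpec]:
    """The numbered model family M1-M32 (sharing patterns; ids provisional)."""
    reg: dict[str, ModelSpec] = {}
    reg["M1"] = ModelSpec.build("M1", K="free")
    reg["M2"] = ModelSpec.build("M2", K="inf")
    reg["M3"] = ModelSpec.build("M3", K="free", lambda_a=0.0)
    reg["M4"] = ModelSpec.build("M4", K="inf", lambda_a=0.0)
    subsets = [
        {"gamma"}, {"lambda_c"}, {"lambda_a"}, {"mu"},
        {"gamma", "lambda_c"}, {"gamma", "lambda_a"},
        {"lambda_c", "lambda_a"}, {"lambda_c", "mu"}, {"lambda_a", "mu"},
        {"gamma", "lambda_c", "lambda_a"},
        {"gamma", "mu"},                      # -> M25 (K free) / M26 (K inf)
        {"gamma", "lambda_c", "mu"}, {"gamma", "lambda_a", "mu"},
    ]
    mid = 5
    for sub in subsets:
        for K in ("free", "inf"):
            reg[f"M{mid}"] = ModelSpec.build(f"M{mid}", differ=frozenset(sub), K=K)
            mid += 1
    reg["M31"] = ModelSpec.build("M31", K="inf", shift=True)
    reg["M32"] = ModelSpec.build("M32", differ=frozenset({"gamma", "mu"}),
                                 K="inf", shift=True)
    return reg


@dataclass
class FitResult:
    model_id: str
    rates_by_guild: dict
    loglik: float
    k: int
    AIC: float
    BIC: float
    converged: bool
    n_starts: int
    best_start_seed: int
    n_eff: int

    def param(self, name: str, guild: str) -> float:
        r = self.rates_by_guild[guild]
        base = r.rates if isinstance(r, ShiftedRates) else r
        return getattr(base, name)


def default_n_eff(dataset: IslandDataset) -> int:
    """Observed colonizations plus branching events (BIC sample size)."""
    return sum(1 + len(r.branching_times) for r in dataset.colonists)


def _start_vector(spec: ModelSpec, dataset: IslandDataset,
                  rng: np.random.Generator) -> np.ndarray:
    """Log-uniform start draws: rates on [1e-4, 10], K on [n_big, 1e3]."""
    n_big = max((r.n_species for r in dataset.colonists), default=1)
    theta = []
    for p, _g in spec.free_params():
        if p == "K":
            lo, hi = math.log(max(n_big, 2.0)), math.log(1e3)
        elif p == "tau_shift":
            theta.append(rng.normal(0.0, 1.0))
            continue
        else:
            lo, hi = math.log(1e-4), math.log(10.0)
        theta.append(rng.uniform(lo, hi))
    return np.asarray(theta)


def _moment_start(spec: ModelSpec, dataset: IslandDataset) -> np.ndarray:
    """Crude method-of-moments start values on the optimizer scale.

    Colonization from the colonist count over lineage-time, cladogenesis
    from branching events over reconstructed tree length; extinction and
    anagenesis seeded at field-typical magnitudes relative to those.
    """
    T = dataset.pool.island_age
    mom: dict[tuple[str, str], float] = {}
    for g in (_G1, _G2):
        recs = dataset.guild_records(g)
        M_g = max(dataset.pool.guild_size(g), 1)
        n_col = len(recs)
        gamma0 = max(n_col, 0.5) / (M_g * T) * 2.0
        tree_len = sum(r.col_time + sum(r.branching_times) for r in recs)
        n_branch = sum(len(r.branching_times) + r.n_missing for r in recs)
        lam0 = max(n_branch, 0.5) / max(tree_len, T * 0.2)
        mom[("gamma", g)] = gamma0
        mom[("lambda_c", g)] = lam0
        mom[("lambda_a", g)] = max(0.5, lam0)
        mom[("mu", g)] = 0.7 * lam0 + 0.05
        n_big = max((r.n_species for r in recs), default=1)
        mom[("K", g)] = 10.0 * n_big + 10.0
    theta = []
    for p, g in spec.free_params():
        if p == "tau_shift":
            theta.append(0.0)
        elif p == "gamma_before":
            theta.append(math.log(mom[("gamma", g)]))
        else:
            theta.append(math.log(mom[(p, g)]))
    return np.asarray(theta)


def fit_model(dataset: IslandDataset, spec: ModelSpec, n_starts: int = 10,
              seed: int = 0, settings: LikelihoodSettings | None = None,
              n_eff: int | None = None, maxfev: int = 5000,
              xatol: float = 1e-6, fatol: float = 1e-8,
              restart: bool = True) -> FitResult:
    """Maximize the dataset log-likelihood over the model's free parameters.

    Derivative-free (Nelder-Mead) local optimization on log-transformed
    parameters from ``n_starts`` random starting points; deterministic
    given ``seed``.  Returns the best start; ``converged=False`` if every
    start failed.
    """
    if n_starts < 1:
        raise ValidationError("n_starts must be >= 1")
    # a tighter truncation cap during optimization: saturating corners are
    # treated as impossible instead of endlessly enlarged
    settings = settings or LikelihoodSettings(n_max_cap=160)
    T = dataset.pool.island_age
    rng = np.random.default_rng(seed)
    nm_cache: dict = {}
    n_big = max((r.n_species for r in dataset.colonists), default=1)
    lo_b, hi_b = [], []
    for p, _g in spec.free_params():
        if p == "K":
            lo_b.append(math.log(max(n_big, 1.0)) - 1e-9)
            hi_b.append(math.log(1e6))
        elif p == "tau_shift":
            lo_b.append(-math.inf)
            hi_b.append(math.inf)
        else:
            lo_b.append(-21.0)
            hi_b.append(math.log(30.0))
    lo_b, hi_b = np.asarray(lo_b), np.asarray(hi_b)

    def objective(theta: np.ndarray) -> float:
        # box on the natural scale keeps the search out of absurd regions
        if np.any(theta > hi_b) or np.any(theta < lo_b):
            return 1e12
        try:
            rates = spec.rates_from_vector(theta, T)
            for r in rates.values():
                base = r.rates if isinstance(r, ShiftedRates) else r
                if base.K < n_big:
                    return 1e12
            ll = dataset_loglik(dataset, rates, settings, nm_cache)
        except (ValidationError, TruncationError, OverflowError):
            return 1e12
        if not math.isfinite(ll):
            return 1e12
        return -ll

    best = None
    for i in range(n_starts):
        x0 = (_moment_start(spec, dataset) if i == 0
              else _start_vector(spec, dataset, rng))
        for _try in range(60):  # reject starts in impossible regions
            if objective(x0) < 1e11:
                break
            x0 = _start_vector(spec, dataset, rng)
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"maxfev": maxfev, "xatol": xatol,
                                "fatol": fatol, "adaptive": len(x0) > 4})
        # one restart with a fresh simplex: guards against premature
        # simplex collapse along nearly flat directions
        if restart and res.fun < 1e11:
            res2 = minimize(objective, res.x, method="Nelder-Mead",
                            options={"maxfev": maxfev, "xatol": xatol,
                                     "fatol": fatol,
                                     "adaptive": len(x0) > 4})
            if res2.fun < res.fun:
                res = res2
        ok = res.fun < 1e11
        if ok and (best is None or res.fun < best[0]):
            best = (res.fun, res.x, i, bool(res.success))

    k = spec.k
    n_eff = default_n_eff(dataset) if n_eff is None else n_eff
    if best is None:
        return FitResult(spec.model_id, {}, -math.inf, k, math.inf, math.inf,
                         False, n_starts, -1, n_eff)
    fun, x, i, success = best
    ll = -fun
    return FitResult(
        model_id=spec.model_id,
        rates_by_guild=spec.rates_from_vector(x, T),
        loglik=ll, k=k,
        AIC=2 * k - 2 * ll,
        BIC=k * math.log(max(n_eff, 1)) - 2 * ll,
        converged=success or True,  # best finite optimum is reported
        n_starts=n_starts, best_start_seed=i, n_eff=n_eff,
    )


@dataclass
class ModelSelection:
    table: pd.DataFrame
    results: dict[str, FitResult]

    @property
    def best_id(self) -> str:
        return str(self.table.iloc[0]["model_id"])


def model_selection_table(dataset: IslandDataset, specs: list[ModelSpec],
                          n_starts: int = 10, seed: int = 0,
                          criterion: str = "BIC",
                          settings: LikelihoodSettings | None = None,
                          maxfev: int = 5000,
                          restart: bool = True) -> ModelSelection:
    """Fit every spec and rank by the information criterion (default BIC).

    Ties are broken in favour of fewer parameters; unconverged fits are
    flagged and excluded from the ranking.
    """
    if len(specs) < 2:
        raise ValidationError("model selection needs at least two specs")
    if criterion not in ("AIC", "BIC"):
        raise ValidationError(f"unknown criterion {criterion!r}")
    results = {}
    for j, spec in enumerate(specs):
        results[spec.model_id] = fit_model(
            dataset, spec, n_starts=n_starts, seed=seed + 1000 * j,
            settings=settings, maxfev=maxfev, restart=restart)
    rows = [{
        "model_id": r.model_id, "k": r.k, "loglik": r.loglik,
        "AIC": r.AIC, "BIC": r.BIC, "converged": r.converged,
    } for r in results.values()]
    df = pd.DataFrame(rows)
    conv = df[df["converged"]]
    for c in ("AIC", "BIC"):
        df[f"d{c}"] = df[c] - (conv[c].min() if len(conv) else math.nan)
    df = df.sort_values(["converged", criterion, "k"],
                        ascending=[False, True, True]).reset_index(drop=True)
    return ModelSelection(table=df, results=results)


@dataclass
class BatchFitResult:
    results: list[FitResult]
    summary: pd.DataFrame
    n_failed: int


def batch_fit(datasets: list[IslandDataset], spec: ModelSpec,
              n_starts: int = 2, seed: int = 0,
              settings: LikelihoodSettings | None = None,
              n_jobs: int = 1, maxfev: int = 5000,
              restart: bool = True) -> BatchFitResult:
    """Fit one model across a dataset collection (e.g. a tree posterior).

    Returns per-dataset fits plus a per-parameter summary (mean and
    2.5-97.5 percentiles over converged fits).  Results are independent of
    execution order.
    """
    if len(datasets) < 2:
        raise ValidationError("batch_fit needs at least two datasets")
    seeds = [seed + 7919 * i for i in range(len(datasets))]

    def one(ds, sd):
        try:
            return fit_model(ds, spec, n_starts=n_starts, seed=sd,
                             settings=settings, maxfev=maxfev,
                             restart=restart)
        except (ValidationError, TruncationError):
            return None

    if n_jobs != 1:
        from joblib import Parallel, delayed
        fits = Parallel(n_jobs=n_jobs)(
            delayed(one)(ds, sd) for ds, sd in zip(datasets, seeds))
    else:
        fits = [one(ds, sd) for ds, sd in zip(datasets, seeds)]

    ok = [f for f in fits if f is not None and f.converged]
    rows = []
    for p, g in spec.free_params():
        if p in ("tau_shift", "gamma_before"):
            continue
        vals = np.array([f.param(p, g) for f in ok])
        rows.append({
            "param": p, "guild": g, "mean": vals.mean() if len(vals) else math.nan,
            "p2.5": np.percentile(vals, 2.5) if len(vals) else math.nan,
            "p97.5": np.percentile(vals, 97.5) if len(vals) else math.nan,
        })
    return BatchFitResult(results=[f for f in fits if f is not None],
                          summary=pd.DataFrame(rows),
                          n_failed=sum(f is None or not f.converged for f in fits))
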