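"""Exact stochastic simulation of island community assembly.

Doob-Gillespie realization of the CES process: every mainland lineage
colonizes at rate ``gamma * max(0, 1 - n/K)`` (``n`` = its clade's current
island diversity, colonization of a clade with an extant conspecific
non-endemic population has no effect), every island species goes extinct
at ``mu`` and speciates cladogenetically at ``lambda_c * max(0, 1 - n/K)``
(both daughters endemic), and every non-endemic population anagenetically
becomes endemic at ``lambda_a``.

The simulation clock runs from the island origin ``T`` (Myr BP) down to
the present (0).  Event logs are complete: the final state is exactly
reproducible by replaying them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .data_model import (
    ColonistRecord,
    ColTimeKind,
    Guild,
    IslandDataset,
    MainlandPool,
    RateSet,
    Status,
    ValidationError,
)

__all__ = [
    "SimEvent",
    "SimSpecies",
    "SimHistory",
    "simulate_island",
    "replay_final_state",
    "prune_to_observed",
    "goodness_of_fit",
    "simulate_lineage_final_states",
]


@dataclass(frozen=True)
class SimEvent:
    time: float
    kind: str                 # colonization | cladogenesis | anagenesis | extinction
    guild: Guild
    lineage: int              # mainland lineage id within guild
    species: int              # focal species id
    new_species: int = -1     # daughter id for colonization/cladogenesis

    def to_dict(self) -> dict:
        return {
            "time": self.time, "kind": self.kind, "guild": self.guild.value,
            "lineage": self.lineage, "species": self.species,
            "new_species": self.new_species,
        }


@dataclass
class SimSpecies:
    sid: int
    guild: Guild
    lineage: int
    parent: int               # parent species id, -1 for colonists
    birth_time: float
    death_time: float | None = None
    endemic: bool = False

    @property
    def alive(self) -> bool:
        return self.death_time is None


@dataclass
class SimHistory:
    pool: MainlandPool
    rates_by_guild: dict
    events: list[SimEvent] = field(default_factory=list)
    species: dict[int, SimSpecies] = field(default_factory=dict)
    seed: int | None = None

    def extant(self, guild: Guild | str | None = None) -> list[SimSpecies]:
        g = Guild(guild) if guild is not None else None
        return [s for s in self.species.values()
                if s.alive and (g is None or s.guild is g)]

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for ev in self.events:
                fh.write(json.dumps(ev.to_dict()) + "\n")


def _rates_for(rates_by_guild: dict, guild: Guild) -> RateSet:
    if guild.value in rates_by_guild:
        return rates_by_guild[guild.value]
    if guild in rates_by_guild:
        return rates_by_guild[guild]
    raise ValidationError(f"no rates for guild {guild.value}")


def _dd(n: int, K: float) -> float:
    return 1.0 if math.isinf(K) else max(0.0, 1.0 - n / K)


class _GuildState:
    """Bookkeeping for one guild's clades during simulation."""

    def __init__(self, rates: RateSet, M: int):
        self.rates = rates
        self.M = M
        # per active mainland lineage: [species ids alive], ne species id or -1
        self.clades: dict[int, list[int]] = {}
        self.ne_of: dict[int, int] = {}

    def propensities(self):
        r = self.rates
        K = r.K
        col = 0.0
        clad = 0.0
        ext = 0.0
        ana = 0.0
        n_active = len(self.clades)
        col += r.gamma * (self.M - n_active)  # empty clades, A(0) = 1
        for lin, members in self.clades.items():
            n = len(members)
            A = _dd(n, K)
            if self.ne_of.get(lin, -1) < 0:
                col += r.gamma * A
            clad += r.lambda_c * n * A
            ext += r.mu * n
            if self.ne_of.get(lin, -1) >= 0:
                ana += r.lambda_a
        return col, clad, ext, ana


def simulate_island(rates_by_guild: dict, pool: MainlandPool,
                    seed: int | np.random.Generator) -> SimHistory:
    """Simulate one island from origin ``T`` to the present.

    Reproducible given ``seed``; per-guild mainland lineages are labelled
    ``0 .. M_guild - 1``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for g in Guild:
        r = _rates_for(rates_by_guild, g)
        if not all(math.isfinite(x) for x in (r.gamma, r.lambda_c, r.lambda_a, r.mu)):
            raise ValidationError("rates must be finite")

    hist = SimHistory(pool=pool, rates_by_guild=dict(rates_by_guild),
                      seed=None if isinstance(seed, np.random.Generator) else int(seed))
    states = {g: _GuildState(_rates_for(rates_by_guild, g), pool.guild_size(g))
              for g in Guild}
    t = pool.island_age
    next_sid = 0

    while True:
        props = {g: st.propensities() for g, st in states.items()}
        total = sum(sum(p) for p in props.values())
        if total <= 0.0:
            break
        t -= rng.exponential(1.0 / total)
        if t <= 0.0:
            break
        # pick guild and channel
        u = rng.uniform(0.0, total)
        guild = None
        for g, p in props.items():
            s = sum(p)
            if u < s:
                guild = g
                break
            u -= s
        st = states[guild]
        r = st.rates
        col, clad, ext, ana = props[guild]

        if u < col:
            # choose lineage: empty ones uniformly, active ones by A(n)
            w_empty = r.gamma * (st.M - len(st.clades))
            if u < w_empty:
                active = set(st.clades)
                lin = None
                while lin is None:
                    cand = int(rng.integers(st.M))
                    if cand not in active:
                        lin = cand
            else:
                u2 = u - w_empty
                lin = None
                for lid, members in st.clades.items():
                    if st.ne_of.get(lid, -1) >= 0:
                        continue
                    w = r.gamma * _dd(len(members), r.K)
                    if u2 < w:
                        lin = lid
                        break
                    u2 -= w
                if lin is None:  # numerical slack
                    continue
            sid = next_sid
            next_sid += 1
            hist.species[sid] = SimSpecies(sid, guild, lin, -1, t, None, False)
            st.clades.setdefault(lin, []).append(sid)
            st.ne_of[lin] = sid
            hist.events.append(SimEvent(t, "colonization", guild, lin, sid, sid))
            continue
        u -= col

        if u < clad:
            lin = None
            for lid, members in st.clades.items():
                w = r.lambda_c * len(members) * _dd(len(members), r.K)
                if u < w:
                    lin = lid
                    break
                u -= w
            if lin is None:
                continue
            members = st.clades[lin]
            parent = members[int(rng.integers(len(members)))]
            child = next_sid
            next_sid += 1
            psp = hist.species[parent]
            if not psp.endemic:  # immigrant split: both daughters endemic
                psp.endemic = True
                if st.ne_of.get(lin, -1) == parent:
                    st.ne_of[lin] = -1
            hist.species[child] = SimSpecies(child, guild, lin, parent, t, None, True)
            members.append(child)
            hist.events.append(SimEvent(t, "cladogenesis", guild, lin, parent, child))
            continue
        u -= clad

        if u < ext:
            all_members = [(lid, s) for lid, mem in st.clades.items() for s in mem]
            lin, sid = all_members[int(rng.integers(len(all_members)))]
            sp = hist.species[sid]
            sp.death_time = t
            st.clades[lin].remove(sid)
            if not st.clades[lin]:
                del st.clades[lin]
                st.ne_of.pop(lin, None)
            elif st.ne_of.get(lin, -1) == sid:
                st.ne_of[lin] = -1
            hist.events.append(SimEvent(t, "extinction", guild, lin, sid))
            continue
        u -= ext

        # anagenesis
        ne_lineages = [lid for lid, sid in st.ne_of.items() if sid >= 0]
        if not ne_lineages:
            continue
        lin = ne_lineages[int(rng.integers(len(ne_lineages)))]
        sid = st.ne_of[lin]
        hist.species[sid].endemic = True
        st.ne_of[lin] = -1
        hist.events.append(SimEvent(t, "anagenesis", guild, lin, sid))

    return hist


def replay_final_state(history: SimHistory) -> dict[int, tuple[bool, bool]]:
    """Replay the event log; map species id -> (alive, endemic)."""
    state: dict[int, tuple[bool, bool]] = {}
    for ev in history.events:
        if ev.kind == "colonization":
            state[ev.new_species] = (True, False)
        elif ev.kind == "cladogenesis":
            state[ev.species] = (state[ev.species][0], True)
            state[ev.new_species] = (True, True)
        elif ev.kind == "anagenesis":
            state[ev.species] = (state[ev.species][0], True)
        else:
            state[ev.species] = (False, state[ev.species][1])
    return state


# ---------------------------------------------------------------------------
# Pruning to the observed dataset
# ---------------------------------------------------------------------------

def _reconstructed_nodes(root: int, species: dict[int, SimSpecies],
                         children: dict[int, list[int]]) -> tuple[list[float], list[int]]:
    """Branching times of the reconstructed (extant-lineage) tree below
    ``root`` and the extant species of that subtree."""
    memo: dict[int, bool] = {}

    def subtree_extant(s: int) -> bool:
        if s not in memo:
            memo[s] = species[s].alive or any(
                subtree_extant(c) for c in children.get(s, []))
        return memo[s]

    def line_extant_after(s: int, t: float) -> bool:
        # the parent's own line after a birth at time t: itself alive, or a
        # later (younger) daughter subtree survives
        if species[s].alive:
            return True
        return any(species[c].birth_time < t and subtree_extant(c)
                   for c in children.get(s, []))

    nodes: list[float] = []
    extant: list[int] = []
    stack = [root]
    while stack:
        s = stack.pop()
        if species[s].alive:
            extant.append(s)
        for c in children.get(s, []):
            if not subtree_extant(c):
                continue
            if line_extant_after(s, species[c].birth_time):
                nodes.append(species[c].birth_time)
            stack.append(c)
    return sorted(nodes, reverse=True), extant


def prune_to_observed(history: SimHistory) -> IslandDataset:
    """Reduce a simulation history to the present-day observation.

    Clades with no extant species vanish.  Per surviving clade the
    colonization time is the oldest colonization with extant descendants,
    branching times are the reconstructed-tree nodes of that colonization's
    extant species, and the status comes from the extant members.  An
    extant non-endemic founded by a later re-colonization marks the record
    ``endemic_and_non_endemic``; extant endemics descending from younger
    re-colonizations are folded into ``n_missing``.
    """
    species = history.species
    children: dict[int, list[int]] = {}
    roots: dict[tuple[Guild, int], list[int]] = {}
    for s in species.values():
        if s.parent >= 0:
            children.setdefault(s.parent, []).append(s.sid)
        else:
            roots.setdefault((s.guild, s.lineage), []).append(s.sid)

    memo: dict[int, bool] = {}

    def subtree_extant(s: int) -> bool:
        if s not in memo:
            memo[s] = species[s].alive or any(
                subtree_extant(c) for c in children.get(s, []))
        return memo[s]

    records = []
    for (guild, lin), rts in sorted(roots.items(),
                                    key=lambda kv: (kv[0][0].value, kv[0][1])):
        live_roots = [r for r in rts if subtree_extant(r)]
        if not live_roots:
            continue
        live_roots.sort(key=lambda r: -species[r].birth_time)
        main = live_roots[0]
        bts, extant = _reconstructed_nodes(main, species, children)
        extra_endemic = 0
        ne_alive = False
        for r in live_roots:
            if r == main:
                continue
            _, ex = _reconstructed_nodes(r, species, children)
            for sid in ex:
                if species[sid].endemic:
                    extra_endemic += 1
                else:
                    ne_alive = True
        main_ne = any(not species[s].endemic for s in extant)
        clade_id = f"{guild.value}_{lin}"
        if main_ne and len(extant) == 1 and not (extra_endemic or ne_alive):
            records.append(ColonistRecord(
                clade_id=clade_id, guild=guild,
                col_time_kind=ColTimeKind.MAX_AGE,
                col_time=species[main].birth_time, branching_times=(),
                status=Status.NON_ENDEMIC, n_missing=0))
            continue
        status = (Status.ENDEMIC_AND_NON_ENDEMIC if (ne_alive or main_ne)
                  else Status.ENDEMIC)
        records.append(ColonistRecord(
            clade_id=clade_id, guild=guild, col_time_kind=ColTimeKind.PRECISE,
            col_time=species[main].birth_time,
            branching_times=tuple(bts), status=status,
            n_missing=extra_endemic))
    return IslandDataset(pool=history.pool, colonists=tuple(records),
                         label="simulated")


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------

def _guild_metrics(ds: IslandDataset, guild: Guild) -> dict[str, float]:
    recs = ds.guild_records(guild)
    n_end = sum(r.n_species for r in recs if r.status is not Status.NON_ENDEMIC)
    n_ne = sum(1 for r in recs
               if r.status in (Status.NON_ENDEMIC, Status.ENDEMIC_AND_NON_ENDEMIC))
    return {
        "n_colonists": len(recs),
        "n_species": ds.n_species(guild) + n_ne - sum(
            1 for r in recs if r.status is Status.NON_ENDEMIC),
        "n_endemic": n_end,
        "n_non_endemic": n_ne,
        "largest_clade": max((r.n_species for r in recs), default=0),
    }


def goodness_of_fit(dataset: IslandDataset, rates_by_guild: dict,
                    n_sims: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Compare observed diversity metrics to their simulated distributions.

    Simulates ``n_sims`` islands under the supplied rates, prunes each to
    an observed dataset and tabulates 2.5/50/97.5 percentiles of colonist
    counts, species counts by endemicity and largest clade size per guild,
    flagging whether each observed value falls in the central 95%.
    """
    if n_sims < 100:
        raise ValidationError("n_sims must be >= 100")
    streams = np.random.SeedSequence(seed).spawn(n_sims)
    sims: list[IslandDataset] = []
    for ss in streams:
        hist = simulate_island(rates_by_guild, dataset.pool,
                               np.random.default_rng(ss))
        sims.append(prune_to_observed(hist))
    rows = []
    for g in Guild:
        obs = _guild_metrics(dataset, g)
        sim_vals = {k: np.array([_guild_metrics(s, g)[k] for s in sims])
                    for k in obs}
        for metric, vals in sim_vals.items():
            lo, med, hi = np.percentile(vals, [2.5, 50, 97.5])
            rows.append({
                "guild": g.value, "metric": metric, "observed": obs[metric],
                "p2.5": lo, "p50": med, "p97.5": hi,
                "inside_95": bool(lo <= obs[metric] <= hi),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fast per-lineage final-state simulation (single mainland lineage)
# ---------------------------------------------------------------------------

def simulate_lineage_final_states(rates: RateSet, T: float, n_sims: int,
                                  seed: int = 0) -> np.ndarray:
    """Simulate one mainland lineage's clade ``n_sims`` times.

    Returns an integer array of shape ``(n_sims, 2)`` with columns
    (non-endemic present, endemic count) at the present: the empirical
    counterpart of :func:`islert.likelihood.lineage_state_probabilities`.
    """
    rng = np.random.default_rng(seed)
    g, lam, la, mu, K = (rates.gamma, rates.lambda_c, rates.lambda_a,
                         rates.mu, rates.K)
    out = np.empty((n_sims, 2), dtype=int)
    for i in range(n_sims):
        t = T
        b, e = 0, 0
        while True:
            n = b + e
            A = _dd(n, K)
            col = g * A if b == 0 else 0.0
            clad = lam * n * A
            ext = mu * n
            ana = la * b
            tot = col + clad + ext + ana
            if tot <= 0.0:
                break
            t -= rng.exponential(1.0 / tot)
            if t <= 0.0:
                break
            u = rng.uniform(0.0, tot)
            if u < col:
                b = 1
            elif u < col + clad:
                if b and rng.uniform(0.0, n) < 1.0:
                    b, e = 0, e + 2   # immigrant split: two endemics
                else:
                    e += 1
            elif u < col + clad + ext:
                if b and rng.uniform(0.0, n) < 1.0:
                    b = 0
                else:
                    e -= 1
            else:
                b, e = 0, e + 1       # anagenesis
        out[i] = (b, e)
    return out
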