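"""Synthetic data generators and packaged study fixtures.

The fixtures encode only printed aggregate quantities of the Madagascar
mammal study system: community counts by guild and endemicity under the
diversity scenarios, the preferred-model (M26-style) CES rates, and the
mainland pool.  The generators create full synthetic artifacts with known
ground truth: species checklists whose aggregates match a configuration
exactly, jittered pseudo-posterior dataset collections, and small dated
trees with annotated island clades for exercising the extraction code.
No real per-species identities are reproduced; all species labels are
synthetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import (
    ChecklistTable,
    CommunityCounts,
    Guild,
    IslandDataset,
    MainlandPool,
    RateSet,
    ValidationError,
)
from .tree_extraction import IslandAnnotation

__all__ = [
    "TruthConfig",
    "GuildChecklistShape",
    "m26_rates",
    "madagascar_pool",
    "madagascar_counts",
    "make_madagascar_fixtures",
    "madagascar_truth_config",
    "fixture",
    "generate_checklist",
    "generate_pseudo_posterior",
    "generate_island_tree_set",
]

_NV, _BAT = Guild.NONVOLANT.value, Guild.BAT.value


def m26_rates() -> dict[str, RateSet]:
    """Preferred-model point estimates: shared speciation rates, separate
    colonization and extinction, no diversity dependence."""
    return {
        _NV: RateSet(gamma=0.00036, lambda_c=0.33, lambda_a=1.47, mu=0.29,
                     K=math.inf),
        _BAT: RateSet(gamma=0.034, lambda_c=0.33, lambda_a=1.47, mu=0.46,
                      K=math.inf),
    }


def madagascar_pool() -> MainlandPool:
    """1000 mainland species, 22% bats, island age 88 Myr."""
    return MainlandPool(M=1000, p_guild2=0.22, island_age=88.0)


def madagascar_counts() -> dict[str, CommunityCounts]:
    """Community counts by scenario (printed aggregates).

    Pre-human: 249 species (46 bats of which 9 non-endemic, 203 non-volant,
    all endemic).  Current: 219 after 30 recent extinctions (2 bats, 28
    non-volant).  post_threat_2021: 91 survivors (5 threatened bats, 123
    threatened non-volant).  scenario_A additionally retires the 18
    unassessed species (10 bats, 8 non-volant).  2010/2015 threatened
    counts are printed as totals only (56 and 110); their guild split here
    (2/54 and 4/106) is a synthetic stand-in, marked as such.
    """
    mk = CommunityCounts.from_mapping
    return {
        "pre_human": mk({_NV: (203, 0), _BAT: (37, 9)}),
        "current": mk({_NV: (175, 0), _BAT: (35, 9)}),
        "post_threat_2021": mk({_NV: (52, 0), _BAT: (30, 9)}),
        "post_threat_2015": mk({_NV: (69, 0), _BAT: (31, 9)}),   # synthetic split
        "post_threat_2010": mk({_NV: (121, 0), _BAT: (33, 9)}),  # synthetic split
        "scenario_A": mk({_NV: (44, 0), _BAT: (20, 9)}),
    }


def make_madagascar_fixtures():
    """(community counts by scenario, preferred rates by guild, pool)."""
    return madagascar_counts(), m26_rates(), madagascar_pool()


def fixture(name: str):
    """Registry access: ``madagascar_d1_counts``, ``m26_rates``,
    ``madagascar_pool``, ``madagascar_checklist``."""
    registry = {
        "madagascar_d1_counts": madagascar_counts,
        "m26_rates": m26_rates,
        "madagascar_pool": madagascar_pool,
        "madagascar_checklist": lambda: generate_checklist(
            madagascar_truth_config(), seed=0),
    }
    if name not in registry:
        raise ValidationError(f"unknown fixture {name!r}; "
                              f"available: {sorted(registry)}")
    return registry[name]()


@dataclass(frozen=True)
class GuildChecklistShape:
    """Aggregate composition of one guild's checklist rows."""

    n_total: int
    n_non_endemic: int
    # extinct rows: (cause, timing, low_impact_keep, count)
    extinct: tuple[tuple[str, str, bool, int], ...]
    threatened_2010: int
    threatened_2015: int
    threatened_2021: int
    n_unevaluated: int          # DD/NE among extant in 2021
    uplisted_evaluated: int     # evaluated non-threat 2010 -> threat 2021

    @property
    def n_extinct(self) -> int:
        return sum(c for *_x, c in self.extinct)


@dataclass(frozen=True)
class TruthConfig:
    """Ground truth for synthetic data generation."""

    rates_by_guild: dict = field(hash=False)
    pool: MainlandPool = field(default_factory=madagascar_pool)
    checklist: dict = field(hash=False, default=None)


def madagascar_truth_config() -> TruthConfig:
    """The study-system configuration from the printed aggregates.

    30 recent extinctions: 16 anthropogenic, 4 natural, 10 uncertain; 9
    with unclear timing relative to human arrival (2 of them bats); two
    undated extinctions kept anthropogenic in both impact scenarios.
    """
    nv = GuildChecklistShape(
        n_total=203, n_non_endemic=0,
        extinct=(
            ("anthropogenic", "after", False, 14),
            ("anthropogenic", "unclear", True, 2),   # the two undated keepers
            ("natural", "after", False, 4),
            ("uncertain", "after", False, 3),
            ("uncertain", "unclear", False, 5),
        ),
        threatened_2010=54, threatened_2015=106, threatened_2021=123,
        n_unevaluated=8, uplisted_evaluated=14,
    )
    bat = GuildChecklistShape(
        n_total=46, n_non_endemic=9,
        extinct=(("uncertain", "unclear", False, 2),),
        threatened_2010=2, threatened_2015=4, threatened_2021=5,
        n_unevaluated=10, uplisted_evaluated=1,
    )
    return TruthConfig(rates_by_guild=m26_rates(), pool=madagascar_pool(),
                       checklist={_NV: nv, _BAT: bat})


def generate_checklist(config: TruthConfig, seed: int = 0) -> ChecklistTable:
    """Synthesize a checklist whose aggregates match the config exactly.

    Statuses are monotone non-improving across 2010/2015/2021 (species are
    only uplisted).  ``uplisted_evaluated`` species are LC in 2010 and
    threatened by 2021; the remaining new threatened entries come from
    DD/NE assessments.  Deterministic given the seed (used only to shuffle
    row order).
    """
    rng = np.random.default_rng(seed)
    frames = []
    for gname, shape in config.checklist.items():
        n_ext = shape.n_extinct
        n_extant = shape.n_total - n_ext
        if shape.threatened_2021 + shape.n_unevaluated > n_extant:
            raise ValidationError(f"{gname}: threatened + unevaluated exceed extant")
        if not (shape.threatened_2010 <= shape.threatened_2015
                <= shape.threatened_2021):
            raise ValidationError(f"{gname}: threatened counts must be monotone")
        if shape.uplisted_evaluated > shape.threatened_2021 - shape.threatened_2010:
            raise ValidationError(f"{gname}: too many uplisted-evaluated species")
        rows = []
        i = 0

        def base(sp_idx):
            return {
                "species_id": f"{gname}_{sp_idx:03d}", "guild": gname,
                "endemic": True, "extinct_recently": False,
                "extinction_cause": "", "extinction_timing": "",
                "low_impact_keep": False,
                "iucn_2010": "LC", "iucn_2015": "LC", "iucn_2021": "LC",
            }

        for cause, timing, keep, count in shape.extinct:
            for _ in range(count):
                r = base(i); i += 1
                r.update(extinct_recently=True, extinction_cause=cause,
                         extinction_timing=timing, low_impact_keep=keep,
                         iucn_2010="NE", iucn_2015="NE", iucn_2021="NE")
                rows.append(r)

        # threatened in 2021, layered by when they entered the threat set
        n21 = shape.threatened_2021
        n_from2010 = shape.threatened_2010
        n_upl = shape.uplisted_evaluated
        n_fromdd = n21 - n_from2010 - n_upl
        # how many of the 2015 additions beyond 2010's set
        n15_new = shape.threatened_2015 - shape.threatened_2010
        entered_2015 = 0
        for j in range(n21):
            r = base(i); i += 1
            if j < n_from2010:
                r.update(iucn_2010="EN", iucn_2015="EN", iucn_2021="EN")
            else:
                in_2015 = entered_2015 < n15_new
                if in_2015:
                    entered_2015 += 1
                pre = "LC" if (j - n_from2010) < n_upl else \
                    ("DD" if j % 2 else "NE")
                r.update(iucn_2010=pre,
                         iucn_2015="EN" if in_2015 else pre,
                         iucn_2021="EN")
            rows.append(r)
        if n_fromdd < 0:
            raise ValidationError(f"{gname}: inconsistent threatened layering")

        for j in range(shape.n_unevaluated):
            r = base(i); i += 1
            cat = "DD" if j % 2 else "NE"
            r.update(iucn_2010=cat, iucn_2015=cat, iucn_2021=cat)
            rows.append(r)

        n_rest = n_extant - n21 - shape.n_unevaluated
        for j in range(n_rest):
            r = base(i); i += 1
            if j < shape.n_non_endemic:
                r["endemic"] = False
            rows.append(r)
        if shape.n_non_endemic > n_rest:
            raise ValidationError(
                f"{gname}: non-endemic species must be extant and untroubled "
                "in this generator")
        frames.append(pd.DataFrame(rows))

    df = pd.concat(frames, ignore_index=True)
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    return ChecklistTable(df)


def generate_pseudo_posterior(base_dataset: IslandDataset, n_trees: int,
                              age_jitter_sd: float, seed: int = 0
                              ) -> list[IslandDataset]:
    """Replicate a dataset with log-normally jittered event times.

    Each colonization/branching time is multiplied by an independent
    log-normal factor with log-sd ``age_jitter_sd`` (unit mean); records
    violating ordering or the island age are resampled.  Deterministic
    given the seed; a stand-in for extraction over a tree posterior.
    """
    if age_jitter_sd < 0:
        raise ValidationError("age_jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    T = base_dataset.pool.island_age
    out = []
    adj = -0.5 * age_jitter_sd ** 2  # unit-mean correction
    for _ in range(n_trees):
        recs = []
        for rec in base_dataset.colonists:
            if age_jitter_sd == 0:
                recs.append(rec)
                continue
            for _try in range(200):
                f = math.exp(rng.normal(adj, age_jitter_sd))
                ct = rec.col_time * f
                bts = tuple(b * math.exp(rng.normal(adj, age_jitter_sd))
                            for b in rec.branching_times)
                bts = tuple(sorted(bts, reverse=True))
                if ct <= T and (not bts or bts[0] < ct):
                    recs.append(replace(rec, col_time=ct, branching_times=bts))
                    break
            else:
                recs.append(rec)  # keep original if jitter keeps violating
        out.append(base_dataset.with_colonists(recs))
    return out


# ---------------------------------------------------------------------------
# Synthetic dated trees with annotated island clades
# ---------------------------------------------------------------------------

class _N:
    def __init__(self, age, label=None, children=()):
        self.age, self.label, self.children = age, label, list(children)

    def newick(self, parent_age=None):
        if self.children:
            inner = ",".join(c.newick(self.age) for c in self.children)
            s = f"({inner})"
        else:
            s = self.label
        if parent_age is None:
            return s + ";"
        return f"{s}:{parent_age - self.age:.8f}"


def _ladder(labels, crown_age):
    """A ladder subtree over ``labels`` with evenly spaced node ages."""
    if len(labels) == 1:
        return _N(0.0, labels[0])
    ages = np.linspace(crown_age, crown_age / len(labels), len(labels) - 1)
    node = _N(0.0, labels[-1])
    for k in range(len(labels) - 2, -1, -1):
        node = _N(ages[k], children=[_N(0.0, labels[k]), node])
    return node


def generate_island_tree_set(clade_specs, n_mainland: int = 10,
                             root_age: float = 80.0, n_trees: int = 1,
                             jitter_sd: float = 0.0, seed: int = 0,
                             cs1_merge: tuple[tuple[str, str], ...] = ()):
    """Build dated trees seeded with known island clades, plus annotation.

    ``clade_specs``: iterable of dicts with keys ``clade_id``, ``guild``,
    ``n_tips`` (>=1), ``stem_age``, optional ``endemic`` (default True) and
    ``n_missing`` (extra off-tree species routed to the clade).  Island
    clades hang off a mainland spine, so each is monophyletic; ``cs1_merge``
    pairs share a cs1 clade id (fewer colonizations under CS1).

    Returns ``(newick_strings, annotation)``.
    """
    rng = np.random.default_rng(seed)
    specs = list(clade_specs)
    specs.sort(key=lambda s: -s["stem_age"])
    if specs and specs[0]["stem_age"] >= root_age:
        raise ValidationError("stem ages must be below the root age")

    ann_rows = []
    merged_cs1 = {}
    for a, b in cs1_merge:
        merged_cs1[b] = a

    def build(jit):
        def j(age):
            if jitter_sd == 0:
                return age
            return age * math.exp(jit.normal(-0.5 * jitter_sd ** 2, jitter_sd))

        sub_nodes = []
        for k, s in enumerate(specs):
            labels = [f'{s["clade_id"]}_t{i}' for i in range(s["n_tips"])]
            crown = 0.75 * s["stem_age"]
            sub = _ladder(labels, j(crown) if s["n_tips"] > 1 else 0.0)
            sub_nodes.append(sub)
        # assemble from the youngest spine node up
        inner = _N(0.0, "mainland_0")
        for k in range(len(specs) - 1, -1, -1):
            age = j(specs[k]["stem_age"])
            age = max(age, _age_of(inner) * 1.001 + 1e-6,
                      _age_of(sub_nodes[k]) * 1.001 + 1e-6)
            inner = _N(age, children=[sub_nodes[k], inner])
        extra = [_N(0.0, f"mainland_{i+1}")
                 for i in range(max(n_mainland - 1, 1))]
        top = inner
        ra = max(j(root_age), _age_of(top) * 1.001 + 1e-6)
        for i, e in enumerate(extra):
            top = _N(ra + i * 0.5, children=[e, top])
        return top.newick()

    def _age_of(n):
        return n.age

    for s in specs:
        endemic = s.get("endemic", True)
        cid = s["clade_id"]
        cs1 = merged_cs1.get(cid, cid)
        for i in range(s["n_tips"]):
            ann_rows.append({
                "species": f"{cid}_t{i}", "in_tree": True, "island": True,
                "endemic": endemic, "guild": s["guild"],
                "cs1_clade": cs1, "cs2_clade": cid, "maxage_ref_age": "",
            })
        for i in range(s.get("n_missing", 0)):
            ann_rows.append({
                "species": f"{cid}_m{i}", "in_tree": False, "island": True,
                "endemic": True, "guild": s["guild"],
                "cs1_clade": cs1, "cs2_clade": cid, "maxage_ref_age": "",
            })
    for i in range(n_mainland):
        ann_rows.append({
            "species": f"mainland_{i}" if i else "mainland_0",
            "in_tree": True, "island": False, "endemic": False,
            "guild": _NV, "cs1_clade": "", "cs2_clade": "",
            "maxage_ref_age": "",
        })
    ann = IslandAnnotation(pd.DataFrame(ann_rows).drop_duplicates("species"))

    trees = [build(np.random.default_rng(rng.integers(2**31)))
             for _ in range(n_trees)]
    return trees, ann
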