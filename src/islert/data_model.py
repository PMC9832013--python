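"""Core domain types for island community assembly data.

The observation unit is an island community assembled from a mainland pool:
each mainland lineage may colonize the island, diversify in situ by
cladogenesis, become endemic by anagenesis, and go extinct.  The observed
data are, per surviving colonist lineage, the colonization time (precise
stem age or a maximum age), the within-island branching times of the
reconstructed tree, the endemicity status and a count of known species
missing from the phylogeny.

Two guilds are distinguished throughout: ``nonvolant`` (guild 1) and
``bat`` (guild 2), each drawing colonists from its share of the mainland
pool and each potentially governed by its own set of CES
(colonization-extinction-speciation) rates.

All times are in Myr before present; the island originates at ``T`` and
the present is 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Guild",
    "ColTimeKind",
    "Status",
    "RateSet",
    "MainlandPool",
    "ColonistRecord",
    "IslandDataset",
    "CommunityCounts",
    "ChecklistTable",
    "ValidationError",
    "read_island_dataset",
    "write_island_dataset",
    "dataset_to_json",
    "dataset_from_json",
    "counts_from_checklist",
    "human_impact_filter",
    "THREAT_CATEGORIES",
    "IUCN_CATEGORIES",
]


class ValidationError(ValueError):
    """A dataset or checklist violated a structural invariant."""


class Guild(str, Enum):
    NONVOLANT = "nonvolant"  # guild 1
    BAT = "bat"              # guild 2


class ColTimeKind(str, Enum):
    PRECISE = "precise"
    MAX_AGE = "max_age"


class Status(str, Enum):
    ENDEMIC = "endemic"
    NON_ENDEMIC = "non_endemic"
    ENDEMIC_AND_NON_ENDEMIC = "endemic_and_non_endemic"


#: IUCN Red List categories used in checklists. NE = not evaluated.
IUCN_CATEGORIES = ("LC", "NT", "VU", "EN", "CR", "DD", "NE")
#: Categories counted as threatened (Vulnerable, Endangered, Critically Endangered).
THREAT_CATEGORIES = frozenset({"VU", "EN", "CR"})


@dataclass(frozen=True)
class RateSet:
    """CES rates for one guild.

    Parameters
    ----------
    gamma : float
        Colonization rate per mainland lineage (events/lineage/Myr).
    lambda_c : float
        Cladogenesis rate per island lineage (1/Myr).
    lambda_a : float
        Anagenesis rate per non-endemic island lineage (1/Myr).
    mu : float
        Extinction rate per island lineage (1/Myr).
    K : float
        Per-clade carrying capacity (species); ``math.inf`` disables
        diversity dependence.
    """

    gamma: float
    lambda_c: float
    lambda_a: float
    mu: float
    K: float = math.inf

    def __post_init__(self) -> None:
        for name in ("gamma", "lambda_c", "lambda_a", "mu"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"rate {name} must be finite and >= 0, got {v}")
        if not (self.K >= 1):  # inf passes
            raise ValidationError(f"K must be >= 1 or infinite, got {self.K}")

    @property
    def diversification(self) -> float:
        """Net per-lineage diversification rate lambda_c - mu."""
        return self.lambda_c - self.mu

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in ("gamma", "lambda_c", "lambda_a", "mu")}
        d["K"] = "inf" if math.isinf(self.K) else self.K
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RateSet":
        K = d.get("K", "inf")
        return cls(
            gamma=float(d["gamma"]),
            lambda_c=float(d["lambda_c"]),
            lambda_a=float(d["lambda_a"]),
            mu=float(d["mu"]),
            K=math.inf if K in ("inf", None) else float(K),
        )


@dataclass(frozen=True)
class MainlandPool:
    """Mainland species pool and island age.

    ``M`` mainland species, a proportion ``p_guild2`` of which are bats;
    guild pools are ``M_bat = round(M * p_guild2)`` and
    ``M_nonvolant = M - M_bat``.  ``island_age`` is the island origin time
    T in Myr before present.
    """

    M: int
    p_guild2: float
    island_age: float

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValidationError(f"M must be >= 1, got {self.M}")
        if not (0.0 <= self.p_guild2 <= 1.0):
            raise ValidationError(f"p_guild2 must be in [0, 1], got {self.p_guild2}")
        if not self.island_age > 0:
            raise ValidationError(f"island_age must be > 0, got {self.island_age}")

    def guild_size(self, guild: Guild | str) -> int:
        m2 = round(self.M * self.p_guild2)
        return m2 if Guild(guild) is Guild.BAT else self.M - m2

    def to_dict(self) -> dict:
        return {"M": self.M, "p_guild2": self.p_guild2, "island_age": self.island_age}

    @classmethod
    def from_dict(cls, d: dict) -> "MainlandPool":
        return cls(M=int(d["M"]), p_guild2=float(d["p_guild2"]),
                   island_age=float(d["island_age"]))


@dataclass(frozen=True)
class ColonistRecord:
    """One island colonist lineage as observed at the present."""

    clade_id: str
    guild: Guild
    col_time_kind: ColTimeKind
    col_time: float
    branching_times: tuple[float, ...] = ()
    status: Status = Status.ENDEMIC
    n_missing: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "guild", Guild(self.guild))
        object.__setattr__(self, "col_time_kind", ColTimeKind(self.col_time_kind))
        object.__setattr__(self, "status", Status(self.status))
        object.__setattr__(self, "branching_times",
                           tuple(float(b) for b in self.branching_times))
        bt = self.branching_times
        if self.col_time <= 0:
            raise ValidationError(f"{self.clade_id}: col_time must be > 0")
        if any(b2 >= b1 for b1, b2 in zip(bt, bt[1:])):
            raise ValidationError(
                f"{self.clade_id}: branching_times must be strictly descending")
        if bt and bt[0] >= self.col_time:
            raise ValidationError(
                f"{self.clade_id}: branching time {bt[0]} >= colonization time "
                f"{self.col_time}")
        if any(b <= 0 for b in bt):
            raise ValidationError(f"{self.clade_id}: branching times must be > 0")
        if self.n_missing < 0:
            raise ValidationError(f"{self.clade_id}: n_missing must be >= 0")
        if self.status is Status.NON_ENDEMIC and bt:
            raise ValidationError(
                f"{self.clade_id}: non_endemic records cannot have branching times")
        if self.status is Status.NON_ENDEMIC and self.n_missing:
            raise ValidationError(
                f"{self.clade_id}: non_endemic records cannot carry missing species")

    @property
    def n_species(self) -> int:
        """Species represented by the record (tips + missing).

        For endemic_and_non_endemic records this counts the island clade;
        the marginalized extant non-endemic population is not included.
        """
        return len(self.branching_times) + 1 + self.n_missing

    def to_dict(self) -> dict:
        return {
            "clade_id": self.clade_id,
            "guild": self.guild.value,
            "col_time_kind": self.col_time_kind.value,
            "col_time": self.col_time,
            "branching_times": list(self.branching_times),
            "status": self.status.value,
            "n_missing": self.n_missing,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ColonistRecord":
        try:
            return cls(
                clade_id=str(d["clade_id"]),
                guild=Guild(d["guild"]),
                col_time_kind=ColTimeKind(d["col_time_kind"]),
                col_time=float(d["col_time"]),
                branching_times=tuple(float(x) for x in d.get("branching_times", [])),
                status=Status(d.get("status", "endemic")),
                n_missing=int(d.get("n_missing", 0)),
            )
        except KeyError as e:  # pragma: no cover - error path
            raise ValidationError(
                f"colonist record {d.get('clade_id', '?')}: missing field {e}") from e


@dataclass(frozen=True)
class IslandDataset:
    """An island community observation: pool, colonists and a label."""

    pool: MainlandPool
    colonists: tuple[ColonistRecord, ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "colonists", tuple(self.colonists))
        T = self.pool.island_age
        for rec in self.colonists:
            if rec.col_time > T:
                raise ValidationError(
                    f"{rec.clade_id}: col_time {rec.col_time} exceeds island age {T}")
        for g in Guild:
            n = sum(1 for r in self.colonists if r.guild is g)
            if n > self.pool.guild_size(g):
                raise ValidationError(
                    f"guild {g.value}: {n} colonists exceed pool size "
                    f"{self.pool.guild_size(g)}")

    def guild_records(self, guild: Guild | str) -> tuple[ColonistRecord, ...]:
        g = Guild(guild)
        return tuple(r for r in self.colonists if r.guild is g)

    def n_colonists(self, guild: Guild | str | None = None) -> int:
        if guild is None:
            return len(self.colonists)
        return len(self.guild_records(guild))

    def n_species(self, guild: Guild | str | None = None) -> int:
        recs = self.colonists if guild is None else self.guild_records(guild)
        return sum(r.n_species for r in recs)

    def with_colonists(self, colonists: Iterable[ColonistRecord]) -> "IslandDataset":
        return replace(self, colonists=tuple(colonists))


def dataset_to_json(dataset: IslandDataset) -> str:
    """Canonical JSON serialization (deterministic field order, UTF-8)."""
    obj = {
        "label": dataset.label,
        "pool": dataset.pool.to_dict(),
        "colonists": [r.to_dict() for r in dataset.colonists],
    }
    return json.dumps(obj, indent=2, ensure_ascii=False) + "\n"


def dataset_from_json(text: str) -> IslandDataset:
    obj = json.loads(text)
    try:
        pool = MainlandPool.from_dict(obj["pool"])
    except KeyError as e:
        raise ValidationError(f"dataset JSON: missing field {e}") from e
    colonists = tuple(ColonistRecord.from_dict(d) for d in obj.get("colonists", []))
    return IslandDataset(pool=pool, colonists=colonists, label=obj.get("label", ""))


def read_island_dataset(path: str | Path) -> IslandDataset:
    """Read and validate an island dataset from its JSON file."""
    return dataset_from_json(Path(path).read_text(encoding="utf-8"))


def write_island_dataset(dataset: IslandDataset, path: str | Path) -> None:
    Path(path).write_text(dataset_to_json(dataset), encoding="utf-8")


# ---------------------------------------------------------------------------
# Community counts and checklist accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommunityCounts:
    """Species counts by guild and endemicity."""

    counts: tuple[tuple[str, int, int], ...]  # (guild, n_endemic, n_non_endemic)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "CommunityCounts":
        rows = []
        for g in Guild:
            ne, nn = mapping.get(g.value, mapping.get(g, (0, 0)))
            if ne < 0 or nn < 0:
                raise ValidationError("counts must be >= 0")
            rows.append((g.value, int(ne), int(nn)))
        return cls(counts=tuple(rows))

    def endemic(self, guild: Guild | str) -> int:
        g = Guild(guild).value
        return next(r[1] for r in self.counts if r[0] == g)

    def non_endemic(self, guild: Guild | str) -> int:
        g = Guild(guild).value
        return next(r[2] for r in self.counts if r[0] == g)

    def total(self, guild: Guild | str | None = None) -> int:
        if guild is None:
            return sum(r[1] + r[2] for r in self.counts)
        g = Guild(guild).value
        return next(r[1] + r[2] for r in self.counts if r[0] == g)


#: Checklist column names (the external CSV schema).
CHECKLIST_COLUMNS = [
    "species_id", "guild", "endemic", "extinct_recently", "extinction_cause",
    "extinction_timing", "low_impact_keep",
    "iucn_2010", "iucn_2015", "iucn_2021",
]

_CAUSES = {"anthropogenic", "natural", "uncertain", ""}
_TIMINGS = {"before", "after", "unclear", ""}


@dataclass
class ChecklistTable:
    """A species checklist with guild, endemicity, extinction and IUCN columns.

    Thin wrapper over a :class:`pandas.DataFrame` with schema validation.
    ``low_impact_keep`` marks extinct species kept as anthropogenic under the
    low human impact scenario despite lacking a dated, post-arrival record.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in CHECKLIST_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"checklist missing columns: {missing}")
        for col in ("iucn_2010", "iucn_2015", "iucn_2021"):
            bad = set(df[col].unique()) - set(IUCN_CATEGORIES)
            if bad:
                raise ValidationError(f"checklist column {col}: unknown categories {bad}")
        if not set(df["guild"].unique()) <= {g.value for g in Guild}:
            raise ValidationError("checklist column guild: unknown guilds")
        if not set(df["extinction_cause"].unique()) <= _CAUSES:
            raise ValidationError("checklist column extinction_cause: unknown values")
        if not set(df["extinction_timing"].unique()) <= _TIMINGS:
            raise ValidationError("checklist column extinction_timing: unknown values")

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "ChecklistTable":
        return ChecklistTable(self.df.copy())

    def threatened_mask(self, year: int) -> pd.Series:
        col = f"iucn_{year}"
        if col not in self.df.columns:
            raise ValidationError(f"checklist has no IUCN column for year {year}")
        return self.df[col].isin(THREAT_CATEGORIES) & ~self.df["extinct_recently"]

    def to_csv(self, path: str | Path) -> None:
        self.df[CHECKLIST_COLUMNS].to_csv(path, index=False, encoding="utf-8")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ChecklistTable":
        df = pd.read_csv(path, keep_default_na=False)
        for col in ("endemic", "extinct_recently", "low_impact_keep"):
            if df[col].dtype != bool:
                df[col] = df[col].astype(str).str.lower().isin(("true", "1"))
        return cls(df)


def _counts_from_frame(df: pd.DataFrame) -> CommunityCounts:
    mapping = {}
    for g in Guild:
        sub = df[df["guild"] == g.value]
        mapping[g.value] = (int(sub["endemic"].sum()), int((~sub["endemic"]).sum()))
    return CommunityCounts.from_mapping(mapping)


def counts_from_checklist(table: ChecklistTable, scenario: str,
                          year: int | None = None) -> CommunityCounts:
    """Species counts under a diversity scenario.

    Scenarios
    ---------
    ``pre_human``
        Every checklist species (present at human arrival).
    ``current``
        pre_human minus recent extinctions.
    ``post_threat``
        current minus species threatened (VU/EN/CR) in ``year``.
    ``scenario_A``
        post_threat(2021) additionally minus Data Deficient / Not Evaluated
        species (i.e. all unassessed species counted as threatened).
    """
    df = table.df
    if scenario == "pre_human":
        return _counts_from_frame(df)
    extant = df[~df["extinct_recently"]]
    if scenario == "current":
        return _counts_from_frame(extant)
    if scenario == "post_threat":
        if year is None:
            raise ValidationError("post_threat scenario requires a year")
        mask = table.threatened_mask(year)
        return _counts_from_frame(extant[~mask.loc[extant.index]])
    if scenario == "scenario_A":
        mask = table.threatened_mask(2021)
        dd = extant["iucn_2021"].isin({"DD", "NE"})
        return _counts_from_frame(extant[~mask.loc[extant.index] & ~dd])
    raise ValidationError(f"unknown scenario {scenario!r}")


def human_impact_filter(table: ChecklistTable, impact: str) -> ChecklistTable:
    """Flag extinct species for inclusion in the phylogenetic data.

    Under the ``high`` human-impact scenario every recent extinction is
    assumed anthropogenic and treated as surviving (included in the
    phylogeny).  Under ``low``, only extinctions with an anthropogenic
    cause that postdate human arrival (or rows explicitly flagged
    ``low_impact_keep``) are included; natural, uncertain and undated
    extinctions are treated as species unknown to science.

    Returns a copy with an ``in_phylogeny`` boolean column; extant rows are
    always included.
    """
    if impact not in ("high", "low"):
        raise ValidationError(f"unknown impact scenario {impact!r}")
    out = table.df.copy()
    extinct = out["extinct_recently"]
    if impact == "high":
        out["in_phylogeny"] = True
    else:
        keep = (
            (out["extinction_cause"] == "anthropogenic")
            & (out["extinction_timing"] == "after")
        ) | out["low_impact_keep"].astype(bool)
        out["in_phylogeny"] = (~extinct) | keep
    return ChecklistTable(out)
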