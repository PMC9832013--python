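"""Derive island datasets from dated phylogenies.

Colonization times follow the stem-age convention: an island clade's
colonization time is the divergence from its closest non-island relative,
i.e. the age of the parent of the clade's MRCA.  Non-endemic island
species are single tips whose tip divergence age is only an upper bound on
the colonization time (max-age records).  Species absent from the tree are
either appended as missing species to an assigned clade, or — when a whole
colonist lineage is unsampled — added as a max-age colonist at a reference
age.  Alternative colonization scenarios (CS1: fewer colonizations, CS2:
more) are expressed entirely through per-species clade assignments in the
annotation table, never inferred from topology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .data_model import (
    ColonistRecord,
    ColTimeKind,
    Guild,
    IslandDataset,
    MainlandPool,
    Status,
    ValidationError,
)

__all__ = [
    "IslandAnnotation",
    "PosteriorExtraction",
    "extract_colonizations",
    "extract_over_posterior",
]

ANNOTATION_COLUMNS = ["species", "in_tree", "island", "endemic", "guild",
                      "cs1_clade", "cs2_clade", "maxage_ref_age"]


@dataclass
class IslandAnnotation:
    """Per-species island membership, endemicity, guild and clade routing."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"annotation missing columns: {missing}")
        isl = self.df[self.df["island"]]
        for col in ("cs1_clade", "cs2_clade"):
            un = isl[col].astype(str)
            if (un == "").any() and not isl.loc[un == "", "in_tree"].empty:
                pass  # validated per scenario during extraction

    def clade_column(self, scenario: str) -> str:
        if scenario not in ("CS1", "CS2"):
            raise ValidationError(f"unknown colonization scenario {scenario!r}")
        return "cs1_clade" if scenario == "CS1" else "cs2_clade"

    @classmethod
    def from_csv(cls, path: str | Path) -> "IslandAnnotation":
        df = pd.read_csv(path, keep_default_na=False)
        for col in ("in_tree", "island", "endemic"):
            if df[col].dtype != bool:
                df[col] = df[col].astype(str).str.lower().isin(("true", "1"))
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        self.df[ANNOTATION_COLUMNS].to_csv(path, index=False, encoding="utf-8")


def _load_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=str(tree), schema="newick")


def _node_ages(tree: dendropy.Tree) -> None:
    height = tree.max_distance_from_root()
    tol = max(1e-6 * height, 1e-9)
    try:
        tree.calc_node_ages(ultrametricity_precision=tol)
    except Exception as e:
        raise ValidationError(f"tree is not ultrametric within tolerance: {e}")


def extract_colonizations(tree, annotation: IslandAnnotation, scenario: str,
                          pool: MainlandPool, label: str = "") -> IslandDataset:
    """Build an :class:`IslandDataset` from one dated tree.

    Island species are grouped into colonist records by the annotation's
    clade column for the scenario.  Per group: colonization time = stem age
    of the group's MRCA, branching times = ages of the nodes of the
    reconstructed subtree induced by the group's sampled tips, status from
    the endemicity flags, unsampled group members counted as missing
    species.  Wholly unsampled groups become max-age colonists at their
    annotated reference age.
    """
    t = _load_tree(tree)
    _node_ages(t)
    col = annotation.clade_column(scenario)
    df = annotation.df
    isl = df[df["island"]].copy()
    unrouted = isl[(isl[col].astype(str) == "") & (~isl["in_tree"])]
    if len(unrouted):
        raise ValidationError(
            f"island species neither in tree nor routed: "
            f"{sorted(unrouted['species'])}")

    leaf_by_label = {}
    for leaf in t.leaf_node_iter():
        # unquoted newick labels read with spaces for underscores
        leaf_by_label[leaf.taxon.label] = leaf
        leaf_by_label[leaf.taxon.label.replace(" ", "_")] = leaf

    records = []
    for clade_id, grp in isl.groupby(isl[col].astype(str)):
        if clade_id == "":
            continue
        tips = []
        for sp in grp.loc[grp["in_tree"], "species"]:
            if sp not in leaf_by_label:
                raise ValidationError(f"species {sp} flagged in_tree but absent")
            tips.append(leaf_by_label[sp])
        guilds = set(grp["guild"])
        if len(guilds) != 1:
            raise ValidationError(f"clade {clade_id}: mixed guilds {guilds}")
        guild = Guild(guilds.pop())
        n_total = len(grp)

        if not tips:
            ages = [float(a) for a in grp["maxage_ref_age"]
                    if str(a) not in ("", "nan")]
            if not ages:
                raise ValidationError(
                    f"clade {clade_id}: unsampled and no maxage_ref_age")
            endemics = grp["endemic"].all()
            status = Status.ENDEMIC if endemics else (
                Status.NON_ENDEMIC if n_total == 1
                else Status.ENDEMIC_AND_NON_ENDEMIC)
            records.append(ColonistRecord(
                clade_id=str(clade_id), guild=guild,
                col_time_kind=ColTimeKind.MAX_AGE, col_time=max(ages),
                branching_times=(),
                status=status, n_missing=n_total - 1))
            continue

        n_missing = n_total - len(tips)
        # induced subtree nodes: nodes with >= 2 child subtrees holding tips
        tipset = set(id(x) for x in tips)
        count: dict[int, int] = {}
        induced_ages: list[float] = []
        mrca = None
        for nd in t.postorder_node_iter():
            if nd.is_leaf():
                count[id(nd)] = 1 if id(nd) in tipset else 0
                continue
            c_children = [count[id(ch)] for ch in nd.child_nodes()]
            c = sum(c_children)
            count[id(nd)] = c
            if sum(1 for x in c_children if x > 0) >= 2:
                induced_ages.append(float(nd.age))
            if c == len(tips) and mrca is None:
                mrca = nd if len(tips) > 1 else None
        if len(tips) == 1:
            mrca = tips[0]
        if mrca is None:
            raise ValidationError(f"clade {clade_id}: could not locate MRCA")
        # keep only induced nodes inside the MRCA subtree
        if len(tips) > 1:
            within = set()
            stack = [mrca]
            while stack:
                nd = stack.pop()
                within.add(id(nd))
                stack.extend(nd.child_nodes())
            induced_ages = sorted(
                (float(nd.age) for nd in t.postorder_internal_node_iter()
                 if id(nd) in within and sum(
                     1 for ch in nd.child_nodes() if count.get(id(ch), 0) > 0
                 ) >= 2),
                reverse=True)
        else:
            induced_ages = []

        parent = mrca.parent_node
        stem_age = float(parent.age) if parent is not None else float(mrca.age)
        endemic_flags = dict(zip(grp["species"], grp["endemic"]))
        tip_endemic = [endemic_flags[sp] for sp in grp.loc[grp["in_tree"], "species"]]
        if all(tip_endemic):
            status = Status.ENDEMIC
            kind = ColTimeKind.PRECISE
        elif len(tips) == 1 and not tip_endemic[0] and n_missing == 0:
            status = Status.NON_ENDEMIC
            kind = ColTimeKind.MAX_AGE
        elif not any(tip_endemic) and len(tips) > 1:
            raise ValidationError(
                f"clade {clade_id}: multiple non-endemic tips in one clade; "
                "split them into separate colonist records")
        else:
            status = Status.ENDEMIC_AND_NON_ENDEMIC
            kind = ColTimeKind.PRECISE
        records.append(ColonistRecord(
            clade_id=str(clade_id), guild=guild, col_time_kind=kind,
            col_time=stem_age, branching_times=tuple(induced_ages),
            status=status, n_missing=n_missing))

    records.sort(key=lambda r: (-r.col_time, r.clade_id))
    return IslandDataset(pool=pool, colonists=tuple(records),
                         label=label or f"extracted_{scenario}")


@dataclass
class PosteriorExtraction:
    datasets: list[IslandDataset]
    clade_summary: pd.DataFrame
    colonization_counts: pd.Series
    failures: list[tuple[int, str]]


def extract_over_posterior(trees, annotation: IslandAnnotation, scenario: str,
                           pool: MainlandPool) -> PosteriorExtraction:
    """Extract a dataset from each posterior tree and summarize.

    Per clade: mean and 2.5-97.5 percentiles of the colonization time
    across trees; plus the distribution of the total colonization count.
    Per-tree failures are collected, not fatal.
    """
    trees = list(trees)
    if not trees:
        raise ValidationError("need at least one tree")
    datasets, failures = [], []
    for i, tr in enumerate(trees):
        try:
            datasets.append(extract_colonizations(tr, annotation, scenario, pool,
                                                  label=f"posterior_{i}"))
        except ValidationError as e:
            failures.append((i, str(e)))
    if not datasets:
        raise ValidationError("extraction failed for every tree")
    times: dict[str, list[float]] = {}
    for ds in datasets:
        for rec in ds.colonists:
            times.setdefault(rec.clade_id, []).append(rec.col_time)
    rows = []
    for cid, vals in sorted(times.items()):
        v = np.asarray(vals)
        rows.append({"clade_id": cid, "n": len(v), "mean": v.mean(),
                     "p2.5": np.percentile(v, 2.5),
                     "p97.5": np.percentile(v, 97.5)})
    counts = pd.Series([ds.n_colonists() for ds in datasets]).value_counts()
    return PosteriorExtraction(datasets=datasets,
                               clade_summary=pd.DataFrame(rows),
                               colonization_counts=counts,
                               failures=failures)
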