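"""Aggregate raw specimen records into sampling-event "lists" and apply the
inclusion filters of the list-length method.

A *list* is the set of species collected by one collector at one locality on
one date — the unit of sampling effort for opportunistic records.  Per list we
compute the two effort proxies: ``L`` (list length, the number of species) and
``records`` (the number of individuals regardless of species).  Lists with
fewer than two species are treated as incomplete samples and dropped; within
each activity class (diurnal/nocturnal) only species appearing on at least
ten lists enter the model roster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "build_lists",
    "filter_events",
    "split_by_activity",
    "taxon_merge",
    "AnalysisDataset",
    "EVENT_KEY",
]

RECORD_COLUMNS = ["species", "year", "locality", "county", "collector"]
EVENT_KEY = ["locality", "date", "collector"]


def _date_string(row) -> str:
    """Full date string when month/day are present; bare year otherwise.

    Museum labels often lack day precision; records carrying only a year form
    their own event key (year, locality, collector).
    """
    month, day = row.get("month"), row.get("day")
    if pd.notna(month) and pd.notna(day):
        return f"{int(row['year']):04d}-{int(month):02d}-{int(day):02d}"
    if pd.notna(month):
        return f"{int(row['year']):04d}-{int(month):02d}"
    return f"{int(row['year']):04d}"


def taxon_merge(records: pd.DataFrame, merge_map: dict[str, str]) -> pd.DataFrame:
    """Rewrite species labels (e.g. collapse a cryptic species pair) before
    list building."""
    out = records.copy()
    out["species"] = out["species"].map(lambda s: merge_map.get(s, s))
    return out


def build_lists(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate record rows into unique (locality, date, collector) events.

    Rows missing any key field (species, year, locality, county, collector)
    are rejected with a logged count.  Returns ``(events, membership)``:

    * events: one row per list with ``list_id, locality, date, county,
      collector, year, L, records``, deterministically ordered by
      (year, county, locality, collector, date).
    * membership: one row per (list_id, species) with the individual count.
    """
    df = records.copy()
    for col in RECORD_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"record table missing column {col!r}")
    bad = df[RECORD_COLUMNS].isna().any(axis=1)
    if bad.any():
        logger.warning("rejected %d record rows with missing key fields", int(bad.sum()))
        df = df[~bad]
    if len(df) == 0:
        empty_events = pd.DataFrame(
            columns=["list_id", "locality", "date", "county", "collector", "year", "L", "records"]
        )
        empty_members = pd.DataFrame(columns=["list_id", "species", "n_individuals"])
        return empty_events, empty_members

    df = df.copy()
    df["county"] = df["county"].astype(str).str.strip().str.casefold()
    df["date"] = df.apply(_date_string, axis=1)
    df["year"] = df["year"].astype(int)

    grouped = df.groupby(EVENT_KEY, sort=True)
    events = grouped.agg(
        county=("county", "first"),
        year=("year", "first"),
        L=("species", "nunique"),
        records=("species", "size"),
    ).reset_index()
    events = events.sort_values(
        ["year", "county", "locality", "collector", "date"], kind="stable", ignore_index=True
    )
    events.insert(0, "list_id", [f"list{idx:06d}" for idx in range(len(events))])

    key_to_id = events.set_index(EVENT_KEY)["list_id"]
    membership = (
        df.groupby(EVENT_KEY + ["species"], sort=True).size().rename("n_individuals").reset_index()
    )
    membership["list_id"] = key_to_id.loc[
        list(membership[EVENT_KEY].itertuples(index=False, name=None))
    ].to_numpy()
    membership = membership[["list_id", "species", "n_individuals"]].sort_values(
        ["list_id", "species"], ignore_index=True
    )
    events = events[
        ["list_id", "locality", "date", "county", "collector", "year", "L", "records"]
    ]
    return events, membership


def filter_events(
    events: pd.DataFrame, membership: pd.DataFrame | None = None, min_L: int = 2
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Drop lists with fewer than ``min_L`` species (incomplete samples)."""
    keep = events["L"] >= min_L
    logger.info(
        "list-length filter (L >= %d): retained %d, dropped %d",
        min_L, int(keep.sum()), int((~keep).sum()),
    )
    filtered = events[keep].reset_index(drop=True)
    if membership is None:
        return filtered
    member = membership[membership["list_id"].isin(filtered["list_id"])].reset_index(drop=True)
    return filtered, member


@dataclass
class AnalysisDataset:
    """One activity class's filtered events, species roster and 0/1 responses.

    ``response`` is indexed by list_id with one 0/1 column per rostered
    species.  Every event contains at least one species of the class; every
    rostered species appears on at least ``min_lists`` of the class's lists.
    """

    activity_class: str
    events: pd.DataFrame
    species_roster: list[str]
    response: pd.DataFrame
    excluded_species: dict[str, int]

    @property
    def n_events(self) -> int:
        return len(self.events)


def split_by_activity(
    events: pd.DataFrame,
    membership: pd.DataFrame,
    traits: pd.DataFrame,
    min_lists: int = 10,
) -> dict[str, AnalysisDataset]:
    """Partition lists into diurnal and nocturnal analysis datasets.

    A list belongs to a class if it contains at least one species of that
    class (a mixed list joins both datasets).  Within each class, species on
    fewer than ``min_lists`` lists are reported and excluded from the roster.
    Raises KeyError for any recorded species absent from the trait table.
    """
    trait_map = traits.set_index("species")["activity"]
    unknown = sorted(set(membership["species"]) - set(trait_map.index))
    if unknown:
        raise KeyError(f"species missing from trait table: {unknown}")

    member = membership.copy()
    member["activity"] = member["species"].map(trait_map).to_numpy()
    out: dict[str, AnalysisDataset] = {}
    for activity in ("diurnal", "nocturnal"):
        cls_members = member[member["activity"] == activity]
        cls_event_ids = sorted(cls_members["list_id"].unique())
        cls_events = events[events["list_id"].isin(cls_event_ids)].reset_index(drop=True)
        lists_per_species = cls_members.groupby("species")["list_id"].nunique()
        roster = sorted(lists_per_species[lists_per_species >= min_lists].index)
        excluded = lists_per_species[lists_per_species < min_lists].to_dict()
        if excluded:
            logger.info(
                "%s: excluded species on fewer than %d lists: %s",
                activity, min_lists,
                ", ".join(f"{s} ({n})" for s, n in sorted(excluded.items())),
            )
        presence = (
            cls_members[cls_members["species"].isin(roster)]
            .assign(present=1)
            .pivot_table(
                index="list_id", columns="species", values="present", fill_value=0,
                aggfunc="max",
            )
            .reindex(index=cls_events["list_id"], columns=roster, fill_value=0)
            .astype(int)
        )
        out[activity] = AnalysisDataset(
            activity_class=activity,
            events=cls_events,
            species_roster=roster,
            response=presence,
            excluded_species={k: int(v) for k, v in excluded.items()},
        )
    return out


def records_total_invariant(events: pd.DataFrame, records: pd.DataFrame) -> bool:
    """Check: per-event record counts sum to the surviving record-row count."""
    return int(events["records"].sum()) == len(records.dropna(subset=RECORD_COLUMNS))
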