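"""Reading, validating, writing and merging lap-time tables.

The canonical exchange format is a long-format CSV with one row per
completed lap::

    event_year,category,team_id,lap_index,lap_time_s
    2019,1,rider a,1,1877.4
    ...

``category`` is the team-size class of a 24-hour relay field (1 = solo,
4 = four-rider, 10 = ten-rider).  Lap times are the seconds elapsed
between consecutive crossings of the finish line, so team inactivity is
embedded in the lap during which it occurred and the cumulative sum of a
team's lap times equals the race clock at each crossing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

CANONICAL_COLUMNS = ("event_year", "category", "team_id", "lap_index", "lap_time_s")
TEAM_SIZES = (1, 4, 10)


@dataclass(frozen=True)
class LapRecord:
    """One completed lap of one team."""

    event_year: int
    category: int
    team_id: str
    lap_index: int
    lap_time_s: float


class RaceTable:
    """All laps of one event: a single (year, team-size category) field.

    Wraps a validated, canonically sorted :class:`pandas.DataFrame`.
    Invariants enforced on construction:

    * all canonical columns present, at least one row;
    * exactly one ``(event_year, category)`` pair, category in {1, 4, 10};
    * lap times strictly positive;
    * per team, lap indices form the contiguous range ``1..L``.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        df = df.copy()
        df["event_year"] = df["event_year"].astype(int)
        df["category"] = df["category"].astype(int)
        df["team_id"] = df["team_id"].astype(str)
        df["lap_index"] = df["lap_index"].astype(int)
        df["lap_time_s"] = df["lap_time_s"].astype(float)
        df = df.sort_values(["team_id", "lap_index"], kind="mergesort")
        df = df.reset_index(drop=True)
        self._df = df
        if validate:
            self._validate()

    def _validate(self) -> None:
        df = self._df
        if len(df) == 0:
            raise ValidationError("empty race table (A >= 1 required)")
        pairs = df[["event_year", "category"]].drop_duplicates()
        if len(pairs) != 1:
            raise ValidationError(
                "a RaceTable holds exactly one (event_year, category) pair; "
                f"found {len(pairs)}"
            )
        if self.category not in TEAM_SIZES:
            raise ValidationError(
                f"category must be one of {TEAM_SIZES}, got {self.category}"
            )
        bad = df.index[df["lap_time_s"] <= 0]
        if len(bad):
            row = df.loc[bad[0]]
            raise ValidationError(
                f"non-positive lap time in row {bad[0]} "
                f"(team {row['team_id']!r}, lap {row['lap_index']})"
            )
        for team, grp in df.groupby("team_id", sort=False):
            laps = grp["lap_index"].to_numpy()
            expected = np.arange(1, len(laps) + 1)
            if not np.array_equal(laps, expected):
                raise ValidationError(
                    f"team {team!r}: lap indices must form 1..L with no gaps "
                    f"or duplicates, got {laps.tolist()}"
                )

    # -- accessors ---------------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def year(self) -> int:
        return int(self._df["event_year"].iloc[0])

    @property
    def category(self) -> int:
        return int(self._df["category"].iloc[0])

    @property
    def teams(self) -> list[str]:
        return sorted(self._df["team_id"].unique())

    @property
    def n_teams(self) -> int:
        return self._df["team_id"].nunique()

    def laps_completed(self) -> pd.Series:
        """Number of completed laps per team (index: team_id, sorted)."""
        return self._df.groupby("team_id")["lap_index"].max().sort_index()

    def records(self) -> list[LapRecord]:
        return [LapRecord(*row) for row in
                self._df[list(CANONICAL_COLUMNS)].itertuples(index=False)]

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RaceTable):
            return NotImplemented
        return self._df[list(CANONICAL_COLUMNS)].equals(
            other._df[list(CANONICAL_COLUMNS)]
        )

    def __repr__(self) -> str:
        return (f"RaceTable(year={self.year}, category=T{self.category}, "
                f"teams={self.n_teams}, laps={len(self)})")


@dataclass
class Cohort:
    """A multi-event cohort: one :class:`RaceTable` per (year, category).

    ``dedup_log`` records, for every solo rider that appeared in more than
    one year, the year retained by :func:`dedup_solo_riders`.
    """

    tables: list[RaceTable]
    dedup_log: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        pairs = [(t.year, t.category) for t in self.tables]
        if len(set(pairs)) != len(pairs):
            dupes = sorted({p for p in pairs if pairs.count(p) > 1})
            raise ValidationError(f"duplicate (year, category) pair(s): {dupes}")

    @property
    def total_records(self) -> int:
        return sum(len(t) for t in self.tables)

    def get(self, year: int, category: int) -> RaceTable:
        for t in self.tables:
            if t.year == year and t.category == category:
                return t
        raise KeyError((year, category))

    def solo_tables(self) -> list[RaceTable]:
        return [t for t in self.tables if t.category == 1]

    def __iter__(self):
        return iter(self.tables)

    def __len__(self) -> int:
        return len(self.tables)


# ---------------------------------------------------------------------------
# CSV ingest / egress
# ---------------------------------------------------------------------------

def read_lap_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    drop_female: bool = True,
) -> RaceTable:
    """Read one event's lap table from CSV.

    Parameters
    ----------
    path
        CSV file with the canonical header (or one mappable onto it).
    column_map
        Optional ``{source_column: canonical_column}`` mapping for export
        variants of the schema.
    drop_female
        If an optional ``sex`` column is present, drop rows labelled
        female and keep male and mixed entries (mixed teams are scored in
        the male classification by race organisers).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=dict(column_map))
    if "sex" in df.columns:
        if drop_female:
            sex = df["sex"].astype(str).str.strip().str.casefold()
            df = df[~sex.isin({"f", "female", "w"})]
        df = df.drop(columns=["sex"])
    return RaceTable(df)


def write_lap_csv(table: RaceTable, path: str | Path) -> None:
    """Write a :class:`RaceTable` in the canonical CSV dialect.

    Fixed column order, '.' decimal separator, UNIX newlines; floats are
    written with full round-trippable precision.
    """
    out = table.df[list(CANONICAL_COLUMNS)].copy()
    # shortest round-trippable representation (pandas' default formatter
    # truncates the 17th significant digit)
    out["lap_time_s"] = [repr(float(v)) for v in out["lap_time_s"]]
    out.to_csv(path, index=False, lineterminator="\n")


def combine_fields(tables: Iterable[RaceTable]) -> RaceTable:
    """Concatenate several team fields of the *same* (year, category) event.

    Used to assemble one race out of separately generated sub-fields.
    Team ids must be distinct across inputs.
    """
    tables = list(tables)
    if not tables:
        raise ValidationError("no tables to combine")
    pairs = {(t.year, t.category) for t in tables}
    if len(pairs) != 1:
        raise ValidationError(f"cannot combine different events: {sorted(pairs)}")
    ids: list[str] = []
    for t in tables:
        ids.extend(t.teams)
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate team ids across combined fields")
    return RaceTable(pd.concat([t.df for t in tables], ignore_index=True))


# ---------------------------------------------------------------------------
# Cohort rules
# ---------------------------------------------------------------------------

def merge_events(tables: Iterable[RaceTable]) -> Cohort:
    """Merge per-event tables across years into a single cohort.

    Year labels are preserved: rank normalization and performance tertiles
    are computed per (year, category) downstream.
    """
    return Cohort(tables=list(tables))


def normalize_rider_id(team_id: str) -> str:
    """Case-folded, whitespace-collapsed rider identity for solo dedup."""
    return " ".join(str(team_id).split()).casefold()


def dedup_solo_riders(cohort: Cohort, seed: int) -> Cohort:
    """Keep one uniformly chosen race entry per repeated solo rider.

    Solo riders racing the event in several years violate the independence
    assumption of the between-subject factors; each such rider is retained
    in exactly one year, chosen uniformly at random.  Team categories
    (4, 10) are left untouched: each team participation is treated as an
    independent observation.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed % 2**32)
    years_by_rider: dict[str, list[tuple[int, str]]] = {}
    for t in cohort.solo_tables():
        for team_id in t.teams:
            years_by_rider.setdefault(normalize_rider_id(team_id), []).append(
                (t.year, team_id)
            )

    drop: dict[int, set[str]] = {}
    log: dict[str, int] = {}
    for rider in sorted(years_by_rider):
        entries = sorted(years_by_rider[rider])
        if len(entries) < 2:
            continue
        kept = entries[rng.integers(len(entries))]
        log[rider] = kept[0]
        for year, team_id in entries:
            if (year, team_id) != kept:
                drop.setdefault(year, set()).add(team_id)

    out: list[RaceTable] = []
    for t in cohort.tables:
        if t.category != 1 or t.year not in drop:
            out.append(t)
            continue
        kept_df = t.df[~t.df["team_id"].isin(drop[t.year])]
        if len(kept_df) == 0:
            warnings.warn(
                f"solo event {t.year}: all riders removed by dedup; "
                "table dropped from cohort"
            )
            continue
        out.append(RaceTable(kept_df, validate=False))
    return Cohort(tables=out, dedup_log=log)
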