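"""Synthetic 24-hour relay race generator.

No machine-readable archive of 24-hour relay lap tables exists, so this
module generates lap-time data carrying the statistical structure the
CFRD analysis assumes: team-size classes of 1, 4 and 10 riders on a
17.9 km circuit, lap times drifting upward with accumulated rider
fatigue, a nocturnal slowdown window, multi-hour inactivity gaps (solo
riders sleep), early terminations, and a configurable lap-to-lap
volatility that drives rank churn.

Published race results record the time between consecutive finish-line
crossings, so a break is embedded in the lap during which it occurred:
the cumulative sum of emitted lap times equals the race clock at every
crossing, never exceeding 24 h.

:func:`plant_rank_trajectories` is the inverse constructor: it builds a
lap table whose recomputed per-lap ranks reproduce a prescribed rank
trajectory exactly, and serves as the ground-truth oracle for CFRD
round-trip tests.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import Cohort, RaceTable, combine_fields, merge_events

HOURS = 3600.0


@dataclass
class RiderProfile:
    """Lap-time model of one rider.

    Parameters
    ----------
    base_lap_time
        Fresh lap time in seconds.
    lap_cv
        Coefficient of variation of multiplicative lognormal lap noise.
    fatigue_rate
        Fractional slowdown per hour *ridden by this rider* (solo riders
        accumulate 1 h of fatigue per race hour ridden; relay riders only
        while on track).
    night_factor
        Multiplicative slowdown applied to laps started inside the
        nocturnal window (>= 1).
    """

    base_lap_time: float
    lap_cv: float = 0.0
    fatigue_rate: float = 0.0
    night_factor: float = 1.0

    def __post_init__(self):
        if self.base_lap_time <= 0:
            raise ValidationError("base_lap_time must be > 0")
        if self.lap_cv < 0:
            raise ValidationError("lap_cv must be >= 0")
        if self.fatigue_rate < 0:
            raise ValidationError("fatigue_rate must be >= 0")
        if self.night_factor < 1:
            raise ValidationError("night_factor must be >= 1")


@dataclass
class TeamConfig:
    """One team: riders, relay rhythm and planned inactivity.

    ``exchange_policy`` is the number of laps per stint before the next
    rider takes over (24-hour relays default to a lap-wise exchange).
    ``break_policy`` lists (start_hour, duration_hours) windows of team
    inactivity; windows must lie within [0, 24) and not overlap.
    """

    team_id: str
    team_size: int
    riders: list[RiderProfile]
    exchange_policy: int = 1
    break_policy: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        if self.team_size not in (1, 4, 10):
            raise ValidationError(f"team_size must be 1, 4 or 10, got {self.team_size}")
        if not 1 <= len(self.riders) <= self.team_size:
            raise ValidationError(
                f"team {self.team_id!r}: rider list length {len(self.riders)} "
                f"must be in 1..team_size ({self.team_size})"
            )
        if self.exchange_policy < 1:
            raise ValidationError("exchange_policy must be >= 1")
        brk = sorted((float(s), float(d)) for s, d in self.break_policy)
        for s, d in brk:
            if not (0 <= s < 24) or d <= 0:
                raise ValidationError(
                    f"team {self.team_id!r}: break ({s}, {d}) outside [0, 24)"
                )
        for (s1, d1), (s2, _) in zip(brk, brk[1:]):
            if s1 + d1 > s2:
                raise ValidationError(f"team {self.team_id!r}: overlapping breaks")
        self.break_policy = brk


@dataclass
class RaceConfig:
    """One event: the track, clock conventions and the team field."""

    name: str
    teams: list[TeamConfig]
    duration_h: float = 24.0
    track_length_km: float = 17.9
    start_clock: str = "20:00"
    night_window: tuple[float, float] = (4.0, 12.0)
    lap_cap: int = 50
    year_label: int = 2022
    category: int | None = None  # inferred from teams when None

    def __post_init__(self):
        if self.duration_h <= 0:
            raise ValidationError("duration must be > 0")
        if self.lap_cap < 1:
            raise ValidationError("lap_cap must be >= 1")
        if not self.teams:
            raise ValidationError("team list must not be empty")
        ids = [t.team_id for t in self.teams]
        if len(set(ids)) != len(ids):
            raise ValidationError("team ids must be distinct")
        sizes = {t.team_size for t in self.teams}
        if len(sizes) != 1:
            raise ValidationError(f"mixed team sizes in one field: {sorted(sizes)}")
        if self.category is None:
            self.category = sizes.pop()
        elif self.category not in sizes:
            raise ValidationError("category does not match team sizes")


def _mean_one_lognormal(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    sigma2 = math.log1p(cv * cv)
    return float(np.exp(rng.normal(-0.5 * sigma2, math.sqrt(sigma2))))


def simulate_race(config: RaceConfig, seed: int) -> RaceTable:
    """Run the per-team event loop and return the emitted lap table.

    A lap is emitted only if its crossing falls within the 24 h race
    clock; a lap straddling the end of the race is not counted.  Each
    team draws from its own random stream, so the result is byte-stable
    under (config, seed) regardless of team order.
    """
    duration_s = config.duration_h * HOURS
    n0, n1 = config.night_window
    rows = []
    base_entropy = seed % 2**32
    for k, team in enumerate(config.teams):
        rng = np.random.default_rng(np.random.SeedSequence([base_entropy, k]))
        breaks = list(team.break_policy)
        bi = 0
        clock = 0.0  # race clock, seconds
        last_cross = 0.0
        rider_idx = 0
        stint_laps = 0
        ridden = [0.0] * len(team.riders)  # hours on track per rider
        lap_index = 0
        while True:
            # consume inactivity windows that have come due
            while bi < len(breaks) and breaks[bi][0] * HOURS <= clock + 1e-9:
                end = (breaks[bi][0] + breaks[bi][1]) * HOURS
                clock = max(clock, end)
                bi += 1
            if clock >= duration_s - 1e-9:
                break
            rider = team.riders[rider_idx]
            night = n0 * HOURS <= clock < n1 * HOURS
            riding = (
                rider.base_lap_time
                * (1.0 + rider.fatigue_rate * ridden[rider_idx])
                * (rider.night_factor if night else 1.0)
                * _mean_one_lognormal(rng, rider.lap_cv)
            )
            if clock + riding > duration_s + 1e-6:
                break
            clock += riding
            ridden[rider_idx] += riding / HOURS
            lap_index += 1
            rows.append(
                (config.year_label, config.category, team.team_id,
                 lap_index, clock - last_cross)
            )
            last_cross = clock
            stint_laps += 1
            if stint_laps >= team.exchange_policy:
                stint_laps = 0
                rider_idx = (rider_idx + 1) % len(team.riders)
        # a team that never crossed the line simply has no rows
    df = pd.DataFrame(
        rows,
        columns=["event_year", "category", "team_id", "lap_index", "lap_time_s"],
    )
    if df.empty:
        raise ValidationError(f"scenario {config.name!r}: no team completed a lap")
    return RaceTable(df)


# ---------------------------------------------------------------------------
# Planted rank trajectories (the CFRD oracle constructor)
# ---------------------------------------------------------------------------

def plant_rank_trajectories(
    rank_sequences: Mapping[str, Sequence[int]],
    base_lap_time: float = 1800.0,
    year: int = 2019,
    category: int = 1,
) -> RaceTable:
    """Construct a lap table realizing a prescribed rank trajectory exactly.

    ``rank_sequences`` maps team id -> rank per lap; at each lap index the
    prescribed ranks must form a permutation of ``1..A``.  Cumulative
    times are built as ``l * base + (rank - 1) * delta`` with a spacing
    ``delta`` small enough that every team's cumulative time stays
    strictly increasing, so sorting by cumulative time at every crossing
    reproduces the prescribed ranks (and, with equal lap counts, the
    final ranks equal the last prescribed row).
    """
    if base_lap_time <= 0:
        raise ValidationError("base_lap_time must be > 0")
    teams = list(rank_sequences)
    if not teams:
        raise ValidationError("no teams")
    a = len(teams)
    lengths = {len(rank_sequences[t]) for t in teams}
    if len(lengths) != 1:
        raise ValidationError("all teams must share equal lap counts")
    n_laps = lengths.pop()
    if n_laps < 1:
        raise ValidationError("at least one lap required")
    ranks = np.array([list(rank_sequences[t]) for t in teams], dtype=float)
    for l in range(n_laps):
        col = np.sort(ranks[:, l])
        if not np.array_equal(col, np.arange(1, a + 1)):
            raise ValidationError(
                f"ranks at lap {l + 1} are not a permutation of 1..{a}: "
                f"{ranks[:, l].tolist()}"
            )
    delta = base_lap_time / (4.0 * a)
    laps_idx = np.arange(1, n_laps + 1, dtype=float)
    cum = laps_idx[None, :] * base_lap_time + (ranks - 1.0) * delta
    lap_times = np.diff(np.concatenate([np.zeros((a, 1)), cum], axis=1), axis=1)
    if (lap_times <= 0).any():
        raise ValidationError("infeasible trajectory: cumulative time would decrease")
    rows = [
        (year, category, team, l + 1, lap_times[i, l])
        for i, team in enumerate(teams)
        for l in range(n_laps)
    ]
    return RaceTable(pd.DataFrame(
        rows, columns=["event_year", "category", "team_id", "lap_index", "lap_time_s"]
    ))


# ---------------------------------------------------------------------------
# Default scenario grid
# ---------------------------------------------------------------------------

LEVELS = ("low", "medium", "high")

# Study conditions of the emulated event (field means of the first lap in
# seconds per team-size class, per-scenario field sizes, and the
# volatility/fatigue/inactivity ladder).  Solo fields are the most
# volatile and take the longest breaks; high-performance fields are the
# fastest and steadiest.  See docs/methods.md for the rationale.
_FIRST_LAP_MEAN = {1: 2024.31, 4: 1769.76, 10: 1758.77}
_N_TEAMS = {1: 18, 4: 12, 10: 10}
_LEVEL_SPEED = {"low": 1.08, "medium": 1.00, "high": 0.92}
_LAP_CV = {
    1: {"low": 0.16, "medium": 0.13, "high": 0.09},
    4: {"low": 0.10, "medium": 0.08, "high": 0.06},
    10: {"low": 0.08, "medium": 0.06, "high": 0.045},
}
_FATIGUE = {
    1: {"low": 0.022, "medium": 0.018, "high": 0.014},
    4: {"low": 0.012, "medium": 0.010, "high": 0.008},
    10: {"low": 0.010, "medium": 0.008, "high": 0.006},
}
_NIGHT = {"low": 1.15, "medium": 1.10, "high": 1.05}
# slowest plausible / fastest plausible relative speed across the level
# grid (level factor 0.92..1.08 times within-field grid 0.90..1.10)
_SPEED_SPAN = (0.92 * 0.90, 1.08 * 1.10)


def _team_grid(n: int, spread: float) -> np.ndarray:
    """Symmetric multiplicative spread of team strengths across a field."""
    if n == 1:
        return np.array([1.0])
    return 1.0 + spread * np.linspace(-1.0, 1.0, n)


def _build_team(size: int, level: str, m: int, n_teams: int) -> TeamConfig:
    center = _FIRST_LAP_MEAN[size] * _LEVEL_SPEED[level]
    team_base = center * _team_grid(n_teams, 0.10)[m]
    n_riders = size
    rider_offsets = (
        np.array([0.0]) if n_riders == 1
        else np.concatenate([[0.0], 0.03 * np.linspace(-1.0, 1.0, n_riders - 1)])
    )
    riders = [
        RiderProfile(
            base_lap_time=team_base * (1.0 + off),
            lap_cv=_LAP_CV[size][level],
            fatigue_rate=_FATIGUE[size][level],
            night_factor=_NIGHT[level],
        )
        for off in rider_offsets
    ]
    # Rest behaviour tracks absolute ability, as in real fields: weaker
    # entrants stop earlier and rest longer.  Because the consumed-break
    # profile is monotone in team strength across the whole merged
    # field, breaks do not scramble the mid-race order beyond lap noise.
    lo, hi = _SPEED_SPAN
    gstr = (team_base / _FIRST_LAP_MEAN[size] - lo) / (hi - lo)  # 0 fast, 1 slow
    gstr = min(max(gstr, 0.0), 1.0)
    jitter = (((m * 7) % n_teams) / n_teams - 0.5)
    if size == 1:
        night = (7.0 - 3.5 * gstr + 0.4 * jitter, 3.5 + 3.5 * gstr)
        # withdrawals happen at the struggling end of the field: riders
        # already near their final (poor) standing stop and hold it
        if n_teams >= 6 and m == n_teams - 2:
            breaks = [night, (14.0, 9.9)]        # withdraws mid-race
        elif n_teams >= 6 and m == n_teams - 4:
            breaks = [night, (18.0, 5.9)]        # withdraws late
        else:
            day_start = 19.0 - 4.0 * gstr + 0.6 * jitter
            breaks = [night, (day_start, 0.5 + 1.2 * gstr)]
    else:
        base_break = 2.2 if size == 4 else 1.3
        breaks = [(7.0 - 2.5 * gstr + 0.4 * jitter,
                   base_break * (0.5 + 1.0 * gstr))]
    return TeamConfig(
        team_id=f"T{size}-{level}-{m:02d}",
        team_size=size,
        riders=riders,
        break_policy=breaks,
    )


def default_scenarios() -> list[RaceConfig]:
    """The 3 x 3 (team size x performance band) scenario grid.

    Nine named configurations -- T1/T4/T10 crossed with low/medium/high
    performance bands -- whose speeds, volatility, fatigue and inactivity
    order as observed in 24-hour relay fields: solo riders are slowest
    and most volatile with the longest breaks; high-performance fields
    are fastest and steadiest.
    """
    return [
        RaceConfig(
            name=f"T{size}-{level}",
            teams=[_build_team(size, level, m, _N_TEAMS[size])
                   for m in range(_N_TEAMS[size])],
        )
        for size in (1, 4, 10)
        for level in LEVELS
    ]


def simulate_default_cohort(seed: int) -> Cohort:
    """Simulate the default grid and assemble one event per team size.

    The three performance bands of one team-size class are merged into a
    single field (sharing one year label), so downstream performance
    tertiles are recovered from final ranks exactly as they would be on
    real results.
    """
    scenarios = default_scenarios()
    by_size: dict[int, list[RaceTable]] = {}
    for i, cfg in enumerate(scenarios):
        table = simulate_race(cfg, seed=(seed % 2**31) * 9 + i)
        by_size.setdefault(cfg.category, []).append(table)
    return merge_events(combine_fields(ts) for ts in by_size.values())


# ---------------------------------------------------------------------------
# TOML scenario files
# ---------------------------------------------------------------------------

def load_scenario(path: str | Path) -> RaceConfig:
    """Read a :class:`RaceConfig` from a TOML scenario file."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    race = doc.get("race", {})
    teams = [
        TeamConfig(
            team_id=t["team_id"],
            team_size=int(t["team_size"]),
            riders=[RiderProfile(**r) for r in t["riders"]],
            exchange_policy=int(t.get("exchange_policy", 1)),
            break_policy=[tuple(b) for b in t.get("breaks", [])],
        )
        for t in doc.get("teams", [])
    ]
    return RaceConfig(
        name=race.get("name", Path(path).stem),
        teams=teams,
        duration_h=float(race.get("duration_h", 24.0)),
        track_length_km=float(race.get("track_length_km", 17.9)),
        start_clock=race.get("start_clock", "20:00"),
        night_window=tuple(race.get("night_window", (4.0, 12.0))),
        lap_cap=int(race.get("lap_cap", 50)),
        year_label=int(race.get("year_label", 2022)),
    )


def _toml_value(v) -> str:
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (bool, np.bool_)):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return repr(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)}")


def dump_scenario(config: RaceConfig, path: str | Path) -> None:
    """Write a :class:`RaceConfig` as a TOML scenario file."""
    lines = ["[race]"]
    for key in ("name", "duration_h", "track_length_km", "start_clock",
                "lap_cap", "year_label"):
        lines.append(f"{key} = {_toml_value(getattr(config, key))}")
    lines.append(f"night_window = {_toml_value(list(config.night_window))}")
    for team in config.teams:
        lines += [
            "",
            "[[teams]]",
            f"team_id = {_toml_value(team.team_id)}",
            f"team_size = {team.team_size}",
            f"exchange_policy = {team.exchange_policy}",
            f"breaks = {_toml_value([list(b) for b in team.break_policy])}",
        ]
        for r in team.riders:
            lines += [
                "",
                "[[teams.riders]]",
                f"base_lap_time = {_toml_value(r.base_lap_time)}",
                f"lap_cv = {_toml_value(r.lap_cv)}",
                f"fatigue_rate = {_toml_value(r.fatigue_rate)}",
                f"night_factor = {_toml_value(r.night_factor)}",
            ]
    Path(path).write_text("\n".join(lines) + "\n")
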