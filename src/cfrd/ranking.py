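"""Cumulative riding times, per-lap and final ranks, rank normalization.

Teams in a 24-hour relay are ranked at every lap crossing on the
cumulative sum of their lap times (the race clock at the crossing).  At
lap index ``l`` the teams that have completed at least ``l`` laps are
ranked ``1..m`` by ascending cumulative time; teams that never reached
lap ``l`` are placed below all of them, ordered by (laps completed
descending, total riding time ascending).  Exact time ties fall back to
lexicographic team id so that the ranking is a total order.

Final classification follows standard 24-hour race logic: more laps beat
fewer laps, equal laps are split by total riding time.  Ranks are
compared across events of different field sizes after a linear
normalization onto ``[1, 100]`` (1 = winner, 100 = last place), computed
per event from its own field size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import RaceTable

DEFAULT_LAP_CAP = 50


def cumulative_times(table: RaceTable) -> pd.DataFrame:
    """Prefix-sum lap times into cumulative riding time per (team, lap).

    Returns a frame indexed by team id (sorted) with integer lap columns
    ``1..Lmax``; entries beyond a team's own lap count are NaN.
    """
    wide = table.df.pivot(index="team_id", columns="lap_index", values="lap_time_s")
    wide = wide.sort_index().sort_index(axis=1)
    return wide.cumsum(axis=1, skipna=False)


def apply_lap_cap(table: RaceTable, cap: int = DEFAULT_LAP_CAP) -> RaceTable:
    """Drop laps beyond ``cap``; the capped table defines final results.

    Lap-by-lap data past the cap is treated as unrecorded, so the standing
    at lap ``cap`` becomes the final result for teams surpassing it.
    """
    if cap < 1:
        raise ValidationError(f"lap cap must be >= 1, got {cap}")
    df = table.df
    if df["lap_index"].max() <= cap:
        return table
    return RaceTable(df[df["lap_index"] <= cap], validate=False)


def _final_order(table: RaceTable) -> list[str]:
    """Team ids best-to-worst by (laps desc, total time asc, team_id)."""
    agg = table.df.groupby("team_id")["lap_time_s"].agg(["count", "sum"])
    key = sorted(
        agg.itertuples(), key=lambda r: (-r.count, r.sum, r.Index)
    )
    return [r.Index for r in key]


def final_ranks(table: RaceTable) -> pd.Series:
    """Final rank per team, 1 = best (index: team_id, sorted)."""
    order = _final_order(table)
    s = pd.Series(np.arange(1, len(order) + 1), index=order, name="final_rank")
    return s.sort_index()


def normalize_ranks(ranks, n: int):
    """Map integer ranks ``1..n`` linearly onto ``[1, 100]``.

    ``r -> 1 + 99 (r - 1) / (n - 1)``; a single-team field maps to 1.
    The transform is order preserving, sends the winner to 1 and the last
    place to 100, and is applied per event so that rank shifts are
    comparable across fields of different size.
    """
    arr = np.asarray(ranks, dtype=float)
    if n < 1:
        raise ValidationError(f"field size must be >= 1, got {n}")
    valid = np.isnan(arr) | ((arr >= 1) & (arr <= n))
    if not valid.all():
        raise ValidationError(f"rank outside 1..{n}: {arr[~valid][:5]}")
    if n == 1:
        out = np.where(np.isnan(arr), np.nan, 1.0)
    else:
        out = 1.0 + 99.0 * (arr - 1.0) / (n - 1.0)
    if np.isscalar(ranks):
        return float(out)
    return out


@dataclass
class RankMatrix:
    """Per-lap and final ranks of one event, raw and normalized.

    ``ranks`` and ``norm_ranks`` are (teams x laps 1..Lmax) frames: every
    team holds a rank at every lap index (teams that never reached a lap
    index are ranked below those that did).  ``cumulative`` is NaN beyond
    a team's own laps.
    """

    year: int
    category: int
    teams: list[str]
    cumulative: pd.DataFrame
    ranks: pd.DataFrame
    final: pd.Series
    norm_ranks: pd.DataFrame
    norm_final: pd.Series
    laps_completed: pd.Series

    @property
    def n_teams(self) -> int:
        return len(self.teams)

    def to_csv(self, path) -> None:
        out = self.norm_ranks.copy()
        out.insert(0, "final_rank", self.final)
        out.insert(1, "final_rank_norm", self.norm_final)
        out.to_csv(path, lineterminator="\n")


def ranks_per_lap(table: RaceTable) -> RankMatrix:
    """Rank every team at every lap crossing of a (capped) event.

    See the module docstring for the ordering rules.  The returned matrix
    also carries final ranks and the ``[1, 100]``-normalized versions of
    both, computed with the event's own field size.
    """
    cum = cumulative_times(table)
    teams = list(cum.index)
    a = len(teams)
    laps = table.laps_completed().reindex(teams)
    total = cum.ffill(axis=1).iloc[:, -1]
    lap_cols = list(cum.columns)

    rank_arr = np.empty((a, len(lap_cols)), dtype=int)
    cum_np = cum.to_numpy()
    laps_np = laps.to_numpy()
    total_np = total.to_numpy()
    for j, _ in enumerate(lap_cols):
        keys = []
        for i, team in enumerate(teams):
            if laps_np[i] >= j + 1:
                keys.append((0, cum_np[i, j], 0.0, team, i))
            else:
                keys.append((1, float(-laps_np[i]), total_np[i], team, i))
        keys.sort(key=lambda k: k[:4])
        for pos, k in enumerate(keys, start=1):
            rank_arr[k[4], j] = pos

    ranks = pd.DataFrame(rank_arr, index=teams, columns=lap_cols)
    fin = final_ranks(table)
    norm = pd.DataFrame(
        normalize_ranks(rank_arr, a), index=teams, columns=lap_cols
    )
    norm_fin = pd.Series(
        normalize_ranks(fin.to_numpy(), a), index=fin.index, name="final_rank_norm"
    )
    return RankMatrix(
        year=table.year,
        category=table.category,
        teams=teams,
        cumulative=cum,
        ranks=ranks,
        final=fin,
        norm_ranks=norm,
        norm_final=norm_fin,
        laps_completed=laps,
    )
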