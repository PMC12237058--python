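"""CFRD computation, 2-hour binning, imputation, clipping, stratification.

The pipeline turns a multi-event cohort of lap tables into the
analysis-ready panel: per team, the median normalized current-to-final
rank difference (CFRD) in each of twelve 2-hour bins of the 24-hour
race, together with the between-subject factors team size ``i`` and
performance level ``j`` (per-year tertiles of final normalized rank).

CFRD_{a,l} = |R_{a,l} - R_{a,final}| on the normalized [1, 100] rank
scale; a value of 0 means the team's current standing already equals its
final outcome.  Teams that stop before the race end hold their final
position for the remaining bins, so post-termination bins are imputed
as exactly 0; bins missed because of temporary inactivity inherit the
next later valid bin value (the rank held through the gap is the one
observed when riding resumes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import Cohort, RaceTable
from .ranking import RankMatrix, apply_lap_cap, ranks_per_lap

N_BINS = 12
BIN_SECONDS = 7200.0
BIN_COLS = [f"b{k:02d}" for k in range(1, N_BINS + 1)]
FACTOR_COLS = ["event_year", "team_size", "team_id", "perf_level",
               "terminated_early", "n_bins_imputed"]


def compute_cfrd(rankmat: RankMatrix, normalized: bool = True) -> pd.DataFrame:
    """Lap-wise |current rank - final rank| per (team, lap).

    Uses normalized ranks by default (raw ranks behind the flag for
    diagnostics).  Entries beyond a team's own last lap are NaN: a team
    contributes CFRD only at its own crossings.
    """
    if normalized:
        ranks, fin = rankmat.norm_ranks, rankmat.norm_final
    else:
        ranks, fin = rankmat.ranks.astype(float), rankmat.final.astype(float)
    cfrd = (ranks.sub(fin, axis=0)).abs()
    own_lap = rankmat.cumulative.notna()
    return cfrd.where(own_lap)


def assign_bins(cumulative: pd.DataFrame) -> pd.DataFrame:
    """Map cumulative riding time (s) to the 2-hour bin index 1..12.

    Half-open intervals (2(b-1), 2b] hours: a crossing exactly on a
    boundary belongs to the earlier bin, keeping bin 12 closed at 24 h.
    """
    arr = cumulative.to_numpy(dtype=float)
    if np.nanmax(arr, initial=0.0) > N_BINS * BIN_SECONDS + 1e-6:
        raise ValidationError("cumulative time beyond 24 h cannot be binned")
    with np.errstate(invalid="ignore"):
        bins = np.ceil(arr / BIN_SECONDS)
    bins = np.where(bins < 1, 1, bins)  # a crossing at t=0 counts to bin 1
    return pd.DataFrame(bins, index=cumulative.index, columns=cumulative.columns)


def bin_medians(cfrd: pd.DataFrame, bins: pd.DataFrame) -> pd.DataFrame:
    """Median lap-wise CFRD per occupied bin; unoccupied bins are NaN."""
    out = np.full((len(cfrd), N_BINS), np.nan)
    c = cfrd.to_numpy(dtype=float)
    b = bins.to_numpy(dtype=float)
    for i in range(len(cfrd)):
        mask = ~np.isnan(c[i])
        for k in range(1, N_BINS + 1):
            sel = mask & (b[i] == k)
            if sel.any():
                out[i, k - 1] = np.median(c[i][sel])
    return pd.DataFrame(out, index=cfrd.index, columns=BIN_COLS)


def impute_panel(
    binned: pd.DataFrame, last_lap_bin: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill the per-team 12-vector to completeness.

    Bins after a team's terminal bin (the bin of its last crossing) are
    set to 0: the rank is frozen at the final position from then on.
    Remaining gaps -- bins skipped during temporary inactivity -- take
    the next later valid bin value (backward fill).  Teams with zero
    occupied bins are excluded with a warning.

    Returns the complete panel and a flags frame with columns
    ``terminated_early`` and ``n_bins_imputed``.
    """
    empty = binned.isna().all(axis=1)
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} team(s) with no occupied bin excluded: "
            f"{list(binned.index[empty])[:5]}"
        )
        binned = binned[~empty]
    last_bin = last_lap_bin.reindex(binned.index).astype(int)

    values = binned.to_numpy(dtype=float).copy()
    n_missing = np.isnan(values).sum(axis=1)
    cols = np.arange(1, N_BINS + 1)
    after_terminal = cols[None, :] > last_bin.to_numpy()[:, None]
    values[after_terminal & np.isnan(values)] = 0.0
    filled = pd.DataFrame(values, index=binned.index, columns=BIN_COLS)
    filled = filled.bfill(axis=1)
    if filled.isna().any().any():  # pragma: no cover - terminal bin is occupied
        raise ValidationError("imputation left missing bins")
    flags = pd.DataFrame(
        {
            "terminated_early": last_bin < N_BINS,
            "n_bins_imputed": n_missing.astype(int),
        },
        index=binned.index,
    )
    return filled, flags


def clip_percentiles(
    values: pd.DataFrame, lo: float = 5.0, hi: float = 95.0,
    scope: str = "pooled",
) -> tuple[pd.DataFrame, tuple]:
    """Winsorize panel values at the [P_lo, P_hi] percentiles.

    ``scope='pooled'`` (default) computes the percentiles once over all
    (team, bin) values of the cohort, preserving cross-bin comparability;
    ``scope='per_bin'`` clips each bin column on its own percentiles.
    """
    arr = values[BIN_COLS] if set(BIN_COLS) <= set(values.columns) else values
    # order-statistic percentiles ('lower'/'higher') keep the bounds at
    # attained data values, which makes winsorization exactly idempotent
    if scope == "pooled":
        pool = arr.to_numpy(dtype=float).ravel()
        p_lo = np.percentile(pool, lo, method="lower")
        p_hi = np.percentile(pool, hi, method="higher")
        clipped = arr.clip(lower=p_lo, upper=p_hi)
        bounds = (float(p_lo), float(p_hi))
    elif scope == "per_bin":
        p_lo = arr.quantile(lo / 100.0, interpolation="lower")
        p_hi = arr.quantile(hi / 100.0, interpolation="higher")
        clipped = arr.clip(lower=p_lo, upper=p_hi, axis=1)
        bounds = (p_lo.to_numpy(), p_hi.to_numpy())
    else:
        raise ValidationError(f"unknown clip scope {scope!r}")
    out = values.copy()
    out[clipped.columns] = clipped
    return out, bounds


def assign_performance_levels(
    final_ranks_normalized: pd.Series,
    final_ranks_raw: pd.Series | None = None,
) -> pd.Series:
    """Tertile split of one event's field on final normalized rank.

    Best third -> level 3 (high), middle -> 2, worst -> 1 (low); group
    sizes differ by at most one, with remainders going to the better
    groups first.  Ties are broken by raw final rank, then team id.
    Fields with fewer than 3 teams are assigned by rank order with a
    warning.
    """
    idx = final_ranks_normalized.index
    raw = (final_ranks_raw if final_ranks_raw is not None
           else pd.Series(0.0, index=idx))
    order = sorted(idx, key=lambda t: (final_ranks_normalized[t], raw[t], t))
    n = len(order)
    if n < 3:
        warnings.warn(f"fewer than 3 teams ({n}); performance levels by rank order")
        levels = {t: 3 - k for k, t in enumerate(order)}
        return pd.Series(levels, name="perf_level").reindex(idx)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if k < rem else 0) for k in range(3)]  # best group first
    levels: dict[str, int] = {}
    pos = 0
    for group, size in zip((3, 2, 1), sizes):
        for t in order[pos:pos + size]:
            levels[t] = group
        pos += size
    return pd.Series(levels, name="perf_level").reindex(idx)


def lap_time_variation(table: RaceTable) -> pd.Series:
    """Per-team median absolute difference between consecutive lap times.

    A pacing-consistency measure in seconds; NaN for teams with fewer
    than two laps.
    """
    out = {}
    for team, grp in table.df.groupby("team_id"):
        t = grp.sort_values("lap_index")["lap_time_s"].to_numpy()
        out[team] = float(np.median(np.abs(np.diff(t)))) if len(t) >= 2 else np.nan
    return pd.Series(out, name="lap_time_variation_s").sort_index()


# ---------------------------------------------------------------------------
# Panel assembly
# ---------------------------------------------------------------------------

@dataclass
class CfrdPanel:
    """Analysis-ready panel: one row per team, 12 bin columns + factors.

    Columns: ``event_year``, ``team_size`` (i), ``team_id``,
    ``perf_level`` (j: 1 low, 2 medium, 3 high), ``terminated_early``,
    ``n_bins_imputed`` and ``b01..b12`` (median normalized CFRD per
    2-hour bin, imputed and clipped).
    """

    df: pd.DataFrame
    clip_bounds: tuple | None = None
    settings: dict = field(default_factory=dict)

    def values(self) -> np.ndarray:
        return self.df[BIN_COLS].to_numpy(dtype=float)

    @property
    def n_teams(self) -> int:
        return len(self.df)

    def cell(self, team_size: int, perf_level: int) -> pd.DataFrame:
        m = (self.df["team_size"] == team_size) & (self.df["perf_level"] == perf_level)
        return self.df[m]

    def to_csv(self, path: str | Path) -> None:
        self.df[FACTOR_COLS + BIN_COLS].to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CfrdPanel":
        return cls(df=pd.read_csv(path))


def build_panel(
    cohort: Cohort,
    cap: int = 50,
    clip: tuple[float, float] | None = (5.0, 95.0),
    clip_scope: str = "pooled",
    normalized: bool = True,
) -> CfrdPanel:
    """Run the full preprocessing chain on a cohort.

    Per event: lap cap -> per-lap + final ranks -> normalization -> CFRD
    -> 2-hour bin medians -> imputation -> performance tertiles; then the
    per-event panels are concatenated and clipped at the pooled
    percentiles.  Deterministic given the cohort.
    """
    parts = []
    for table in cohort:
        capped = apply_lap_cap(table, cap)
        rm = ranks_per_lap(capped)
        cfrd = compute_cfrd(rm, normalized=normalized)
        bins = assign_bins(rm.cumulative)
        med = bin_medians(cfrd, bins)
        last_bin = pd.Series(
            {t: int(bins.loc[t].dropna().iloc[-1]) for t in bins.index}
        )
        filled, flags = impute_panel(med, last_bin)
        levels = assign_performance_levels(
            rm.norm_final.reindex(filled.index), rm.final.reindex(filled.index)
        )
        part = filled.copy()
        part.insert(0, "event_year", table.year)
        part.insert(1, "team_size", table.category)
        part.insert(2, "team_id", part.index)
        part.insert(3, "perf_level", levels)
        part.insert(4, "terminated_early", flags["terminated_early"])
        part.insert(5, "n_bins_imputed", flags["n_bins_imputed"])
        parts.append(part.reset_index(drop=True))
    if not parts:
        raise ValidationError("empty cohort")
    df = pd.concat(parts, ignore_index=True)
    bounds = None
    if clip is not None:
        df, bounds = clip_percentiles(df, *clip, scope=clip_scope)
    return CfrdPanel(
        df=df,
        clip_bounds=bounds,
        settings={"cap": cap, "clip": clip, "clip_scope": clip_scope,
                  "normalized": normalized},
    )


def build_variation(cohort: Cohort, cap: int = 50,
                    panel: CfrdPanel | None = None) -> pd.DataFrame:
    """Per-team lap-time variation with the panel's factor columns.

    Teams with fewer than two laps carry NaN and a ``missing`` flag.
    """
    parts = []
    for table in cohort:
        capped = apply_lap_cap(table, cap)
        v = lap_time_variation(capped)
        part = pd.DataFrame({
            "event_year": table.year,
            "team_size": table.category,
            "team_id": v.index,
            "lap_time_variation_s": v.to_numpy(),
        })
        parts.append(part)
    out = pd.concat(parts, ignore_index=True)
    out["missing"] = out["lap_time_variation_s"].isna()
    if panel is not None:
        key = ["event_year", "team_size", "team_id"]
        out = out.merge(panel.df[key + ["perf_level"]], on=key, how="left")
    return out


def cell_bin_means(panel: CfrdPanel) -> pd.DataFrame:
    """Mean CFRD per (team size, performance level) cell and bin.

    The figure-level summary: bins hold per-team medians, cells are
    averaged over teams.
    """
    return panel.df.groupby(["team_size", "perf_level"])[BIN_COLS].mean()


def median_lap_times(cohort: Cohort, panel: CfrdPanel, cap: int = 50) -> pd.DataFrame:
    """Median lap time (s) per (team size, performance level, bin)."""
    rows = []
    lev = panel.df.set_index(["event_year", "team_size", "team_id"])["perf_level"]
    for table in cohort:
        capped = apply_lap_cap(table, cap)
        cum = ranks_per_lap(capped).cumulative
        bins = assign_bins(cum)
        wide = capped.df.pivot(index="team_id", columns="lap_index",
                               values="lap_time_s").sort_index()
        for team in wide.index:
            j = lev.get((table.year, table.category, team), np.nan)
            laps = wide.loc[team].dropna()
            b = bins.loc[team, laps.index]
            for k in range(1, N_BINS + 1):
                sel = laps[b == k]
                if len(sel):
                    rows.append((table.category, j, k, float(np.median(sel))))
    df = pd.DataFrame(rows, columns=["team_size", "perf_level", "bin", "lap_time_s"])
    return (df.groupby(["team_size", "perf_level", "bin"])["lap_time_s"]
              .median().reset_index())
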