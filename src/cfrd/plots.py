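"""Figure rendering for the CFRD analysis.

Five figure families mirror the standard presentation of this analysis:

* a heatmap of mean CFRD per (team size x performance level) cell and
  2-hour bin;
* mean-CFRD trajectories with 95% confidence intervals and significance
  boxes, once per performance level (lines = team sizes) and once per
  team size (lines = performance levels);
* lower-triangle Cohen's-d matrices of the significant pairwise
  time-interval contrasts per cell;
* median lap times per bin and cell;
* lap-time-variation box plots with significance brackets.

Trajectories plot the *mean* over teams of the per-team bin medians;
the two statistics are deliberately kept distinct.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
# fixed hash salt so SVG element ids (and hence whole output trees) are
# reproducible across runs with the same seed
matplotlib.rcParams["svg.hashsalt"] = "cfrd"

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns
from scipy import stats as sps

from .errors import ValidationError
from .pipeline import BIN_COLS, CfrdPanel, N_BINS
from .stats import StatBundle

_BIN_LABELS = [f"{2 * (b - 1)}-{2 * b}h" for b in range(1, N_BINS + 1)]
_PERF_NAMES = {1: "low", 2: "medium", 3: "high"}


@dataclass
class ReportSpec:
    """Where and how figures are written."""

    outdir: Path
    formats: tuple[str, ...] = ("png", "svg")
    alpha: float = 0.05
    labels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")

    def perf_name(self, j) -> str:
        return self.labels.get(j, _PERF_NAMES.get(int(j), str(j)))


def _save(fig, spec: ReportSpec, name: str) -> list[Path]:
    spec.outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for fmt in spec.formats:
        path = spec.outdir / f"{name}.{fmt}"
        # suppress volatile metadata so identical runs are byte-identical
        meta = {"Date": None} if fmt == "svg" else None
        fig.savefig(path, format=fmt, dpi=110, metadata=meta,
                    bbox_inches="tight")
        paths.append(path)
    plt.close(fig)
    return paths


def _check_panel(panel: CfrdPanel) -> None:
    missing = [c for c in BIN_COLS if c not in panel.df.columns]
    if missing:
        raise ValidationError(
            f"panel must carry all {N_BINS} bin columns; missing {missing} "
            "(single-bin panels cannot be rendered)"
        )


def _ci95(values: np.ndarray) -> float:
    n = len(values)
    if n < 2:
        return 0.0
    return float(sps.t.ppf(0.975, n - 1) * np.std(values, ddof=1) / np.sqrt(n))


def plot_heatmap(panel: CfrdPanel, spec: ReportSpec) -> list[Path]:
    _check_panel(panel)
    means = panel.df.groupby(["team_size", "perf_level"])[BIN_COLS].mean()
    means.index = [f"T{i} {spec.perf_name(j)}" for i, j in means.index]
    fig, ax = plt.subplots(figsize=(9, 0.5 * len(means) + 2))
    sns.heatmap(means, ax=ax, cmap="viridis", annot=False,
                cbar_kws={"label": "mean CFRD (normalized ranks)"})
    ax.set_xticklabels(_BIN_LABELS, rotation=45, ha="right")
    ax.set_xlabel("time interval")
    ax.set_ylabel("team size / performance level")
    ax.set_title("Mean current-to-final rank difference")
    return _save(fig, spec, "cfrd_heatmap")


def _sig_pairs(gh: pd.DataFrame | None, by: str, level, alpha: float):
    """Significant (pair, bin) contrasts from a Games-Howell table."""
    out: dict[tuple, set[int]] = {}
    if gh is None or len(gh) == 0:
        return out
    sub = gh[(gh[by] == level) & (gh["p_adj"] < alpha)]
    for r in sub.itertuples(index=False):
        out.setdefault((r.group_a, r.group_b), set()).add(int(r.bin))
    return out


def _trajectory_figure(panel: CfrdPanel, spec: ReportSpec, by: str,
                       line_factor: str, gh: pd.DataFrame | None,
                       fmt_level, fmt_line) -> tuple:
    levels = sorted(panel.df[by].unique())
    fig, axes = plt.subplots(1, len(levels), figsize=(4.2 * len(levels), 4.4),
                             sharey=True, squeeze=False)
    x = np.arange(1, N_BINS + 1)
    n_boxes = 0
    for ax, level in zip(axes[0], levels):
        sub = panel.df[panel.df[by] == level]
        for line_level in sorted(sub[line_factor].unique()):
            vals = sub.loc[sub[line_factor] == line_level, BIN_COLS]
            mean = vals.mean(axis=0).to_numpy()
            ci = np.array([_ci95(vals[c].to_numpy()) for c in BIN_COLS])
            ax.errorbar(x, mean, yerr=ci, marker="o", ms=3, capsize=2,
                        label=fmt_line(line_level))
        # significance boxes under the curves
        sig = _sig_pairs(gh, by, level, spec.alpha)
        y0 = -2.0
        for (ga, gb), bins in sorted(sig.items()):
            for b in bins:
                ax.plot(b, y0, marker="s", ms=5, color="0.3")
                n_boxes += 1
            ax.text(N_BINS + 0.6, y0, f"{fmt_line(ga)}-{fmt_line(gb)}",
                    fontsize=7, va="center")
            y0 -= 2.0
        ax.set_title(fmt_level(level))
        ax.set_xticks(x[::2])
        ax.set_xticklabels(_BIN_LABELS[::2], rotation=45, ha="right", fontsize=7)
        ax.set_xlabel("time interval")
    axes[0][0].set_ylabel("mean CFRD (95% CI)")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    return fig, n_boxes


def plot_trajectories_by_perf(panel: CfrdPanel, stats: StatBundle,
                              spec: ReportSpec) -> tuple[list[Path], int]:
    """One subplot per performance level, one line per team size."""
    _check_panel(panel)
    fig, n_boxes = _trajectory_figure(
        panel, spec, by="perf_level", line_factor="team_size",
        gh=stats.gh_size,
        fmt_level=lambda j: f"{spec.perf_name(j)} performance",
        fmt_line=lambda i: f"T{i}",
    )
    return _save(fig, spec, "cfrd_by_performance"), n_boxes


def plot_trajectories_by_size(panel: CfrdPanel, stats: StatBundle,
                              spec: ReportSpec) -> tuple[list[Path], int]:
    """One subplot per team size, one line per performance level."""
    _check_panel(panel)
    fig, n_boxes = _trajectory_figure(
        panel, spec, by="team_size", line_factor="perf_level",
        gh=stats.gh_perf,
        fmt_level=lambda i: f"T{i}",
        fmt_line=lambda j: spec.perf_name(j),
    )
    return _save(fig, spec, "cfrd_by_team_size"), n_boxes


def plot_cohend_matrices(panel: CfrdPanel, stats: StatBundle,
                         spec: ReportSpec) -> list[Path]:
    """Lower-triangle Cohen's-d matrices of significant interval pairs."""
    pt = stats.paired_time
    if pt is None or len(pt) == 0:
        warnings.warn("no paired-t table; Cohen's-d matrices skipped")
        return []
    sizes = sorted(pt["team_size"].unique())
    perfs = sorted(pt["perf_level"].unique())
    fig, axes = plt.subplots(len(sizes), len(perfs),
                             figsize=(3.2 * len(perfs), 2.8 * len(sizes)),
                             squeeze=False)
    for r, i in enumerate(sizes):
        for c, j in enumerate(perfs):
            ax = axes[r][c]
            sub = pt[(pt["team_size"] == i) & (pt["perf_level"] == j)]
            mat = np.full((N_BINS, N_BINS), np.nan)
            for row in sub.itertuples(index=False):
                if row.significant and not row.d_undefined:
                    mat[int(row.time_b) - 1, int(row.time_a) - 1] = abs(row.cohen_d)
            sns.heatmap(mat, ax=ax, cmap="rocket_r", vmin=0,
                        cbar=c == len(perfs) - 1, square=True,
                        mask=np.isnan(mat))
            ax.set_title(f"T{i} {spec.perf_name(j)}", fontsize=8)
            ax.set_xticks([])
            ax.set_yticks([])
    fig.suptitle("|Cohen's d| of significant time-interval contrasts", fontsize=10)
    fig.tight_layout()
    return _save(fig, spec, "cohend_matrices")


def plot_median_laptimes(lap_medians: pd.DataFrame,
                         spec: ReportSpec) -> list[Path]:
    """Median lap time per bin, one subplot per team size."""
    sizes = sorted(lap_medians["team_size"].unique())
    fig, axes = plt.subplots(1, len(sizes), figsize=(4.2 * len(sizes), 3.8),
                             sharey=False, squeeze=False)
    for ax, i in zip(axes[0], sizes):
        sub = lap_medians[lap_medians["team_size"] == i]
        for j in sorted(sub["perf_level"].dropna().unique()):
            jj = sub[sub["perf_level"] == j]
            ax.plot(jj["bin"], jj["lap_time_s"], marker="o", ms=3,
                    label=spec.perf_name(j))
        ax.set_title(f"T{i}")
        ax.set_xlabel("time interval")
        ax.set_xticks(range(1, N_BINS + 1, 2))
    axes[0][0].set_ylabel("median lap time [s]")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    return _save(fig, spec, "median_lap_times")


def plot_variation(variation: pd.DataFrame, stats: StatBundle,
                   spec: ReportSpec) -> list[Path]:
    """Lap-time-variation box plots with Mann-Whitney brackets."""
    v = variation.dropna(subset=["lap_time_variation_s"]).copy()
    if "perf_level" not in v.columns or v["perf_level"].isna().all():
        warnings.warn("variation table lacks performance levels; figure skipped")
        return []
    v["perf"] = v["perf_level"].map(spec.perf_name)
    fig, ax = plt.subplots(figsize=(8, 4.4))
    order = [f"T{i}" for i in sorted(v["team_size"].unique())]
    v["size"] = "T" + v["team_size"].astype(int).astype(str)
    sns.boxplot(data=v, x="size", y="lap_time_variation_s", hue="perf",
                order=order, ax=ax, showfliers=False)
    vt = stats.variation_tests
    if vt is not None and len(vt):
        sig = vt[vt["p_adj"] < spec.alpha]
        y = float(v["lap_time_variation_s"].quantile(0.95))
        step = 0.06 * y if y else 1.0
        for k, row in enumerate(sig.itertuples(index=False)):
            ax.text(0.02, 0.97 - 0.05 * k,
                    f"{row.family}: {row.group_a} vs {row.group_b} "
                    f"(p={row.p_adj:.3g})",
                    transform=ax.transAxes, fontsize=7, va="top")
    ax.set_ylim(0, float(v["lap_time_variation_s"].quantile(0.97)) * 1.3 or 1)
    ax.set_ylabel("median |Δ lap time| [s]")
    ax.set_xlabel("team size")
    fig.tight_layout()
    return _save(fig, spec, "lap_time_variation")


def plot_panels(
    panel: CfrdPanel,
    stats: StatBundle,
    spec: ReportSpec,
    lap_medians: pd.DataFrame | None = None,
    variation: pd.DataFrame | None = None,
) -> dict:
    """Render every figure family available from the given inputs.

    Returns a manifest dict: figure name -> written paths, plus the
    total count of significance boxes drawn (useful to verify that an
    all-null cohort produces none).
    """
    _check_panel(panel)
    out: dict = {"n_sig_boxes": 0}
    out["cfrd_heatmap"] = [p.name for p in plot_heatmap(panel, spec)]
    paths, n1 = plot_trajectories_by_perf(panel, stats, spec)
    out["cfrd_by_performance"] = [p.name for p in paths]
    paths, n2 = plot_trajectories_by_size(panel, stats, spec)
    out["cfrd_by_team_size"] = [p.name for p in paths]
    out["n_sig_boxes"] = n1 + n2
    out["cohend_matrices"] = [p.name for p in
                              plot_cohend_matrices(panel, stats, spec)]
    if lap_medians is not None and len(lap_medians):
        out["median_lap_times"] = [p.name for p in
                                   plot_median_laptimes(lap_medians, spec)]
    else:
        warnings.warn("no lap-time medians provided; figure skipped")
    if variation is not None and len(variation):
        out["lap_time_variation"] = [p.name for p in
                                     plot_variation(variation, stats, spec)]
    else:
        warnings.warn("no lap-time variation provided; figure skipped")
    return out
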