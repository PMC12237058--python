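"""Rank-based longitudinal statistics for the CFRD panel.

The core inferential tool is the ANOVA-type statistic (ATS) for a
factorial longitudinal design with two whole-plot factors (team size
``i``, performance level ``j``) and one sub-plot factor (the twelve
2-hour bins).  The ATS is the rank analogue of the mixed-model ANOVA:
all observations are jointly mid-ranked, the vector of cell-by-time
rank means is contrasted with the projection matrix of each effect, and
the quadratic form is referred to an F distribution whose numerator
degrees of freedom come from the Box approximation and whose
denominator degrees of freedom are set to infinity (so the reference
distribution is chi-square over its df).  Being rank-based, every ATS
is invariant under strictly monotone transformations of the response.

Around the omnibus test, the layer provides the simple-effect machinery
reported for this design: Welch's heteroscedastic ANOVA with
Games-Howell pairwise post hocs for the between-subject contrasts,
repeated-measures ANOVA with Greenhouse-Geisser correction plus
Bonferroni-corrected paired t tests (with Cohen's d) for the
within-subject time contrasts, and Bonferroni-corrected Mann-Whitney U
tests for the lap-time-variation comparisons.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .errors import ValidationError
from .pipeline import BIN_COLS, CfrdPanel

EFFECTS = ("size", "perf", "time", "size:perf", "size:time",
           "perf:time", "size:perf:time")


# ---------------------------------------------------------------------------
# Design container
# ---------------------------------------------------------------------------

@dataclass
class LongitudinalDesign:
    """Complete subjects x time response with two between factors."""

    response: np.ndarray        # (n_subjects, n_times)
    factor_a: np.ndarray        # team size per subject
    factor_b: np.ndarray        # performance level per subject
    subjects: np.ndarray | None = None

    def __post_init__(self):
        self.response = np.asarray(self.response, dtype=float)
        self.factor_a = np.asarray(self.factor_a)
        self.factor_b = np.asarray(self.factor_b)
        if self.response.ndim != 2:
            raise ValidationError("response must be subjects x time")
        n = self.response.shape[0]
        if len(self.factor_a) != n or len(self.factor_b) != n:
            raise ValidationError("factor length does not match subjects")
        if np.isnan(self.response).any():
            raise ValidationError("design must be complete (impute first)")
        for ia, ib, cnt in self.cell_counts():
            if cnt < 2:
                raise ValidationError(
                    f"cell (size={ia}, perf={ib}) has {cnt} subject(s); >= 2 required"
                )

    @property
    def levels_a(self):
        return np.unique(self.factor_a)

    @property
    def levels_b(self):
        return np.unique(self.factor_b)

    def cell_counts(self):
        for ia in self.levels_a:
            for ib in self.levels_b:
                yield ia, ib, int(np.sum((self.factor_a == ia) & (self.factor_b == ib)))

    @classmethod
    def from_panel(cls, panel: CfrdPanel) -> "LongitudinalDesign":
        df = panel.df
        return cls(
            response=df[BIN_COLS].to_numpy(dtype=float),
            factor_a=df["team_size"].to_numpy(),
            factor_b=df["perf_level"].to_numpy(),
            subjects=df["team_id"].to_numpy(),
        )


@dataclass
class AtsResult:
    """One effect's ANOVA-type statistic: F(df, inf) reference."""

    effect: str
    statistic: float
    df: float
    p: float


def _center(n: int) -> np.ndarray:
    return np.eye(n) - np.ones((n, n)) / n


def _mean_op(n: int) -> np.ndarray:
    return np.ones((n, n)) / n


def ats_f2_ld_f1(
    design: LongitudinalDesign,
    effects: Sequence[str] = EFFECTS,
) -> list[AtsResult]:
    """ANOVA-type statistics for the two-between x one-within rank design.

    All ``n x t`` observations are pooled and mid-ranked; the vector of
    cell-by-time rank means ``p`` (ordered size-major, time fastest) is
    tested per effect with the idempotent projector ``T`` built from
    Kronecker products of centering/averaging operators:

    ``ATS = p' T p / tr(T V)``, ``df = tr(T V)^2 / tr(T V T V)``,
    ``p-value = P(F(df, inf) > ATS)``,

    where ``V`` is the block-diagonal estimate of ``Cov(p)`` from the
    empirical covariance of subject rank vectors within each cell.
    """
    X = design.response
    n, t = X.shape
    la, lb = design.levels_a, design.levels_b
    a, b = len(la), len(lb)

    if np.all(X == X.ravel()[0]):
        raise ValidationError("constant response: ranks covariance undefined")

    ranks = sps.rankdata(X.ravel()).reshape(n, t)
    q = (ranks - 0.5) / (n * t)  # relative-effect scale (cancels in the ATS)

    p_vec = np.empty(a * b * t)
    blocks = []
    for i, ia in enumerate(la):
        for j, ib in enumerate(lb):
            cell = q[(design.factor_a == ia) & (design.factor_b == ib)]
            nij = cell.shape[0]
            p_vec[(i * b + j) * t:(i * b + j + 1) * t] = cell.mean(axis=0)
            blocks.append(np.cov(cell, rowvar=False, ddof=1) / nij)
    d = a * b * t
    V = np.zeros((d, d))
    for k, blk in enumerate(blocks):
        V[k * t:(k + 1) * t, k * t:(k + 1) * t] = blk

    Pa, Ma = _center(a), _mean_op(a)
    Pb, Mb = _center(b), _mean_op(b)
    Pt, Mt = _center(t), _mean_op(t)
    projectors = {
        "size": (Pa, Mb, Mt),
        "perf": (Ma, Pb, Mt),
        "time": (Ma, Mb, Pt),
        "size:perf": (Pa, Pb, Mt),
        "size:time": (Pa, Mb, Pt),
        "perf:time": (Ma, Pb, Pt),
        "size:perf:time": (Pa, Pb, Pt),
    }

    results = []
    for name in effects:
        A, B, Tt = projectors[name]
        T = np.kron(np.kron(A, B), Tt)
        TV = T @ V
        tr_tv = float(np.trace(TV))
        if tr_tv <= 0:
            raise ValidationError(f"effect {name}: degenerate covariance trace")
        ats = float(p_vec @ T @ p_vec) / tr_tv
        df = tr_tv**2 / float(np.trace(TV @ TV))
        p = float(sps.chi2.sf(ats * df, df))  # F(df, inf) upper tail
        results.append(AtsResult(effect=name, statistic=ats, df=df, p=p))
    return results


def ats_table(results: list[AtsResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.effect, r.statistic, r.df, r.p) for r in results],
        columns=["effect", "ATS", "df", "p"],
    )


# ---------------------------------------------------------------------------
# Classical simple-effect machinery
# ---------------------------------------------------------------------------

@dataclass
class WelchAnovaResult:
    F: float
    df1: float
    df2: float
    p: float


def _check_groups(groups: Sequence[np.ndarray]) -> list[np.ndarray]:
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[~np.isnan(g)] for g in groups]
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    for k, g in enumerate(groups):
        if len(g) < 2:
            raise ValidationError(f"group {k} has fewer than 2 observations")
        if np.var(g, ddof=1) <= 0:
            raise ValidationError(f"group {k} has zero variance")
    return groups


def welch_anova(groups: Sequence[np.ndarray]) -> WelchAnovaResult:
    """Welch's heteroscedastic one-way F test.

    With two groups this reduces to the squared Welch t statistic and an
    identical two-sided p-value.
    """
    groups = _check_groups(groups)
    data = pd.DataFrame({
        "y": np.concatenate(groups),
        "g": np.repeat(np.arange(len(groups)), [len(g) for g in groups]),
    })
    aov = pg.welch_anova(data=data, dv="y", between="g")
    return WelchAnovaResult(
        F=float(aov["F"].iloc[0]),
        df1=float(aov["ddof1"].iloc[0]),
        df2=float(aov["ddof2"].iloc[0]),
        p=float(aov["p_unc"].iloc[0]),
    )


def _cohen_d_pooled(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    s2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
    if s2 <= 0:
        return np.nan
    return float((np.mean(x) - np.mean(y)) / np.sqrt(s2))


def games_howell(
    groups: Sequence[np.ndarray],
    labels: Sequence | None = None,
) -> pd.DataFrame:
    """Games-Howell pairwise comparisons (unequal variances).

    Per pair: Welch-type standard error and Satterthwaite df, p-value
    from the studentized range distribution with k = number of groups.
    Returns one row per unordered pair with the t-type statistic, the
    adjusted p and a pooled-SD Cohen's d.
    """
    groups = _check_groups(groups)
    if labels is None:
        labels = list(range(len(groups)))
    data = pd.DataFrame({
        "y": np.concatenate(groups),
        "g": np.repeat(np.asarray(labels, dtype=object), [len(g) for g in groups]),
    })
    gh = pg.pairwise_gameshowell(data=data, dv="y", between="g")
    by_label = dict(zip(labels, groups))
    rows = []
    for r in gh.itertuples(index=False):
        rows.append((
            r.A, r.B, float(r.T), float(r.df), float(r.pval),
            _cohen_d_pooled(by_label[r.A], by_label[r.B]),
        ))
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "statistic", "df", "p_adj", "cohen_d"]
    )


@dataclass
class RmAnovaResult:
    F: float
    df1: float
    df2: float
    epsilon: float
    p: float
    sphericity_violated: bool
    gg_applied: bool


def rm_anova_gg(responses: np.ndarray) -> RmAnovaResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser guard.

    Mauchly's test decides whether the GG epsilon multiplies both
    degrees of freedom.  With two time points sphericity holds trivially
    and the test equals the squared paired t.  When the within-subject
    covariance is rank deficient (n - 1 <= t) Mauchly is not computable;
    the GG correction is then applied unconditionally with a warning.
    """
    X = np.asarray(responses, dtype=float)
    if X.ndim != 2:
        raise ValidationError("responses must be subjects x time")
    n, t = X.shape
    if n < 3:
        raise ValidationError(f"need >= 3 subjects for a repeated-measures ANOVA, got {n}")
    if t < 2:
        raise ValidationError("need >= 2 time points")
    wide = pd.DataFrame(X)
    aov = pg.rm_anova(wide)
    F = float(aov["F"].iloc[0])
    df1 = float(aov["ddof1"].iloc[0])
    df2 = float(aov["ddof2"].iloc[0])
    p_unc = float(aov["p_unc"].iloc[0])
    if t == 2:
        return RmAnovaResult(F, df1, df2, 1.0, p_unc, False, False)
    eps = float(pg.epsilon(wide, correction="gg"))
    if n - 1 <= t:
        warnings.warn(
            f"covariance rank deficient (n={n} subjects, t={t} time points): "
            "Mauchly untestable, Greenhouse-Geisser applied; increase n to "
            f">= {t + 2} for a sphericity test"
        )
        violated = True
    else:
        spher = pg.sphericity(wide)
        violated = not bool(spher[0])
    if violated:
        p = float(sps.f.sf(F, df1 * eps, df2 * eps))
        return RmAnovaResult(F, df1 * eps, df2 * eps, eps, p, True, True)
    return RmAnovaResult(F, df1, df2, eps, p_unc, False, False)


def paired_t_bonferroni(
    responses: np.ndarray,
    alpha: float = 0.05,
    d_method: str = "diff_sd",
) -> pd.DataFrame:
    """All pairwise paired t tests across time points, Bonferroni family.

    For ``t`` time points the family holds ``t (t-1) / 2`` pairs (66 for
    twelve bins); raw p-values are multiplied by the family size and
    capped at 1.  Cohen's d is the mean difference over the SD of the
    paired differences (``d_method='avg_sd'`` switches to the averaged
    column-SD variant).  Zero-variance differences flag d as undefined.
    """
    X = np.asarray(responses, dtype=float)
    n, t = X.shape
    if n < 2:
        raise ValidationError("need >= 2 subjects")
    pairs = list(itertools.combinations(range(t), 2))
    m = len(pairs)
    rows = []
    for s, u in pairs:
        diff = X[:, u] - X[:, s]
        sd = float(np.std(diff, ddof=1))
        if sd == 0:
            p_raw = 1.0 if np.mean(diff) == 0 else 0.0
            tval, d, flagged = np.nan, np.nan, True
        else:
            tval, p_raw = sps.ttest_rel(X[:, u], X[:, s])
            flagged = False
            if d_method == "diff_sd":
                d = float(np.mean(diff)) / sd
            elif d_method == "avg_sd":
                d = float(np.mean(diff)) / float(
                    (np.std(X[:, s], ddof=1) + np.std(X[:, u], ddof=1)) / 2
                )
            else:
                raise ValidationError(f"unknown d_method {d_method!r}")
        p_adj = min(1.0, float(p_raw) * m)
        rows.append((s + 1, u + 1, float(tval), float(p_raw), p_adj,
                     d, flagged, p_adj < alpha))
    return pd.DataFrame(rows, columns=[
        "time_a", "time_b", "t", "p_raw", "p_adj", "cohen_d",
        "d_undefined", "significant",
    ])


def mann_whitney_bonferroni(
    samples: Mapping, family: Sequence[tuple],
) -> pd.DataFrame:
    """Mann-Whitney U over a named family of pairs, Bonferroni-adjusted.

    U is reported for the first-named sample of each pair.  The exact
    null distribution is used for small tie-free samples
    (min(n1, n2) <= 8), otherwise the normal approximation with tie
    correction.
    """
    m = len(family)
    if m == 0:
        raise ValidationError("empty comparison family")
    rows = []
    for la, lb in family:
        x = np.asarray(samples[la], dtype=float)
        y = np.asarray(samples[lb], dtype=float)
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        if len(x) == 0 or len(y) == 0:
            raise ValidationError(f"empty sample in pair ({la}, {lb})")
        pooled = np.concatenate([x, y])
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        p_adj = min(1.0, float(res.pvalue) * m)
        rows.append((la, lb, float(res.statistic), float(res.pvalue), p_adj, method))
    return pd.DataFrame(rows, columns=[
        "group_a", "group_b", "U", "p_raw", "p_adj", "method",
    ])


def normality_check(sample: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W and p for 3 <= n <= 5000 non-constant samples."""
    x = np.asarray(sample, dtype=float)
    x = x[~np.isnan(x)]
    if not 3 <= len(x) <= 5000:
        raise ValidationError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValidationError("constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class StatBundle:
    """All tables of the reported analysis plus the settings manifest."""

    omnibus: pd.DataFrame | None
    welch_size: pd.DataFrame | None
    gh_size: pd.DataFrame | None
    welch_perf: pd.DataFrame | None
    gh_perf: pd.DataFrame | None
    rm_time: pd.DataFrame
    paired_time: pd.DataFrame
    variation_tests: pd.DataFrame | None
    settings: dict = field(default_factory=dict)

    _TABLES = ("omnibus", "welch_size", "gh_size", "welch_perf", "gh_perf",
               "rm_time", "paired_time", "variation_tests")

    def save(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name in self._TABLES:
            tab = getattr(self, name)
            if tab is not None:
                path = outdir / f"{name}.csv"
                tab.to_csv(path, index=False, lineterminator="\n")
                written.append(path)
        manifest = outdir / "manifest.json"
        manifest.write_text(json.dumps(self.settings, indent=2, sort_keys=True) + "\n")
        written.append(manifest)
        return written

    @classmethod
    def load(cls, outdir: str | Path) -> "StatBundle":
        outdir = Path(outdir)
        kw = {}
        for name in cls._TABLES:
            path = outdir / f"{name}.csv"
            kw[name] = pd.read_csv(path) if path.exists() else None
        settings = json.loads((outdir / "manifest.json").read_text())
        if kw["rm_time"] is None or kw["paired_time"] is None:
            raise ValidationError(f"incomplete stat bundle in {outdir}")
        return cls(settings=settings, **kw)


def _simple_effects_between(
    panel: CfrdPanel, by: str, across: str, alpha: float,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per (level of `by`, bin): Welch ANOVA over `across` + Games-Howell."""
    welch_rows, gh_parts = [], []
    for level in sorted(panel.df[by].unique()):
        sub = panel.df[panel.df[by] == level]
        labels = sorted(sub[across].unique())
        for k, col in enumerate(BIN_COLS, start=1):
            groups = [sub.loc[sub[across] == g, col].to_numpy() for g in labels]
            try:
                res = welch_anova(groups)
            except ValidationError as exc:
                welch_rows.append((level, k, np.nan, np.nan, np.nan, np.nan,
                                   f"untestable: {exc}"))
                continue
            welch_rows.append((level, k, res.F, res.df1, res.df2, res.p, ""))
            if res.p < alpha:
                gh = games_howell(groups, labels=labels)
                gh.insert(0, by, level)
                gh.insert(1, "bin", k)
                gh_parts.append(gh)
    welch = pd.DataFrame(welch_rows, columns=[
        by, "bin", "F", "df1", "df2", "p", "note"])
    gh = (pd.concat(gh_parts, ignore_index=True) if gh_parts
          else pd.DataFrame(columns=[by, "bin", "group_a", "group_b",
                                     "statistic", "df", "p_adj", "cohen_d"]))
    return welch, gh


def analyze(
    panel: CfrdPanel,
    variation: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> StatBundle:
    """Run the full reported analysis on an analysis-ready panel.

    1. omnibus rank-based ATS over (size, perf, time);
    2. if the three-way interaction is significant: per (performance
       level, bin) Welch ANOVA over team sizes and per (team size, bin)
       Welch ANOVA over performance levels, each with Games-Howell post
       hocs for significant ANOVAs;
    3. per (size, perf) cell: repeated-measures ANOVA (GG-guarded) over
       bins plus Bonferroni-corrected paired t tests with Cohen's d;
    4. Mann-Whitney U families on lap-time variation (performance levels
       within team size and team sizes within performance level).

    Degenerate designs (a single cell, or cells with < 2 subjects) skip
    steps 1-2 with a warning; step 3 runs on whatever cells allow it.
    """
    df = panel.df
    sizes = sorted(df["team_size"].unique())
    perfs = sorted(df["perf_level"].unique())
    cells = {(i, j): len(panel.cell(i, j)) for i in sizes for j in perfs}

    omnibus = welch_size = gh_size = welch_perf = gh_perf = None
    interaction_p = None
    can_omnibus = len(sizes) >= 2 and len(perfs) >= 2 and all(
        n >= 2 for n in cells.values())
    if can_omnibus:
        design = LongitudinalDesign.from_panel(panel)
        omnibus = ats_table(ats_f2_ld_f1(design))
        interaction_p = float(
            omnibus.loc[omnibus["effect"] == "size:perf:time", "p"].iloc[0])
        if interaction_p < alpha:
            welch_size, gh_size = _simple_effects_between(
                panel, by="perf_level", across="team_size", alpha=alpha)
            welch_perf, gh_perf = _simple_effects_between(
                panel, by="team_size", across="perf_level", alpha=alpha)
        else:
            warnings.warn(
                f"three-way interaction not significant (p={interaction_p:.3f}); "
                "between-subject simple effects skipped"
            )
    else:
        warnings.warn(
            "degenerate design (single factor level or cell with < 2 subjects); "
            "omnibus ATS and between-subject simple effects skipped"
        )

    rm_rows, paired_parts = [], []
    for (i, j), n in cells.items():
        cell = panel.cell(i, j)
        if n < 3:
            warnings.warn(f"cell (size={i}, perf={j}): n={n} < 3, time effect skipped")
            continue
        X = cell[BIN_COLS].to_numpy(dtype=float)
        if np.ptp(X) == 0:
            warnings.warn(f"cell (size={i}, perf={j}): constant response, skipped")
            continue
        res = rm_anova_gg(X)
        rm_rows.append((i, j, n, res.F, res.df1, res.df2, res.epsilon, res.p,
                        res.sphericity_violated, res.gg_applied))
        pt = paired_t_bonferroni(X, alpha=alpha)
        pt.insert(0, "team_size", i)
        pt.insert(1, "perf_level", j)
        paired_parts.append(pt)
    rm_time = pd.DataFrame(rm_rows, columns=[
        "team_size", "perf_level", "n", "F", "df1", "df2", "epsilon", "p",
        "sphericity_violated", "gg_applied"])
    paired_time = (pd.concat(paired_parts, ignore_index=True) if paired_parts
                   else pd.DataFrame())

    variation_tests = None
    if variation is not None and "perf_level" in variation.columns:
        var_rows = []
        v = variation.dropna(subset=["lap_time_variation_s", "perf_level"])
        for i in sizes:
            sub = v[v["team_size"] == i]
            samples = {j: sub.loc[sub["perf_level"] == j,
                                  "lap_time_variation_s"].to_numpy()
                       for j in perfs}
            fam = [(a_, b_) for a_, b_ in itertools.combinations(perfs, 2)
                   if len(samples[a_]) and len(samples[b_])]
            if fam:
                tab = mann_whitney_bonferroni(samples, fam)
                tab.insert(0, "family", f"perf_within_T{i}")
                var_rows.append(tab)
        for j in perfs:
            sub = v[v["perf_level"] == j]
            samples = {i: sub.loc[sub["team_size"] == i,
                                  "lap_time_variation_s"].to_numpy()
                       for i in sizes}
            fam = [(a_, b_) for a_, b_ in itertools.combinations(sizes, 2)
                   if len(samples[a_]) and len(samples[b_])]
            if fam:
                tab = mann_whitney_bonferroni(samples, fam)
                tab.insert(0, "family", f"size_within_perf{j}")
                var_rows.append(tab)
        variation_tests = (pd.concat(var_rows, ignore_index=True)
                           if var_rows else pd.DataFrame())

    settings = {
        "alpha": alpha,
        "n_subjects": int(len(df)),
        "cells": {f"T{i}/perf{j}": n for (i, j), n in cells.items()},
        "interaction_p": interaction_p,
        "paired_family_size": int(len(BIN_COLS) * (len(BIN_COLS) - 1) / 2),
        "clip_bounds": list(panel.clip_bounds) if panel.clip_bounds else None,
        "panel_settings": panel.settings,
    }
    return StatBundle(
        omnibus=omnibus, welch_size=welch_size, gh_size=gh_size,
        welch_perf=welch_perf, gh_perf=gh_perf, rm_time=rm_time,
        paired_time=paired_time, variation_tests=variation_tests,
        settings=settings,
    )
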