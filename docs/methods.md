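# Methods

## The quantity being analyzed

At every crossing of the finish line a team is ranked on its cumulative
riding time; published 24-hour relay results record the time between
consecutive crossings, so inactivity (a sleep break, a withdrawal) is
embedded in the lap during which it occurred and the cumulative sum of
a team's lap times equals the race clock at each of its crossings.
Ranks at lap index *l* compare cumulative times among teams that have
completed at least *l* laps; teams that never reach lap *l* rank below
all of them, ordered by (total laps descending, total time ascending) —
the same rule that defines the final classification.  Exact time ties
(measure zero in practice) fall back to lexicographic team id so every
ranking is a deterministic total order.

Ranks are min–max normalized onto [1, 100] per event from its own
field size, `r → 1 + 99 (r − 1)/(N − 1)` (a single-team field maps to
1), which makes a one-position shift in a 10-team field worth the same
as a ten-position shift in a 91-team field.  The current-to-final rank
difference is the absolute difference of normalized current and final
rank; by construction it is 0 at a team's final crossing whenever the
order at that crossing matches the final classification (always true
when all teams share a lap count).

Lap data beyond lap 50 is treated as unrecorded: the standing at lap 50
defines the final result for teams that exceed it.

## Binning, imputation, winsorization, stratification

Lap-wise CFRD is aggregated into twelve 2-hour bins of cumulative
riding time, half-open `(2(b−1), 2b]` hours so a crossing exactly on a
boundary belongs to the earlier bin and bin 12 closes at 24 h; each
occupied bin holds the median of its lap-wise values (unweighted — the
data are per crossing, and no duration weighting is applied within a
bin).  Two kinds of missingness are distinguished:

* bins after a team's last calculable bin (early termination): the rank
  is frozen at the final position, so these bins are imputed as exactly
  0;
* interior or leading gaps (a break longer than 2 h): the rank held
  through the gap is the one observed when riding resumes, so gaps take
  the next *later* valid bin value (backward fill; no forward fill).

Teams with no occupied bin at all are excluded with a warning.

Panel values are winsorized at the pooled 5th/95th percentiles across
all (team, bin) values of the cohort — pooled rather than per bin to
preserve cross-bin comparability (per-bin clipping is available behind
a flag).  Percentiles use the `lower`/`higher` order statistics so the
bounds are attained data values and the operation is exactly
idempotent.

Performance levels are per-(year, team-size) tertiles of final
normalized rank: best third → high (j = 3), worst third → low (j = 1),
group sizes differing by at most one with remainders going to the
better groups, ties broken by raw final rank then team id.  Fields of
fewer than three teams are assigned by rank order with a warning.

Lap-time variation — the pacing-consistency measure — is the per-team
median of |t_{a,l+1} − t_{a,l}| in seconds, undefined (flagged) below
two laps.

## The rank-based ANOVA-type statistic

The panel is a two-between (team size i ∈ {1, 4, 10}, performance
j ∈ {1, 2, 3}) × one-within (twelve bins) longitudinal design.  CFRD
panels are heteroscedastic, bounded, and heavily tied (exact zeros), so
the omnibus test is the rank-based ANOVA-type statistic rather than a
Gaussian mixed ANOVA.  All n × 12 observations are pooled and
mid-ranked; with p̂ the vector of cell-by-time means of the scaled
ranks (ordered size-major, time fastest) and V̂ the block-diagonal
estimate of Cov(p̂) from the empirical covariance of subject rank
vectors within each cell, each effect's projector T is a Kronecker
product of centering (P = I − J/n) and averaging (J/n) operators and

```
ATS = p̂' T p̂ / tr(T V̂),   df = tr(T V̂)² / tr(T V̂ T V̂),
p = P( F(df, ∞) > ATS ) = P( χ²_df > df · ATS ).
```

The denominator degrees of freedom are fixed at infinity, so only the
Box-approximated numerator df is reported.  Being rank-based, every
ATS is invariant under strictly monotone transformations of the
response and under subject permutation; the test suite verifies both,
checks the statistic against an independent contrast-matrix/pinv
implementation to 10⁻⁶, and measures the null rejection rate of the
three-way interaction (10,000 iid replicates at 24 subjects per cell —
the scale of the smallest team-size cells in a merged multi-year
cohort): the statistic is mildly conservative (observed level ≈ 0.04 at
nominal 0.05), consistent with the known small-sample behaviour of this
family, and noticeably more conservative below ~10 subjects per cell.

## Simple effects and post hocs

When the three-way interaction is significant at α = 0.05 the analysis
cascades, per 2-hour bin: Welch's heteroscedastic ANOVA across team
sizes within each performance level and across performance levels
within each team size, with Games–Howell pairwise comparisons
(Welch-type SE, Satterthwaite df, studentized-range reference with
k = number of groups) for significant ANOVAs.  Bins where a group has
zero variance (e.g. all-zero late bins of a settled cell) are recorded
as untestable rather than failing the run.

Within each (size, performance) cell the time effect uses a one-way
repeated-measures ANOVA.  Mauchly's test decides whether the
Greenhouse–Geisser ε multiplies both degrees of freedom; with two time
points sphericity holds trivially (the test equals the squared paired
t); when the within-subject covariance is rank deficient (n − 1 ≤ 12)
Mauchly is not computable and GG is applied unconditionally with a
warning — a deliberate choice over erroring, since realistic cells
often hold ~10 teams.  Post hoc time contrasts are all 66 pairwise
paired t tests with Bonferroni correction (p × 66, capped at 1) and
Cohen's d = mean difference / SD of the paired differences (the
averaged-column-SD variant is available via `d_method`).

Lap-time variation is compared with two-sided Mann–Whitney U tests —
exact null distribution for tie-free samples with min(n₁, n₂) ≤ 8,
normal approximation with tie correction otherwise; U is reported for
the first-named sample — Bonferroni-corrected within each family
(performance levels within a team size; team sizes within a performance
level).  Welch/Games–Howell and the RM-ANOVA machinery delegate to
pingouin behind this module's validation layer; the ATS is implemented
here.

## What the synthetic generator emulates

No public machine-readable archive of these races exists, so the
package ships a generator whose defaults encode the study conditions:
24 h on a 17.9 km circuit starting at 20:00, a 50-lap recording cap,
and a 3 × 3 grid of (team size × performance band) scenarios with 18
solo / 12 four-rider / 10 ten-rider teams per scenario.  Field-mean
first-lap times are 2024.31 s (solo), 1769.76 s (T4) and 1758.77 s
(T10); performance bands sit ±8 % around those centers and teams
spread ±10 % within a band (published first-lap SDs are ~13–16 % of
the mean across a merged field).  Per team, lap times follow

```
base × (1 + fatigue_rate · hours ridden by the rider)
     × night_factor (laps started in race hours 4–12)
     × mean-one lognormal noise (CV = lap_cv)
```

with lap-wise rider exchange in squads.  Volatility (lap CV
0.16→0.045), fatigue (0.022→0.006 /h) and the nocturnal factor
(1.15→1.05) all decrease from solo-low to T10-high.  Multiplicative
lognormal noise keeps lap times positive by construction.

Rest behaviour tracks absolute ability, as in real fields: weaker
entrants stop earlier and rest longer (solo night breaks 3.5–7 h
starting between hours 3.5 and 7, short afternoon stops, small
deterministic jitter; squads take one 0.7–3 h gap), and withdrawals
happen at the struggling end of the field, which keeps the
consumed-break profile monotone in team strength — mid-race standings
are then perturbed by lap noise, not scrambled by uncorrelated sleep
schedules, and the pooled mean CFRD declines through the race as it
does in real data.  Mean lap counts land near the published ones
(solo ≈ 27, T4 ≈ 43, T10 ≈ 45, with the fastest squads clipped by the
50-lap cap).  A lap straddling the 24-hour mark is not counted.

What the generator does *not* model: per-rider attribution within
squads, weather, drafting, nutrition or any physiological state, crash
events, and field-size variation across editions.  Passing the
qualitative suite therefore shows that the pipeline recovers the
expected orderings from data with this correlation structure — not
that the effect sizes match any particular real edition.

`plant_rank_trajectories` is the exact oracle: given any per-lap
permutation sequence it builds cumulative times
`l · base + (rank − 1) · δ` with δ = base/(4A), so recomputed ranks
reproduce the prescribed trajectory and CFRD values are checkable by
hand.

## Numerical conventions and degenerate inputs

* All randomness flows through `numpy.random.default_rng`; the
  simulator derives one independent stream per team from
  (seed, team index), so results are byte-stable under (config, seed)
  and independent of team iteration order.  Figures are written with
  volatile metadata suppressed (SVG date, hash salt) so output trees
  are reproducible.
* Cumulative-time bins reject values beyond 24 h + 1 µs; a crossing at
  exactly 0 s counts to bin 1.
* Welch ANOVA requires ≥ 2 observations and positive variance per
  group; the RM-ANOVA requires ≥ 3 subjects; Shapiro–Wilk requires
  3 ≤ n ≤ 5000 and a non-constant sample.  Violations raise
  `ValidationError` (orchestration converts per-bin violations into
  untestable rows).
* Degenerate designs (a single factor level, or a cell with < 2
  subjects) skip the omnibus and between-subject cascades with a
  warning; the within-cell time analysis still runs where possible.

## Scale choices in the test suite

Simulation-backed checks are sized to run comfortably on one CPU: the
qualitative reproduction pools 40 seeds of the 9-scenario cohort
(~4,800 teams), monotonicity of the pooled mean CFRD is asserted
statistically (no adjacent-bin increase beyond 2.5 standard errors of
the per-seed differences — imputation backfill makes some adjacent true
means exactly equal, so a pointwise comparison of noisy estimates would
be ill-posed), ranking equivalence uses 1,000 random fields of ≤ 25
teams against an exhaustive pairwise oracle, and the ATS null
calibration uses 10,000 replicates.

## Known limitations

* The ATS is conservative for very small cells (< ~10 subjects); its
  denominator-∞ convention also ignores the second-moment variability
  a finite denominator df would absorb.
* Backward-fill imputation propagates post-break values into gap bins;
  long synchronized breaks in a field whose rest behaviour is
  *uncorrelated* with strength would bias mid-race CFRD upward — the
  generator deliberately avoids this regime, and real analyses should
  check the inactivity structure of their cohort.
* Per-lap-index ranking is not wall-clock ("on the road") position;
  the two coincide only when lap counts are equal.
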