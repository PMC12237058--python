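"""Run the full CFRD analysis on the default synthetic cohort.

Simulates the 3 x 3 (team size x performance band) scenario grid for
four editions, merges them as a multi-year cohort, builds the binned
CFRD panel and runs the rank-based longitudinal statistics.
"""

import warnings

from cfrd import RaceTable, build_panel, build_variation, cell_bin_means, merge_events
from cfrd.stats import analyze
from cfrd.synthetic import simulate_default_cohort

tables = []
for y in range(4):
    for t in simulate_default_cohort(seed=100 + y):
        df = t.df.copy()
        df["event_year"] = 2019 + y
        df["team_id"] += f"-y{y}"
        tables.append(RaceTable(df, validate=False))
cohort = merge_events(tables)

panel = build_panel(cohort)
variation = build_variation(cohort, panel=panel)
print(f"panel: {panel.n_teams} teams, clip bounds "
      f"({panel.clip_bounds[0]:.1f}, {panel.clip_bounds[1]:.1f})")

print("\nMean CFRD per (team size, performance level) cell and 2-h bin:")
print(cell_bin_means(panel).round(1).to_string())
print("\nCFRD shrinks toward 0 in every cell: standings firm up as the "
      "race runs; solo cells (T1) stay unsettled longest.")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    bundle = analyze(panel, variation=variation)

print("\nOmnibus rank-based ANOVA-type statistics, F(df, inf):")
print(bundle.omnibus.round(4).to_string(index=False))
ip = bundle.settings["interaction_p"]
print(f"\nThree-way interaction p = {ip:.4f}: "
      + ("simple effects were run per bin." if ip < 0.05 else
         "simple effects not warranted at this seed."))
if bundle.variation_tests is not None:
    sig = bundle.variation_tests.query("p_adj < 0.05")
    print(f"\n{len(sig)} significant lap-time-variation contrasts "
          "(solo riders pace least evenly):")
    print(sig.round(4).to_string(index=False))
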