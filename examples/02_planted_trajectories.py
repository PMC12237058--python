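"""Plant an exact rank trajectory and recover its CFRD profile.

The inverse constructor builds lap times that realize a prescribed rank
sequence, which makes CFRD values checkable by hand: a team whose rank
never moves has CFRD 0 everywhere; a volatile team's CFRD mirrors its
distance from the final standing.
"""

from cfrd import compute_cfrd, plant_rank_trajectories, ranks_per_lap

scenario = {
    "steady": [1, 1, 1, 1, 1, 1],       # wire-to-wire leader
    "faded":  [2, 2, 3, 3, 3, 3],       # loses one place mid-race
    "volatile": [3, 3, 2, 2, 2, 2],     # gains it
}
table = plant_rank_trajectories(scenario, base_lap_time=1800.0)
rm = ranks_per_lap(table)
cfrd = compute_cfrd(rm)

print("Normalized CFRD per lap (0 = current standing equals the final):")
print(cfrd.round(1).to_string())
print("\nThe steady leader is at 0 throughout; the other two deviate "
      "exactly while they still hold the rank they will later exchange "
      "(on a 3-team field one position is 49.5 normalized-rank points).")
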