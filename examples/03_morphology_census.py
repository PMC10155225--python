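"""Arm-morphology summaries: trait tallies and the multi-armed census.

Family-level species tallies come straight from the character census;
the multi-armed table lists every species with more than five arms, with
dubious single-specimen reports flagged as exceptional.
"""

import euryalida as eu

chars = eu.load_characters()
tallies = eu.tally_traits(chars)

print("Species tallies per family (branched / with pedicellariae / snakestars):")
for name, fam in tallies["families"].items():
    if name == "Ophiurida":
        continue
    print(f"  {name:18s} {fam['species']:3d} species in {fam['genera']:2d} "
          f"genera: {fam['branched']:2d} / {fam['pedicellariae']:3d} / "
          f"{fam['snakestars']:3d}")
o = tallies["overall"]
print(f"  whole order: {o['species']} species, {o['genera']} genera, "
      f"{o['branched']} basketstars, {o['snakestars']} snakestars")
pct = tallies["percent_of_class"]
print(f"  ~{pct['branched']}% of the ~{pct['class_total']} living ophiuroids "
      f"have branched arms")

print("\nMulti-armed species (> 5 arms):")
census = eu.multiarm_census(eu.load_multiarm())
for _, row in census.iterrows():
    arms = (f"{row.n_arms_min}" if row.n_arms_min == row.n_arms_max
            else f"{row.n_arms_min}-{row.n_arms_max}")
    flag = "  (exceptional case)" if row.exceptional else ""
    print(f"  {row.family:18s} {row.species:28s} {arms} arms{flag}")

# the "at least n forks" recording rule in action
print("\nFork-count recording:", eu.parse_fork_count(">=12"),
      "<- 'at least 12 forks' enters as 13, flagged as a lower bound")
print("First fork at 80 segments ->", eu.classify_pattern(80), "branching;",
      "at 5 segments ->", eu.classify_pattern(5))
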