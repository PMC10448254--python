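"""Bridge an unmapped input segment through a database trail.

The input is a copy of the single database genome with a heavily diverged
100 nt stretch (no 13-mer of it matches) plus a cluster of substitutions
elsewhere, so the circle decomposes into two components. The gap between
them is sequence-similar to the original's trail, which the bridging
routine accepts by local alignment (E-value <= 1e-3), merging the
components back into one."""

import random

from mitodbg import Genome, build_mdbg, build_subgraph, cc_bridging

rng = random.Random(10)
seq = "".join(rng.choice("ACGT") for _ in range(2000))
mutated = list(seq)
for pos in [150, 160, 170, 180] + list(range(1000, 1100, 10)):
    mutated[pos] = rng.choice([c for c in "ACGT" if c != mutated[pos]])
r_in = Genome("input", "".join(mutated))

mdbg = build_mdbg([Genome("donor", seq)], k=12)
match, ccs = build_subgraph(mdbg, r_in)
print(f"{len(ccs)} components:",
      [(cc.start, cc.end) for cc in ccs])

bridges, groups, log = cc_bridging(match, ccs, mdbg)
for event in log:
    print(f"bridge {event.gap_start}..{event.gap_end} via {event.genome_id} "
          f"trail {event.trail_start}..{event.trail_end} "
          f"(score {event.score:.0f}, E = {event.evalue:.2e})")
print("components after bridging:", len(groups))
# the diverged segment still aligns to the donor trail far better than
# chance, so annotation transfer can cross it; bridging stops as soon as a
# single component remains
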