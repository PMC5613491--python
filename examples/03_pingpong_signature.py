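"""Ping-pong 5'-5' overlap signature across developmental stages.

Secondary piRNA biogenesis leaves an excess of sense-antisense read pairs
whose 5' ends overlap by exactly 10 nt.  The signature should peak at
offset 10 only after zygotic genome activation, when TE transcripts start
being cleaved.
"""

import pirnascape as pk

params = pk.SimulationParams(seed=11)
params.genome.n_chroms = 2
params.genome.chrom_length = 400_000
params.clusters.n = 3
params.clusters.min_length = 40_000
params.clusters.max_length = 60_000
params.reads.depth = 20_000

sim = pk.simulate_genome(params)
libraries = pk.simulate_libraries(sim)
unique = {
    stage: pk.partition_by_uniqueness(pk.filter_by_size(lib, 25, 35))[0]
    for stage, lib in libraries.items()
}

sig = pk.stagewise_signature(unique, sim.truth.clusters, max_offset=25)
print("normalized overlap fraction by 5'-5' offset (rows: stages):")
print(sig.round(3).to_string())

print("\nper-stage peak offset and offset-10 participation:")
for stage in sim.params.stages:
    reads = pk.pingpong.restrict_to_loci(unique[stage], sim.truth.clusters)
    part = pk.participation_fraction(reads, offset=10)
    peak = int(sig.loc[stage].idxmax())
    active = "ping-pong active" if stage in sim.params.pingpong.active_stages else "maternal-only"
    print(f"  {stage:8s} peak offset {peak:2d}   {100 * part:5.1f}% of reads in "
          f"offset-10 pairs   ({active})")

print("\nA peak at 10 with rising participation marks secondary piRNA "
      "production; maternal stages show only the flat accidental background.")
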