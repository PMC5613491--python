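"""TE enrichment of piRNA clusters by random-window permutation.

Compares the mean TE-covered fraction of 1-kb windows inside clusters with
the means of repeatedly drawn random window sets of equal size, reporting
an add-one empirical p-value and a z-score.
"""

import pandas as pd

import pirnascape as pk

params = pk.SimulationParams(seed=11)
params.genome.n_chroms = 2
params.genome.chrom_length = 400_000
params.clusters.n = 3
params.clusters.min_length = 40_000
params.clusters.max_length = 60_000

sim = pk.simulate_genome(params)
cluster_bed = pd.DataFrame(
    [(c.chrom, c.start, c.end) for c in sim.truth.clusters],
    columns=["chrom", "start", "end"],
)
genome_windows = pk.tile_windows(sim.chrom_sizes, 1000)
cluster_windows = pk.tile_windows(cluster_bed, 1000)
genome_fr = pk.te_fraction_per_window(sim.te_table, genome_windows)
cluster_fr = pk.te_fraction_per_window(sim.te_table, cluster_windows)

res = pk.enrichment_permutation(cluster_fr, genome_fr, n_perm=1000, seed=17)
print(f"mean TE fraction per 1-kb window inside clusters: {res.observed_mean:.4f} "
      f"({res.n_cluster_windows} windows)")
print(f"genome-wide mean:                                 {res.genome_mean:.4f} "
      f"({res.n_genome_windows} windows)")
print(f"random-sample null: mean {res.perm_means.mean():.4f}, sd {res.perm_sd:.4f}")
print(f"z = {res.z:.1f}, empirical p = {res.p_empirical:.4g} "
      f"(add-one rule; minimum attainable 1/{1000 + 1})")
print("\nClusters carry planted TE insertions, so their windows are far more "
      "TE-dense than any random draw -> p at the grid minimum.")
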