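"""Recombination bin map of a simulated outcrossing F1 population.

Simulates a 'female x male' cross with unequal map lengths, recodes
pseudo-testcross markers to parental origin, collapses them into
recombination bins, and scans for segregation distortion.
"""

import panelsmith as ps

genome, _ = ps.simulate_genome(
    ps.GenomeConfig(n_chroms=2, lengths=(300_000, 200_000)), seed=37
)
g, breakpoints, _ = ps.simulate_f1(
    ps.CrossConfig(n_progeny=200, n_markers=800,
                   map_length_cM_female=120, map_length_cM_male=80),
    genome, seed=38,
)
progeny = [s for s in g.samples if s not in ("P1", "P2")]

for parent, label in (("P1", "female"), ("P2", "male")):
    origin, idx = ps.origin_matrix(g, "P1", "P2", parent)
    bins = ps.build_bins(origin, g.chroms[idx], g.positions[idx])
    rmap = ps.recombination_map(bins, progeny, parent)
    lengths = [b.end - b.start for b in bins if b.end > b.start]
    print(f"{label} parent: {len(idx)} informative markers -> {len(bins)} bins "
          f"({min(lengths)/1e3:.1f}-{max(lengths)/1e3:.1f} kb), "
          f"{rmap.mean_crossovers:.2f} crossovers/progeny")

scan = ps.distortion_scan(g, "P1", "P2")
regions = ps.distortion_regions(scan, alpha=0.05, min_run=3)
print(f"segregation scan: {len(scan)} markers tested, "
      f"{len(regions)} distorted regions (none expected in a neutral cross)")
# The female map is longer, so female-side crossover counts exceed the
# male side; bins collapse co-segregating markers into mapping units.
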