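"""Sweep-region annotation, gene-set enrichment and term similarity.

Candidate windows are merged (>= 50% overlap), extended by 10 kb,
intersected with GFF3 genes, tested for hypergeometric term enrichment and
summarised by the pairwise Jaccard similarity of the term gene sets.
"""

import pandas as pd

import charrscan as cs

cfg = cs.SimulationConfig(
    n_per_pop=8, chrom_lengths=[("chr1", 2_000_000)], fst_target=0.1, seed=1
)
gm = cs.simulate_divergent_populations(cfg)
paths = cs.write_fixture(gm, "example_fixture_annot")

windows = pd.DataFrame([
    {"chrom": "chr1", "start": 400_000, "end": 450_000},
    {"chrom": "chr1", "start": 425_000, "end": 475_000},   # half-overlaps
    {"chrom": "chr1", "start": 1_200_000, "end": 1_250_000},
])
regions = cs.merge_extend(windows, gm.chrom_lengths, extend=10_000)
print("merged + extended regions:")
print(regions.to_string(index=False))

annotated = cs.intersect_genes(regions, paths["gff3"])
genes = set(annotated["gene_id"].dropna())
print(f"\ngenes hit: {sorted(genes)}")

term_sets = cs.read_term_map(paths["term_map"])
result = cs.enrich(genes & term_sets.background, term_sets)
top = result.sort_values("p").head(3)
print("\nmost enriched terms (fold = (k/n)/(K/N), hypergeometric p):")
print(top[["term", "k", "K", "fold", "p"]].to_string(index=False))

jac = cs.jaccard_matrix(term_sets)
print(f"\nJaccard matrix over {len(jac)} terms; "
      f"max off-diagonal similarity = {jac.where(~(jac == 1.0)).max().max():.2f}")
# Two half-overlapping 50-kb windows merge into one 75-kb region; the genes
# inside the extended regions drive the enrichment table, and the Jaccard
# matrix shows which terms share genes.
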