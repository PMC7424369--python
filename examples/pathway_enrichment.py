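"""Hypergeometric enrichment of an up-regulated DEG list in gene sets."""

from reokit import hypergeom_enrich, rankcompv2
from reokit.simulate import generate, scenario_suite

matrix, meta, truth = generate(scenario_suite()["smoking-like"])
g1 = list(meta.index[meta.group == "nonsmoker"])
g2 = list(meta.index[meta.group == "smoker"])
deg = rankcompv2(matrix, g1, g2)

# a small collection: one set seeded with planted genes, one background set
genes = sorted(matrix.index)
collection = {
    "xenobiotic_like": set(truth.degs.gene_id) | set(genes[:15]),
    "background_a": set(genes[40:80]),
    "background_b": set(genes[100:140]),
}
universe = set(matrix.index)  # all genes in the analysed matrix

for label, query in (("up", deg.up_genes), ("down", deg.down_genes)):
    if not query:
        continue
    print(f"{label}-regulated query ({len(query)} genes):")
    for rec in hypergeom_enrich(query, collection, universe):
        print(f"  {rec.name}: overlap {rec.overlap}/{rec.set_size}, "
              f"p = {rec.p_value:.3g}, FDR = {rec.fdr:.3g}")
# The set containing the planted genes is strongly enriched; background sets
# have p near 1. N (universe), K (set size), q (query) and x (overlap) fully
# determine each upper-tail p-value.
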