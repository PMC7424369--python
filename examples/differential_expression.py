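"""Call differentially expressed genes from REO disruption and check them
against the generator's planted ground truth."""

from reokit import rankcompv2
from reokit.simulate import generate, scenario_suite

matrix, meta, truth = generate(scenario_suite()["smoking-like"])
g1 = list(meta.index[meta.group == "nonsmoker"])
g2 = list(meta.index[meta.group == "smoker"])

deg = rankcompv2(matrix, g1, g2, alpha=0.05, stable_alpha=0.05)
print(f"{len(deg.flagged)} DEGs flagged ({len(deg.up_genes)} up, "
      f"{len(deg.down_genes)} down in smokers); "
      f"{deg.iterations_run} iterations, converged={deg.converged}")

planted = set(truth.degs.gene_id)
called = set(deg.flagged)
tp = len(planted & called)
print(f"planted: {len(planted)}, recovered: {tp} "
      f"(sensitivity {tp / len(planted):.2f}, precision {tp / len(called):.2f})")
print(deg.frame.loc[sorted(called)][["g1_gt", "g1_lt", "g2_gt", "g2_lt",
                                     "fdr", "direction"]])
# Each flagged gene's 2x2 table shows how its position among stable partner
# genes differs between groups; direction says which group it moved up in.
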