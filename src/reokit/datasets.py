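"""Small bundled reference tables used by the worked examples and tests.

These are published summary tables from a normal-lung-tissue microarray
cohort study of confounding factors (smoking, sex, race) on within-sample
gene orderings: the 2x2 sample-composition tables used for confounder
balance checks, and the catalog of 24 sex-biased genes with their cytobands.
They are inputs, small enough to ship as literals; every statistic derived
from them (Fisher p-values, chromosome tallies) is computed at run time.
"""

from __future__ import annotations

__all__ = [
    "lung_cohort_balance_tables",
    "sex_biased_gene_cytobands",
]


def lung_cohort_balance_tables() -> dict[str, tuple[tuple[int, int], tuple[int, int]]]:
    """2x2 sample counts from the lung cohort, keyed ``"<split>_x_<factor>"``.

    Rows are split-factor levels, columns test-factor levels:

    - smoking_x_sex: (smoker, nonsmoker) x (male, female) = (31, 18) / (33, 11)
    - smoking_x_race: (white, black) x (smoker, nonsmoker) = (14, 20) / (35, 24)
    - sex_x_race: (male, female) x (white, black) = (25, 9) / (39, 20)
    """
    return {
        "smoking_x_sex": ((31, 18), (33, 11)),
        "smoking_x_race": ((14, 20), (35, 24)),
        "sex_x_race": ((25, 9), (39, 20)),
    }


def sex_biased_gene_cytobands() -> tuple[dict[str, str], dict[str, str]]:
    """The 24 sex-biased lung genes: (upregulated-in-males, upregulated-in-females).

    Each maps gene symbol -> cytoband. 6 of the 10 male-up genes sit on the Y
    chromosome and 12 of the 14 female-up genes on the X; 5 genes in total are
    autosomal.
    """
    male_up = {
        "TTTY10": "Yq11.221",
        "PRKY": "Yp11.2",
        "TBL1Y": "Yp11.2",
        "KDM5D": "Yq11",
        "DDX3Y": "Yq11",
        "UTY": "Yq11",
        "ARSE": "Xp22.3",
        "PRDM7": "16q24.3",
        "DDX43": "6q13",
        "CRISP2": "6p12.3",
    }
    female_up = {
        "SMC1A": "Xp11.22-p11.21",
        "DDX3X": "Xp11.3-p11.23",
        "STS": "Xp22.32",
        "RIBC1": "Xp11.22",
        "ZFX": "Xp21.3",
        "EFHC2": "Xp11.3",
        "KDM6A": "Xp11.2",
        "JPX": "Xq13.2",
        "ZRSR2": "Xp22.1",
        "PNPLA4": "Xp22.3",
        "ARSD": "Xp22.3",
        "GEMIN8": "Xp22.2",
        "C3orf79": "3q25.2",
        "NLRP2": "19q13.42",
    }
    return male_up, female_up
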