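"""Confounder handling: per-pair age association and categorical balance tests.

Age: for each gene pair the samples split into two groups by their
within-sample REO direction (A > B vs A < B; ties drop out), and a two-sided
Mann-Whitney U test asks whether age differs between the two groups. A pair
whose ordering tracks age would show a significant difference; BH adjustment
runs across all tested pairs.

Categorical balance: before attributing reversal REOs to one factor, the
other binary factors must be distributed alike between the two sample groups;
this is the standard 2x2 Fisher exact test on the cross-tabulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .rankcomp import fisher_exact_2x2
from .reo import _iter_pair_blocks, _sorted_gene_order, DEFAULT_BLOCK_SIZE

__all__ = ["AgeAssociationRecord", "BalanceReport", "age_association", "balance_test"]


@dataclass
class AgeAssociationRecord:
    gene_a: str
    gene_b: str
    n_group_gt: int  # samples with expr(a) > expr(b)
    n_group_lt: int
    u_statistic: float
    p_value: float
    fdr: float


def _mwu(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact when both sides <= 25 with no ties.

    Degenerate pooled samples (zero variance) carry no ordering information:
    U is its null mean and p = 1.
    """
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return len(x) * len(y) / 2.0, 1.0
    exact = len(x) <= 25 and len(y) <= 25 and len(np.unique(pooled)) == pooled.size
    res = stats.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.statistic), float(res.pvalue)


def age_association(
    matrix: pd.DataFrame,
    ages: Mapping[str, float] | pd.Series,
    alpha: float = 0.05,
    min_group: int = 5,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> list[AgeAssociationRecord]:
    """Test every gene pair's REO split for an age difference.

    Samples with unknown (NaN) age are dropped for this analysis only. Pairs
    where either REO side has fewer than ``min_group`` samples are skipped and
    excluded from the BH multiplicity. Returns all tested pairs, sorted by
    p-value; callers threshold on ``fdr``.
    """
    ages = pd.Series(ages, dtype=float)
    ages = ages.dropna()
    if ages.empty:
        raise ValueError("all ages unknown")
    if len(ages) < 2 * min_group:
        raise ValueError(f"need ages for at least {2 * min_group} samples")
    known = [s for s in matrix.columns if s in ages.index]
    age_vec = ages.loc[known].to_numpy()
    order = _sorted_gene_order(matrix)
    genes = matrix.index.to_numpy().astype(str)[order]
    values = matrix.loc[:, known].to_numpy(dtype=float)[order]

    records: list[AgeAssociationRecord] = []
    pvals: list[float] = []
    for ia, ib in _iter_pair_blocks(len(genes), block_size):
        diff = values[ia] - values[ib]
        for j in range(ia.size):
            gt_mask = diff[j] > 0
            lt_mask = diff[j] < 0
            if gt_mask.sum() < min_group or lt_mask.sum() < min_group:
                continue
            u, p = _mwu(age_vec[gt_mask], age_vec[lt_mask])
            records.append(
                AgeAssociationRecord(
                    gene_a=genes[ia[j]],
                    gene_b=genes[ib[j]],
                    n_group_gt=int(gt_mask.sum()),
                    n_group_lt=int(lt_mask.sum()),
                    u_statistic=u,
                    p_value=p,
                    fdr=np.nan,
                )
            )
            pvals.append(p)
    if records:
        fdr = multipletests(np.asarray(pvals), method="fdr_bh")[1]
        for rec, q in zip(records, fdr):
            rec.fdr = float(q)
        records.sort(key=lambda r: (r.p_value, r.gene_a, r.gene_b))
    return records


@dataclass
class BalanceReport:
    """2x2 balance check of one factor against the grouping factor."""

    split_factor: str
    test_factor: str
    split_levels: tuple[str, str]
    test_levels: tuple[str, str]
    table: np.ndarray  # rows: split levels, cols: test levels
    fisher_p: float

    @property
    def n(self) -> int:
        return int(self.table.sum())


def balance_test(
    metadata: pd.DataFrame, split_factor: str, test_factor: str
) -> BalanceReport:
    """Fisher exact test of test_factor's distribution across split_factor.

    Samples with unknown values in either factor are dropped; both factors
    must then show exactly two levels. Transposing the roles of the two
    factors leaves the p-value unchanged.
    """
    sub = metadata[[split_factor, test_factor]].astype(str)
    sub = sub[(sub != "unknown").all(axis=1) & (sub != "nan").all(axis=1)]
    split_levels = sorted(sub[split_factor].unique())
    test_levels = sorted(sub[test_factor].unique())
    for name, levels in ((split_factor, split_levels), (test_factor, test_levels)):
        if len(levels) != 2:
            raise ValueError(
                f"factor {name!r} has {len(levels)} observed level(s); need exactly 2"
            )
    table = np.array(
        [
            [
                int(((sub[split_factor] == s) & (sub[test_factor] == t)).sum())
                for t in test_levels
            ]
            for s in split_levels
        ]
    )
    p = fisher_exact_2x2(*table.ravel().tolist())
    return BalanceReport(
        split_factor=split_factor,
        test_factor=test_factor,
        split_levels=tuple(split_levels),
        test_levels=tuple(test_levels),
        table=table,
        fisher_p=p,
    )
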