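"""Population-level differential expression from REO disruption (RankCompV2 style).

A differentially expressed gene shifts its rank relative to many partner
genes, so among the gene pairs whose ordering is stable in *both* groups its
partner-direction profile differs between groups. For each gene we count, over
its common stable partners x,

    g1_gt = #{x : gene > x under group-1 directions},  g1_lt = the mirror,
    g2_gt, g2_lt = the same under group-2 directions,

and test the 2x2 table (g1_gt, g1_lt / g2_gt, g2_lt) with Fisher's exact
test, BH-adjusted across all genes with at least one partner. Because a
strongly shifted gene also perturbs the tables of its (unchanged) partners,
flagged genes are removed from everyone's partner set and the test repeats
until the flagged set reaches a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .reo import compare_stable_pairs, stable_pairs

__all__ = ["fisher_exact_2x2", "rankcompv2", "DegTable"]

UP = "up_in_group2"
DOWN = "down_in_group2"
NONE = "none"


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Two-sided by the standard convention: sum of probabilities of all tables
    with the same margins whose point probability does not exceed the
    observed table's.
    """
    counts = (a, b, c, d)
    if any(x < 0 for x in counts):
        raise ValueError("counts must be nonnegative")
    if not any(counts):
        raise ValueError("at least one count must be positive")
    return _fisher_cached(counts)


@lru_cache(maxsize=100_000)
def _fisher_cached(counts: tuple[int, int, int, int]) -> float:
    a, b, c, d = counts
    return float(stats.fisher_exact([[a, b], [c, d]])[1])


@dataclass
class DegTable:
    """Per-gene REO-disruption results.

    ``frame`` is indexed by gene_id with columns g1_gt, g1_lt, g2_gt, g2_lt,
    fisher_p, fdr, direction, flagged_iteration (nullable Int64; the iteration
    at which a finally-flagged gene was first called). Genes with no common
    stable partner carry NaN statistics and direction "none".
    """

    frame: pd.DataFrame
    alpha: float
    iterations_run: int
    converged: bool

    @property
    def flagged(self) -> list[str]:
        return list(self.frame.index[self.frame["direction"] != NONE])

    @property
    def up_genes(self) -> list[str]:
        return list(self.frame.index[self.frame["direction"] == UP])

    @property
    def down_genes(self) -> list[str]:
        return list(self.frame.index[self.frame["direction"] == DOWN])


def _partner_counts(n_genes, pair_a, pair_b, d, excluded):
    """Per-gene (gt, lt) partner counts under direction vector d (+1: a>b).

    A pair contributes to gene a only if partner b is not excluded, and vice
    versa, so exclusion is asymmetric by construction.
    """
    ok_a = ~excluded[pair_b]
    ok_b = ~excluded[pair_a]
    gt = np.bincount(pair_a[(d > 0) & ok_a], minlength=n_genes) + np.bincount(
        pair_b[(d < 0) & ok_b], minlength=n_genes
    )
    lt = np.bincount(pair_a[(d < 0) & ok_a], minlength=n_genes) + np.bincount(
        pair_b[(d > 0) & ok_b], minlength=n_genes
    )
    return gt, lt


def rankcompv2(
    matrix: pd.DataFrame,
    group1_samples: Sequence[str],
    group2_samples: Sequence[str],
    alpha: float = 0.05,
    stable_alpha: float = 0.05,
    max_iter: int = 10,
    block_size: int | None = None,
) -> DegTable:
    """Call DEGs between two sample groups from their common stable REOs.

    Iteration 0 tests every gene against all of its common stable partners;
    iteration t >= 1 excludes partners flagged at iteration t-1 and re-tests,
    re-adjusts and re-flags from scratch. The process stops when two
    consecutive iterations flag the identical gene set (converged) or at
    ``max_iter``. Direction is up_in_group2 when the gene sits above a larger
    share of its partners under group-2 directions than under group-1; equal
    shares give direction "none" and the gene is not flagged.
    """
    if len(group1_samples) < 2 or len(group2_samples) < 2:
        raise ValueError("need at least 2 samples per group")
    if matrix.shape[0] < 3:
        raise ValueError("need at least 3 genes")
    kwargs = {} if block_size is None else {"block_size": block_size}
    set1 = stable_pairs(matrix, group1_samples, alpha=stable_alpha, group="group1", **kwargs)
    set2 = stable_pairs(matrix, group2_samples, alpha=stable_alpha, group="group2", **kwargs)
    comp = compare_stable_pairs(set1, set2)
    if comp.m == 0:
        raise ValueError(
            "no gene pair is stable in both groups; REO disruption testing cannot proceed"
        )
    genes = comp.gene_ids
    n_genes = len(genes)
    pair_a, pair_b, d1, d2 = comp.common_pair_arrays()

    flagged = np.zeros(n_genes, dtype=bool)
    first_called = np.full(n_genes, -1, dtype=np.int64)
    converged = False
    iterations = 0
    g1_gt = g1_lt = g2_gt = g2_lt = None
    p = fdr_full = None

    for t in range(max_iter):
        iterations = t + 1
        g1_gt, g1_lt = _partner_counts(n_genes, pair_a, pair_b, d1, flagged)
        g2_gt, g2_lt = _partner_counts(n_genes, pair_a, pair_b, d2, flagged)
        total = g1_gt + g1_lt
        testable = total > 0
        idx = np.flatnonzero(testable)
        p = np.full(n_genes, np.nan)
        for g in idx:
            p[g] = fisher_exact_2x2(int(g1_gt[g]), int(g1_lt[g]), int(g2_gt[g]), int(g2_lt[g]))
        fdr_full = np.full(n_genes, np.nan)
        fdr_full[idx] = multipletests(p[idx], method="fdr_bh")[1]
        new_flagged = testable & (fdr_full < alpha) & (g1_gt != g2_gt)
        newly = new_flagged & (first_called < 0)
        first_called[newly] = t
        if t > 0 and np.array_equal(new_flagged, flagged):
            flagged = new_flagged
            converged = True
            break
        flagged = new_flagged

    direction = np.full(n_genes, NONE, dtype=object)
    direction[flagged & (g2_gt > g1_gt)] = UP
    direction[flagged & (g2_gt < g1_gt)] = DOWN
    flag_iter = pd.array(
        [first_called[g] if flagged[g] else None for g in range(n_genes)], dtype="Int64"
    )
    frame = pd.DataFrame(
        {
            "g1_gt": g1_gt,
            "g1_lt": g1_lt,
            "g2_gt": g2_gt,
            "g2_lt": g2_lt,
            "fisher_p": p,
            "fdr": fdr_full,
            "direction": direction,
            "flagged_iteration": flag_iter,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return DegTable(frame=frame, alpha=alpha, iterations_run=iterations, converged=converged)
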