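"""Within-sample relative expression orderings (REOs) and stable gene pairs.

Within one sample the REO of genes A and B is the qualitative relation
A > B or A < B between their expression values. Across a group of samples a
pair is *stable* when one direction holds in a significant majority: with the
direction consistent in k of n informative samples, the one-tailed binomial
upper tail

    p = P(X >= k),  X ~ Binomial(n, p0),  p0 = 0.5

is adjusted by Benjamini-Hochberg across all C(G,2) pairs and thresholded at
an FDR level. Pairs stable in two groups but with opposite directions are
*reversal* pairs; the reversal ratio k/m (reversals over common stable pairs)
quantifies how strongly a factor perturbs the ordering structure.

Samples where the two values are exactly equal support neither direction and
are excluded from n; pairs with n = 0 are untestable but still count in the
BH multiplicity. Everything here is a rank statistic: any strictly monotone
transform of the expression values leaves every output identical.

Pair enumeration proceeds in fixed-size blocks so peak memory is
O(block_size x samples), independent of the total C(G,2) pair count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairDirectionSummary",
    "StablePairSet",
    "PairComparison",
    "binomial_stability_p",
    "summarize_pairs",
    "stable_pairs",
    "compare_stable_pairs",
]

DEFAULT_BLOCK_SIZE = 1_000_000


class PairDirectionSummary(NamedTuple):
    """Direction counts for one canonical gene pair (gene_a < gene_b)."""

    gene_a: str
    gene_b: str
    n_gt: int  # samples with expr(a) > expr(b)
    n_lt: int  # samples with expr(a) < expr(b)
    n_tie: int
    n: int  # informative samples, n_gt + n_lt
    k: int  # majority count, max(n_gt, n_lt)


def binomial_stability_p(k, n, p0: float = 0.5):
    """One-tailed binomial upper tail P(X >= k) for X ~ Binomial(n, p0).

    Vectorised over k and n; evaluated through the survival function so it is
    numerically stable for n well beyond 10,000.
    """
    k = np.asarray(k)
    n = np.asarray(n)
    if not (0 < p0 < 1):
        raise ValueError("p0 must be in (0, 1)")
    if np.any(n < 1):
        raise ValueError("n must be >= 1")
    if np.any((k < 0) | (k > n)):
        raise ValueError("k must satisfy 0 <= k <= n")
    p = stats.binom.sf(k - 1, n, p0)
    return float(p) if p.ndim == 0 else p


def _sorted_gene_order(matrix: pd.DataFrame) -> np.ndarray:
    """Row permutation putting genes in canonical (lexicographic) order."""
    return np.argsort(matrix.index.to_numpy().astype(str), kind="stable")


def _iter_pair_blocks(n_genes: int, block_size: int) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield (ia, ib) index blocks covering all i < j pairs in row-major order."""
    ia_all: list[np.ndarray] = []
    ib_all: list[np.ndarray] = []
    buffered = 0
    for i in range(n_genes - 1):
        ib = np.arange(i + 1, n_genes)
        ia_all.append(np.full(ib.shape, i))
        ib_all.append(ib)
        buffered += ib.size
        if buffered >= block_size:
            ia = np.concatenate(ia_all)
            ib = np.concatenate(ib_all)
            for start in range(0, ia.size, block_size):
                yield ia[start : start + block_size], ib[start : start + block_size]
            ia_all, ib_all, buffered = [], [], 0
    if buffered:
        yield np.concatenate(ia_all), np.concatenate(ib_all)


def _pair_counts(values: np.ndarray, ia: np.ndarray, ib: np.ndarray):
    diff = values[ia] - values[ib]
    n_gt = (diff > 0).sum(axis=1)
    n_lt = (diff < 0).sum(axis=1)
    return n_gt, n_lt


def _subset_values(matrix: pd.DataFrame, samples: Sequence[str] | None) -> np.ndarray:
    sub = matrix if samples is None else matrix.loc[:, list(samples)]
    if sub.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    if sub.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    return sub.to_numpy(dtype=float)


def summarize_pairs(
    matrix: pd.DataFrame,
    samples: Sequence[str] | None = None,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> Iterator[PairDirectionSummary]:
    """Stream direction summaries for all C(G,2) canonical gene pairs."""
    order = _sorted_gene_order(matrix)
    genes = matrix.index.to_numpy().astype(str)[order]
    values = _subset_values(matrix, samples)[order]
    n_samples = values.shape[1]
    for ia, ib in _iter_pair_blocks(len(genes), block_size):
        n_gt, n_lt = _pair_counts(values, ia, ib)
        for j in range(ia.size):
            gt, lt = int(n_gt[j]), int(n_lt[j])
            yield PairDirectionSummary(
                gene_a=genes[ia[j]],
                gene_b=genes[ib[j]],
                n_gt=gt,
                n_lt=lt,
                n_tie=n_samples - gt - lt,
                n=gt + lt,
                k=max(gt, lt),
            )


def _bh_discrete(
    p: np.ndarray, n_tests: int
) -> np.ndarray:
    """BH step-up adjustment of p over a multiplicity of n_tests >= len(p).

    Exploits p-value discreteness by adjusting over distinct values weighted
    by their counts; bit-identical to naive BH on the full vector with the
    n_tests - len(p) untested entries entered as p = 1.
    """
    if p.size == 0:
        return p.copy()
    uniq, inverse, counts = np.unique(p, return_inverse=True, return_counts=True)
    ranks = np.cumsum(counts)  # rank of each value's last occurrence
    adj = uniq * (n_tests / ranks)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    return np.minimum(adj, 1.0)[inverse]


@dataclass
class StablePairSet:
    """Gene pairs with significantly stable REO direction in one sample group.

    Pairs are stored in canonical orientation (gene_a < gene_b
    lexicographically) as index arrays into the sorted gene universe;
    direction +1 means expr(a) > expr(b) in the majority of samples, -1 the
    opposite. Only pairs with fdr < alpha are retained; ``n_total_pairs``
    records the C(G,2) BH multiplicity.
    """

    group: str
    gene_ids: np.ndarray  # sorted gene universe
    pair_a: np.ndarray
    pair_b: np.ndarray
    direction: np.ndarray  # +1 a>b, -1 a<b
    k: np.ndarray
    n: np.ndarray
    p_value: np.ndarray
    fdr: np.ndarray
    alpha: float
    n_total_pairs: int

    def __len__(self) -> int:
        return self.pair_a.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_a": self.gene_ids[self.pair_a],
                "gene_b": self.gene_ids[self.pair_b],
                "direction": np.where(self.direction > 0, "a_gt_b", "a_lt_b"),
                "k": self.k,
                "n": self.n,
                "p_value": self.p_value,
                "fdr": self.fdr,
            }
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, gene_ids: Sequence[str], group: str = "", alpha: float = 0.05
    ) -> "StablePairSet":
        genes = np.sort(np.asarray(list(gene_ids), dtype=str))
        lookup = {g: i for i, g in enumerate(genes)}
        pair_a = np.array([lookup[g] for g in frame["gene_a"]], dtype=np.int64)
        pair_b = np.array([lookup[g] for g in frame["gene_b"]], dtype=np.int64)
        g = len(genes)
        return cls(
            group=group,
            gene_ids=genes,
            pair_a=pair_a,
            pair_b=pair_b,
            direction=np.where(frame["direction"].to_numpy() == "a_gt_b", 1, -1),
            k=frame["k"].to_numpy(dtype=np.int64),
            n=frame["n"].to_numpy(dtype=np.int64),
            p_value=frame["p_value"].to_numpy(dtype=float),
            fdr=frame["fdr"].to_numpy(dtype=float),
            alpha=alpha,
            n_total_pairs=g * (g - 1) // 2,
        )


def stable_pairs(
    matrix: pd.DataFrame,
    samples: Sequence[str] | None = None,
    alpha: float = 0.05,
    group: str = "",
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> StablePairSet:
    """Identify pairs whose REO direction is stable at BH FDR < alpha.

    The BH multiplicity is all C(G,2) pairs, including pairs that are
    untestable because every sample ties (they contribute p = 1 conceptually).
    """
    order = _sorted_gene_order(matrix)
    genes = matrix.index.to_numpy().astype(str)[order]
    values = _subset_values(matrix, samples)[order]
    n_genes = len(genes)
    total_pairs = n_genes * (n_genes - 1) // 2

    ia_parts, ib_parts, k_parts, n_parts, dir_parts = [], [], [], [], []
    for ia, ib in _iter_pair_blocks(n_genes, block_size):
        n_gt, n_lt = _pair_counts(values, ia, ib)
        n = n_gt + n_lt
        informative = n > 0
        ia, ib = ia[informative], ib[informative]
        n_gt, n_lt, n = n_gt[informative], n_lt[informative], n[informative]
        ia_parts.append(ia)
        ib_parts.append(ib)
        k_parts.append(np.maximum(n_gt, n_lt))
        n_parts.append(n)
        dir_parts.append(np.where(n_gt >= n_lt, 1, -1))

    ia = np.concatenate(ia_parts) if ia_parts else np.empty(0, dtype=np.int64)
    ib = np.concatenate(ib_parts) if ib_parts else np.empty(0, dtype=np.int64)
    k = np.concatenate(k_parts) if k_parts else np.empty(0, dtype=np.int64)
    n = np.concatenate(n_parts) if n_parts else np.empty(0, dtype=np.int64)
    direction = np.concatenate(dir_parts) if dir_parts else np.empty(0, dtype=np.int64)

    p = binomial_stability_p(k, n) if k.size else np.empty(0)
    fdr = _bh_discrete(np.asarray(p, dtype=float), total_pairs)
    keep = fdr < alpha
    return StablePairSet(
        group=group,
        gene_ids=genes,
        pair_a=ia[keep].astype(np.int64),
        pair_b=ib[keep].astype(np.int64),
        direction=direction[keep],
        k=k[keep],
        n=n[keep],
        p_value=np.asarray(p)[keep],
        fdr=fdr[keep],
        alpha=alpha,
        n_total_pairs=total_pairs,
    )


_UNDEFINED = object()


@dataclass
class PairComparison:
    """Overlap of two StablePairSets classified concordant vs reversal.

    ``reversal_ratio`` is k/m; when m = 0 it is None (explicitly undefined,
    never a division error). Symmetric in the two input sets.
    """

    gene_ids: np.ndarray
    m: int
    k_reversal: int
    pair_a: np.ndarray = field(repr=False)
    pair_b: np.ndarray = field(repr=False)
    direction_1: np.ndarray = field(repr=False)
    direction_2: np.ndarray = field(repr=False)

    @property
    def concordant(self) -> int:
        return self.m - self.k_reversal

    @property
    def reversal_ratio(self) -> float | None:
        return None if self.m == 0 else self.k_reversal / self.m

    def _iter(self, reversal: bool):
        mask = self.direction_1 != self.direction_2 if reversal else self.direction_1 == self.direction_2
        for a, b, d1, d2 in zip(
            self.pair_a[mask], self.pair_b[mask], self.direction_1[mask], self.direction_2[mask]
        ):
            yield (self.gene_ids[a], self.gene_ids[b], int(d1), int(d2))

    def reversal_pairs(self):
        """Yield (gene_a, gene_b, dir_group1, dir_group2) for reversal pairs."""
        return self._iter(reversal=True)

    def concordant_pairs(self):
        return self._iter(reversal=False)

    def common_pair_arrays(self):
        """Index arrays (pair_a, pair_b, dir1, dir2) over the common stable pairs."""
        return self.pair_a, self.pair_b, self.direction_1, self.direction_2


def compare_stable_pairs(set1: StablePairSet, set2: StablePairSet) -> PairComparison:
    """Classify pairs stable in both groups as concordant or reversal."""
    if set1.gene_ids.shape != set2.gene_ids.shape or not np.array_equal(
        set1.gene_ids, set2.gene_ids
    ):
        raise ValueError("stable pair sets built over different gene universes")
    g = len(set1.gene_ids)
    code1 = set1.pair_a * g + set1.pair_b
    code2 = set2.pair_a * g + set2.pair_b
    common, idx1, idx2 = np.intersect1d(code1, code2, return_indices=True)
    d1 = set1.direction[idx1]
    d2 = set2.direction[idx2]
    return PairComparison(
        gene_ids=set1.gene_ids,
        m=int(common.size),
        k_reversal=int((d1 != d2).sum()),
        pair_a=set1.pair_a[idx1],
        pair_b=set1.pair_b[idx1],
        direction_1=d1,
        direction_2=d2,
    )
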