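"""Hypergeometric gene-set enrichment of DEG lists.

Up- and downregulated gene lists are tested separately against a named
collection of gene sets (GMT). For a universe of N genes, a set covering K of
them and a query of q genes overlapping the set in x, the enrichment p-value
is the upper tail P(X >= x) of the hypergeometric distribution, BH-adjusted
across the collection. The universe defaults to all genes in the expression
matrix under analysis and must be stated explicitly — the p-value depends
strongly on N.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["EnrichmentRecord", "hypergeom_enrich"]


@dataclass
class EnrichmentRecord:
    name: str
    set_size: int  # K: set members inside the universe
    universe_size: int  # N
    query_size: int  # q
    overlap: int  # x
    p_value: float
    fdr: float


def hypergeom_enrich(
    query: Iterable[str],
    collection: Mapping[str, set[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
    min_set_size: int = 2,
) -> list[EnrichmentRecord]:
    """Upper-tail hypergeometric enrichment of ``query`` in each gene set.

    Sets are intersected with the universe first; sets smaller than
    ``min_set_size`` after intersection are skipped and excluded from the BH
    multiplicity. Records are sorted by p-value, ties broken by set name.
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query")
    extra = query - universe
    if extra:
        raise ValueError(f"query genes outside the universe: {sorted(extra)[:5]}")
    n_universe = len(universe)
    n_query = len(query)

    records: list[EnrichmentRecord] = []
    for name in sorted(collection):
        members = collection[name] & universe
        if len(members) < min_set_size:
            continue
        overlap = len(members & query)
        p = float(stats.hypergeom.sf(overlap - 1, n_universe, len(members), n_query))
        records.append(
            EnrichmentRecord(
                name=name,
                set_size=len(members),
                universe_size=n_universe,
                query_size=n_query,
                overlap=overlap,
                p_value=p,
                fdr=np.nan,
            )
        )
    if records:
        fdr = multipletests([r.p_value for r in records], method="fdr_bh")[1]
        for rec, q in zip(records, fdr):
            rec.fdr = float(q)
        records.sort(key=lambda r: (r.p_value, r.name))
    return records
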