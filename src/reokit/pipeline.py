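"""End-to-end orchestration: balance checks -> stable pairs -> comparison ->
REO-disruption DEGs -> enrichment, plus chromosome tallies of DEG lists.

``run_pipeline`` is a thin sequencer over the stage functions — it holds no
hidden state, so every number in its manifest can be reproduced by calling
the corresponding stage directly on the same inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .covariates import balance_test
from .enrichment import hypergeom_enrich
from .io import (
    chromosome_of,
    read_cytobands,
    read_expression,
    read_gmt,
    read_metadata,
)
from .rankcomp import rankcompv2
from .reo import compare_stable_pairs, stable_pairs

__all__ = ["RunConfig", "run_pipeline", "chromosome_class_tally", "top_variance_genes"]


@dataclass
class RunConfig:
    expression: str
    metadata: str
    out_dir: str
    gmt: str | None = None
    cytobands: str | None = None
    group_col: str = "group"
    g1: str | None = None  # group labels; default: the two observed, sorted
    g2: str | None = None
    stable_alpha: float = 0.05
    deg_alpha: float = 0.05
    enrich_alpha: float = 0.05
    max_iter: int = 10
    gene_cap: int | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("stable_alpha", "deg_alpha", "enrich_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")


def top_variance_genes(matrix: pd.DataFrame, cap: int) -> pd.DataFrame:
    """Deterministic desk-scale reduction: keep the ``cap`` highest-variance
    genes (log scale), ties broken by gene ID."""
    if cap >= matrix.shape[0]:
        return matrix
    var = np.log(matrix.clip(lower=np.finfo(float).tiny)).var(axis=1)
    order = sorted(matrix.index, key=lambda g: (-var[g], g))
    keep = sorted(order[:cap])
    return matrix.loc[keep]


def chromosome_class_tally(
    directions: Mapping[str, str], annot: Mapping[str, str]
) -> dict:
    """Tally DEGs per chromosome class {X, Y, autosome} for each direction label.

    ``directions`` maps gene -> direction label (any string, e.g.
    "up_in_group2"). Every gene must be annotated with a cytoband.
    """
    missing = [g for g in directions if g not in annot]
    if missing:
        raise ValueError(f"unannotated gene(s): {sorted(missing)}")
    tally: dict[str, dict[str, int]] = {}
    for gene, direction in directions.items():
        chrom = chromosome_of(annot[gene])
        cls = chrom if chrom in ("X", "Y") else "autosome"
        tally.setdefault(direction, {"X": 0, "Y": 0, "autosome": 0})
        tally[direction][cls] += 1
    total = {"X": 0, "Y": 0, "autosome": 0}
    for counts in tally.values():
        for cls in total:
            total[cls] += counts[cls]
    tally["total"] = total
    tally["sex_chromosome_total"] = total["X"] + total["Y"]
    return tally


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _stamp(config_hash: str) -> str:
    return f"reokit {__version__} config_hash={config_hash}"


def _write_tsv(frame: pd.DataFrame, path: Path, stamp: str, index_label=None) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# {stamp}\n")
        frame.to_csv(fh, sep="\t", index=index_label is not None, index_label=index_label)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write per-stage TSVs plus ``manifest.json``.

    Returns the manifest: config echo, software version, output paths, and
    the headline statistics of each stage (balance p-values, per-group stable
    pair counts, m, reversal count and ratio, DEG counts, enrichment hits).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = _stamp(_config_hash(config))

    matrix = read_expression(config.expression)
    meta = read_metadata(config.metadata)
    unknown = [s for s in matrix.columns if s not in meta.index]
    if unknown:
        raise ValueError(f"stage load: samples without metadata: {unknown[:5]}")
    if config.gene_cap is not None:
        matrix = top_variance_genes(matrix, config.gene_cap)

    groups = meta.loc[list(matrix.columns), config.group_col]
    observed = sorted(g for g in groups.unique() if g != "unknown")
    g1 = config.g1 if config.g1 is not None else observed[0]
    g2 = config.g2 if config.g2 is not None else observed[1] if len(observed) > 1 else None
    if g1 is None or g2 is None or g1 == g2:
        raise ValueError("stage grouping: need two distinct group labels")
    samples1 = list(groups.index[groups == g1])
    samples2 = list(groups.index[groups == g2])

    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "groups": {"group1": g1, "group2": g2, "n1": len(samples1), "n2": len(samples2)},
        "outputs": {},
        "stages": {},
    }

    # 1. confounder balance between the two groups
    balance = {}
    sub = meta.loc[samples1 + samples2].copy()
    sub["__group"] = [g1] * len(samples1) + [g2] * len(samples2)
    for factor in ("sex", "race", "smoking"):
        if factor == config.group_col:
            continue
        try:
            report = balance_test(sub, "__group", factor)
            balance[factor] = {"table": report.table.tolist(), "fisher_p": report.fisher_p}
        except ValueError as exc:
            balance[factor] = {"skipped": str(exc)}
    manifest["stages"]["balance"] = balance

    # 2. stable pairs per group
    set1 = stable_pairs(matrix, samples1, alpha=config.stable_alpha, group=g1)
    set2 = stable_pairs(matrix, samples2, alpha=config.stable_alpha, group=g2)
    for label, spset in (("group1", set1), ("group2", set2)):
        path = out / f"stable_pairs_{label}.tsv"
        _write_tsv(spset.to_frame(), path, stamp)
        manifest["outputs"][f"stable_pairs_{label}"] = str(path)
    manifest["stages"]["stable_pairs"] = {
        "group1_stable": len(set1),
        "group2_stable": len(set2),
        "total_pairs": set1.n_total_pairs,
    }

    # 3. concordant / reversal comparison
    comp = compare_stable_pairs(set1, set2)
    rev_frame = pd.DataFrame(
        list(comp.reversal_pairs()), columns=["gene_a", "gene_b", "dir_group1", "dir_group2"]
    )
    _write_tsv(rev_frame, out / "reversal_pairs.tsv", stamp)
    manifest["outputs"]["reversal_pairs"] = str(out / "reversal_pairs.tsv")
    manifest["stages"]["comparison"] = {
        "m_common": comp.m,
        "k_reversal": comp.k_reversal,
        "concordant": comp.concordant,
        "reversal_ratio": comp.reversal_ratio,
    }

    # 4. REO-disruption DEG calling
    deg = rankcompv2(
        matrix,
        samples1,
        samples2,
        alpha=config.deg_alpha,
        stable_alpha=config.stable_alpha,
        max_iter=config.max_iter,
    )
    _write_tsv(deg.frame, out / "deg_table.tsv", stamp, index_label="gene_id")
    manifest["outputs"]["deg_table"] = str(out / "deg_table.tsv")
    manifest["stages"]["rankcomp"] = {
        "n_flagged": len(deg.flagged),
        "n_up_in_group2": len(deg.up_genes),
        "n_down_in_group2": len(deg.down_genes),
        "iterations_run": deg.iterations_run,
        "converged": deg.converged,
    }

    # 5. enrichment of up/down lists, if gene sets were provided
    if config.gmt is not None:
        collection = read_gmt(config.gmt)
        universe = set(matrix.index)
        enrich_summary = {}
        for label, genes in (("up", deg.up_genes), ("down", deg.down_genes)):
            if not genes:
                enrich_summary[label] = {"skipped": "no genes"}
                continue
            records = hypergeom_enrich(genes, collection, universe, alpha=config.enrich_alpha)
            frame = pd.DataFrame([vars(r) for r in records])
            path = out / f"enrichment_{label}.tsv"
            _write_tsv(frame, path, stamp)
            manifest["outputs"][f"enrichment_{label}"] = str(path)
            enrich_summary[label] = {
                "n_tested": len(records),
                "n_significant": sum(r.fdr < config.enrich_alpha for r in records),
            }
        manifest["stages"]["enrichment"] = enrich_summary

    # 6. chromosome tally of the DEG list, if cytobands were provided
    if config.cytobands is not None and len(deg.flagged):
        annot = read_cytobands(config.cytobands)
        directions = {
            g: deg.frame.loc[g, "direction"] for g in deg.flagged
        }
        manifest["stages"]["chromosome_tally"] = chromosome_class_tally(directions, annot)

    with open(out / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["outputs"]["manifest"] = str(out / "manifest.json")
    return manifest
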