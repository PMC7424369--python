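"""Readers, writers and validation for the formats the pipeline touches.

Expression matrices are plain pandas DataFrames: rows indexed by gene ID,
columns by sample ID, values numeric. REO analysis only ever compares values
*within* a column, so the expression scale (linear, log, arbitrary units) is
irrelevant as long as it is monotone — the pipeline is deliberately agnostic.

Sample metadata is a DataFrame indexed by sample ID with columns
``group``, ``sex``, ``race``, ``smoking`` and ``age``. Categorical values the
vocabulary does not recognise are normalised to the explicit string
``"unknown"``; unknown ages are NaN. Nothing is dropped at load time —
filtering is the job of the analysis stages.
"""

from __future__ import annotations

import io as _io
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "read_expression",
    "write_expression",
    "validate_expression",
    "read_metadata",
    "write_metadata",
    "read_gmt",
    "write_gmt",
    "read_cytobands",
    "write_cytobands",
    "read_probe_annotation",
    "probe_collapse",
    "chromosome_of",
]

METADATA_COLUMNS = ["group", "sex", "race", "smoking", "age"]
_SEX_LEVELS = {"male", "female"}
_SMOKING_LEVELS = {"smoker", "nonsmoker"}
_CHROMOSOMES = {str(i) for i in range(1, 23)} | {"X", "Y"}


def _strip_comments(path) -> _io.StringIO:
    with open(path, "rt", encoding="utf-8") as fh:
        return _io.StringIO("".join(ln for ln in fh if not ln.startswith("#")))


def validate_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check ExpressionMatrix invariants; returns the matrix unchanged."""
    dup = matrix.index[matrix.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene ID(s): {sorted(set(dup))}")
    dup = matrix.columns[matrix.columns.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample ID(s): {sorted(set(dup))}")
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("expression values must be numeric")
    if not np.isfinite(values).all():
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"non-finite expression value at gene {matrix.index[bad[0]]!r}, "
            f"sample {matrix.columns[bad[1]]!r}"
        )
    return matrix


def read_expression(path) -> pd.DataFrame:
    """Read a gene-by-sample TSV: header row of sample IDs, first column gene IDs.

    Row and column order are preserved. Duplicate IDs, missing cells and
    non-numeric cells are load errors naming the offending coordinates.
    """
    raw = pd.read_csv(_strip_comments(path), sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    out = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            gene = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-numeric or missing value at gene {gene!r}, sample {col!r}"
            )
        out[col] = converted.to_numpy()
    return validate_expression(out)


def write_expression(matrix: pd.DataFrame, path, comment: str | None = None) -> None:
    validate_expression(matrix)
    with open(path, "wt", encoding="utf-8") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        matrix.to_csv(fh, sep="\t", index_label="gene_id")


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata TSV with columns sample_id, group, sex, race, smoking, age."""
    raw = pd.read_csv(_strip_comments(path), sep="\t", dtype=str).fillna("")
    if "sample_id" not in raw.columns:
        raise ValueError("metadata must have a sample_id column")
    missing = [c for c in METADATA_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"metadata missing column(s): {missing}")
    raw = raw.set_index("sample_id")
    return normalize_metadata(raw)


def normalize_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Apply the unknown-value conventions and check metadata invariants."""
    dup = meta.index[meta.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample ID(s): {sorted(set(dup))}")
    out = pd.DataFrame(index=meta.index.astype(str))
    clean = lambda s: s.astype(str).str.strip().str.lower()
    out["group"] = meta["group"].astype(str).str.strip().replace("", "unknown")
    out["sex"] = clean(meta["sex"]).where(clean(meta["sex"]).isin(_SEX_LEVELS), "unknown")
    out["race"] = clean(meta["race"]).replace({"": "unknown", "nan": "unknown"})
    out["smoking"] = clean(meta["smoking"]).where(
        clean(meta["smoking"]).isin(_SMOKING_LEVELS), "unknown"
    )
    out["age"] = pd.to_numeric(meta["age"], errors="coerce")
    if (out["age"].dropna() < 0).any():
        bad = out.index[out["age"] < 0][0]
        raise ValueError(f"negative age for sample {bad!r}")
    return out


def write_metadata(meta: pd.DataFrame, path, comment: str | None = None) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        out = meta.copy()
        out["age"] = out["age"].map(lambda a: "" if pd.isna(a) else f"{a:g}")
        out.to_csv(fh, sep="\t", index_label="sample_id")


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name, description, then member genes, tab-separated."""
    sets: dict[str, set[str]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line {lineno}: fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r} at line {lineno}")
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise ValueError(f"empty gene set {name!r} at line {lineno}")
            sets[name] = genes
    return sets


def write_gmt(sets: Mapping[str, set[str]], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for name in sets:
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tna\t{genes}\n")


def chromosome_of(cytoband: str) -> str:
    """Leading chromosome token of a cytoband string, e.g. ``"Yq11.221" -> "Y"``.

    Parsing stops at the arm designator (p/q); the token must be 1-22, X or Y.
    """
    if not cytoband:
        raise ValueError("empty cytoband")
    token = ""
    for ch in cytoband:
        if ch in ("p", "q"):
            break
        token += ch
    token = token.strip()
    if token not in _CHROMOSOMES:
        raise ValueError(f"unparseable cytoband {cytoband!r}")
    return token


def read_cytobands(path) -> dict[str, str]:
    """Two-column TSV (gene_id, cytoband) -> dict; cytobands validated on load."""
    out: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"malformed cytoband line {lineno}")
            gene, band = fields
            if gene in out:
                raise ValueError(f"duplicate gene {gene!r} at line {lineno}")
            chromosome_of(band)  # validates
            out[gene] = band
    return out


def write_cytobands(annot: Mapping[str, str], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for gene in annot:
            fh.write(f"{gene}\t{annot[gene]}\n")


def read_probe_annotation(path) -> dict[str, set[str]]:
    """TSV of (probe_id, gene_id) rows; repeated probe rows accumulate genes."""
    out: dict[str, set[str]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            probe, gene = line.split("\t")[:2]
            out.setdefault(probe, set())
            if gene:
                out[probe].add(gene)
    return out


def probe_collapse(
    probe_matrix: pd.DataFrame, annotation: Mapping[str, set[str]]
) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene level.

    Probes mapping to zero or multiple genes are discarded; when several
    surviving probes hit the same gene the gene's value is the per-sample
    arithmetic mean of those probes. Output genes are sorted lexicographically,
    the canonical tie-free gene order used downstream.
    """
    validate_expression(probe_matrix)
    gene_for_probe = {}
    for probe in probe_matrix.index:
        genes = annotation.get(probe, set())
        if len(genes) == 1:
            gene_for_probe[probe] = next(iter(genes))
    if not gene_for_probe:
        raise ValueError("no probe maps uniquely to a gene; empty output")
    kept = probe_matrix.loc[list(gene_for_probe)]
    collapsed = kept.groupby(pd.Series(gene_for_probe), sort=True).mean()
    collapsed.index.name = probe_matrix.index.name
    return collapsed
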