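"""Readers and writers for the package's file dialects.

Tables travel as delimited text (tab by default, comma accepted; anything
else must be stated explicitly — silent delimiter guessing corrupts gene
ids), gene sets as GMT, ground truth and configs as JSON.  All writers sort
deterministically so that re-runs are byte-identical and diffs meaningful.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genesets import GeneSet, TermAnnotation
from .vg import VGTable, column_label, normalize_gene_id

__all__ = [
    "DEFAULT_DE_COLUMNS",
    "file_sha256",
    "read_de_table",
    "read_feature_matrix",
    "read_gene_list",
    "read_gmt_gene_sets",
    "read_gmt_terms",
    "read_tissue_weights",
    "read_vg_table",
    "write_de_table",
    "write_feature_matrix",
    "write_gmt",
    "write_recalibrated_table",
    "write_tissue_weights",
    "write_vg_table",
]

logger = logging.getLogger(__name__)

#: DESeq2-style default column names for DE result tables.
DEFAULT_DE_COLUMNS = {
    "log_fc": "log2FoldChange",
    "p": "pvalue",
    "p_adj": "padj",
}

_NA_VALUES = ["", "NA", "NaN", "nan"]


def _detect_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        if sep not in ("\t", ","):
            raise ValidationError(f"unsupported delimiter {sep!r}; use tab or comma")
        return sep
    header = path.open().readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise ValidationError(
        f"{path}: cannot detect delimiter (neither tab nor comma in header)"
    )


def file_sha256(path: str | Path) -> str:
    """Hex digest of a file's contents (for provenance logging)."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ----------------------------------------------------------------- DE tables
def read_de_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    gene_column: str | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a DE results table into the internal normal form.

    ``column_map`` maps internal names (``log_fc``, ``p``, ``p_adj``,
    optionally ``base_expr``) to file column names; DESeq2 defaults apply
    when omitted.  Gene ids are taken from ``gene_column`` or the first
    column, version suffixes stripped; ``NA`` adjusted p-values survive as
    missing.
    """
    path = Path(path)
    sep = _detect_sep(path, sep)
    column_map = dict(column_map) if column_map is not None else dict(DEFAULT_DE_COLUMNS)
    df = pd.read_csv(path, sep=sep, na_values=_NA_VALUES, keep_default_na=False,
                     float_precision="round_trip")
    if gene_column is None:
        gene_column = df.columns[0]
    if gene_column not in df.columns:
        raise ValidationError(f"{path}: gene id column {gene_column!r} not found")
    missing = [v for v in column_map.values() if v not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    if "base_expr" not in column_map and "baseMean" in df.columns:
        column_map["base_expr"] = "baseMean"  # optional mean-expression column
    out = pd.DataFrame(index=pd.Index(df[gene_column].map(normalize_gene_id),
                                      name="gene_id"))
    for internal, external in column_map.items():
        out[internal] = pd.to_numeric(df[external].to_numpy(), errors="coerce")
    if out.index.has_duplicates:
        dupes = out.index[out.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate gene ids {dupes[:10]}")
    return out


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    """Write a DE table in the DESeq2-style dialect (round-trips through
    :func:`read_de_table` with the default mapping)."""
    inv = {v: k for k, v in DEFAULT_DE_COLUMNS.items()}
    cols = {}
    for external, internal in inv.items():
        if internal in de.columns:
            cols[external] = de[internal]
    if "base_expr" in de.columns:
        cols["baseMean"] = de["base_expr"]
    out = pd.DataFrame(cols, index=de.index).sort_index()
    out.to_csv(Path(path), sep="\t", na_rep="NA", index_label="gene_id")


def write_recalibrated_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a recalibrated table: original columns plus ``fc_star``,
    ``vg_used`` and both rank columns, sorted by recalibrated rank then
    gene id."""
    out = table.copy()
    if "rank_recal" in out.columns:
        # rank first (unranked genes last), gene id breaks ties
        sort_key = out["rank_recal"].astype("float64").fillna(np.inf).to_numpy()
        order = np.lexsort((out.index.to_numpy(), sort_key))
        out = out.iloc[order]
    out.to_csv(Path(path), sep="\t", na_rep="NA", index_label="gene_id")


def read_recalibrated_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read back a table written by :func:`write_recalibrated_table`."""
    path = Path(path)
    sep = _detect_sep(path, sep)
    df = pd.read_csv(path, sep=sep, na_values=_NA_VALUES, keep_default_na=False,
                     index_col=0, float_precision="round_trip")
    for col in ("rank_nominal", "rank_recal"):
        if col in df.columns:
            df[col] = df[col].astype("Int64")
    return df


# ---------------------------------------------------------------- V^G tables
def read_vg_table(
    path: str | Path,
    weights: Mapping[str, float] | None = None,
    sep: str | None = None,
) -> VGTable:
    """Read a V^G table: first column gene id, remaining columns named
    ``<source>`` (cross-tissue mean) or ``<source>:<tissue>``; empty or
    ``NA`` cells are missing.  Zero or negative variances are rejected."""
    path = Path(path)
    sep = _detect_sep(path, sep)
    df = pd.read_csv(path, sep=sep, na_values=_NA_VALUES, keep_default_na=False,
                     index_col=0, float_precision="round_trip")
    return VGTable(df, weights=weights)


def write_vg_table(table: VGTable, path: str | Path) -> None:
    flat = table.data.copy()
    flat.columns = [column_label(s, t) for s, t in flat.columns]
    flat = flat.sort_index()[sorted(flat.columns)]
    flat.to_csv(Path(path), sep="\t", na_rep="NA", index_label="gene_id")


def read_tissue_weights(path: str | Path, sep: str | None = None) -> dict[str, float]:
    """Two-column (tissue, TPM) file -> tissue weight map."""
    path = Path(path)
    sep = _detect_sep(path, sep)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected two columns (tissue, TPM)")
    weights = {}
    for _, row in df.iterrows():
        w = float(row.iloc[1])
        if not np.isfinite(w) or w < 0:
            raise ValidationError(f"{path}: weight for {row.iloc[0]!r} must be >= 0")
        weights[str(row.iloc[0])] = w
    return weights


def write_tissue_weights(weights: Mapping[str, float], path: str | Path) -> None:
    df = pd.DataFrame(
        {"tissue": sorted(weights), "TPM": [weights[t] for t in sorted(weights)]}
    )
    df.to_csv(Path(path), sep="\t", index=False)


# ----------------------------------------------------------------- gene sets
def _parse_gmt(path: Path) -> list[tuple[str, str, list[str]]]:
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not any(f.strip() for f in fields[2:]):
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and >= 1 gene"
                )
            genes = [f.strip() for f in fields[2:] if f.strip()]
            rows.append((fields[0], fields[1], genes))
    if not rows:
        logger.warning("%s: empty GMT file", path)
    return rows


def read_gmt_gene_sets(path: str | Path) -> list[GeneSet]:
    """GMT -> list of :class:`GeneSet` (description field ignored)."""
    return [GeneSet(name, frozenset(genes)) for name, _, genes in _parse_gmt(Path(path))]


def read_gmt_terms(path: str | Path, namespace: str = "default") -> list[TermAnnotation]:
    """GMT -> list of :class:`TermAnnotation`; first field is the term id,
    description field the human-readable name."""
    return [
        TermAnnotation(term_id=tid, name=name or tid, genes=frozenset(genes),
                       namespace=namespace)
        for tid, name, genes in _parse_gmt(Path(path))
    ]


def write_gmt(items: Iterable[GeneSet | TermAnnotation], path: str | Path) -> None:
    lines = []
    for item in items:
        if isinstance(item, TermAnnotation):
            head = [item.term_id, item.name]
        else:
            head = [item.name, ""]
        lines.append("\t".join(head + sorted(item.genes)))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """One-gene-per-line text file -> :class:`GeneSet`."""
    path = Path(path)
    genes = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    return GeneSet(name or path.stem, frozenset(genes))


# ------------------------------------------------------------ feature tables
def read_feature_matrix(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Gene x metric TSV with ``NA`` for missing cells."""
    path = Path(path)
    sep = _detect_sep(path, sep)
    df = pd.read_csv(path, sep=sep, na_values=_NA_VALUES, keep_default_na=False,
                     index_col=0, float_precision="round_trip")
    df.index = pd.Index([normalize_gene_id(g) for g in df.index], name="gene_id")
    return df.astype(float)


def write_feature_matrix(features: pd.DataFrame, path: str | Path) -> None:
    features.sort_index().to_csv(Path(path), sep="\t", na_rep="NA",
                                 index_label="gene_id")


def write_resolved_config(config: Mapping, path: str | Path) -> None:
    """Persist the fully resolved parameters of a run next to its outputs."""
    Path(path).write_text(json.dumps(dict(config), indent=1, sort_keys=True, default=str))
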