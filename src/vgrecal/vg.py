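"""Per-gene dosage-variance (V^G) tables and their algebra.

V^G is the variance, in squared log-fold-change units, of genetically
regulated expression of a gene across individuals in a population.  It is
estimated per tissue (from allelic expression, ``AE``, or from eQTL effect
sizes, ``eQTL``), extended by a supervised model (``ML``), and merged
(``AEML`` = AE with ML fallback).  A cross-tissue summary, stored under the
pseudo-tissue ``MEAN``, is the TPM-weighted harmonic mean of the per-tissue
estimates.

Missing values are explicit (NaN); a V^G of zero is invalid, never a stand-in
for "missing" — downstream recalibration divides by sqrt(V^G).
"""

from __future__ import annotations

import math
import re
from collections.abc import Mapping


import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "MEAN_TISSUE",
    "SOURCES",
    "VGTable",
    "aggregate_tissue_vg",
    "convert_log_base",
    "merge_vg",
    "normalize_gene_id",
]

#: Pseudo-tissue label for the cross-tissue weighted harmonic mean.
MEAN_TISSUE = "MEAN"

#: Recognised derivations of V^G.
SOURCES = ("AE", "eQTL", "ML", "AEML")

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def normalize_gene_id(gene_id: str) -> str:
    """Strip an Ensembl version suffix (``ENSG00000171189.13`` -> ``ENSG00000171189``).

    Tables produced against different Ensembl releases carry different version
    suffixes; joins are done on the unversioned identifier.
    """
    gene_id = str(gene_id).strip()
    if not gene_id:
        raise ValidationError("empty gene identifier")
    return _VERSION_SUFFIX.sub("", gene_id)


def _check_positive_variance(value: float, context: str = "V^G") -> None:
    if not math.isfinite(value) or value <= 0:
        raise ValidationError(
            f"{context} must be finite and > 0, got {value!r}; "
            "missing values must be encoded as NaN, not 0"
        )


def aggregate_tissue_vg(
    tissue_vg: Mapping[str, float],
    weights: Mapping[str, float],
) -> float:
    """Weighted harmonic mean of per-tissue V^G estimates.

    Uses mean expression per tissue (TPM) as weight:

        mean V^G = (sum_t w_t) / (sum_t w_t / v_t)

    over the tissues for which both a V^G value and a strictly positive
    weight exist (weights are effectively re-normalised over that subset).

    Parameters
    ----------
    tissue_vg
        Tissue label -> V^G.  NaN entries are treated as missing.
    weights
        Tissue label -> TPM weight (non-negative).  Every tissue supplying a
        V^G value must have a weight defined.

    Returns
    -------
    float
        The aggregated variance, or NaN when no tissue has both a value and
        a positive weight.  The result always lies within
        ``[min v_t, max v_t]`` of the tissues used.
    """
    num = 0.0
    den = 0.0
    used = 0
    for tissue, v in tissue_vg.items():
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        _check_positive_variance(float(v), f"V^G for tissue {tissue!r}")
        if tissue not in weights:
            raise ValidationError(f"no weight defined for tissue {tissue!r}")
        w = float(weights[tissue])
        if not math.isfinite(w) or w < 0:
            raise ValidationError(f"weight for tissue {tissue!r} must be >= 0, got {w!r}")
        if w == 0:
            continue
        num += w
        den += w / float(v)
        used += 1
    if used == 0:
        return float("nan")
    return num / den


def merge_vg(ae: float | None, ml: float | None) -> float:
    """Merge two V^G estimates with the first taking precedence.

    Builds ``AEML``: the allelic-expression estimate where it exists, the
    model-derived one otherwise.  Missing (None/NaN) propagates only when
    both sides are missing.
    """

    def _present(x: float | None) -> bool:
        return x is not None and not (isinstance(x, float) and math.isnan(x))

    if _present(ae):
        _check_positive_variance(float(ae))
        return float(ae)
    if _present(ml):
        _check_positive_variance(float(ml))
        return float(ml)
    return float("nan")


def convert_log_base(vg: float, base_from: float, base_to: float) -> float:
    """Convert a variance of log-expression between log bases.

    A variance of log_b1 values becomes a variance of log_b2 values by the
    square of the change-of-base factor: ``vg * (ln b1 / ln b2) ** 2``.
    """
    for b in (base_from, base_to):
        if not math.isfinite(b) or b <= 0 or b == 1:
            raise ValidationError(f"log base must be positive and != 1, got {b!r}")
    _check_positive_variance(vg)
    return vg * (math.log(base_from) / math.log(base_to)) ** 2


class VGTable:
    """Per-gene V^G estimates, keyed by (source, tissue).

    Thin wrapper over a :class:`pandas.DataFrame` whose index is the
    (version-stripped) Ensembl gene id and whose columns are a 2-level
    MultiIndex ``(source, tissue)``; the cross-tissue mean lives under the
    pseudo-tissue :data:`MEAN_TISSUE`.  NaN encodes missing; zeros are
    rejected.

    Parameters
    ----------
    data
        Frame with MultiIndex ``(source, tissue)`` columns, or flat columns
        named ``<source>`` (meaning the cross-tissue mean) or
        ``<source>:<tissue>``.
    weights
        Optional tissue -> TPM map used by :meth:`compute_mean`.
    """

    def __init__(self, data: pd.DataFrame, weights: Mapping[str, float] | None = None):
        if not isinstance(data.columns, pd.MultiIndex):
            data = data.copy()
            data.columns = pd.MultiIndex.from_tuples(
                [_split_column(c) for c in data.columns], names=["source", "tissue"]
            )
        else:
            data = data.copy()
            data.columns = data.columns.set_names(["source", "tissue"])
        index = pd.Index([normalize_gene_id(g) for g in data.index], name="gene_id")
        if index.has_duplicates:
            dupes = index[index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids after version stripping: {dupes[:5]}")
        data.index = index
        values = data.to_numpy(dtype=float)
        bad = np.isfinite(values) & (values <= 0)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-positive V^G for gene {data.index[r]!r}, column {data.columns[c]}"
            )
        self._data = data.astype(float)
        self.weights = dict(weights) if weights is not None else None

    # ------------------------------------------------------------------ views
    @property
    def data(self) -> pd.DataFrame:
        """The underlying (gene x (source, tissue)) frame."""
        return self._data

    @property
    def genes(self) -> pd.Index:
        return self._data.index

    def sources(self) -> list[str]:
        return sorted(self._data.columns.get_level_values("source").unique())

    def tissues(self, source: str) -> list[str]:
        """Tissue labels (excluding MEAN) available for a source."""
        if source not in self._data.columns.get_level_values("source"):
            raise KeyError(f"unknown V^G source {source!r}")
        ts = self._data[source].columns.tolist()
        return sorted(t for t in ts if t != MEAN_TISSUE)

    def get(self, source: str, tissue: str = MEAN_TISSUE) -> pd.Series:
        """Series of V^G values (NaN = missing) for one (source, tissue) column."""
        key = (source, tissue)
        if key not in self._data.columns:
            raise KeyError(f"V^G column {source}:{tissue} not present")
        return self._data[key]

    def __len__(self) -> int:
        return len(self._data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VGTable):
            return NotImplemented
        a = self._data.sort_index().sort_index(axis=1)
        b = other._data.sort_index().sort_index(axis=1)
        return a.equals(b) and (self.weights or {}) == (other.weights or {})

    # ------------------------------------------------------------- operations
    def compute_mean(
        self, source: str, weights: Mapping[str, float] | None = None
    ) -> "VGTable":
        """Add/replace the ``(source, MEAN)`` column as the TPM-weighted
        harmonic mean of that source's tissue columns.

        Returns a new table; genes with no usable tissue get NaN.
        """
        weights = weights if weights is not None else self.weights
        if weights is None:
            raise ValidationError("tissue weights required to compute the mean V^G")
        tissues = self.tissues(source)
        missing_w = [t for t in tissues if t not in weights]
        if missing_w:
            raise ValidationError(f"no weight defined for tissues {missing_w[:5]}")
        sub = self._data[source][tissues]
        w = np.array([float(weights[t]) for t in tissues])
        if (w < 0).any() or not np.isfinite(w).all():
            raise ValidationError("tissue weights must be finite and >= 0")
        vals = sub.to_numpy(dtype=float)
        usable = np.isfinite(vals) & (w[None, :] > 0)
        num = np.where(usable, w[None, :], 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            den = np.where(usable, w[None, :] / vals, 0.0).sum(axis=1)
            mean = np.where(den > 0, num / den, np.nan)
        out = self._data.copy()
        out[(source, MEAN_TISSUE)] = mean
        return VGTable(out, weights=dict(weights))

    def merge_sources(
        self, primary: str = "AE", fallback: str = "ML", out: str = "AEML"
    ) -> "VGTable":
        """Element-wise merge of two sources, primary taking precedence.

        Applied to every tissue column (and MEAN) present in either source;
        the result is stored under ``out``.
        """
        cols_p = set(self._data[primary].columns) if primary in self.sources() else set()
        cols_f = set(self._data[fallback].columns) if fallback in self.sources() else set()
        if not cols_p and not cols_f:
            raise ValidationError(f"neither {primary!r} nor {fallback!r} present")
        result = self._data.copy()
        for tissue in sorted(cols_p | cols_f):
            p = (
                self._data[(primary, tissue)]
                if (primary, tissue) in self._data.columns
                else pd.Series(np.nan, index=self._data.index)
            )
            f = (
                self._data[(fallback, tissue)]
                if (fallback, tissue) in self._data.columns
                else pd.Series(np.nan, index=self._data.index)
            )
            result[(out, tissue)] = p.where(p.notna(), f)
        return VGTable(result, weights=self.weights)

    def convert_base(self, base_from: float, base_to: float) -> "VGTable":
        """Rescale every stored variance between log bases (see
        :func:`convert_log_base`)."""
        factor = convert_log_base(1.0, base_from, base_to)
        return VGTable(self._data * factor, weights=self.weights)


def _split_column(name: str) -> tuple[str, str]:
    name = str(name)
    if ":" in name:
        source, tissue = name.split(":", 1)
        return source, tissue
    return name, MEAN_TISSUE


def column_label(source: str, tissue: str) -> str:
    """Flat-file column name for a (source, tissue) pair."""
    return source if tissue == MEAN_TISSUE else f"{source}:{tissue}"


def build_vg_table(
    frames: Mapping[tuple[str, str], Mapping[str, float] | pd.Series],
    weights: Mapping[str, float] | None = None,
) -> VGTable:
    """Assemble a :class:`VGTable` from per-(source, tissue) gene->value maps."""
    cols = {k: pd.Series(v, dtype=float) for k, v in frames.items()}
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["source", "tissue"])
    return VGTable(df, weights=weights)
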