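"""Fold-change recalibration: standardize DE log fold changes by sqrt(V^G).

A differential-expression log fold change measures how far a gene's
expression moved in an experiment; V^G measures how far it moves between
people for genetic reasons alone.  The recalibrated fold change

    FC* = FC / sqrt(V^G)

expresses the experimental change in units of population standard deviations
of genetically regulated expression, so dosage-constrained genes (small V^G)
rise in the ranking and genes that habitually swing (large V^G) fall.

:class:`FoldChangeRecalibrator` is a scikit-learn style transformer: ``fit``
takes the V^G table, ``transform`` takes a DESeq2-like results frame and
returns it augmented with ``fc_star`` and the nominal/recalibrated ranks.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import EmptyResultError, ValidationError
from .vg import MEAN_TISSUE, VGTable, normalize_gene_id

__all__ = [
    "FoldChangeRecalibrator",
    "abs_pearson",
    "rank_by_abs",
    "recalibrate_fc",
    "recalibrate_table",
    "spearman_with_bootstrap_ci",
]


def recalibrate_fc(log_fc: float, vg: float) -> float:
    """Recalibrate a single signed log fold change by a V^G variance.

    Returns ``log_fc / sqrt(vg)``; the sign of the change is preserved.
    """
    if not math.isfinite(log_fc):
        raise ValidationError(f"log fold change must be finite, got {log_fc!r}")
    if not math.isfinite(vg) or vg <= 0:
        raise ValidationError(f"V^G must be finite and > 0, got {vg!r}")
    return log_fc / math.sqrt(vg)


def rank_by_abs(values: pd.Series) -> pd.Series:
    """1-based ranks by descending absolute value.

    Ties are broken lexicographically by gene id so that output files are
    reproducible.
    """
    idx = values.index
    abs_vals = values.abs().to_numpy()
    # lexsort: last key is primary -> sort by -|v|, then gene id ascending
    order = np.lexsort((idx.to_numpy(), -abs_vals))
    ranks = np.empty(len(idx), dtype=np.int64)
    ranks[order] = np.arange(1, len(idx) + 1)
    return pd.Series(ranks, index=idx)


class FoldChangeRecalibrator(BaseEstimator, TransformerMixin):
    """Transformer recalibrating DE fold changes by population dosage variance.

    Parameters
    ----------
    source : {"AE", "eQTL", "ML", "AEML"}, default="AEML"
        Which V^G derivation to use.
    tissue : str, default="MEAN"
        Tissue column, or ``"MEAN"`` for the cross-tissue harmonic mean.
    sig_threshold : float or None, default=None
        When given, only genes with ``p_adj`` strictly below the threshold
        receive ranks; other genes are retained but unranked.
    missing_policy : {"drop", "keep_unscaled_flagged"}, default="drop"
        Genes without a usable V^G are either excluded from the output
        (mirroring the restriction of downstream analysis to genes with a
        V^G estimate) or kept with ``fc_star`` missing and ``vg_missing``
        set.

    Attributes
    ----------
    vg_ : pandas.Series
        The gene -> V^G column selected at fit time (NaN = missing).
    """

    def __init__(
        self,
        source: str = "AEML",
        tissue: str = MEAN_TISSUE,
        sig_threshold: float | None = None,
        missing_policy: str = "drop",
    ):
        self.source = source
        self.tissue = tissue
        self.sig_threshold = sig_threshold
        self.missing_policy = missing_policy

    def fit(self, X: VGTable, y=None) -> "FoldChangeRecalibrator":
        """Select the (source, tissue) V^G column from a :class:`VGTable`."""
        if self.missing_policy not in ("drop", "keep_unscaled_flagged"):
            raise ValidationError(f"unknown missing_policy {self.missing_policy!r}")
        if not isinstance(X, VGTable):
            raise ValidationError("fit expects a VGTable")
        try:
            self.vg_ = X.get(self.source, self.tissue)
        except KeyError as exc:
            raise ValidationError(str(exc)) from exc
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Recalibrate a DE results frame.

        ``X`` must be indexed by gene id with columns ``log_fc`` and,
        when a significance threshold is set, ``p_adj``.  Returns a copy
        with ``fc_star``, ``vg_used``, ``rank_nominal`` and ``rank_recal``
        added; ranks are nullable integers (unranked = <NA>).
        """
        if not hasattr(self, "vg_"):
            raise ValidationError("recalibrator is not fitted")
        de = _validate_de_table(X)
        vg = self.vg_.reindex(de.index)
        if self.missing_policy == "drop":
            de = de.loc[vg.notna()]
            vg = vg.loc[de.index]
        if len(de) == 0:
            raise EmptyResultError(
                "no genes retained: none of the DE genes has a usable V^G"
            )
        out = de.copy()
        out["vg_used"] = vg
        with np.errstate(invalid="ignore"):
            out["fc_star"] = out["log_fc"] / np.sqrt(out["vg_used"])

        if self.sig_threshold is not None:
            if "p_adj" not in out.columns:
                raise ValidationError("sig_threshold set but table has no p_adj column")
            rankable = out.index[(out["p_adj"] < self.sig_threshold).fillna(False)]
        else:
            rankable = out.index
        out["rank_nominal"] = pd.Series(dtype="Int64", index=out.index)
        out["rank_recal"] = pd.Series(dtype="Int64", index=out.index)
        if len(rankable) > 0:
            out.loc[rankable, "rank_nominal"] = rank_by_abs(out.loc[rankable, "log_fc"])
            scaled = out.loc[rankable, "fc_star"].dropna()
            out.loc[scaled.index, "rank_recal"] = rank_by_abs(scaled)
        if self.missing_policy == "keep_unscaled_flagged":
            out["vg_missing"] = out["vg_used"].isna()
        return out


def recalibrate_table(
    de: pd.DataFrame,
    vg: VGTable,
    source: str = "AEML",
    tissue: str = MEAN_TISSUE,
    sig_threshold: float | None = None,
    missing_policy: str = "drop",
) -> pd.DataFrame:
    """Functional wrapper around :class:`FoldChangeRecalibrator`."""
    rec = FoldChangeRecalibrator(
        source=source,
        tissue=tissue,
        sig_threshold=sig_threshold,
        missing_policy=missing_policy,
    )
    return rec.fit(vg).transform(de)


def abs_pearson(nominal, recal) -> float:
    """Pearson correlation between the absolute nominal and recalibrated FCs.

    The standard agreement summary between the two rankings' underlying
    magnitudes.  Returns NaN when either magnitude vector is constant
    (correlation undefined).
    """
    x = np.abs(np.asarray(nominal, dtype=float))
    y = np.abs(np.asarray(recal, dtype=float))
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("inputs must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValidationError("need at least 3 pairs for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


class SpearmanCI(NamedTuple):
    rho: float
    ci_low: float
    ci_high: float


def spearman_with_bootstrap_ci(
    x,
    y,
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> SpearmanCI:
    """Spearman correlation with a percentile bootstrap confidence interval.

    Resamples gene pairs with replacement ``n_boot`` times; the interval is
    the ``(1-level)/2`` and ``1-(1-level)/2`` quantiles of the resampled
    correlations.  Returns NaN throughout when a vector is all-tied.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("inputs must be equal-length 1-D vectors")
    n = len(x)
    if n < 10:
        raise ValidationError("need at least 10 pairs for a bootstrap CI")
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanCI(float("nan"), float("nan"), float("nan"))
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            boots[b] = np.nan
            continue
        boots[b] = stats.spearmanr(xb, yb).statistic
    alpha = 1.0 - level
    lo, hi = np.nanpercentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return SpearmanCI(rho, float(lo), float(hi))


def _validate_de_table(de: pd.DataFrame) -> pd.DataFrame:
    if "log_fc" not in de.columns:
        raise ValidationError("DE table must have a 'log_fc' column")
    if len(de) == 0:
        raise ValidationError("DE table is empty")
    idx = pd.Index([normalize_gene_id(g) for g in de.index], name="gene_id")
    if idx.has_duplicates:
        dupes = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids in DE table: {dupes[:5]}")
    de = de.copy()
    de.index = idx
    if not np.isfinite(de["log_fc"].to_numpy(dtype=float)).all():
        raise ValidationError("log_fc must be finite for every gene")
    for col in ("p", "p_adj"):
        if col in de.columns:
            vals = de[col].to_numpy(dtype=float)
            ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
            if not ok.all():
                raise ValidationError(f"{col} values must lie in [0, 1]")
    return de
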