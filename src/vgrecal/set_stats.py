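"""Gene-set level statistics.

Two families of questions:

* do two curated gene sets (say, dosage-sensitive disease genes vs.
  nonessential genes) differ in some per-gene quantity — V^G, nominal |FC|,
  recalibrated |FC|?  Answered with a two-sided Mann-Whitney U test.
* is a gene set's tissue of lowest V^G concentrated in a tissue group
  (e.g. known autism genes in brain tissues)?  Answered with a one-sided
  binomial test against the background assignment rate.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .genesets import GeneSet
from .vg import VGTable, normalize_gene_id

__all__ = [
    "SetComparisonResult",
    "TissueEnrichmentResult",
    "binomial_tail",
    "compare_gene_sets",
    "group_lowest_tissue_enrichment",
    "lowest_vg_tissue",
    "lowest_vg_tissue_table",
    "mann_whitney_two_sided",
]

#: Exact enumeration is used when the pooled sample is at most this large
#: (covers every pair of samples of size <= 8 each).
EXACT_MAX_TOTAL = 16


class SetComparisonResult(NamedTuple):
    set_a: str
    set_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    p: float


def _mw_u_statistic(ranks: np.ndarray, a_idx: np.ndarray, n_a: int) -> float:
    # U_A from the rank-sum of group A (midranks handle ties)
    return float(ranks[a_idx].sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney_two_sided(a: Iterable[float], b: Iterable[float]) -> float:
    """Two-sided Mann-Whitney U p-value.

    For small samples (pooled size <= 16, i.e. at most 8 per side in the
    balanced case) the p-value is computed by exhaustive enumeration of all
    C(n_a+n_b, n_a) assignments of the pooled values to the two groups,
    which stays exact in the presence of ties; larger samples use the
    normal approximation with tie and continuity correction.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both samples must be non-empty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("samples must be finite")
    n_a, n_b = len(a), len(b)
    if n_a + n_b <= EXACT_MAX_TOTAL:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        u_obs = _mw_u_statistic(ranks, np.arange(n_a), n_a)
        n = n_a + n_b
        count_le = 0
        count_ge = 0
        total = 0
        for comb in combinations(range(n), n_a):
            u = _mw_u_statistic(ranks, np.array(comb), n_a)
            # tolerance guards float rank sums
            if u <= u_obs + 1e-9:
                count_le += 1
            if u >= u_obs - 1e-9:
                count_ge += 1
            total += 1
        p = 2.0 * min(count_le, count_ge) / total
        return min(1.0, p)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def compare_gene_sets(
    values: Mapping[str, float] | pd.Series,
    set_a: GeneSet,
    set_b: GeneSet,
) -> SetComparisonResult:
    """Compare a per-gene quantity between two gene sets.

    Genes present in both sets are removed from both before testing; genes
    without a (finite) value are dropped.  Returns the two-sided
    Mann-Whitney p-value together with per-set medians and counts.
    """
    values = pd.Series(values, dtype=float)
    values.index = [normalize_gene_id(g) for g in values.index]
    shared = set_a.genes & set_b.genes
    genes_a = sorted(set_a.genes - shared)
    genes_b = sorted(set_b.genes - shared)
    va = values.reindex(genes_a).dropna()
    vb = values.reindex(genes_b).dropna()
    if len(va) == 0 or len(vb) == 0:
        raise ValidationError(
            f"no values available for set {set_a.name if len(va) == 0 else set_b.name!r}"
        )
    p = mann_whitney_two_sided(va.to_numpy(), vb.to_numpy())
    return SetComparisonResult(
        set_a=set_a.name,
        set_b=set_b.name,
        n_a=len(va),
        n_b=len(vb),
        median_a=float(va.median()),
        median_b=float(vb.median()),
        p=p,
    )


def lowest_vg_tissue_table(vg: VGTable, source: str = "AEML") -> pd.Series:
    """Per-gene tissue with the smallest V^G under the given source.

    Only tissues with a value for the gene are considered; genes with no
    per-tissue value at all get NaN.  Ties are broken by taking the
    lexicographically first tissue label.
    """
    tissues = vg.tissues(source)
    if not tissues:
        raise ValidationError(f"source {source!r} has no per-tissue columns")
    sub = vg.data[source][sorted(tissues)]
    arr = sub.to_numpy(dtype=float)
    any_value = np.isfinite(arr).any(axis=1)
    # nanargmin takes the first minimum -> lexicographic tie-break via sorted columns
    idx = np.full(len(sub), -1)
    if any_value.any():
        idx[any_value] = np.nanargmin(arr[any_value], axis=1)
    labels = np.array(sorted(tissues), dtype=object)
    out = pd.Series(
        [labels[i] if i >= 0 else np.nan for i in idx], index=sub.index, dtype=object
    )
    out.name = "lowest_vg_tissue"
    return out


def lowest_vg_tissue(gene: str, vg: VGTable, source: str = "AEML") -> str | None:
    """Tissue of lowest V^G for one gene, or None when no tissue has a value."""
    gene = normalize_gene_id(gene)
    table = lowest_vg_tissue_table(vg, source=source)
    if gene not in table.index:
        return None
    val = table.loc[gene]
    return None if pd.isna(val) else str(val)


def binomial_tail(k: int, n: int, p0: float) -> float:
    """One-sided (greater) binomial tail P[X >= k], X ~ Binomial(n, p0)."""
    if not (0 <= k <= n):
        raise ValidationError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 <= p0 <= 1.0):
        raise ValidationError(f"p0 must lie in [0, 1], got {p0!r}")
    return float(stats.binomtest(k, n, p0, alternative="greater").pvalue)


class TissueEnrichmentResult(NamedTuple):
    k: int
    n: int
    p0: float
    p_binomial: float


def group_lowest_tissue_enrichment(
    genes_of_interest: GeneSet,
    background: GeneSet,
    vg: VGTable,
    tissue_group: set[str],
    source: str = "AEML",
) -> TissueEnrichmentResult:
    """One-sided binomial enrichment of lowest-V^G tissues in a tissue group.

    ``k`` of the ``n`` interest genes with any tissue assignment fall into
    ``tissue_group``; the null rate ``p0`` is the corresponding fraction
    among assigned background genes (interest genes are subtracted from the
    background first).  Returns P[X >= k] for X ~ Binomial(n, p0).
    """
    if not tissue_group:
        raise ValidationError("tissue_group must be non-empty")
    assignments = lowest_vg_tissue_table(vg, source=source)
    bg = background.subtract(genes_of_interest)
    interest = assignments.reindex(sorted(genes_of_interest.genes)).dropna()
    bg_assign = assignments.reindex(sorted(bg.genes)).dropna()
    if len(interest) == 0 or len(bg_assign) == 0:
        raise ValidationError("no tissue assignments in interest or background set")
    n = int(len(interest))
    k = int(interest.isin(tissue_group).sum())
    p0 = float(bg_assign.isin(tissue_group).mean())
    if p0 == 0.0 and k > 0:
        raise ValidationError("background never falls in tissue_group but interest does")
    if p0 == 1.0 and k < n:
        raise ValidationError("background always falls in tissue_group but interest does not")
    return TissueEnrichmentResult(k=k, n=n, p0=p0, p_binomial=binomial_tail(k, n, p0))
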