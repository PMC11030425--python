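"""Over-representation analysis and before/after enrichment comparison.

The recalibration changes which genes occupy the top of the DE ranking, and
the question is what that does to functional enrichment: terms describing
*response* to a stimulus (populated by reactive, high-V^G genes) should fade,
terms describing *regulation* (populated by dosage-constrained, low-V^G
genes) should rise.

The machinery is deliberately plain: select the top-N genes under either
ranking, run an upper-tail hypergeometric test per term against the
V^G-restricted background, BH-adjust within each annotation namespace, take
the union of terms significant in either run (imputing the missing side to
p = 1), and summarise name-matched groups of terms by their geometric mean
p-value.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EmptyResultError, ValidationError
from .genesets import GeneSet, TermAnnotation

__all__ = [
    "adjust_bh",
    "association_logmean",
    "compare_enrichment",
    "ora",
    "round_to_nearest_100",
    "run_ora",
    "select_top_genes",
]

RESULT_COLUMNS = ["term_id", "name", "namespace", "k", "K", "n", "N", "p", "p_adj"]


def round_to_nearest_100(x: float) -> int:
    """Round to the nearest multiple of 100, half-way cases up."""
    return int(math.floor(x / 100.0 + 0.5)) * 100


def select_top_genes(
    table: pd.DataFrame,
    by: str = "nominal",
    n: int | str = "auto",
) -> GeneSet:
    """Select the top-N genes of a recalibrated table under one ranking.

    ``by`` is ``"nominal"`` (rank by |log FC|) or ``"recalibrated"`` (rank
    by |FC*|).  ``n="auto"`` takes half of the ranked (significant) genes,
    rounded to the nearest 100 — the default selection depth for enrichment
    comparisons.
    """
    col = {"nominal": "rank_nominal", "recalibrated": "rank_recal"}.get(by)
    if col is None:
        raise ValidationError(f"by must be 'nominal' or 'recalibrated', got {by!r}")
    if col not in table.columns:
        raise ValidationError(f"table has no {col!r} column; recalibrate first")
    ranks = table[col].dropna()
    n_ranked = len(ranks)
    if n == "auto":
        n = round_to_nearest_100(0.5 * n_ranked)
        n = max(n, min(100, n_ranked))  # tiny inputs: never select zero genes
    n = int(n)
    if n < 1 or n > n_ranked:
        raise ValidationError(f"cannot select top {n} of {n_ranked} ranked genes")
    chosen = ranks[ranks <= n].index
    return GeneSet(f"top{n}_{by}", frozenset(chosen))


def ora(
    term: TermAnnotation,
    query: GeneSet,
    background: GeneSet,
) -> dict:
    """Upper-tail hypergeometric over-representation test for one term.

    With ``N`` background genes of which ``K`` carry the term, and a query
    of ``n`` genes overlapping the term in ``k``, the p-value is
    ``P[X >= k]`` for ``X ~ Hypergeometric(N, K, n)``.  Term genes outside
    the background are ignored; the query must be a subset of the
    background.
    """
    if len(background) == 0 or len(query) == 0:
        raise ValidationError("query and background must be non-empty")
    if not query.genes <= background.genes:
        extra = sorted(query.genes - background.genes)
        raise ValidationError(f"query genes missing from background: {extra[:5]}")
    term_bg = term.genes & background.genes
    N = len(background)
    K = len(term_bg)
    n = len(query)
    k = len(term_bg & query.genes)
    p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K > 0 else 1.0
    return {
        "term_id": term.term_id,
        "name": term.name,
        "namespace": term.namespace,
        "k": k,
        "K": K,
        "n": n,
        "N": N,
        "p": min(p, 1.0),
        "p_adj": np.nan,
    }


def adjust_bh(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_ora(
    terms: Iterable[TermAnnotation],
    query: GeneSet,
    background: GeneSet,
) -> pd.DataFrame:
    """ORA over a collection of terms, BH-adjusted within each namespace.

    Annotation resources (e.g. the GO BP/CC/MF sub-ontologies) are kept as
    separate multiple-testing families.
    """
    rows = [ora(t, query, background) for t in terms]
    if not rows:
        raise EmptyResultError("no terms supplied")
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if df["term_id"].duplicated().any():
        raise ValidationError("duplicate term ids in annotation")
    for _, idx in df.groupby("namespace").groups.items():
        df.loc[idx, "p_adj"] = adjust_bh(df.loc[idx, "p"])
    return df.sort_values(["namespace", "p", "term_id"]).reset_index(drop=True)


def compare_enrichment(
    run_nominal: pd.DataFrame,
    run_recal: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Union of terms enriched in either run, with the missing side set to 1.

    Both runs must have been computed against the same background (checked
    via ``N``).  A term enters the comparison when its adjusted p-value is
    at or below ``alpha`` in at least one run; a term not enriched in one
    run gets an imputed p of exactly 1 on that side.  Terms are classified
    as ``more_enriched_after`` when the recalibrated p is smaller,
    ``more_enriched_before`` when larger, ``unchanged`` otherwise.
    """
    for run in (run_nominal, run_recal):
        missing = [c for c in ("term_id", "name", "p_adj", "N") if c not in run.columns]
        if missing:
            raise ValidationError(f"enrichment run lacks columns {missing}")
    if len(run_nominal) and len(run_recal):
        if set(run_nominal["N"].unique()) != set(run_recal["N"].unique()):
            raise ValidationError(
                "enrichment runs were computed against different backgrounds"
            )
    sig_n = run_nominal[run_nominal["p_adj"] <= alpha]
    sig_r = run_recal[run_recal["p_adj"] <= alpha]
    keep = sorted(set(sig_n["term_id"]) | set(sig_r["term_id"]))
    if not keep:
        return pd.DataFrame(
            columns=["term_id", "name", "p_nominal", "p_recal", "classification"]
        )
    names = (
        pd.concat([run_nominal[["term_id", "name"]], run_recal[["term_id", "name"]]])
        .drop_duplicates("term_id")
        .set_index("term_id")["name"]
    )
    p_nom = run_nominal.set_index("term_id")["p_adj"].reindex(keep)
    p_rec = run_recal.set_index("term_id")["p_adj"].reindex(keep)
    # terms absent or non-enriched on one side are imputed to exactly 1
    p_nom = p_nom.where(p_nom <= alpha, 1.0).fillna(1.0)
    p_rec = p_rec.where(p_rec <= alpha, 1.0).fillna(1.0)
    out = pd.DataFrame(
        {
            "term_id": keep,
            "name": names.reindex(keep).to_numpy(),
            "p_nominal": p_nom.to_numpy(),
            "p_recal": p_rec.to_numpy(),
        }
    )
    out["classification"] = np.select(
        [out["p_recal"] < out["p_nominal"], out["p_recal"] > out["p_nominal"]],
        ["more_enriched_after", "more_enriched_before"],
        default="unchanged",
    )
    return out.reset_index(drop=True)


def association_logmean(
    comparison: pd.DataFrame, pattern: str
) -> tuple[list[str], float, float]:
    """Geometric-mean p-value of name-matched terms, per ranking.

    ``pattern`` is a case-insensitive substring matched against term names
    (e.g. ``"response"`` or ``"regulation"``).  The log-mean is
    ``10 ** mean(log10 p)`` over the matched terms, computed separately for
    the nominal and recalibrated columns.
    """
    if comparison.empty:
        raise EmptyResultError("comparison is empty")
    mask = comparison["name"].str.contains(pattern, case=False, regex=False)
    matched = comparison[mask]
    if matched.empty:
        raise EmptyResultError(f"no term name matches {pattern!r}")
    lm_nom = float(10 ** np.log10(matched["p_nominal"].to_numpy()).mean())
    lm_rec = float(10 ** np.log10(matched["p_recal"].to_numpy()).mean())
    return matched["term_id"].tolist(), lm_nom, lm_rec
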