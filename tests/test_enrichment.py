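"""Over-representation analysis and nominal-vs-recalibrated comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vgrecal import (
    EmptyResultError,
    GeneSet,
    TermAnnotation,
    ValidationError,
    adjust_bh,
    association_logmean,
    compare_enrichment,
    ora,
    run_ora,
    select_top_genes,
)
from vgrecal.enrichment import round_to_nearest_100


def make_ranked_table(n_sig: int, n_total: int | None = None) -> pd.DataFrame:
    n_total = n_total or n_sig
    genes = [f"G{i:05d}" for i in range(n_total)]
    df = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    df["log_fc"] = np.linspace(5, 0.1, n_total)
    df["fc_star"] = df["log_fc"][::-1].to_numpy()
    df["rank_nominal"] = pd.array(
        [i + 1 if i < n_sig else pd.NA for i in range(n_total)], dtype="Int64"
    )
    df["rank_recal"] = pd.array(
        [n_sig - i if i < n_sig else pd.NA for i in range(n_total)], dtype="Int64"
    )
    return df


class TestSelectTopGenes:
    def test_auto_takes_half_rounded_to_100(self):
        table = make_ranked_table(4000)
        assert len(select_top_genes(table, "nominal", "auto")) == 2000

    def test_explicit_n(self):
        table = make_ranked_table(746, 1000)
        top = select_top_genes(table, "recalibrated", 300)
        assert len(top) == 300

    def test_full_selection(self):
        table = make_ranked_table(50)
        assert len(select_top_genes(table, "nominal", 50)) == 50

    def test_n_beyond_ranked_rejected(self):
        table = make_ranked_table(50)
        with pytest.raises(ValidationError):
            select_top_genes(table, "nominal", 51)

    def test_rankings_select_different_ends(self):
        table = make_ranked_table(100)
        top_nom = select_top_genes(table, "nominal", 10)
        top_rec = select_top_genes(table, "recalibrated", 10)
        assert top_nom.genes.isdisjoint(top_rec.genes)

    def test_round_half_up(self):
        assert round_to_nearest_100(150) == 200
        assert round_to_nearest_100(149.9) == 100
        assert round_to_nearest_100(2000) == 2000


class TestORA:
    def test_query_equal_background_gives_p_one(self):
        genes = frozenset(f"G{i}" for i in range(30))
        bg = GeneSet("bg", genes)
        q = GeneSet("q", genes)
        for size in (3, 10, 30):
            term = TermAnnotation("T:1", "t", frozenset(list(genes)[:size]))
            assert ora(term, q, bg)["p"] == pytest.approx(1.0)

    def test_closed_form_full_overlap(self):
        bg = GeneSet("bg", frozenset(f"G{i}" for i in range(20)))
        term = TermAnnotation("T:1", "t", frozenset(f"G{i}" for i in range(5)))
        q = GeneSet("q", frozenset(f"G{i}" for i in range(5)))
        res = ora(term, q, bg)
        assert res["p"] == pytest.approx(1 / math.comb(20, 5), rel=1e-12)
        assert (res["k"], res["K"], res["n"], res["N"]) == (5, 5, 5, 20)

    def test_pmf_summation_value(self):
        bg = GeneSet("bg", frozenset(f"G{i}" for i in range(100)))
        term = TermAnnotation("T:1", "t", frozenset(f"G{i}" for i in range(10)))
        q = GeneSet("q", frozenset([f"G{i}" for i in range(3)]
                                   + [f"G{i}" for i in range(50, 57)]))
        expected = sum(
            math.comb(10, j) * math.comb(90, 10 - j) / math.comb(100, 10)
            for j in range(3, 11)
        )
        assert ora(term, q, bg)["p"] == pytest.approx(expected, rel=1e-10)
        assert expected == pytest.approx(0.06002, abs=1e-4)

    def test_query_outside_background_rejected(self):
        bg = GeneSet("bg", frozenset({"G1", "G2"}))
        q = GeneSet("q", frozenset({"G1", "G9"}))
        term = TermAnnotation("T:1", "t", frozenset({"G1"}))
        with pytest.raises(ValidationError):
            ora(term, q, bg)

    def test_matches_fisher_exact_oracle(self, rng):
        for _ in range(120):
            N = int(rng.integers(10, 201))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            genes = [f"G{i}" for i in range(N)]
            bg = GeneSet("bg", frozenset(genes))
            term = TermAnnotation("T:1", "t", frozenset(genes[:K]))
            q = GeneSet("q", frozenset(rng.choice(genes, size=n, replace=False)))
            p = ora(term, q, bg)["p"]
            k = len(term.genes & q.genes)
            table = [[k, K - k], [n - k, N - K - (n - k)]]
            p_fisher = stats.fisher_exact(table, alternative="greater")[1]
            assert p == pytest.approx(p_fisher, rel=1e-9, abs=1e-12)


class TestAdjustBH:
    @pytest.mark.parametrize(
        "pvals, expected",
        [
            ([0.04], [0.04]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([1.0, 1.0], [1.0, 1.0]),
        ],
    )
    def test_hand_values(self, pvals, expected):
        assert adjust_bh(pvals) == pytest.approx(expected)

    def test_matches_step_up_reference(self, rng):
        def reference_bh(p):
            p = np.asarray(p, dtype=float)
            m = len(p)
            order = np.argsort(p, kind="stable")
            adj = np.empty(m)
            running = 1.0
            for rank_from_top, idx in enumerate(order[::-1]):
                i = m - rank_from_top  # 1-based rank in ascending order
                running = min(running, p[idx] * m / i)
                adj[idx] = running
            return np.minimum(adj, 1.0)

        for size in (1, 2, 17, 1000, 10_000):
            p = rng.uniform(size=size)
            assert np.max(np.abs(adjust_bh(p) - reference_bh(p))) < 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_bh([0.5, 1.5])


class TestCompareEnrichment:
    def run_frame(self, rows):
        return pd.DataFrame(
            rows, columns=["term_id", "name", "namespace", "k", "K", "n", "N", "p",
                           "p_adj"]
        )

    def test_one_sided_significance_imputes_other_side(self):
        nom = self.run_frame(
            [("T:1", "response to x", "BP", 5, 10, 20, 100, 0.5, 0.9)]
        )
        rec = self.run_frame(
            [("T:1", "response to x", "BP", 9, 10, 20, 100, 1e-6, 1e-5)]
        )
        comp = compare_enrichment(nom, rec, alpha=0.05)
        assert len(comp) == 1
        row = comp.iloc[0]
        assert row["p_nominal"] == 1.0  # imputed exactly
        assert row["p_recal"] == pytest.approx(1e-5)
        assert row["classification"] == "more_enriched_after"

    def test_identical_runs_unchanged(self):
        run = self.run_frame([("T:1", "t", "BP", 5, 10, 20, 100, 1e-4, 1e-3)])
        comp = compare_enrichment(run, run.copy())
        assert comp.iloc[0]["classification"] == "unchanged"

    def test_no_significant_terms_gives_empty(self):
        run = self.run_frame([("T:1", "t", "BP", 1, 10, 20, 100, 0.9, 0.9)])
        assert compare_enrichment(run, run.copy()).empty

    def test_background_mismatch_rejected(self):
        nom = self.run_frame([("T:1", "t", "BP", 5, 10, 20, 100, 1e-4, 1e-3)])
        rec = self.run_frame([("T:1", "t", "BP", 5, 10, 20, 250, 1e-4, 1e-3)])
        with pytest.raises(ValidationError):
            compare_enrichment(nom, rec)

    def test_every_term_has_both_columns(self):
        nom = self.run_frame([("T:1", "a", "BP", 5, 10, 20, 100, 1e-4, 1e-3)])
        rec = self.run_frame([("T:2", "b", "BP", 6, 10, 20, 100, 1e-5, 1e-4)])
        comp = compare_enrichment(nom, rec)
        assert set(comp["term_id"]) == {"T:1", "T:2"}
        assert comp[["p_nominal", "p_recal"]].notna().all().all()


class TestAssociationLogmean:
    def comparison(self):
        return pd.DataFrame(
            {
                "term_id": ["T:1", "T:2", "T:3"],
                "name": ["response to a", "response to b", "regulation of c"],
                "p_nominal": [0.01, 0.0001, 1.0],
                "p_recal": [1.0, 1.0, 1.0],
                "classification": ["x", "x", "x"],
            }
        )

    def test_geometric_mean(self):
        terms, lm_nom, lm_rec = association_logmean(self.comparison(), "response")
        assert terms == ["T:1", "T:2"]
        assert lm_nom == pytest.approx(1e-3)
        assert lm_rec == pytest.approx(1.0)

    def test_single_match(self):
        _, lm_nom, _ = association_logmean(self.comparison(), "regulation")
        assert lm_nom == pytest.approx(1.0)

    def test_no_match_rejected(self):
        with pytest.raises(EmptyResultError):
            association_logmean(self.comparison(), "zzz")


class TestPlantedStructure:
    def test_response_and_regulation_terms_flip(self, default_fixture):
        """On the planted fixture the response-like term dominates nominal
        selection and the regulation-like term recalibrated selection."""
        from vgrecal import recalibrate_table

        fx = default_fixture
        table = recalibrate_table(fx["de"], fx["vg"], source="AE",
                                  sig_threshold=1e-3)
        bg = GeneSet("bg", frozenset(table.index))
        top_nom = select_top_genes(table, "nominal", "auto")
        top_rec = select_top_genes(table, "recalibrated", "auto")
        run_nom = run_ora(fx["terms"], top_nom, bg)
        run_rec = run_ora(fx["terms"], top_rec, bg)
        p_nom = run_nom.set_index("term_id")["p_adj"]
        p_rec = run_rec.set_index("term_id")["p_adj"]
        response, regulation = "SYN:0000001", "SYN:0000002"
        assert p_nom[response] <= 0.05
        assert p_rec[regulation] <= 0.05
        assert p_nom[response] < p_rec[response]
        assert p_rec[regulation] < p_nom[regulation]
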