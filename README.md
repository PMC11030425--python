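# vgrecal

Recalibrate differential-expression fold changes by population genetic
dosage variance (V^G).

## The problem

A differential-expression study ranks genes by log fold change and
significance, but neither says whether a change is *meaningful for that
gene*. Genes differ by orders of magnitude in how much their expression
varies between people for genetic reasons alone: a 1.5-fold shift is
business as usual for a gene with loose dosage control and drastic for a
tightly constrained one. Rankings by nominal fold change therefore fill up
with reactive, high-variance "responder" genes and bury the dosage-
sensitive "driver" genes that analyses of disease mechanism usually want.

`vgrecal` standardizes each gene's DE log fold change by the standard
deviation of its genetically regulated expression:

    FC*_i = FC_i / sqrt(V^G_i)

where V^G_i is the per-gene variance of genetic dosage variation in the
population (in squared log-fold-change units, estimated upstream from
allelic expression or eQTLs, per tissue or as a TPM-weighted harmonic mean
across tissues). FC* expresses the experimental change in population
standard deviations; re-ranking by |FC*| promotes constrained genes.

The package is aimed at people doing downstream interpretation of bulk or
single-cell DE results (DESeq2-style tables) who have per-gene V^G
estimates and want to re-rank, compare gene sets, and see how functional
enrichment shifts. It provides:

* the V^G algebra: TPM-weighted harmonic-mean tissue aggregation, source
  merging with AE precedence (`AEML`), log-base conversion;
* the recalibration transformer and agreement metrics (absolute-value
  Pearson, Spearman with bootstrap CI);
* gene-set statistics: Mann-Whitney set comparisons (exact by enumeration
  at small n), lowest-V^G-tissue assignment and one-sided binomial
  enrichment in a tissue group;
* native over-representation analysis (upper-tail hypergeometric, BH
  within annotation namespace) and the nominal-vs-recalibrated top-N
  enrichment comparison with p = 1 imputation;
* a gradient-boosted model (XGBoost) predicting ln V^G from 14 gene
  metrics with KNN feature imputation, to extend coverage to genes
  without direct estimates;
* a synthetic-data generator with planted driver/responder structure and
  full ground truth, so everything is testable offline;
* a CLI (`vgrecal`) tying the stages together.

## Worked example

Simulate the default study (5,000 genes, 10 tissues, planted driver and
responder blocks), recalibrate, and compare enrichment under the two
rankings:

```python
from vgrecal import (SimulationConfig, simulate_vg_table, simulate_de_experiment,
                     recalibrate_table, abs_pearson, select_top_genes, run_ora,
                     compare_enrichment, GeneSet)

config = SimulationConfig(seed=1)
vg, truth = simulate_vg_table(config)
de, gene_sets, terms = simulate_de_experiment(vg, truth, config)

table = recalibrate_table(de, vg, source="AE", sig_threshold=1e-3)
print(f"genes with V^G: {len(table)} of {config.n_genes}")
print(f"abs-Pearson(|FC|, |FC*|): {abs_pearson(table['log_fc'], table['fc_star']):.3f}")

drivers = table.index.intersection(sorted(gene_sets['driver'].genes))
print(f"driver median rank: nominal {table.loc[drivers,'rank_nominal'].median():.0f}"
      f" -> recalibrated {table.loc[drivers,'rank_recal'].median():.1f}")

background = GeneSet("background", frozenset(table.index))
top_nom = select_top_genes(table, "nominal", "auto")
top_rec = select_top_genes(table, "recalibrated", "auto")
comp = compare_enrichment(run_ora(terms, top_nom, background),
                          run_ora(terms, top_rec, background))
print(comp[["term_id", "name", "p_nominal", "p_recal"]].to_string(index=False))
```

Output:

```
genes with V^G: 4776 of 5000
abs-Pearson(|FC|, |FC*|): 0.806
driver median rank: nominal 704 -> recalibrated 100.5
    term_id                            name     p_nominal       p_recal
SYN:0000001  response to simulated stimulus 1.129763e-166  6.580582e-12
SYN:0000002 regulation of simulated process  1.471044e-03 1.129763e-166
```

Reading it: 4,776 of 5,000 genes have a usable V^G and are retained. The
nominal and recalibrated magnitudes stay strongly correlated (abs-Pearson
0.81) — recalibration reshuffles the top of the list, it does not scramble
it. The planted low-V^G driver genes jump from a median rank of 704 to
100.5, and the enrichment comparison flips: the "response" term is
overwhelmingly enriched among the top genes by nominal fold change
(p ≈ 1e-166 vs 7e-12 after), while the "regulation" term only reaches
p ≈ 1e-166 after recalibration.

The same pipeline from the shell:

```
vgrecal simulate --preset driver-responder --seed 1 --outdir fx/
vgrecal recalibrate --de fx/de.tsv --vg fx/vg.tsv --source AE \
        --sig 0.001 --out recal.tsv
vgrecal enrich-compare --table recal.tsv --terms fx/terms.gmt --out comparison.tsv
```

Other subcommands: `aggregate-vg` (tissue table -> weighted harmonic
mean), `compare-sets` (Mann-Whitney between gene sets), `train-vg` /
`predict-vg` (the ML extension).

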