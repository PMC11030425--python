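"""Synthetic fixtures with known ground truth.

Everything downstream of the recalibration statistic is testable without any
external download through this module.  It emulates the moving parts of a
real study:

* a per-tissue V^G table: lognormal gene-level variances with tissue-level
  random effects, per-(gene, tissue) missingness, a fraction of genes with
  no allelic-expression estimate at all, and a cross-tissue mean computed by
  the package's own TPM-weighted harmonic aggregation;
* a DE experiment whose fold-change magnitudes are coupled to V^G at a
  configurable Spearman target, with two planted gene blocks — *responders*
  (high V^G, large nominal fold change: genes that react to the stimulus)
  and *drivers* (low V^G, modest nominal fold change but large once
  expressed in population standard deviations) — plus matching
  "response-like" and "regulation-like" annotation terms, so that top-N
  enrichment flips between the nominal and recalibrated rankings;
* a gene x 14-metric feature matrix whose label is a known monotone
  function of three features plus noise, for exercising imputation and the
  gradient-boosted V^G model.

All randomness flows from ``SimulationConfig.seed``; identical configs give
byte-identical emitted files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import adjust_bh
from .errors import ValidationError
from .genesets import GeneSet, TermAnnotation
from .vg import MEAN_TISSUE, VGTable

__all__ = [
    "GroundTruth",
    "SimulationConfig",
    "emit_fixture",
    "simulate_de_experiment",
    "simulate_feature_matrix",
    "simulate_vg_table",
]

FEATURE_NAMES = [
    "vg_eqtl_ln",
    "loeuf",
    "pli",
    "phaplo",
    "ptriplo",
    "tpm_ln",
    "tau",
    "n_enhancers",
    "promoter_cpg",
    "gene_length_ln",
    "exon_count",
    "conservation",
    "ppi_degree",
    "expr_breadth",
]

#: Features the synthetic label actually depends on.
SIGNAL_FEATURES = ["vg_eqtl_ln", "loeuf", "tpm_ln"]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the documented conditions.

    V^G is lognormal around 0.01 (squared log2-FC units) with an ln-scale
    spread of 1.0, matching the orders-of-magnitude range of published
    allelic-expression-based estimates.  The fold-change/V^G coupling
    target of 0.148 mirrors the correlation observed between stimulus
    response magnitude and population dosage variance.
    """

    n_genes: int = 5000
    n_tissues: int = 10
    vg_log_mean: float = math.log(0.01)
    vg_log_sd: float = 1.0
    tissue_effect_sd: float = 0.3
    gene_tissue_noise_sd: float = 0.2
    missing_rate: float = 0.1
    frac_no_vg: float = 0.05
    fc_vg_coupling: float = 0.148
    # planted blocks
    n_driver: int = 200
    n_responder: int = 200
    n_decoy_per_term: int = 100
    n_sig_background: int = 600
    responder_lfc_mean: float = 2.0
    responder_lfc_sd: float = 0.25
    driver_fcstar_mean: float = 20.0
    driver_fcstar_sd: float = 2.0
    background_sig_lfc: float = 1.35
    background_sig_lfc_sd: float = 0.1
    null_lfc_scale: float = 0.12
    sig_p_ceiling: float = 1e-8
    # feature matrix
    n_feature_genes: int = 4000
    feature_missing_rate: float = 0.05
    row_blackout_frac: float = 0.01
    feature_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for name in ("missing_rate", "frac_no_vg", "feature_missing_rate",
                     "row_blackout_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v!r}")
        for name in ("n_genes", "n_tissues", "n_feature_genes"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        if self.n_driver + self.n_responder + self.n_sig_background > self.n_genes:
            raise ValidationError("planted blocks exceed n_genes")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named stream of the simulation."""
        return np.random.default_rng([int(self.seed), stream])


@dataclass
class GroundTruth:
    """What the generator actually planted; serialisable to JSON."""

    gene_ids: list[str]
    base_ln_vg: list[float]
    has_ae: list[bool]
    tissues: list[str]
    tissue_effects: list[float]
    membership: dict[str, str] = field(default_factory=dict)
    true_log_fc: dict[str, float] = field(default_factory=dict)
    realized_coupling: float | None = None
    coupling_coefficient: float | None = None
    label_function: str | None = None
    seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _gene_ids(n: int) -> list[str]:
    # synthetic Ensembl-style ids, offset so they never collide with real genes
    return [f"ENSG{900000000 + i:011d}" for i in range(n)]


def simulate_vg_table(config: SimulationConfig) -> tuple[VGTable, GroundTruth]:
    """Draw the per-tissue V^G table and its cross-tissue mean.

    ln V^G of gene *i* in tissue *t* is ``base_i + u_t + eps_it`` with
    ``base_i ~ N(vg_log_mean, vg_log_sd)``, tissue effect
    ``u_t ~ N(0, tissue_effect_sd)`` and residual noise.  Each cell is then
    masked missing with ``missing_rate``; a ``frac_no_vg`` fraction of genes
    has no allelic-expression estimate at all.  The MEAN column is the
    TPM-weighted harmonic mean over observed tissues.
    """
    rng = config.rng(1)
    genes = _gene_ids(config.n_genes)
    tissues = [f"T{t:02d}" for t in range(config.n_tissues)]
    base = rng.normal(config.vg_log_mean, config.vg_log_sd, size=config.n_genes)
    u = rng.normal(0.0, config.tissue_effect_sd, size=config.n_tissues)
    eps = rng.normal(
        0.0, config.gene_tissue_noise_sd, size=(config.n_genes, config.n_tissues)
    )
    ln_v = base[:, None] + u[None, :] + eps
    values = np.exp(ln_v)
    mask = rng.random(size=values.shape) < config.missing_rate
    no_ae = rng.random(config.n_genes) < config.frac_no_vg
    values[mask] = np.nan
    values[no_ae, :] = np.nan
    weights = {
        t: float(w) for t, w in zip(tissues, np.exp(rng.normal(math.log(10.0), 1.0,
                                                               config.n_tissues)))
    }
    frame = pd.DataFrame(values, index=genes, columns=pd.MultiIndex.from_tuples(
        [("AE", t) for t in tissues], names=["source", "tissue"]))
    table = VGTable(frame, weights=weights).compute_mean("AE")
    truth = GroundTruth(
        gene_ids=genes,
        base_ln_vg=[float(x) for x in base],
        has_ae=[bool(x) for x in table.get("AE", MEAN_TISSUE).notna()],
        tissues=tissues,
        tissue_effects=[float(x) for x in u],
        seed=config.seed,
    )
    return table, truth


def _signed(rng: np.random.Generator, magnitudes: np.ndarray) -> np.ndarray:
    return magnitudes * rng.choice([-1.0, 1.0], size=len(magnitudes))


def simulate_de_experiment(
    vg_table: VGTable,
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict[str, GeneSet], list[TermAnnotation]]:
    """Plant a DE experiment on top of a simulated V^G table.

    Gene roles (recorded in ``truth.membership``):

    * ``responder`` — V^G in the top quartile; |log FC| drawn around
      ``responder_lfc_mean``.  Dominates the nominal top-N.
    * ``driver`` — V^G in the bottom quartile; |log FC| drawn as a
      recalibrated target times sqrt(V^G), i.e. modest nominally but
      dominant after standardisation.
    * ``sig_background`` — significant genes whose |log FC| tracks V^G
      (half-power coupling), filling both top lists.
    * ``null`` — no effect: small noise fold changes, uniform p-values.

    Null-gene fold-change magnitudes carry a coupling term ``alpha *
    z(ln V^G)`` whose coefficient is calibrated by bisection so the
    realised Spearman(|log FC|, V^G) over genes with a V^G estimate hits
    ``config.fc_vg_coupling``.  Returns the DE frame, the three gene sets
    (driver/responder/background) and the two planted annotation terms.
    """
    rng = config.rng(2)
    genes = np.array(truth.gene_ids, dtype=object)
    n = len(genes)
    vg_mean = vg_table.get("AE", MEAN_TISSUE).reindex(genes).to_numpy(dtype=float)
    has_vg = np.isfinite(vg_mean)
    if has_vg.sum() < config.n_driver + config.n_responder + config.n_sig_background:
        raise ValidationError("not enough genes with V^G for the planted blocks")
    ln_vg = np.full(n, np.nan)
    ln_vg[has_vg] = np.log(vg_mean[has_vg])

    q25, q75 = np.nanquantile(ln_vg, [0.25, 0.75])
    low_pool = np.flatnonzero(has_vg & (ln_vg <= q25))
    high_pool = np.flatnonzero(has_vg & (ln_vg >= q75))
    if len(low_pool) < config.n_driver or len(high_pool) < config.n_responder:
        raise ValidationError("quartile pools smaller than the planted blocks")
    drivers = np.sort(rng.choice(low_pool, size=config.n_driver, replace=False))
    responders = np.sort(rng.choice(high_pool, size=config.n_responder, replace=False))
    taken = set(drivers) | set(responders)
    rest_pool = np.array([i for i in np.flatnonzero(has_vg) if i not in taken])
    sig_bg = np.sort(rng.choice(rest_pool, size=config.n_sig_background, replace=False))
    taken |= set(sig_bg)
    null_idx = np.array([i for i in range(n) if i not in taken])

    membership = np.full(n, "null", dtype=object)
    membership[drivers] = "driver"
    membership[responders] = "responder"
    membership[sig_bg] = "sig_background"

    abs_fc = np.empty(n)
    # responders: large nominal fold change
    abs_fc[responders] = np.maximum(
        rng.normal(config.responder_lfc_mean, config.responder_lfc_sd,
                   size=len(responders)), 0.0,
    )
    # drivers: target recalibrated magnitude times sqrt(V^G)
    fcstar_target = np.maximum(
        rng.normal(config.driver_fcstar_mean, config.driver_fcstar_sd,
                   size=len(drivers)), 0.0,
    )
    abs_fc[drivers] = fcstar_target * np.sqrt(vg_mean[drivers])
    # significant background: half-power V^G coupling keeps FC* flat
    bg_noise = rng.normal(0.0, config.background_sig_lfc_sd, size=len(sig_bg))
    abs_fc[sig_bg] = config.background_sig_lfc * np.exp(
        0.5 * (ln_vg[sig_bg] - config.vg_log_mean) + bg_noise
    )
    # null genes: coupling coefficient calibrated below
    null_eps = rng.normal(0.0, 0.5, size=len(null_idx))
    z_null = np.zeros(len(null_idx))
    base_ln = np.asarray(truth.base_ln_vg)
    z_null = (base_ln[null_idx] - config.vg_log_mean) / max(config.vg_log_sd, 1e-9)

    with_vg = np.flatnonzero(has_vg)

    def realized(alpha: float) -> float:
        abs_fc[null_idx] = config.null_lfc_scale * np.exp(alpha * z_null + null_eps)
        return float(
            stats.spearmanr(abs_fc[with_vg], vg_mean[with_vg]).statistic
        )

    lo, hi = -3.0, 3.0
    target = config.fc_vg_coupling
    if realized(lo) > target:
        alpha = lo
    elif realized(hi) < target:
        alpha = hi
    else:
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if realized(mid) < target:
                lo = mid
            else:
                hi = mid
        alpha = 0.5 * (lo + hi)
    rho = realized(alpha)  # also fixes abs_fc[null_idx] at the calibrated alpha

    log_fc = _signed(rng, abs_fc)
    p = rng.uniform(0.0, 1.0, size=n)
    sig = membership != "null"
    p[sig] = rng.uniform(0.0, config.sig_p_ceiling, size=int(sig.sum()))
    p_adj = adjust_bh(p)
    base_expr = np.exp(rng.normal(math.log(50.0), 1.2, size=n))

    de = pd.DataFrame(
        {
            "log_fc": log_fc,
            "p": p,
            "p_adj": p_adj,
            "base_expr": base_expr,
        },
        index=pd.Index(genes, name="gene_id"),
    )

    truth.membership = {g: str(m) for g, m in zip(genes, membership)}
    truth.true_log_fc = {g: float(v) for g, v in zip(genes, log_fc)}
    truth.realized_coupling = rho
    truth.coupling_coefficient = float(alpha)

    gene_sets = {
        "driver": GeneSet("driver", frozenset(genes[drivers])),
        "responder": GeneSet("responder", frozenset(genes[responders])),
        "background": GeneSet(
            "background",
            frozenset(genes[i] for i in with_vg if i not in set(drivers) | set(responders)),
        ),
    }

    decoy_rng = config.rng(3)
    sig_bg_list = list(genes[sig_bg])
    null_list = list(genes[null_idx[has_vg[null_idx]]])
    half = config.n_decoy_per_term // 2
    decoys_resp = list(
        decoy_rng.choice(sig_bg_list, size=half, replace=False)
    ) + list(decoy_rng.choice(null_list, size=config.n_decoy_per_term - half,
                              replace=False))
    decoys_drv = list(
        decoy_rng.choice(sig_bg_list, size=half, replace=False)
    ) + list(decoy_rng.choice(null_list, size=config.n_decoy_per_term - half,
                              replace=False))
    terms = [
        TermAnnotation(
            term_id="SYN:0000001",
            name="response to simulated stimulus",
            genes=frozenset(list(genes[responders]) + decoys_resp),
            namespace="SYN",
        ),
        TermAnnotation(
            term_id="SYN:0000002",
            name="regulation of simulated process",
            genes=frozenset(list(genes[drivers]) + decoys_drv),
            namespace="SYN",
        ),
    ]
    return de, gene_sets, terms


def simulate_feature_matrix(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series]:
    """Gene x 14-metric feature matrix with a known label function.

    The label (ln V^G scale) is a monotone function of three features —
    linear in the eQTL-based variance, decreasing in LOEUF, saturating in
    expression level — plus Gaussian noise at ``feature_noise_sd`` times
    the signal SD.  Missing cells are injected at ``feature_missing_rate``;
    an additional ``row_blackout_frac`` of rows receive 6-10 missing
    features to exercise the imputer's drop rule.  Labels are returned for
    every row, missing or not.
    """
    rng = config.rng(4)
    n = config.n_feature_genes
    genes = [f"ENSG{910000000 + i:011d}" for i in range(n)]
    X = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(n, len(FEATURE_NAMES))),
        index=pd.Index(genes, name="gene_id"),
        columns=FEATURE_NAMES,
    )
    # give the metric columns plausible scales/shapes
    X["vg_eqtl_ln"] = config.vg_log_mean + config.vg_log_sd * X["vg_eqtl_ln"]
    X["loeuf"] = np.clip(1.0 + 0.5 * X["loeuf"], 0.0, None)
    X["pli"] = 1.0 / (1.0 + np.exp(-1.5 * X["pli"]))
    X["phaplo"] = 1.0 / (1.0 + np.exp(-1.5 * X["phaplo"]))
    X["ptriplo"] = 1.0 / (1.0 + np.exp(-1.5 * X["ptriplo"]))
    X["tpm_ln"] = math.log(10.0) + 1.5 * X["tpm_ln"]
    X["tau"] = 1.0 / (1.0 + np.exp(-X["tau"]))
    X["n_enhancers"] = np.floor(np.exp(1.0 + 0.8 * X["n_enhancers"]))
    X["gene_length_ln"] = math.log(3e4) + X["gene_length_ln"]
    X["exon_count"] = np.floor(np.clip(np.exp(2.0 + 0.6 * X["exon_count"]), 1, None))
    X["ppi_degree"] = np.floor(np.exp(1.5 + X["ppi_degree"]))
    X["expr_breadth"] = 1.0 / (1.0 + np.exp(-X["expr_breadth"]))

    signal = (
        0.7 * (X["vg_eqtl_ln"] - config.vg_log_mean) / config.vg_log_sd
        - 0.6 * X["loeuf"]
        + 0.4 * np.tanh((X["tpm_ln"] - math.log(10.0)) / 1.5)
    )
    noise_sd = config.feature_noise_sd * float(signal.std(ddof=0))
    labels = config.vg_log_mean + signal + rng.normal(0.0, noise_sd, size=n)
    labels = pd.Series(labels, index=X.index, name="ln_vg")

    holes = rng.random(size=X.shape) < config.feature_missing_rate
    n_blackout = int(round(config.row_blackout_frac * n))
    if n_blackout:
        rows = rng.choice(n, size=n_blackout, replace=False)
        for r in rows:
            k_miss = int(rng.integers(6, 11))
            cols = rng.choice(len(FEATURE_NAMES), size=k_miss, replace=False)
            holes[r, cols] = True
    X = X.mask(holes)
    return X, labels


def emit_fixture(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the full generator and write every fixture file to ``outdir``.

    Emits the V^G table, tissue weights, DE table, gene sets and planted
    terms (GMT), feature matrix and labels (TSV), the ground-truth JSON
    sidecar and the resolved config.  Returns the path of each artifact.
    """
    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vg_table, truth = simulate_vg_table(config)
    de, gene_sets, terms = simulate_de_experiment(vg_table, truth, config)
    features, labels = simulate_feature_matrix(config)
    truth.label_function = (
        "ln_vg = vg_log_mean + 0.7*z(vg_eqtl_ln) - 0.6*loeuf "
        "+ 0.4*tanh((tpm_ln - ln 10)/1.5) + noise"
    )

    paths = {
        "vg": outdir / "vg.tsv",
        "weights": outdir / "tissue_weights.tsv",
        "de": outdir / "de.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "terms": outdir / "terms.gmt",
        "features": outdir / "features.tsv",
        "labels": outdir / "labels.tsv",
        "ground_truth": outdir / "ground_truth.json",
        "config": outdir / "config.json",
    }
    _io.write_vg_table(vg_table, paths["vg"])
    _io.write_tissue_weights(vg_table.weights, paths["weights"])
    _io.write_de_table(de, paths["de"])
    _io.write_gmt(list(gene_sets.values()), paths["gene_sets"])
    _io.write_gmt(terms, paths["terms"])
    _io.write_feature_matrix(features, paths["features"])
    labels.rename("ln_vg").to_frame().to_csv(paths["labels"], sep="\t")
    truth.to_json(paths["ground_truth"])
    paths["config"].write_text(
        json.dumps(dataclasses.asdict(config), indent=1, sort_keys=True)
    )
    return paths
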