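import numpy as np
import pandas as pd
import pytest

from vgrecal import (
    GeneSet,
    SimulationConfig,
    VGTable,
    build_vg_table,
    simulate_de_experiment,
    simulate_vg_table,
)


@pytest.fixture(scope="session")
def default_fixture():
    """The default driver-responder study: V^G table, DE table, sets, terms."""
    config = SimulationConfig(seed=11)
    vg_table, truth = simulate_vg_table(config)
    de, gene_sets, terms = simulate_de_experiment(vg_table, truth, config)
    return {
        "config": config,
        "vg": vg_table,
        "truth": truth,
        "de": de,
        "gene_sets": gene_sets,
        "terms": terms,
    }


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study for fast end-to-end paths."""
    return SimulationConfig(
        n_genes=1500,
        n_tissues=4,
        n_driver=60,
        n_responder=60,
        n_sig_background=180,
        n_decoy_per_term=30,
        n_feature_genes=600,
        seed=5,
    )


@pytest.fixture()
def toy_vg_table():
    """Hand-sized V^G table with two tissues, known mean, and gaps."""
    data = pd.DataFrame(
        {
            "AE:Liver": [0.01, 0.02, np.nan, 0.04],
            "AE:Brain": [0.03, np.nan, np.nan, 0.01],
            "ML": [0.02, 0.02, 0.05, np.nan],
        },
        index=["ENSG01", "ENSG02", "ENSG03", "ENSG04"],
    )
    return VGTable(data, weights={"Liver": 1.0, "Brain": 1.0})


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
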