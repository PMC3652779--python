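"""Shared fixtures: tiny simulated screens and hand-built phenotype tables."""
import numpy as np
import pandas as pd
import pytest

from ionoscreen import ElementPanel, PipelineConfig, SimConfig, simulate_screen
from ionoscreen.normalization import PhenotypeTable


@pytest.fixture(scope="session")
def ko_panel():
    return ElementPanel.knockout()


@pytest.fixture(scope="session")
def small_screen():
    """A 60-gene, 4-replicate simulated screen with 3% spiked effects."""
    cfg = SimConfig(n_genes=60, spike_fraction=0.03, seed=7)
    raw, truth = simulate_screen(cfg)
    return cfg, raw, truth


def make_pheno(replicates: dict, panel: ElementPanel | None = None) -> PhenotypeTable:
    """Build a PhenotypeTable from {gene: {element: [replicate values]}}."""
    elements = sorted({e for d in replicates.values() for e in d})
    panel = panel or ElementPanel(tuple(elements))
    rows = []
    for gene, per_elem in replicates.items():
        for e, vals in per_elem.items():
            for i, v in enumerate(vals, start=1):
                rows.append((gene, e, i, float(v)))
    long = pd.DataFrame(rows, columns=["gene_id", "element", "replicate", "value"])
    grp = long.groupby(["gene_id", "element"])["value"]
    D = grp.mean().unstack().reindex(columns=list(panel.names))
    sigma = grp.std(ddof=1).unstack().reindex(columns=list(panel.names))
    return PhenotypeTable(
        D=D, sigma_tilde=sigma, replicate_values=long, panel=panel
    )


@pytest.fixture
def pheno_factory():
    return make_pheno


@pytest.fixture(scope="session")
def default_pipeline_config():
    return PipelineConfig()


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Simulated degenerate inputs legitimately trigger warnings; keep logs clean."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
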