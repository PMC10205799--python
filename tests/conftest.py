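import logging

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from mamshift.simulate import SimConfig, default_conversion_plan, generate_cohort

logging.getLogger("mamshift").setLevel(logging.ERROR)


def small_sim_config(seed: int = 11, scale: int = 8) -> SimConfig:
    """Down-scaled default cohort (400 cells/stage) for fast unit tests;
    conversion counts scaled with the cohort."""
    plan = [(a, d, t, max(4, n // scale)) for a, d, t, n in default_conversion_plan()]
    return SimConfig(seed=seed, n_cells_per_stage=3200 // scale, conversion_plan=plan)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = small_sim_config()
    adata, truth = generate_cohort(cfg)
    return cfg, adata, truth


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size default cohort (~2000 CM cells/stage), generated once."""
    cfg = SimConfig(seed=101)
    adata, truth = generate_cohort(cfg)
    return cfg, adata, truth


def toy_adata(X, cell_ids=None, gene_ids=None, stage=None, major_type=None,
              subtype=None, stages=None):
    """Assemble an AnnData from a dense cells x genes array and metadata."""
    X = np.asarray(X)
    n, g = X.shape
    cell_ids = cell_ids or [f"c{i:03d}" for i in range(n)]
    gene_ids = gene_ids or [f"g{i:03d}" for i in range(g)]
    obs = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
    if stage is not None:
        cats = stages or list(pd.unique(pd.Series(stage)))
        obs["stage"] = pd.Categorical(stage, categories=cats, ordered=True)
    if major_type is not None:
        obs["major_type"] = major_type
    if subtype is not None:
        obs["subtype"] = subtype
    adata = ad.AnnData(X=X.astype(float), obs=obs,
                       var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")))
    if stages:
        adata.uns["stages"] = list(stages)
    return adata
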