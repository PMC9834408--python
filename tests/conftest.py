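import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import ttstall as t

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_cfg():
    """A fast two-condition, three-replicate design with no effects."""
    return t.SimConfig(
        n_genes=60,
        gene_length_range=(800, 4000),
        depth=30_000,
        seed=123,
        frac_txn_change=0.0,
        frac_stab_change=0.0,
        frac_pause_change=0.0,
    )


@pytest.fixture
def small_world(small_cfg):
    genes = t.generate_genes(small_cfg)
    truth = t.generate_truth(genes, small_cfg)
    samples = t.make_samples(truth, small_cfg)
    return small_cfg, genes, truth, samples


def make_design(conditions, n_reps, assay="TT"):
    rows = {
        f"{assay}_{c}_rep{r}": {"assay": assay, "condition": c, "replicate": r}
        for c in conditions
        for r in range(1, n_reps + 1)
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df


def unit_size_factors(design):
    return pd.Series(1.0, index=design.index, name="size_factor")
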