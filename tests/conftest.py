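"""Shared fixtures: a desk-scale synthetic cohort and its screen design."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from fusionscreen import cohort as cohort_mod
from fusionscreen.io_formats import ExpressionMatrix
from fusionscreen.synthetic_data import SimConfig, generate_cohort

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


SMALL_CONFIG = SimConfig(
    n_genes=400,
    n_tumor_samples=120,
    n_normal_samples=10,
    n_metastasis_samples=1,
    n_cases=7,
    module_sizes=(30,),
    module_rhos=(0.6,),
    seed=11,
)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_design(small_cohort):
    c = small_cohort
    tumor_ids = cohort_mod.filter_tumor_samples(c.metadata)
    cases = cohort_mod.select_cases(
        c.fusion_calls, c.expression, c.config.reference_gene, tumor_ids
    )
    pool = cohort_mod.build_control_pool(
        c.expression, tumor_ids, cases, c.config.reference_gene
    )
    return cohort_mod.draw_resamples(cases, pool, n_resamples=100,
                                     control_size=50, seed=23)


@pytest.fixture(scope="session")
def small_screen(small_cohort, small_design):
    from fusionscreen.correlation_screen import run_screen

    return run_screen(small_cohort.expression, small_design,
                      small_cohort.config.reference_gene)


def make_expression(values: np.ndarray, genes=None, samples=None) -> ExpressionMatrix:
    """Wrap a raw array as an ExpressionMatrix with generated IDs."""
    n_g, n_s = values.shape
    genes = genes or [f"g{i}" for i in range(n_g)]
    samples = samples or [f"s{j}" for j in range(n_s)]
    return ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                     columns=samples)
    )
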