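"""Shared fixtures: small ground-truthed synthetic studies."""

import numpy as np
import pytest

from msntx import (make_atlas, make_truth, simulate_cohort,
                   simulate_expression_bundle, strength_table)
from msntx.expression import ExpressionConfig, build_region_gene_matrix


@pytest.fixture(scope="session")
def atlas():
    return make_atlas(30, 7, seed=1)


@pytest.fixture(scope="session")
def truth(atlas):
    return make_truth(atlas, n_effect_regions=6, n_planted_genes=40,
                      effect_size=3.0, seed=5, smoothness=0.4)


@pytest.fixture(scope="session")
def cohort(atlas, truth):
    subjects, participants = simulate_cohort(atlas, n_per_group=60, truth=truth,
                                             smoothness=0.4)
    return subjects, participants


@pytest.fixture(scope="session")
def strengths(cohort):
    subjects, _ = cohort
    return strength_table(subjects)


@pytest.fixture(scope="session")
def bundle(atlas, truth):
    return simulate_expression_bundle(atlas, n_genes=200, truth=truth,
                                      probes_per_gene=3, n_donors=4,
                                      samples_per_donor=45, n_bad_probes=9,
                                      n_background_probes=20)


@pytest.fixture(scope="session")
def region_gene(bundle, atlas):
    return build_region_gene_matrix(bundle, atlas, ExpressionConfig(ds_threshold=1.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
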