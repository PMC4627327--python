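import numpy as np
import pytest

from pclexome.filtering import CascadeParams, run_cascade
from pclexome.simulate import SimConfig, simulate_cohort


def small_config(seed: int, **overrides) -> SimConfig:
    """A fast cohort: same study structure, desk-scale counts."""
    defaults = dict(
        n_tumors=4,
        n_paired=2,
        n_germline_per_sample=150,
        n_somatic_clonal=40,
        n_somatic_subclonal=8,
        n_somatic_silent=8,
        n_twohit_mutloss_per_sample=2,
        n_homdel_total=1,
        n_cna_per_sample=8,
        n_genes=120,
        n_expr_background=8,
        n_de_genes=10,
        n_group_genes=15,
        n_variable_noise_genes=30,
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config(11))


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort at the default study conditions."""
    return simulate_cohort(SimConfig(seed=5))


def run_all_cascades(cohort, params: CascadeParams | None = None):
    """Cascade every tumor in its natural mode; returns calls per sample."""
    params = params or CascadeParams()
    pooled = [r for recs in cohort.controls.values() for r in recs]
    out = {}
    for m in cohort.tumors:
        if m.matched_control_id:
            ctrl, mode = cohort.variants[m.matched_control_id], "paired"
        else:
            ctrl, mode = pooled, "unpaired"
        out[m.sample_id] = run_cascade(
            cohort.variants[m.sample_id], ctrl, mode, m.purity, params
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
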