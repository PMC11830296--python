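import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A compact planted dataset shared by pipeline-level tests."""
    from covote.annotations import propagate_to_ancestors
    from covote.simulate import SyntheticConfig, generate_sc_dataset

    cfg = SyntheticConfig(
        n_genes=240,
        n_cells=300,
        n_modules=4,
        genes_per_module=25,
        n_housekeeping=20,
        seed=11,
    )
    expr, meta, ann, dag, truth = generate_sc_dataset(cfg)
    ann_prop = propagate_to_ancestors(ann, dag)
    return {
        "cfg": cfg,
        "expr": expr,
        "meta": meta,
        "ann": ann,
        "ann_prop": ann_prop,
        "dag": dag,
        "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
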