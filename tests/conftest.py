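import numpy as np
import pytest

from preydna.data_model import FilterConfig
from preydna.decontamination import run_cascade
from preydna.synthetic_data import SimConfig, simulate_experiment

# small, fast experiment shared by the heavier suites
SMALL_CONFIG = SimConfig(
    n_female=22, n_male=16, n_taxa=40, reads_per_sample=800,
    prevalence_beta=(0.8, 7.2), seed=0,
)


@pytest.fixture(scope="session")
def filter_config():
    return FilterConfig()


@pytest.fixture(scope="session")
def small_experiment(filter_config):
    datasets, tax, meta, truth = simulate_experiment(SMALL_CONFIG)
    pm, report = run_cascade(datasets, tax, meta, filter_config)
    return {"datasets": datasets, "taxonomy": tax, "meta": meta,
            "truth": truth, "presence": pm, "report": report}


@pytest.fixture(scope="session")
def default_experiment(filter_config):
    cfg = SimConfig(seed=42)
    datasets, tax, meta, truth = simulate_experiment(cfg)
    pm, report = run_cascade(datasets, tax, meta, filter_config)
    return {"config": cfg, "datasets": datasets, "taxonomy": tax,
            "meta": meta, "truth": truth, "presence": pm, "report": report}
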