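import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from sexmir.io_formats import CountMatrix, SampleDesign

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_design(libraries_per_cell: int = 3, pool_size: int = 5) -> SampleDesign:
    rows = []
    for sex in ("male", "female"):
        for cond in ("control", "stress"):
            for r in range(libraries_per_cell):
                estrous = (
                    "not_applicable"
                    if sex == "male"
                    else ("estrus" if r % 2 == 0 else "proestrus")
                )
                rows.append(
                    {
                        "sample_id": f"lib_{sex}_{cond}_{r + 1}",
                        "sex": sex,
                        "condition": cond,
                        "estrous": estrous,
                        "pool_size": pool_size,
                    }
                )
    return SampleDesign(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def design12() -> SampleDesign:
    """The study layout: 2 sexes x 2 conditions x 3 pooled libraries."""
    return make_design()


@pytest.fixture(scope="session")
def small_experiment():
    """One scaled-down simulated experiment shared across tests."""
    from sexmir.synthetic_data import SimulationConfig, simulate_experiment

    cfg = SimulationConfig(n_genes=1200, n_mirs=120, seed=11, coupling_prob=0.8)
    return cfg, simulate_experiment(cfg)


def gaussian_logcpm(design: SampleDesign, n_genes: int, sd: float, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(5.0, sd, (n_genes, len(design.sample_ids))),
        index=[f"g{i}" for i in range(n_genes)],
        columns=design.sample_ids,
    )
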