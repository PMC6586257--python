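import math

import pytest

from mrphewas.instruments import load_instruments
from mrphewas.phecodes import load_phecode_map
from mrphewas.simulate import (
    PhecodeScenario,
    ScenarioConfig,
    calibrated_snps,
    generate_cohort,
    noise_sd_for_unit_variance,
    paper_like_scenario,
    synthetic_scenario_map,
)


@pytest.fixture(scope="session")
def instruments():
    return load_instruments()


@pytest.fixture(scope="session")
def snps():
    return calibrated_snps()


@pytest.fixture(scope="session")
def packaged_map():
    return load_phecode_map()


@pytest.fixture(scope="session")
def small_scenario():
    """60-phecode phenome: 10 causal (OR 0.72/SD iron), 4 pleiotropic."""
    return paper_like_scenario(
        n_individuals=20_000, n_phecodes=60, seed=3, n_related_pairs=100
    )


@pytest.fixture(scope="session")
def small_cohort(small_scenario):
    return generate_cohort(small_scenario)


@pytest.fixture(scope="session")
def small_map(small_scenario):
    return synthetic_scenario_map(small_scenario)


def one_phecode_config(
    n: int,
    causal_log_or: float = 0.0,
    prevalence: float = 0.05,
    seed: int = 0,
    direct=None,
    snp_list=None,
):
    snp_list = snp_list or calibrated_snps()
    return ScenarioConfig(
        n_individuals=n,
        snps=snp_list,
        phecode_scenarios=[
            PhecodeScenario(
                "280.1",
                prevalence,
                causal_log_or_per_sd_iron=causal_log_or,
                direct_snp_log_ors=direct or {},
            )
        ],
        biomarker_noise_sd=noise_sd_for_unit_variance(snp_list),
        seed=seed,
    )
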