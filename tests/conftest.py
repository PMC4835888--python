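import pandas as pd
import pytest

from c4cnv import (
    call_integer_cn, demo_config, impute_total_c4, normalize_dosages,
    simulate_cohort, simulate_linked_snps, simulate_peaks,
)
from c4cnv.calling import LOCI


@pytest.fixture(scope="session")
def sim_config():
    """Moderate cohort at the default measurement noise (CV 0.04)."""
    return demo_config(seed=11)


@pytest.fixture(scope="session")
def sim_truth_cohort(sim_config):
    return simulate_cohort(sim_config)


@pytest.fixture(scope="session")
def sim_truth(sim_truth_cohort):
    return sim_truth_cohort[0]


@pytest.fixture(scope="session")
def sim_cohort(sim_truth_cohort):
    return sim_truth_cohort[1]


@pytest.fixture(scope="session")
def sim_peaks(sim_truth, sim_config):
    return simulate_peaks(sim_truth, sim_config)


@pytest.fixture(scope="session")
def sim_dosages(sim_peaks):
    return impute_total_c4(normalize_dosages(sim_peaks))


@pytest.fixture(scope="session")
def sim_calls(sim_dosages):
    return pd.concat(
        [call_integer_cn(sim_dosages, locus) for locus in LOCI],
        ignore_index=True,
    )


@pytest.fixture(scope="session")
def sim_genotypes(sim_truth, sim_config):
    return simulate_linked_snps(sim_truth, sim_config)
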