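import numpy as np
import pandas as pd
import pytest

from rcclnc import preprocess
from rcclnc.synthetic import SimConfig, generate_expression_study

SMALL_CLASSES = {
    "intronic_antisense": 200,
    "lincRNA": 60,
    "protein_coding": 140,
    "negative_control": 40,
}


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        seed=7, n_probes_by_class=dict(SMALL_CLASSES), frac_de=0.1,
        genome_length_bp=20_000_000,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_expression_study(small_config)


def lnc_log_ratios(study):
    """Tumor/nontumor log2 ratios over the lncRNA probes of a study."""
    lnc = study.probes.index[
        study.probes["probe_class"].isin(["intronic_antisense", "lincRNA"])
    ]
    norm = preprocess.quantile_normalize(study.intensities.loc[lnc])
    return preprocess.log2_ratio(norm, study.pairs)


@pytest.fixture(scope="session")
def small_ratios(small_study):
    study, _ = small_study
    return lnc_log_ratios(study)
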