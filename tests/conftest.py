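import numpy as np
import pytest

from polyqmod.simulate import OnsetParams, SimConfig, simulate_cohort, study_config


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Two-disease cohort with a perfect-LD pair plus independent SNPs."""
    return SimConfig(
        n_per_disease={"HD": 300, "SCA3": 200},
        onset_params={
            "HD": OnsetParams(6.119939, -0.052966, 0.2),
            "SCA3": OnsetParams(7.137211, -0.049477, 0.2),
        },
        cag_range={"HD": (37, 92), "SCA3": (50, 82)},
        n_snps=6,
        ld_blocks=[(2, 1.0)] + [(1, 0.0)] * 4,
        maf=np.array([0.3, 0.3, 0.2, 0.4, 0.25, 0.5]),
        effect_sizes=0.0,
        missing_rate=0.03,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def study_cohort():
    """Null cohort at the seven-disease study scale (22-SNP panel)."""
    return simulate_cohort(study_config(seed=7))
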