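import math

import pytest
from hypothesis import HealthCheck, settings

import ednaclock as ec

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def pair_16s():
    """The 16S RNA/DNA marker pair with its reference kinetics."""
    return tuple(
        (t, kp) for t, kp in ec.reference_targets() if t.name == "16S_141"
    )


@pytest.fixture(scope="session")
def noiseless_pair_series(pair_16s):
    """Noise-free 16S pair time courses on the reference sampling grid."""
    cfg = ec.SimConfig(
        targets=pair_16s,
        abundances=(2, 6, 12),
        replicates_per_abundance=1,
        timepoints_h=ec.REFERENCE_TIMEPOINTS_H,
    )
    series, truth = ec.simulate_experiment(cfg)
    return series, truth


@pytest.fixture(scope="session")
def reference_sim():
    """One noisy reference-design experiment with the two compromised
    tanks excluded (13 analyzed tanks)."""
    cfg = ec.reference_config(seed=1)
    series, truth = ec.simulate_experiment(cfg)
    return ec.exclude_tanks(series, ec.REFERENCE_EXCLUDED_TANKS), truth
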