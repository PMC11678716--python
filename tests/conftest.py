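import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from loopblock import (
    AffinityModel,
    GenomicInterval,
    PipelineConfig,
    SimulationConfig,
    generate_bundle,
    run_analysis,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=100_000, max_len=2_000, prefix="iv"):
    """n validated intervals with unique names on a small coordinate range."""
    out = []
    for i in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        chrom = chroms[int(rng.integers(len(chroms)))]
        out.append(
            GenomicInterval(chrom, start, start + length, name=f"{prefix}{i:04d}")
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def dimer_model():
    """2-mer model: consensus 'AT', every mismatch weighted 0.1."""
    w = np.array([[1.0, 0.1, 0.1, 0.1], [0.1, 0.1, 0.1, 1.0]])
    return AffinityModel.from_weights(w, name="dimer")


@pytest.fixture(scope="session")
def tiny_bundle(tmp_path_factory):
    """One tiny synthetic bundle shared across tests (read-only)."""
    out = tmp_path_factory.mktemp("tiny_bundle")
    truth = generate_bundle(SimulationConfig.tiny(seed=7), out)
    return out, truth


@pytest.fixture(scope="session")
def tiny_report(tiny_bundle, tmp_path_factory):
    bundle_dir, truth = tiny_bundle
    out = tmp_path_factory.mktemp("tiny_results")
    report = run_analysis(PipelineConfig.from_bundle(bundle_dir, out, seed=7))
    return out, report, truth
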