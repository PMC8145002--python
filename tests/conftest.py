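import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oncopanel.cnv_caller import Log2RatioProfile
from oncopanel.core_io import CoverageProfile, SampleMeta, TargetRegion

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_targets(n, chrom="chr1", start=1_000_000, size=100, gap=1_000):
    return tuple(
        TargetRegion(chrom, start + i * (size + gap), start + i * (size + gap) + size,
                     name=f"{chrom}_t{i}")
        for i in range(n)
    )


@pytest.fixture
def toy_targets():
    return make_targets(10)


@pytest.fixture
def flat_profile(toy_targets):
    return Log2RatioProfile("s1", toy_targets, np.zeros(len(toy_targets)))


@pytest.fixture
def tumor_meta():
    return SampleMeta(sample_id="s1", tumor_cellularity=0.5, din=3.0)


@pytest.fixture
def coverage_trio(toy_targets):
    """A sample plus two identical flat references at depth 100."""
    depths = np.full(len(toy_targets), 100.0)
    sample = CoverageProfile("s1", toy_targets, depths.copy())
    refs = [CoverageProfile(f"r{i}", toy_targets, depths.copy()) for i in range(2)]
    return sample, refs
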