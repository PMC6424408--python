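import pytest
from hypothesis import HealthCheck, settings

from triovar.pipeline import run_generate
from triovar.simulate import SimulationConfig, build_construct

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def construct():
    """Default ABCA4-like construct (2,268 codons, C7 run at c.4170-4176)."""
    return build_construct(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """A complete synthetic input bundle on disk (seed 7)."""
    outdir = tmp_path_factory.mktemp("bundle")
    manifest = run_generate(SimulationConfig(seed=7), outdir, force=True)
    return outdir, manifest
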