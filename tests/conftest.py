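import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def presets():
    from supdep import paper_scenarios

    return paper_scenarios()


@pytest.fixture(scope="session")
def printed_energy_presets(presets):
    """The single-class presets whose true energies are the study's printed
    replicate-set means."""
    names = [
        "pdz1-apm+par-complex",
        "pdz2+apkc-pbm",
        "pdz1-apm-dpdz2+par-complex",
        "pdz1-apm+par6-dpbm-complex",
        "pdz1-apm+apkc-kd-pbm",
        "pdz1-3+par-complex",
    ]
    return {name: presets[name] for name in names}
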