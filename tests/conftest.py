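import pytest
from hypothesis import HealthCheck, settings

from lohtrack import ArmDefinition, GenomeAnnotation

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """Two small chromosomes with p/q arms and a centromeric gap."""
    arms = []
    for c in (1, 2):
        arms.append(ArmDefinition(c, "p", 1, 50_000, centromere_boundary=50_000))
        arms.append(
            ArmDefinition(c, "q", 60_001, 150_000, centromere_boundary=60_001)
        )
    return GenomeAnnotation(arms=arms)
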