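import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def transcriptome():
    """Default synthetic transcriptome (seed 7), shared across the session."""
    from mlncforge.synth import SynthDesign, generate_transcriptome

    return generate_transcriptome(SynthDesign(seed=7))


@pytest.fixture(scope="session")
def transcripts_by_id(transcriptome):
    return {t.id: t for t in transcriptome.transcripts}
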