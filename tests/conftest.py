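import pytest

import naranjo as na


@pytest.fixture(scope="session")
def params():
    """Cohort parameters calibrated to the published summaries."""
    return na.calibrate()


@pytest.fixture
def scored_factory():
    """Build a list of ScoredRecord from parallel scores and labels."""

    def make(scores, labels, scheme_name="test"):
        return [
            na.ScoredRecord(f"r{i}", scheme_name, {}, int(s), bool(l))
            for i, (s, l) in enumerate(zip(scores, labels))
        ]

    return make
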