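from fractions import Fraction

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def paper_params():
    """The canonical worked-example parameters: x = 0.95, y = 0.87."""
    from matdrive import DriveParams

    return DriveParams(Fraction(95, 100), Fraction(87, 100))


@pytest.fixture
def count_fixture_rows():
    """Reconstructed progeny-class counts for the four germline crosses.

    Counts are round(percentage * n) reconstructions of printed percentages
    and totals; the percentages and n are the measured quantities, the raw
    class counts were not published.
    """
    return {
        "no_components": {"cross_id": "no_components", "GAL4plus": 53,
                          "dGAL4": 360, "QF2plus": 0},          # 87.2%, n=413
        "both_components": {"cross_id": "both_components", "GAL4plus": 3,
                            "dGAL4": 145, "QF2plus": 16},       # 98.2%, n=164
        "cas9_only": {"cross_id": "cas9_only", "GAL4plus": 16,
                      "dGAL4": 184, "QF2plus": 0},              # 92%, n=200
        "grna_only": {"cross_id": "grna_only", "GAL4plus": 6,
                      "dGAL4": 174, "QF2plus": 20},             # 97%, n=200
    }
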