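import numpy as np
import pytest

from offtarget_bias.metrics import UNDEFINED
from offtarget_bias.synthetic_data import default_rule

REFERENCE_TOL = 0.005 + 1e-9  # half a unit in the tables' last printed decimal


def assert_report_matches_reference(report, expected):
    """Compare a MetricReport against a published 2-decimal table row.

    ``None`` cells must be UNDEFINED.  Balanced-accuracy cells are also
    accepted when they match the mean of the already-rounded sensitivity
    and specificity cells (the convention the reference tables use, which
    differs from the direct value by half a cent in one row).
    """
    for stat, ref in expected.items():
        value = getattr(report, stat)
        if ref is None:
            assert value is UNDEFINED, f"{stat}: expected undefined, got {value}"
            continue
        assert value is not UNDEFINED, f"{stat}: unexpectedly undefined"
        if abs(value - ref) <= REFERENCE_TOL:
            continue
        if (
            stat == "balanced_accuracy"
            and report.sensitivity is not UNDEFINED
            and report.specificity is not UNDEFINED
        ):
            chain = (round(report.sensitivity, 2) + round(report.specificity, 2)) / 2
            if abs(chain - ref) <= REFERENCE_TOL:
                continue
        raise AssertionError(f"{stat}: {value} vs reference {ref}")


@pytest.fixture(scope="session")
def rule():
    """Session-wide latent activity rule (potency cache shared across tests)."""
    return default_rule(noise_seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_bits(rng, n, d, density=0.3):
    return (rng.random((n, d)) < density).astype(np.uint8)


@pytest.fixture()
def bit_matrix(rng):
    return random_bits(rng, 40, 64)
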