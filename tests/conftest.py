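import numpy as np
import pytest

from vepfair import evidence, synthetic as sy
from vepfair.variants import VariantRecord


@pytest.fixture(scope="session")
def demo_cohort():
    """Small three-ancestry cohort shared across tests (read-only)."""
    return sy.generate_cohort(sy.demo_spec(seed=42))


@pytest.fixture()
def toy_table():
    """Calibration table with every pathogenic tier and three benign tiers."""
    return evidence.CalibrationTable(
        predictor="toy",
        pathogenic_thresholds=((0.6, 1), (0.7, 2), (0.8, 3), (0.9, 4)),
        benign_thresholds=((0.3, -1), (0.2, -2), (0.1, -3)),
    )


@pytest.fixture()
def labeled_records():
    """Hand-built records spanning the filter edge cases."""
    def rec(vid, gene, afs, label="unlabeled", consequence="missense", scores=None):
        return VariantRecord(
            variant_id=vid, gene=gene, consequence=consequence, label=label,
            af_by_ancestry=afs, scores=scores or {},
        )

    return [
        rec("1-1-A-G", "G1", {"EUR": 0.005, "AFR": 0.015}),          # fails rarity
        rec("1-2-A-G", "G1", {"EUR": 0.009999}),                      # passes (strict <)
        rec("1-3-A-G", "G2", {}),                                     # never observed
        rec("1-4-A-G", "G2", {"EUR": 0.001, "EAS": 0.0002}),          # two memberships
        rec("1-5-A-G", "G3", {"AFR": 0.004}),                         # one membership
        rec("1-6-A-G", "G3", {"EUR": 0.01}),                          # exactly cutoff: out
        rec("1-7-A-G", "G1", {"EUR": 0.0}),                           # AF 0 = unobserved
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
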