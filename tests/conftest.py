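import numpy as np
import pandas as pd
import pytest

from neoresponse.synth import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient cohort with default (planted) effect sizes."""
    return simulate_cohort(SimulationConfig(n_patients=60, seed=42))


@pytest.fixture(scope="session")
def genome_model():
    return SimulationConfig(n_patients=20, seed=0).genome_model


@pytest.fixture
def toy_genome():
    """Single 200-Mb chromosome with the centromere at 100-103 Mb."""
    return pd.DataFrame(
        {
            "chrom": ["1"],
            "length": [200_000_000],
            "centromere_start": [100_000_000],
            "centromere_end": [103_000_000],
        }
    )


def segments(rows, patient="P1", chrom="1"):
    """Helper: build a segment table from (start, end, major, minor) tuples."""
    return pd.DataFrame(
        [(patient, chrom, s, e, ma, mi) for s, e, ma, mi in rows],
        columns=["patient", "chrom", "start", "end", "major_cn", "minor_cn"],
    )
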