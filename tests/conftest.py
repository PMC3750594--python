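import numpy as np
import pandas as pd
import pytest

from tdmr import (
    BetaMatrix,
    PlantedDMR,
    ProbeManifest,
    SampleSheet,
    SimulationConfig,
    simulate_methylation,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest simulated dataset with 20 planted 5-probe regions."""
    cfg = SimulationConfig(
        n_probes=800,
        planted_dmrs=tuple(PlantedDMR() for _ in range(20)),
        snp_fraction=0.0,
        seed=42,
    )
    return simulate_methylation(cfg)


@pytest.fixture()
def toy_matrix():
    """3 probes x 4 samples, two tissues x two individuals, fully observed."""
    manifest = ProbeManifest(
        pd.DataFrame(
            {
                "probe_id": ["p1", "p2", "p3"],
                "chromosome": ["chr1", "chr1", "chr2"],
                "position": [100, 900, 500],
                "strand": ["+", "-", "+"],
            }
        )
    )
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s4"],
                "tissue": ["blood", "blood", "liver", "liver"],
                "individual": ["i1", "i2", "i1", "i2"],
            }
        )
    )
    values = pd.DataFrame(
        np.array([[0.1, 0.2, 0.5, 0.8], [0.9, 0.8, 0.1, 0.2], [0.5, 0.5, 0.5, 0.5]]),
        index=pd.Index(["p1", "p2", "p3"], name="probe_id"),
        columns=["s1", "s2", "s3", "s4"],
    )
    return BetaMatrix(values=values, manifest=manifest, samples=sheet)
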