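import numpy as np
import pytest

from otuherit import SimulationConfig, simulate_twin_otu_table
from otuherit.tables_io import OtuTable, SampleRecord, Zygosity


@pytest.fixture
def tiny_table() -> OtuTable:
    return OtuTable(
        "tiny",
        ["OTU1", "OTU2", "OTU3"],
        ["s1", "s2", "s3", "s4"],
        np.array([[5, 0, 2, 1], [0, 0, 0, 3], [1, 1, 1, 1]]),
    )


def make_records(n_pairs_mz: int = 2, n_pairs_dz: int = 1, rng=None) -> list[SampleRecord]:
    rng = rng or np.random.default_rng(0)
    records = []
    k = 0
    for p in range(n_pairs_mz + n_pairs_dz):
        zyg = Zygosity.MZ if p < n_pairs_mz else Zygosity.DZ
        for _ in range(2):
            records.append(
                SampleRecord(
                    f"s{k + 1}",
                    f"F{p}",
                    zyg,
                    covariates={
                        "gender": "F" if k % 2 else "M",
                        "age": float(30 + p),
                        "sequencing_run": "run1" if k % 3 else "run2",
                    },
                )
            )
            k += 1
    return records


@pytest.fixture
def twin_records() -> list[SampleRecord]:
    return make_records(2, 1)


@pytest.fixture(scope="session")
def small_dataset():
    """Mid-sized synthetic twin dataset shared across tests (seeded)."""
    cfg = SimulationConfig(n_mz=40, n_dz=30, n_otus=12, library_size=5000.0, seed=7)
    return simulate_twin_otu_table(cfg)
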