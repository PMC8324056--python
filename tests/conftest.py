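import warnings

import numpy as np
import pandas as pd
import pytest

from sedadiv.filtering import harmonize
from sedadiv.qc import sample_qc_table
from sedadiv.synthetic import SimulationConfig, generate_dataset

# a scaled-down study: 5 lakes, shorter records, 120-taxon pool; keeps the
# session fixtures fast while preserving the full data structure
SMALL = dict(
    n_lakes=5,
    samples_per_lake=(10, 18),
    pool_size=120,
    n_initial_taxa=10,
    n_ref_taxa=170,
    colonization_rate_curve=(
        (11_700, 7_000, 15.0), (7_000, 5_000, 5.0),
        (5_000, 3_300, 8.0), (3_300, 0, 2.0),
    ),
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, **SMALL)


@pytest.fixture(scope="session")
def dataset(small_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_dataset(small_config)


@pytest.fixture(scope="session")
def stages(dataset):
    return harmonize(dataset["counts"], dataset["refdb"])


@pytest.fixture(scope="session")
def qc_table(dataset, stages):
    return sample_qc_table(dataset["counts"], stages["postfilter"], stages["clean"])


@pytest.fixture(scope="session")
def gated_final(stages, qc_table):
    passed = qc_table[qc_table["passed"]]
    keep = set(map(tuple, passed[["lake_id", "sample_id"]].to_numpy()))
    final = stages["final"]
    mask = [tuple(k) in keep for k in final[["lake_id", "sample_id"]].to_numpy()]
    return final[mask].reset_index(drop=True)


@pytest.fixture(scope="session")
def diversity_table(gated_final, dataset):
    from sedadiv.diversity import sample_diversity_table

    return sample_diversity_table(gated_final, dataset["ages"])


@pytest.fixture(scope="session")
def fixture_dir(dataset, tmp_path_factory):
    from sedadiv.synthetic import write_fixture

    path = tmp_path_factory.mktemp("fixture")
    write_fixture(dataset, path)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_counts(rng, n_rows=20, n_reps=8, max_reads=50, sample_id="s1",
                lake_id="lakeA", dnas=None):
    """Random counts table in the pipeline's long format."""
    if dnas is None:
        dnas = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(n_rows)]
    counts = rng.integers(0, max_reads, size=(len(dnas), n_reps))
    df = pd.DataFrame({
        "lake_id": lake_id, "sample_id": sample_id, "sample_type": "sample",
        "sequence_id": [f"sq{i:04d}" for i in range(len(dnas))], "dna": dnas,
    })
    for r in range(n_reps):
        df[f"rep_{r + 1}"] = counts[:, r]
    return df
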