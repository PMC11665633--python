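import numpy as np
import pytest

from ldamark import (
    AbundanceTable,
    SampleGroups,
    SyntheticSpec,
    generate_synthetic,
)


@pytest.fixture
def small_table():
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [4.0, 3.0, 2.0, 1.0],
            [2.0, 2.0, 3.0, 3.0],
        ]
    )
    return AbundanceTable(values, ["f1", "f2", "f3"], ["s1", "s2", "s3", "s4"])


@pytest.fixture
def small_groups():
    return SampleGroups(["s1", "s2", "s3", "s4"], ["A", "A", "B", "B"])


@pytest.fixture
def spiked_dataset():
    """Medium synthetic dataset with 3 strong spikes and known truth."""
    spec = SyntheticSpec(
        n_features=40,
        n_samples_per_class=(15, 15),
        n_spiked=3,
        fold_change=6.0,
        log_sd=0.5,
        seed=42,
    )
    return generate_synthetic(spec)


@pytest.fixture
def subclass_dataset():
    spec = SyntheticSpec(
        n_features=30,
        n_samples_per_class=(12, 12),
        n_spiked=2,
        fold_change=6.0,
        subclass_count=2,
        log_sd=0.5,
        seed=7,
    )
    return generate_synthetic(spec)


@pytest.fixture
def table_tsv(tmp_path, small_table):
    path = tmp_path / "table.tsv"
    small_table.to_dataframe().to_csv(path, sep="\t", index_label="feature")
    return path


@pytest.fixture
def metadata_tsv(tmp_path):
    path = tmp_path / "metadata.tsv"
    path.write_text(
        "sample\tgroup\tage\n"
        "s1\tA\tyoung\n"
        "s2\tA\told\n"
        "s3\tB\tyoung\n"
        "s4\tB\told\n"
    )
    return path
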