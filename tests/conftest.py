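import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def samplesheet():
    from cnvpop.simulate import default_samplesheet

    return default_samplesheet()


@pytest.fixture(scope="session")
def small_layout():
    """A 3 Mb single-chromosome layout shared by unit tests."""
    from cnvpop.simulate import generate_genome

    return generate_genome(n_chroms=1, chrom_len=3_000_000, masked_fraction=0.1,
                           n_genes=40, seed=11)


@pytest.fixture
def tiny_sheet():
    from cnvpop.intervals import SampleSheet

    rows = [
        ("w1", "RJF", "wild"), ("w2", "RJF", "wild"), ("w3", "RJF", "wild"),
        ("a1", "A", "domestic"), ("a2", "A", "domestic"), ("a3", "A", "domestic"),
        ("b1", "B", "domestic"), ("b2", "B", "domestic"), ("b3", "B", "domestic"),
    ]
    return SampleSheet(pd.DataFrame(rows, columns=["sample_id", "breed", "group"]))
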