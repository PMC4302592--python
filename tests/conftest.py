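import pytest

from xcitrio.model import AlleleObservation, Source
from xcitrio.pipeline import run_trio_dataset
from xcitrio.synthetic_data import SimulationParams, simulate_trio


def obs(
    sample="daughter",
    source=Source.TRANSCRIPTOME,
    scaffold="ScaffoldX1",
    position=1000,
    ref="A",
    alt="G",
    reads_ref=10,
    reads_alt=10,
):
    return AlleleObservation(
        sample_id=sample,
        source=source,
        scaffold=scaffold,
        position=position,
        ref_allele=ref,
        alt_allele=alt,
        reads_ref=reads_ref,
        reads_alt=reads_alt,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A 60-locus simulated trio shared across tests (read-only)."""
    return simulate_trio(SimulationParams(seed=3, n_loci=60))


@pytest.fixture(scope="session")
def small_result(small_dataset):
    return run_trio_dataset(small_dataset)
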