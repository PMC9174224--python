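import numpy as np
import pytest

from linkstr.loci import StrLocus
from linkstr.sim import SimConfig, simulate_dataset


def small_sim_config() -> SimConfig:
    """A 300-kb diploid toy genome with a heterozygous 800-copy ATTCT
    expansion — small enough for seconds-scale tests, large enough for
    molecule bridging and barcode selection to behave realistically."""
    return SimConfig(
        reference_length=300_000,
        str_locus=StrLocus("chrS", 150_000, 150_075, "ATTCT", name="toySTR"),
        allele_repeat_counts=(15, 800),
        molecule_length_mean=30_000,
        barcode_pool_size=600,
        target_depth=20.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("small_sim")
    return simulate_dataset(small_sim_config(), str(outdir))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
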