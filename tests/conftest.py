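import warnings

import numpy as np
import pytest

from larkmt.datasets import REPEAT_UNIT_TABLE
from larkmt.simulate import CR2Spec, SimConfig, simulate_mitogenome


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def table_haplotypes():
    """Decoded published haplotypes per species (redundant-letter warnings
    in two printed masks are expected and silenced)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return {sp: rec.haplotypes() for sp, rec in REPEAT_UNIT_TABLE.items()}


@pytest.fixture(scope="session")
def sim_genome_c():
    """A type-C mitogenome with a clean planted repeat array (seed 1)."""
    return simulate_mitogenome(
        SimConfig(
            seed=1,
            order_type="C",
            cr2=CR2Spec(per_unit_substitution_rate=0.0),
            plant_rrns_overlap=True,
        )
    )
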