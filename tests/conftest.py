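import numpy as np
import pytest

from fibroin_arch import (
    ArchitectureParams,
    CurationConfig,
    ReadSimParams,
    generate_fibroin_gene,
    generate_fibroin_protein,
    simulate_reads,
)

#: The worked one-unit example: A^5 E A^5 | (GA)^4 | IVIVI | GA-S block.
TOY_PARAMS = ArchitectureParams(
    n_units=1,
    polyA_half_len=5,
    ga_pure_len=8,
    linker_len=5,
    ga_ser_len=10,
    ser_rate=0.4,
    jitter=0.0,
    n_term_len=0,
    c_term_len=0,
)

TOY_PROTEIN = "AAAAAEAAAAAGAGAGAGAIVIVIGASGAGASGA"


@pytest.fixture(scope="session")
def toy_gene():
    return generate_fibroin_protein(TOY_PARAMS, rng_seed=0)


@pytest.fixture(scope="session")
def gene5():
    """Five-unit jitter-free gene with terminal domains, ~3 kb CDS."""
    params = ArchitectureParams(
        n_units=5,
        polyA_half_len=11,
        ga_pure_len=40,
        linker_len=6,
        ga_ser_len=90,
        jitter=0.0,
    )
    return generate_fibroin_gene(params, rng_seed=1)


@pytest.fixture(scope="session")
def gene5_reads(gene5):
    """Error-free 30x 150-bp reads over the five-unit gene."""
    return simulate_reads(gene5.cds, ReadSimParams(coverage=30.0, rng_seed=5))


@pytest.fixture(scope="session")
def random_template():
    """Non-repetitive 2 kb nucleotide template."""
    rng = np.random.default_rng(7)
    return "".join(rng.choice(list("ACGT"), 2000))


@pytest.fixture(scope="session")
def default_curation():
    return CurationConfig()
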