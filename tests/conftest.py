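import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from txflow import (
    GeneConstruct,
    NetworkSpec,
    constant_protocol,
    reference_parameters,
)


@pytest.fixture(scope="session")
def db_params():
    params, _ = reference_parameters("database")
    return params


@pytest.fixture(scope="session")
def db_bounds():
    _, bounds = reference_parameters("database")
    return bounds


@pytest.fixture(scope="session")
def one_gene_network():
    """Single constitutive gene driving the deGFP reporter."""
    return NetworkSpec(
        constructs=(GeneConstruct(name="g", promoter="p70a", orf="deGFP", riboj=True),),
        name="one-gene",
    )


@pytest.fixture
def one_gene_protocol():
    return constant_protocol(["g"], {"g": 5.0}, {"g": 0.2}, 48)


def cascade_steady_state(params, dna, lam, orf="deGFP", riboj=True, kcat_tx=None):
    """Closed-form steady state of an unregulated constitutive reporter gene.

    Independent oracle for the simulator: DNA -> mRNA -> dark -> mature chain
    solved analytically under constant inflow and dilution.
    """
    kcat_tx = params.kcat_tx_s70 if kcat_tx is None else kcat_tx
    mrna = kcat_tx * dna / (params.kdeg_mrna[orf] + lam)
    dark = params.kcat_tl[(orf, riboj)] * mrna / (lam + params.kmat[orf])
    mature = params.kmat[orf] * dark / lam
    return {"DNA": dna, "mRNA": mrna, "dark": dark, "mature": mature}
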