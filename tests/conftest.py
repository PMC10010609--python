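"""Shared fixtures: small synthetic roots and reference conditions."""
import numpy as np
import pytest

from rootflow import (
    Axis,
    BathSolution,
    RootSystem,
    TransportParams,
    discretize,
    generate_synthetic_rsa,
)

SEED = 20240901


@pytest.fixture(scope="session")
def ctr_bath():
    return BathSolution(Pe=0.0)


@pytest.fixture(scope="session")
def peg_bath():
    return BathSolution(Pe=0.0, w_peg=0.150)


@pytest.fixture(scope="session")
def ctr_params():
    return TransportParams()  # first-guess/control defaults


@pytest.fixture(scope="session")
def peg_params():
    # water-deficit roots: radial conductivity reduced 10-fold
    return TransportParams(k=1e-8)


@pytest.fixture(scope="session")
def small_rs():
    """~10 cm root with a handful of laterals; fast to solve."""
    return generate_synthetic_rsa(
        primary_length=0.10, lateral_density=60.0,
        lateral_length_law=(0.025, 0.008), seed=SEED,
    )


@pytest.fixture(scope="session")
def small_graph(small_rs):
    return discretize(small_rs, 1e-3)


@pytest.fixture(scope="session")
def reference_rs():
    """Full-size seminal root emulating the experimental plants."""
    return generate_synthetic_rsa(primary_length=0.30, lateral_density=70.0, seed=1)


@pytest.fixture(scope="session")
def reference_graph(reference_rs):
    return discretize(reference_rs, 1e-3)


@pytest.fixture(scope="session")
def one_rev_graph():
    """Single-REV root: the tree solver's osmometer limit."""
    rs = RootSystem([Axis("p", None, 0.0, 1e-3, 1.05e-3, 0)])
    return discretize(rs, 1e-3)


@pytest.fixture(scope="session")
def huge_axial_params():
    """Negligible axial resistance: xylem at basal pressure everywhere."""
    return TransportParams(K_knots=((0.0, 1.0),))
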