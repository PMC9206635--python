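import numpy as np
import pytest

from shapearena import synthetic as syn


@pytest.fixture(scope="session")
def template_2d():
    return syn.build_template("thorax-like", (64, 64), seed=0)


@pytest.fixture(scope="session")
def basis_2d(template_2d):
    return syn.build_deformation_basis(template_2d, k=3, seed=1)


@pytest.fixture(scope="session")
def population_2d(template_2d, basis_2d):
    """Small 2D population: 30 instances, 3 known modes."""
    return syn.sample_population(
        template_2d, basis_2d, 30, offset_scale=0.05, seed=2
    )


@pytest.fixture(scope="session")
def template_3d():
    return syn.build_template("brain-like", (24, 32, 24), seed=7)


@pytest.fixture(scope="session")
def recovery_population(template_2d):
    """Larger population used by parameter-recovery checks (k=3, n=200)."""
    basis = syn.build_deformation_basis(template_2d, k=3, seed=11)
    return syn.sample_population(
        template_2d, basis, 200, offset_scale=0.0, seed=12
    )
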