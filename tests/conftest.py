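import numpy as np
import pytest

from magicmap.pedigree import DesignSpec
from magicmap.simulate import GeneticMapSpec, random_marker_model, simulate_design


@pytest.fixture(scope="session")
def mp8_design():
    return DesignSpec(n_funnels=40, lines_per_funnel=2)


@pytest.fixture(scope="session")
def small_map():
    return GeneticMapSpec.uniform(1, 100.0, 21)


@pytest.fixture(scope="session")
def small_pop(mp8_design, small_map):
    mm = random_marker_model(small_map, seed=3, alleles="biallelic")
    return simulate_design(mp8_design, small_map, seed=11, marker_model=mm)
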