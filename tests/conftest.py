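"""Shared fixtures: synthetic input tables and pre-run base-case results.

Everything is generated in memory; nothing is downloaded or read from
outside the repository.
"""

import pytest

from pnhcea import CostEffectivenessModel, default_parameters
from pnhcea.synthetic import generate_life_table, generate_weight_table


@pytest.fixture(scope="session")
def life_table():
    return generate_life_table()


@pytest.fixture(scope="session")
def weight_table():
    return generate_weight_table()


@pytest.fixture()
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def base_model(life_table, weight_table):
    return CostEffectivenessModel(default_parameters(), life_table, weight_table)


@pytest.fixture(scope="session")
def base_results(base_model):
    return base_model.run()
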