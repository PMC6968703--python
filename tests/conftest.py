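from __future__ import annotations

import pytest
from hypothesis import settings

from selprof import SelectivityConfig, SimScenario, simulate, write_fixture

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

#: Diverse 50-molecule SMILES panel for fingerprint cross-checks: drugs,
#: sulfonamide zinc binders, heterocycles, charged and disconnected species.
PANEL_50 = [
    "C", "O", "CCO", "CC(=O)O", "c1ccccc1", "Cc1ccccc1", "Oc1ccccc1",
    "Nc1ccccc1", "Clc1ccccc1", "Brc1ccc(Br)cc1", "c1ccc2ccccc2c1",
    "c1ccncc1", "c1ccoc1", "c1ccsc1", "c1cnc2[nH]ccc2c1",
    "NS(=O)(=O)c1ccccc1", "NS(=O)(=O)c1ccc(N)cc1",
    "CC(=O)Nc1nnc(S(N)(=O)=O)s1",  # acetazolamide
    "NS(=O)(=O)Oc1ccccc1",  # phenyl sulfamate
    "NS(=O)(=O)NC1CCCCC1",
    "CC(C)Cc1ccc(C(C)C(=O)O)cc1",  # ibuprofen
    "CC(=O)Oc1ccccc1C(=O)O",  # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",  # caffeine
    "NCCc1ccc(O)c(O)c1",  # dopamine
    "C1CCNCC1", "C1CCOC1", "O=C1CCCCC1", "CC(C)(C)O", "CC(F)(F)F",
    "N#Cc1ccccc1", "O=[N+]([O-])c1ccccc1", "FC(F)(F)c1ccccc1",
    "OCC(O)CO", "NC(N)=O", "NC(=O)c1ccccc1", "OC(=O)c1ccccc1O",
    "C=CC=C", "C#CC", "CC=O", "CN(C)C=O", "CS(C)=O", "CSSC",
    "[Na+].[Cl-]", "CC(=O)[O-].[Na+]",
    "O=S(=O)(O)c1ccccc1", "NS(=O)(=O)c1cc2c(s1)CCC2",
    "Oc1ccc2ccccc2c1", "CCN(CC)C(=O)c1ccccc1",
    "NS(=O)(=O)c1ccc(CNC(=O)OC(C)(C)C)cc1", "[He]",
]


@pytest.fixture(scope="session")
def default_dataset():
    """Default-scenario synthetic records + ground truth (seed 7)."""
    return simulate(SimScenario(seed=7))


@pytest.fixture(scope="session")
def clean_scenario():
    """No decoys, no outliers, no noise: analytic expectations hold."""
    return SimScenario(noise_sd=1e-12, outlier_rate=0.0, decoy_rate=0.0, seed=3)


@pytest.fixture
def fixture_csv(tmp_path, default_dataset):
    records, truth = default_dataset
    path = tmp_path / "fixture.csv"
    write_fixture(records, path, truth)
    return path


@pytest.fixture
def ix_ii_config():
    return SelectivityConfig(on_target="hCA IX", off_target="hCA II")
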