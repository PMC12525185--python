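import dataclasses

import pytest

import smilescw as s

# In-text reference compounds with measured pLC50 values.
HEXACHLOROPHENE = s.SmilesRecord(
    id="70-30-4",
    smiles="Oc1c(Cl)cc(Cl)c(Cl)c1Cc1c(O)c(Cl)cc(Cl)c1Cl",
    endpoint=1.68,
)
THIURAM_DISULFIDE = s.SmilesRecord(
    id="97-77-8", smiles="CCN(CC)C(=S)SSC(=S)N(CC)CC", endpoint=0.49
)
DICHLOROPHENE = s.SmilesRecord(
    id="97-23-4", smiles="Oc1ccc(Cl)cc1Cc1cc(Cl)ccc1O", endpoint=0.510
)


@pytest.fixture(scope="session")
def paper_records():
    return [HEXACHLOROPHENE, THIURAM_DISULFIDE, DICHLOROPHENE]


@pytest.fixture(scope="session")
def small_dataset():
    """40 compounds, mild noise: cheap input for optimizer-driven tests."""
    spec = s.SyntheticSpec(n_compounds=40, seed=11, noise_fraction=0.1)
    records, truth = s.generate_dataset(spec)
    split = s.make_split([r.id for r in records], seed=2)
    return records, truth, split


@pytest.fixture(scope="session")
def small_model(small_dataset):
    """One cheap fitted model shared by IO/domain/interpretation tests."""
    records, _, split = small_dataset
    config = dataclasses.replace(s.TF1_PRESET, epochs_N=3, seed=4)
    model, history = s.optimize(records, split, config)
    return model, history, records, split
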