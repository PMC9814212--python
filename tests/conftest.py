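import numpy as np
import pytest

from taulogp.dataset import MoleculeRecord


@pytest.fixture
def simple_records():
    return [
        MoleculeRecord(id="r1", smiles="CCO", logp_exp=-0.31),
        MoleculeRecord(id="r2", smiles="c1ccccc1", logp_exp=2.13),
        MoleculeRecord(id="r3", smiles="CC(C)=O", logp_exp=-0.24, pka_acidic=[19.0]),
        MoleculeRecord(id="r4", smiles="CCCCCCCC(=O)O", logp_exp=3.05, pka_acidic=[4.9]),
    ]


@pytest.fixture
def dataset_csv(tmp_path, simple_records):
    from taulogp.dataset import write_dataset

    path = tmp_path / "data.csv"
    write_dataset(simple_records, path)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
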