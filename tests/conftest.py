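import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from triadnet.compounds import Compound, default_registry, embed_conformer
from triadnet.dataset import FeatureMatrix
from triadnet.simulate import SyntheticWorldConfig, generate_world, plant_triads


def make_compound(smiles: str, cid: str = "X", seed: int = 0, embed: bool = False) -> Compound:
    c = Compound(id=cid, mol=Chem.MolFromSmiles(smiles))
    if embed:
        embed_conformer(c, seed)
    return c


def make_feature_matrix(X: np.ndarray, y: np.ndarray, names=None) -> FeatureMatrix:
    """Wrap a plain array as a FeatureMatrix with dummy role/category tags."""
    names = names or [f"f{j}" for j in range(X.shape[1])]
    meta = pd.DataFrame({"role": "substrate", "category": "chemistry"},
                        index=pd.Index(names, name="name"))
    return FeatureMatrix(pd.DataFrame(X, columns=names), np.asarray(y), meta)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def tiny_world():
    """A small but complete world, encoded once per session."""
    cfg = SyntheticWorldConfig(n_compounds=25, n_enzymes=12, n_positive=40,
                               ratio=3, seed=7)
    world = generate_world(cfg)
    positives, planted = plant_triads(world, cfg)
    return world, positives, planted
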