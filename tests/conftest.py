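import numpy as np
import pytest
import biotite.structure as struc

from c1ring.structure_metrics import StructureModel


def build_model(
    coords,
    chain="A",
    res_ids=None,
    res_names=None,
    atom_names=None,
    elements=None,
    hetero=False,
):
    """Programmatic StructureModel for geometry tests."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    arr = struc.AtomArray(n)
    arr.coord = coords
    arr.chain_id = np.array([chain] * n) if isinstance(chain, str) else np.asarray(chain)
    arr.res_id = np.asarray(res_ids if res_ids is not None else range(1, n + 1))
    arr.res_name = np.array(res_names if res_names is not None else ["GLY"] * n)
    arr.atom_name = np.array(atom_names if atom_names is not None else ["CA"] * n)
    arr.element = np.array(elements if elements is not None else ["C"] * n)
    arr.hetero = np.array(
        [hetero] * n if isinstance(hetero, bool) else hetero, dtype=bool
    )
    return StructureModel(atoms=arr, source="synthetic")


@pytest.fixture
def atom_factory():
    return build_model


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
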