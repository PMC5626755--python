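import numpy as np
import pytest

from stardynet import synthetic, trajio


@pytest.fixture(scope="session")
def toy_complex():
    return synthetic.build_toy_complex(seed=0)


@pytest.fixture(scope="session")
def toy_ensemble(toy_complex):
    """Small isotropic ensemble of the toy complex (sigma^2 = 0.04 A^2)."""
    spec = synthetic.EnsembleSpec(
        toy_complex, np.full(toy_complex.n_atoms, 0.04), n_frames=60, seed=3
    )
    return synthetic.sample_harmonic_ensemble(spec)


def make_structure(coords, names=None, resseqs=None, chains=None,
                   elements=None, resnames=None):
    """Minimal Structure factory for geometric unit tests."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    names = names or ["CA"] * n
    resseqs = list(resseqs) if resseqs is not None else list(range(1, n + 1))
    elements = elements or ["C"] * n
    from stardynet.constants import ATOMIC_MASSES

    return trajio.Structure(
        atom_names=names,
        residue_seqs=resseqs,
        residue_names=resnames or ["ALA"] * n,
        chain_ids=chains or ["A"] * n,
        elements=elements,
        coords=coords,
        bfactors=np.zeros(n),
        occupancies=np.ones(n),
        masses=[ATOMIC_MASSES.get(str(e).upper(), 12.0) for e in elements],
    )


@pytest.fixture
def structure_factory():
    return make_structure
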