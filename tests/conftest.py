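import numpy as np
import pytest

import seqgp as sg


@pytest.fixture
def gb1_space():
    """Four amino-acid sites with the GB1 position labels."""
    return sg.SequenceSpace.uniform(
        4, sg.PROTEIN_ALPHABET, site_labels=["39", "40", "41", "54"]
    )


@pytest.fixture
def gb1_connectedness(gb1_space):
    """Connectedness kernel with the fitted GB1 decay factors."""
    return sg.ConnectednessKernel(gb1_space, 1.0, [0.23, 0.08, 0.54, 0.38])


@pytest.fixture
def small_binary_space():
    return sg.SequenceSpace.uniform(3, 2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_kernel(space, family, rng, sigma2=None):
    """Random kernel of a given family with decay factors in the default domain."""
    sigma2 = float(rng.uniform(0.5, 2.0)) if sigma2 is None else sigma2
    if family == "geometric":
        return sg.GeometricKernel(space, sigma2, float(rng.uniform(0, 0.95)))
    if family == "connectedness":
        return sg.ConnectednessKernel(space, sigma2, rng.uniform(0, 0.95, space.length))
    if family == "jenga":
        return sg.JengaKernel(
            space, sigma2, [rng.uniform(0, 0.95, a) for a in space.alphabet_sizes]
        )
    if family == "general_product":
        # decay factors in [0,1] alone do not guarantee PSD for alpha >= 3:
        # rejection-sample until every per-site factor matrix is PSD
        mats = []
        for a in space.alphabet_sizes:
            while True:
                m = np.zeros((a, a))
                iu = np.triu_indices(a, k=1)
                m[iu] = rng.uniform(0, 0.95, len(iu[0]))
                m += m.T
                F = 1.0 - m
                np.fill_diagonal(F, 1.0)
                if np.linalg.eigvalsh(F)[0] >= -1e-12:
                    mats.append(m)
                    break
        return sg.GeneralProductKernel(space, sigma2, mats)
    if family == "vc":
        lam = rng.uniform(0, 1, space.length + 1)
        return sg.VCKernel(space, lam)
    raise ValueError(family)
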