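import numpy as np
import pytest

from selscape import datasets
from selscape.core import TraitMatrix


@pytest.fixture(scope="session")
def published_gamma():
    return datasets.load_selection_gradients()


@pytest.fixture(scope="session")
def published_P():
    return datasets.load_p_matrix()


@pytest.fixture(scope="session")
def published_D():
    return datasets.load_d_matrix()


@pytest.fixture(scope="session")
def published_vectors():
    return datasets.load_canonical_vectors()


@pytest.fixture(scope="session")
def taxon_table():
    return datasets.load_taxon_summaries()


@pytest.fixture(scope="session")
def reference_means():
    return datasets.load_reference_means()


@pytest.fixture()
def rng():
    return np.random.default_rng(20250923)


def make_trait_matrix(values, **kw):
    values = np.asarray(values, dtype=float)
    p = values.shape[1]
    kw.setdefault("trait_labels", tuple(f"z{i+1}" for i in range(p)))
    kw.setdefault("units", ("",) * p)
    return TraitMatrix(values, **kw)


@pytest.fixture(scope="session")
def brute_force_eigh_3x3():
    """Characteristic-polynomial eigensolver, independent of LAPACK eigh."""

    def solve(M):
        M = np.asarray(M, dtype=float)
        a = -1.0
        b = np.trace(M)
        c = -0.5 * (np.trace(M) ** 2 - np.trace(M @ M))
        d = np.linalg.det(M)
        roots = np.roots([a, b, c, d])
        roots = np.sort(roots.real)
        vecs = []
        for lam in roots:
            A = M - lam * np.eye(3)
            # nullspace direction via cross products of rows
            candidates = [
                np.cross(A[0], A[1]),
                np.cross(A[0], A[2]),
                np.cross(A[1], A[2]),
            ]
            v = max(candidates, key=np.linalg.norm)
            vecs.append(v / np.linalg.norm(v))
        return roots, np.array(vecs)

    return solve
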