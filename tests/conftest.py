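import numpy as np
import pytest

from fmgda.grassmann import GrassmannPoint, LabeledGrassmannSet, orthonormalize


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def random_point(rng, D, p):
    """A uniformly random point of G(p, D) (QR of a Gaussian matrix)."""
    Q, _ = orthonormalize(rng.standard_normal((D, p)))
    return GrassmannPoint(Q)


def random_rotation(rng, p):
    """A random p x p orthogonal matrix."""
    Q, _ = np.linalg.qr(rng.standard_normal((p, p)))
    return Q


def random_labeled_set(rng, K=2, n_per_class=4, D=6, p=2):
    bases = np.stack(
        [random_point(rng, D, p).basis for _ in range(K * n_per_class)]
    )
    labels = np.repeat(np.arange(K), n_per_class)
    return LabeledGrassmannSet(bases, labels)
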