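import numpy as np
import pytest

from regvar3d import FixtureSpec, generate_bundle
from regvar3d.binding_affinity import pfm_to_pwm


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One default positive-control bundle shared across read-only tests."""
    out = tmp_path_factory.mktemp("bundle")
    return generate_bundle(FixtureSpec(), out, seed=7)


@pytest.fixture()
def sharp_motif():
    """Width-4 motif with a near-deterministic consensus ACGT."""
    pfm = np.full((4, 4), 0.01)
    for i in range(4):
        pfm[i, i] = 0.97
    return pfm_to_pwm(pfm, name="sharp", family="TEST")


def random_pfm(rng, width):
    """Dirichlet-random PFM columns, occasionally informative."""
    alpha = rng.choice([0.3, 1.0, 3.0])
    return rng.dirichlet(np.full(4, alpha), size=width)


def enumeration_pvalue(motif, observed_int_score, background=None):
    """Independent oracle: exhaustive enumeration over all 4^k k-mers,
    scored with the motif's grid-rounded integer weights."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    width = motif.length
    kmers = np.indices((4,) * width).reshape(width, -1).T  # (4^k, k)
    scores = motif.iwm[np.arange(width), kmers].sum(axis=1)
    probs = bg[kmers].prod(axis=1)
    return float(probs[scores >= observed_int_score].sum())
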