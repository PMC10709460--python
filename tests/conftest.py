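"""Shared fixtures: random rotations and a hydrated host-guest fixture."""

from __future__ import annotations

import numpy as np
import pytest

from cdtraj.synthetic import make_hydrated_complex


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture(scope="session")
def hydrated_complex():
    return make_hydrated_complex()
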