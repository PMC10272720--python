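import numpy as np
import pytest

from ticvelo.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def straight_phantom():
    """Noiseless straight-vessel phantom at 30 fps, 0.2 mm/px, 300 mm/s."""
    config = PhantomConfig()
    seq, truth = generate_phantom(config)
    return config, seq, truth


@pytest.fixture(scope="session")
def sinusoid_phantom():
    """Noiseless projected-helix (sinusoidal) phantom."""
    config = PhantomConfig(path_kind="sinusoid", shape=(128, 512))
    seq, truth = generate_phantom(config)
    return config, seq, truth


def polyline_distance(points, polyline):
    """Max distance from each of ``points`` to the segments of ``polyline``.

    Brute-force point-to-segment distances; used as an independent check
    of centerline accuracy against phantom truth.
    """
    p = np.asarray(points, dtype=float)[:, None, :]  # (N, 1, 2)
    a = np.asarray(polyline, dtype=float)[None, :-1, :]  # (1, M-1, 2)
    b = np.asarray(polyline, dtype=float)[None, 1:, :]
    ab = b - a
    t = np.clip(np.sum((p - a) * ab, axis=-1) / np.sum(ab * ab, axis=-1), 0.0, 1.0)
    proj = a + t[..., None] * ab
    d = np.linalg.norm(p - proj, axis=-1).min(axis=1)
    return d
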