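import numpy as np
import pytest

from nca.phantom import gen_test_set


@pytest.fixture(scope="session")
def gaussian_peak():
    """Isotropic Gaussian bump, amplitude 100, sigma 10 px, zero background."""
    y, x = np.mgrid[0:128, 0:128]
    img = 100.0 * np.exp(-(((x - 64) ** 2 + (y - 64) ** 2) / (2 * 10.0**2)))
    return img


@pytest.fixture(scope="session")
def two_peaks():
    """Two well-separated Gaussian peaks on a zero background."""
    y, x = np.mgrid[0:160, 0:256]
    img = 100.0 * np.exp(-(((x - 64) ** 2 + (y - 80) ** 2) / (2 * 10.0**2)))
    img += 100.0 * np.exp(-(((x - 192) ** 2 + (y - 80) ** 2) / (2 * 10.0**2)))
    return img


@pytest.fixture(scope="session")
def default_test_set():
    """The full default synthetic test set (100 positives + 100 negatives).

    Session-scoped: generating and detecting on it is the expensive part of
    the suite and is shared between the end-to-end tests.
    """
    return gen_test_set(seed=7)


@pytest.fixture(scope="session")
def default_test_set_detections(default_test_set):
    from nca.core import detect_lesions

    return [detect_lesions(s.image) for s in default_test_set]
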