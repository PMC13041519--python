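import numpy as np
import pytest

from avistrike import FrontalSilhouette, generate_parametric_silhouette


@pytest.fixture(scope="session")
def default_sil():
    """The default 737-like parametric silhouette at full resolution."""
    return generate_parametric_silhouette()


@pytest.fixture(scope="session")
def small_sil():
    """Low-resolution default silhouette for fast sweeps."""
    return generate_parametric_silhouette(resolution=120)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def random_silhouette(rng, n_rows=None, n_cols=None, width_m=None, p=0.4):
    """Random binary mask with at least one occupied pixel."""
    n_rows = n_rows or int(rng.integers(3, 40))
    n_cols = n_cols or int(rng.integers(3, 60))
    mask = (rng.random((n_rows, n_cols)) < p).astype(np.uint8)
    mask[int(rng.integers(n_rows)), int(rng.integers(n_cols))] = 1
    width_m = width_m or float(rng.uniform(0.5, 30.0))
    return FrontalSilhouette(mask=mask, width_m=width_m)


def window_probability_oracle(s, d_collision, l):
    """Independent per-pixel loop over the discretized collision window.

    Recomputes the window bounds from first principles: the window covers
    [d_collision - l/2, d_collision + l/2]; each pixel column i spans
    [i*scale, (i+1)*scale).  The window is w = round(l/scale) columns wide
    (min 1), centered on the column whose center is closest to d_collision,
    shifted left by w//2.  Out-of-grid columns contribute 0 but count in the
    denominator.
    """
    scale = s.width_m / s.mask.shape[1]
    w = max(1, round(l / scale))
    center = round(d_collision / scale - 0.5)
    start = center - w // 2
    occupied = 0
    for col in range(start, start + w):
        if 0 <= col < s.mask.shape[1]:
            for row in range(s.mask.shape[0]):
                if s.mask[row, col]:
                    occupied += 1
    return occupied / (w * s.mask.shape[0])
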