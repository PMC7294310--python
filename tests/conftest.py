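import numpy as np
import pytest

from gelquant.image_ops import GelImage


def brute_force_rolling_ball(image: GelImage, radius: int, light_background: bool = True):
    """Independent double-loop rolling-ball oracle.

    Literal erosion-then-dilation with the half-ball structuring element,
    support clipped at the image borders, evaluated pixel by pixel.
    Returns the corrected image as integer pixels, rounded exactly like
    the library does, plus the working-image background.
    """
    maxval = image.max_value
    px = image.pixels.astype(np.float64)
    W = maxval - px if light_background else px
    n, m = W.shape

    offs = []
    for i in range(-radius, radius + 1):
        for j in range(-radius, radius + 1):
            d2 = i * i + j * j
            if d2 <= radius * radius:
                offs.append((i, j, np.sqrt(float(radius * radius - d2))))

    eroded = np.empty_like(W)
    for x in range(n):
        for y in range(m):
            best = np.inf
            for i, j, h in offs:
                u, v = x + i, y + j
                if 0 <= u < n and 0 <= v < m:
                    val = W[u, v] - h
                    if val < best:
                        best = val
            eroded[x, y] = best
    bg = np.empty_like(W)
    for x in range(n):
        for y in range(m):
            best = -np.inf
            for i, j, h in offs:
                u, v = x + i, y + j
                if 0 <= u < n and 0 <= v < m:
                    val = eroded[u, v] + h
                    if val > best:
                        best = val
            bg[x, y] = best

    corrected_W = np.clip(W - bg, 0.0, maxval)
    corrected = maxval - corrected_W if light_background else corrected_W
    corrected_int = np.clip(np.floor(corrected + 0.5), 0, maxval).astype(image.pixels.dtype)
    return GelImage(pixels=corrected_int, bit_depth=image.bit_depth), bg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image_16(rng):
    def make(shape=(32, 32), low=0, high=65535):
        px = rng.integers(low, high + 1, size=shape, dtype=np.uint16)
        return GelImage(pixels=px, bit_depth=16)

    return make
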