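import numpy as np
import pytest


def bruteforce_adaptive_median(img: np.ndarray, initial_size: int, s_max: int) -> np.ndarray:
    """Independent per-pixel re-implementation of the adaptive median filter.

    Pure-Python, explicit index clamping for edge replication, explicit sort
    for the order statistics; deliberately shares no code with the package.
    """
    h, w = img.shape
    out = np.empty_like(img)
    for r in range(h):
        for c in range(w):
            zxy = int(img[r, c])
            result = zxy
            size = initial_size
            while size <= s_max:
                half = size // 2
                vals = []
                for dr in range(-half, half + 1):
                    for dc in range(-half, half + 1):
                        rr = min(max(r + dr, 0), h - 1)
                        cc = min(max(c + dc, 0), w - 1)
                        vals.append(int(img[rr, cc]))
                vals.sort()
                z_min, z_max = vals[0], vals[-1]
                z_med = vals[len(vals) // 2]
                if z_med - z_min > 0 and z_max - z_med > 0:
                    if zxy - z_min > 0 and z_max - zxy > 0:
                        result = zxy
                    else:
                        result = z_med
                    break
                size += 2
            out[r, c] = result
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def disk_mask() -> np.ndarray:
    yy, xx = np.mgrid[0:32, 0:32]
    return ((yy - 16) ** 2 + (xx - 16) ** 2 <= 64).astype(np.uint8)
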