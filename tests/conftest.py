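"""Shared helpers for the test suite."""

import numpy as np


def band_power(frame, freq_cpp, halfwidth=1):
    """Spectral power near +/- (freq_cpp, 0) cycles/px (horizontal wave)."""
    h, w = frame.shape
    spec = np.fft.fftshift(np.fft.fft2(frame))
    cy, cx = h // 2, w // 2
    k = int(round(freq_cpp * w))
    s = 0.0
    for sign in (+1, -1):
        patch = spec[cy - halfwidth : cy + halfwidth + 1,
                     cx + sign * k - halfwidth : cx + sign * k + halfwidth + 1]
        s += np.sum(np.abs(patch) ** 2)
    return s


def scene_power(frame, radius=8):
    """Power of the protected low-frequency (scene) band."""
    h, w = frame.shape
    spec = np.fft.fftshift(np.fft.fft2(frame))
    yy, xx = np.mgrid[0:h, 0:w]
    disc = (yy - h // 2) ** 2 + (xx - w // 2) ** 2 <= radius**2
    return np.sum(np.abs(spec[disc]) ** 2)


def dice(a, b):
    """Dice overlap of two boolean masks (1.0 for two empty masks)."""
    denom = a.sum() + b.sum()
    return 1.0 if denom == 0 else 2.0 * (a & b).sum() / denom
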