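"""Separable image resampling with Keys cubic and linear kernels.

The degradation model that produces low-resolution training inputs is bicubic
resizing.  It is implemented here from the Keys (1981) cubic convolution
kernel with a = -0.5, the convention shared by the classical bicubic
literature, using the half-pixel-center coordinate mapping and edge clamping.
Resampling along one axis is a dense matrix product, so a 2-D resize is two
matrix multiplications and is exactly reproducible.
"""

from __future__ import annotations

from math import ceil

import numpy as np

__all__ = ["cubic_kernel", "resample_matrix", "resize_2d", "downscale_2d"]


def cubic_kernel(x: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Keys cubic convolution kernel with free parameter ``a``."""
    x = np.abs(x)
    out = np.zeros_like(x)
    m1 = x <= 1
    m2 = (x > 1) & (x < 2)
    out[m1] = (a + 2) * x[m1] ** 3 - (a + 3) * x[m1] ** 2 + 1
    out[m2] = a * x[m2] ** 3 - 5 * a * x[m2] ** 2 + 8 * a * x[m2] - 4 * a
    return out


def resample_matrix(n_in: int, n_out: int, kernel: str = "cubic") -> np.ndarray:
    """Dense (n_out, n_in) 1-D resampling matrix.

    Output sample ``i`` is centered at input coordinate
    ``(i + 0.5) * n_in / n_out - 0.5``; taps outside the signal are clamped to
    the nearest edge sample.  Rows sum to one, so constants are preserved.
    """
    if n_in < 1 or n_out < 1:
        raise ValueError("resample_matrix requires positive sizes")
    mat = np.zeros((n_out, n_in))
    ratio = n_in / n_out
    for i in range(n_out):
        pos = (i + 0.5) * ratio - 0.5
        base = int(np.floor(pos))
        if kernel == "cubic":
            taps = range(base - 1, base + 3)
        elif kernel == "linear":
            taps = range(base, base + 2)
        else:
            raise ValueError(f"unknown kernel {kernel!r}")
        for t in taps:
            if kernel == "cubic":
                w = float(cubic_kernel(np.array([pos - t]))[0])
            else:
                w = max(0.0, 1.0 - abs(pos - t))
            mat[i, min(max(t, 0), n_in - 1)] += w
    return mat


def resize_2d(img: np.ndarray, out_shape: tuple[int, int],
              kernel: str = "cubic") -> np.ndarray:
    """Resample a 2-D array to ``out_shape`` with the separable kernel."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"resize_2d expects a 2-D array, got ndim={img.ndim}")
    Ar = resample_matrix(img.shape[0], out_shape[0], kernel)
    Ac = resample_matrix(img.shape[1], out_shape[1], kernel)
    return Ar @ img @ Ac.T


def downscale_2d(img: np.ndarray, scale: int, kernel: str = "cubic") -> np.ndarray:
    """Downscale a 2-D array by an integer factor to ceil(dim/scale)."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"downscale_2d expects a 2-D array, got ndim={img.ndim}")
    out_shape = (ceil(img.shape[0] / scale), ceil(img.shape[1] / scale))
    return resize_2d(img, out_shape, kernel)
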