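"""Denoising stage: median filtering followed by non-local means.

The median filter suppresses impulse noise; the non-local means (NLM) filter
averages pixels whose surrounding patches look alike, which smooths Gaussian
noise while preserving the fibre/space boundaries.  The combination is applied
in the fixed order median -> NLM.

The NLM here is the classic pixelwise estimator: for pixel ``p`` the output is

    u(p) = sum_q w(p,q) v(q) / sum_q w(p,q),   q in the search window,
    w(p,q) = exp(-d2(p,q) / h^2),

where ``d2`` is the mean squared difference between the uniform patches around
``p`` and ``q`` and ``h`` sets the decay of the patch-similarity weights.  It
is implemented with shifted-image algebra (one box filter per search offset),
which makes its limits exactly checkable: a constant image is a fixed point,
and as ``h -> inf`` the output tends to the plain search-window mean.
By default NLM runs slice-by-slice (2D) on the stack; a full 3D variant is
available.  Both filters use reflective edge padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import Volume

__all__ = ["DenoiseParams", "median_filter", "nlm_filter", "denoise", "estimate_noise_sigma"]


@dataclass(frozen=True)
class DenoiseParams:
    """Parameters of the median -> NLM denoising chain.

    ``nlm_h`` may be a number (grey levels) or ``"auto"``, in which case it is
    set to ``0.8 x`` the estimated noise standard deviation of the volume.
    """

    median_radius: int = 1
    nlm_patch: int = 5
    nlm_search: int = 11
    nlm_h: float | str = "auto"
    nlm_3d: bool = False

    def validate(self) -> None:
        if self.median_radius < 1:
            raise ValueError("median_radius must be >= 1")
        if self.nlm_patch < 1 or self.nlm_search < 1:
            raise ValueError("NLM window sizes must be >= 1")
        if self.nlm_patch % 2 == 0 or self.nlm_search % 2 == 0:
            raise ValueError("NLM windows must be odd-sized")
        if self.nlm_patch > self.nlm_search:
            raise ValueError("nlm_patch must not exceed nlm_search")
        if not (self.nlm_h == "auto" or float(self.nlm_h) > 0):
            raise ValueError("nlm_h must be positive or 'auto'")


def median_filter(vol: Volume | np.ndarray, radius: int = 1) -> Volume | np.ndarray:
    """Cubic-window median filter with reflective edge padding."""
    if radius < 1:
        raise ValueError(f"radius must be >= 1; got {radius}")
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
    out = ndimage.median_filter(data, size=2 * int(radius) + 1, mode="reflect")
    return vol.like(out) if isinstance(vol, Volume) else out


def _nlm(
    img: np.ndarray, patch: int, search: int, h: float, sigma: float, axes: tuple[int, ...]
) -> np.ndarray:
    """Classic NLM via shifted-image box filtering.

    ``axes`` are the axes the search window and patches extend over; other
    axes are carried along vectorised (so a stack is filtered slice-wise in a
    single pass).  ``sigma`` enables the standard noise compensation
    ``w = exp(-max(d2 - 2 sigma^2, 0)/h^2)``; with ``sigma = 0`` the kernel is
    the plain ``exp(-d2/h^2)``.
    """
    img = np.asarray(img, dtype=np.float32)
    s = (search - 1) // 2
    pad_width = [(s, s) if ax in axes else (0, 0) for ax in range(img.ndim)]
    pad = np.pad(img, pad_width, mode="reflect")
    size = [patch if ax in axes else 1 for ax in range(img.ndim)]
    acc = np.zeros_like(img)
    wsum = np.zeros_like(img)
    inv_h2 = np.float32(1.0 / (h * h))
    two_sigma2 = np.float32(2.0 * sigma * sigma)
    for offset in np.ndindex(*([search] * len(axes))):
        sl = [slice(None)] * img.ndim
        for ax, o in zip(axes, offset):
            sl[ax] = slice(o, o + img.shape[ax])
        shifted = pad[tuple(sl)]
        d2 = ndimage.uniform_filter((img - shifted) ** 2, size=size, mode="reflect")
        np.subtract(d2, two_sigma2, out=d2)
        np.maximum(d2, 0.0, out=d2)
        np.multiply(d2, -inv_h2, out=d2)
        w = np.exp(d2, out=d2)
        acc += w * shifted
        wsum += w
    return acc / wsum


def nlm_filter(
    vol: Volume | np.ndarray,
    patch: int = 5,
    search: int = 11,
    h: float = 10.0,
    sigma: float = 0.0,
    three_d: bool = False,
) -> Volume | np.ndarray:
    """Non-local-means filter; 2D slice-by-slice on stacks by default."""
    if patch > search:
        raise ValueError("patch must not exceed search window")
    if patch < 1 or patch % 2 == 0 or search % 2 == 0:
        raise ValueError("patch and search must be odd and >= 1")
    if h <= 0:
        raise ValueError("h must be positive")
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
    if data.ndim == 2:
        axes: tuple[int, ...] = (0, 1)
    elif three_d:
        axes = (0, 1, 2)
    else:
        axes = (1, 2)
    out = _nlm(data, patch, search, h, sigma, axes).astype(np.float32)
    return vol.like(out) if isinstance(vol, Volume) else out


def estimate_noise_sigma(vol: Volume | np.ndarray) -> float:
    """Wavelet-based noise sd estimate (median slice of a stack)."""
    from skimage.restoration import estimate_sigma

    data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
    sl = data[data.shape[0] // 2] if data.ndim == 3 else data
    return float(estimate_sigma(sl.astype(np.float64)))


def denoise(vol: Volume, params: DenoiseParams | None = None) -> Volume:
    """Median then non-local means; returns a volume of identical geometry."""
    params = params or DenoiseParams()
    params.validate()
    out = median_filter(vol, params.median_radius)
    sigma = estimate_noise_sigma(out)
    h = params.nlm_h
    if h == "auto":
        h = max(0.8 * sigma, 1e-3)
    return nlm_filter(
        out, params.nlm_patch, params.nlm_search, float(h), sigma=sigma, three_d=params.nlm_3d
    )
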