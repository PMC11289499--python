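"""Shared FFT conventions and small frequency-domain helpers.

Package-wide conventions (documented once, used everywhere):

* Frequencies are in cycles/μm (not rad/μm).
* All public arrays — pupils, PSFs, OTFs, separated bands — are
  **zero-centered**: the real-space origin / zero-frequency sample sits at
  index ``n // 2`` along each axis.  Transforms shift internally.
* Real space -> frequency space uses the forward FFT, frequency -> real the
  inverse FFT, both with orthonormal (``norm="ortho"``) scaling so that
  Parseval's theorem holds exactly.
* Volumes are stored numpy-style ``(z, y, x)``; 2D pupil-plane arrays are
  ``(kz, kx)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "fft_centered",
    "ifft_centered",
    "freq_axis",
    "hermitian_conjugate",
    "block_downsample",
]


def fft_centered(arr: np.ndarray, axes=None) -> np.ndarray:
    """Forward FFT of a zero-centered array, returning a zero-centered spectrum."""
    return np.fft.fftshift(
        np.fft.fftn(np.fft.ifftshift(arr, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def ifft_centered(arr: np.ndarray, axes=None) -> np.ndarray:
    """Inverse of :func:`fft_centered`."""
    return np.fft.fftshift(
        np.fft.ifftn(np.fft.ifftshift(arr, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def freq_axis(n: int, step: float) -> np.ndarray:
    """Centered frequency axis (cycles/μm) for ``n`` samples of size ``step`` μm."""
    return np.fft.fftshift(np.fft.fftfreq(n, d=step))


def hermitian_conjugate(arr: np.ndarray, axes=None) -> np.ndarray:
    """Return ``conj(arr(-k))`` for a zero-centered spectrum.

    For even-length axes the sample at −Nyquist is its own mirror partner.
    """
    if axes is None:
        axes = range(arr.ndim)
    out = np.conj(arr)
    for ax in axes:
        out = np.roll(np.flip(out, axis=ax), 1, axis=ax)
    return out


def block_downsample(arr: np.ndarray, factor: int, axes=None) -> np.ndarray:
    """Block-mean downsample by ``factor`` along ``axes`` (camera pixel binning)."""
    if factor == 1:
        return arr
    if axes is None:
        axes = range(arr.ndim)
    out = arr
    for ax in axes:
        n = out.shape[ax]
        if n % factor:
            raise ValueError(f"axis {ax} length {n} not divisible by {factor}")
        shape = list(out.shape)
        shape[ax] = n // factor
        shape.insert(ax + 1, factor)
        out = out.reshape(shape).mean(axis=ax + 1)
    return out
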