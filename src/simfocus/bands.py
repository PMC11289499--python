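"""Separating phase-stepped stacks into lateral-order spectra and shifting bands.

Each phase image mixes the lateral orders through the matrix
``M[j, m] = exp(i·m·φ_j)``.  For five equally spaced phases M is a scaled
DFT matrix (condition number 1) and the separation is exact.  Separated
bands are returned unshifted (centered at kx = 0, as acquired); moving a
band to its true lateral position is a spectrum translation by m·p along kx
performed by real-space modulation (subsample-accurate; an exact roll when
the shift is an integer number of frequency samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from ._fft import fft_centered, ifft_centered
from .errors import RetrievalError, SeparationError
from .forward import RawSIMStack, TransferFunctionSet, default_phases

__all__ = [
    "SeparatedBands",
    "separate_orders",
    "remix_orders",
    "shift_band",
    "PatternFrequencyEstimate",
    "estimate_pattern_frequency",
]


@dataclass
class SeparatedBands:
    """Per-order complex spectra D̃_m(k), zero-centered, unshifted."""

    bands: Dict[int, np.ndarray]
    p_used: Optional[float]       # lateral fundamental used downstream (cycles/μm)
    dk_x: float
    phases: Tuple[float, ...]
    meta: dict = field(default_factory=dict)

    @property
    def m_range(self) -> Tuple[int, ...]:
        return tuple(sorted(self.bands))


def _mixing_matrix(phases: Sequence[float], orders: Sequence[int]) -> np.ndarray:
    return np.exp(1j * np.outer(phases, orders))


def separate_orders(
    stack: RawSIMStack,
    phases: Optional[Sequence[float]] = None,
    orders: Sequence[int] = (-2, -1, 0, 1, 2),
    p_used: Optional[float] = None,
) -> SeparatedBands:
    """Unmix the phase-stepped stack into per-order spectra.

    ``phases`` defaults to the stack's recorded phase list (or 2πj/n).  The
    per-voxel linear system is solved with the (pseudo)inverse of the mixing
    matrix; duplicate phases make it rank deficient and raise.
    """
    if phases is None:
        phases = stack.meta.get("phases", default_phases(stack.n_phases))
    phases = tuple(phases)
    if len(phases) != stack.n_phases:
        raise SeparationError("number of phases does not match the stack")
    if len(phases) < len(orders):
        raise SeparationError("need at least as many phases as lateral orders")
    M = _mixing_matrix(phases, orders)
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e8:
        raise SeparationError(f"phase-step mixing matrix is ill-conditioned (cond={cond:.3g})")
    Minv = np.linalg.pinv(M)
    spectra = np.stack([fft_centered(stack.values[j].astype(np.float64)) for j in range(stack.n_phases)])
    coeffs = np.tensordot(Minv, spectra, axes=(1, 0))
    bands = {m: coeffs[i] for i, m in enumerate(orders)}
    nx = stack.values.shape[-1]
    return SeparatedBands(
        bands=bands,
        p_used=p_used,
        dk_x=1.0 / (nx * stack.voxel_xy),
        phases=phases,
        meta=dict(stack.meta),
    )


def remix_orders(bands: SeparatedBands) -> np.ndarray:
    """Inverse of :func:`separate_orders`: per-phase spectra from the bands."""
    orders = bands.m_range
    M = _mixing_matrix(bands.phases, orders)
    stackspec = np.stack([bands.bands[m] for m in orders])
    return np.tensordot(M, stackspec, axes=(1, 0))


def shift_band(band: np.ndarray, shift: float, dk_x: float) -> np.ndarray:
    """Return the spectrum evaluated at ``k + shift·x̂`` (translation along kx)."""
    if shift == 0:
        return band
    nx = band.shape[-1]
    nyquist = nx // 2 * dk_x
    if abs(shift) > nyquist:
        raise RetrievalError("requested band shift exceeds the lateral Nyquist frequency")
    steps = shift / dk_x
    if abs(steps - round(steps)) < 1e-9:
        return np.roll(band, -round(steps), axis=-1)
    x = (np.arange(nx) - nx // 2) / (nx * dk_x)
    mod = np.exp(-2j * np.pi * shift * x)
    real_space = ifft_centered(band, axes=(-1,))
    return fft_centered(real_space * mod, axes=(-1,))


@dataclass
class PatternFrequencyEstimate:
    p_hat: float
    candidates: np.ndarray
    scores: np.ndarray
    low_confidence: bool


def estimate_pattern_frequency(
    bands: SeparatedBands,
    tf: TransferFunctionSet,
    p_center: float,
    *,
    pair: Tuple[int, int] = (0, 1),
    half_width_rel: float = 0.03,
    n_candidates: int = 25,
    mask_threshold: float = 1e-3,
) -> PatternFrequencyEstimate:
    """Refine the lateral pattern frequency by overlap cross-correlation.

    For each candidate p, the order-``m2`` band and transfer function are
    shifted by the corresponding m·p and the normalized cross-correlation
    magnitude between D̃_m1·O'_m2 and D̃_m2·O'_m1 over the overlap support is
    evaluated; the argmax is returned.  A flat or empty correlation surface
    raises the ``low_confidence`` flag.
    """
    m1, m2 = pair
    d1 = bands.bands[m1]
    d2 = bands.bands[m2]
    o1 = tf.get(m1)
    o2 = tf.get(m2)
    candidates = p_center * np.linspace(1 - half_width_rel, 1 + half_width_rel, n_candidates)
    scores = np.zeros(n_candidates)
    for i, p in enumerate(candidates):
        d1s = shift_band(d1, m1 * p, bands.dk_x)
        o1s = shift_band(o1, m1 * p, bands.dk_x)
        d2s = shift_band(d2, m2 * p, bands.dk_x)
        o2s = shift_band(o2, m2 * p, bands.dk_x)
        num = d1s * o2s
        den = d2s * o1s
        w = np.abs(o1s) * np.abs(o2s)
        mask = w > mask_threshold * w.max() if w.max() > 0 else np.zeros_like(w, bool)
        if not mask.any():
            continue
        a = num[mask]
        b = den[mask]
        na = np.linalg.norm(a)
        nb = np.linalg.norm(b)
        if na > 0 and nb > 0:
            scores[i] = np.abs(np.vdot(b, a)) / (na * nb)
    smax = scores.max()
    low_conf = smax <= 0 or (smax - scores.min()) < 1e-3 * max(smax, 1e-30)
    p_hat = float(candidates[np.argmax(scores)]) if smax > 0 else float(p_center)
    return PatternFrequencyEstimate(p_hat, candidates, scores, low_conf)
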