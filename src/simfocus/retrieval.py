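"""Axial/lateral offset retrieval from the residual phase of band overlaps.

The method: after band separation, the sample spectrum is common to every
lateral order, so the ratio

    R_{m1,m2}(k) = [D̃_m1(k+m1·p)·O'_m2(k+m2·p)] / [D̃_m2(k+m2·p)·O'_m1(k+m1·p)]

cancels the sample and leaves only phase contributed by the mismatch between
the axial offset δz present during acquisition and the offset δz' of the
calibration transfer functions, plus a constant (m1−m2)·φ from the lateral
starting phase.  For every library entry δz' and lateral-phase candidate φ
we score the magnitude-weighted circular deviation of that residual phase,

    Φ(δz', φ) = Σ_k w(k)·(1 − cos(arg R(k) − (m1−m2)·φ)) / Σ_k w(k),

summed over the order pairs (0,1) and (1,2).  The metric vanishes exactly
when δz' = δz and φ matches; its minimum over the 2D (δz', φ) map is the
offset estimate.  A second local minimum always exists half an axial period
away (δz + T_z/2, φ ± π) because shifting the pattern by half a period flips
the sign of every odd axial harmonic; the lateral search is therefore
restricted to (−π/2, π/2] by default, and both minima plus their metric gap
(ambiguity ratio) are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .bands import SeparatedBands, separate_orders, shift_band
from .errors import RetrievalError
from .forward import RawSIMStack, TFLibrary, TransferFunctionSet

__all__ = [
    "OverlapRatioField",
    "ResidualPhaseMap",
    "OffsetEstimate",
    "overlap_support",
    "compute_overlap_ratio",
    "residual_phase_metric",
    "build_residual_phase_map",
    "find_minimum",
    "retrieve_offset",
    "default_phi_grid",
]

DEFAULT_PAIRS: Tuple[Tuple[int, int], ...] = ((0, 1), (1, 2))


@dataclass
class OverlapRatioField:
    """Regularized overlap ratio R on its support mask, with weights."""

    ratio: np.ndarray          # complex; arg(ratio) is the residual phase
    mask: np.ndarray           # bool support
    weights: np.ndarray        # |O'_m1|·|O'_m2| on the mask, 0 elsewhere
    pair: Tuple[int, int]

    def phase_concentration(self) -> complex:
        """Weighted circular mean of exp(i·arg R) over the support."""
        w = self.weights[self.mask]
        r = self.ratio[self.mask]
        mag = np.abs(r)
        unit = np.where(mag > 0, r / np.where(mag > 0, mag, 1.0), 0.0)
        wsum = w.sum()
        if wsum == 0:
            raise RetrievalError("overlap support has zero total weight")
        return complex(np.sum(w * unit) / wsum)


@dataclass
class ResidualPhaseMap:
    """Summed residual-phase metric over (δz' grid, φ candidates)."""

    metric: np.ndarray         # (n_dz, n_phi), >= 0
    dz_um: np.ndarray
    dz_pi: np.ndarray
    phi_grid: np.ndarray
    pairs_used: Tuple[Tuple[int, int], ...]


@dataclass
class OffsetEstimate:
    dz_um: float
    dz_pi: float
    phi_rad: float
    metric_at_min: float
    secondary_min: Optional[dict]
    ambiguity_ratio: float
    search_range_lateral: Tuple[float, float]
    degenerate: bool = False
    map: Optional[ResidualPhaseMap] = field(default=None, repr=False)


def default_phi_grid(n: int = 64) -> np.ndarray:
    """``n`` lateral-phase candidates spanning (−π, π]."""
    return -np.pi + 2.0 * np.pi * (np.arange(n) + 1) / n


def overlap_support(
    tf1: np.ndarray, tf2: np.ndarray, rel_threshold: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Support mask and weights where both (already shifted) TFs carry signal."""
    prod = np.abs(tf1) * np.abs(tf2)
    peak = prod.max()
    if peak == 0:
        raise RetrievalError("transfer functions have no joint support")
    mask = prod >= rel_threshold * peak if rel_threshold > 0 else prod > 0
    if not mask.any():
        raise RetrievalError("overlap support is empty at this threshold")
    weights = np.where(mask, prod, 0.0)
    return mask, weights


def compute_overlap_ratio(
    bands: SeparatedBands,
    tfset: TransferFunctionSet,
    pair: Tuple[int, int],
    p: float,
    *,
    mask_threshold: float = 1e-3,
    eps: float = 1e-6,
) -> OverlapRatioField:
    """Sample-cancelling overlap ratio for one order pair.

    The ratio is evaluated as ``N·conj(D) / (|D|² + ε·max|D|²)`` so that its
    phase (the quantity the metric consumes) is ``arg(N·conj(D))`` and the
    division cannot blow up at the support edge.
    """
    m1, m2 = pair
    if m1 == m2:
        raise RetrievalError("overlap ratio requires two distinct orders")
    b1 = shift_band(bands.bands[m1], m1 * p, bands.dk_x)
    b2 = shift_band(bands.bands[m2], m2 * p, bands.dk_x)
    o1 = shift_band(tfset.get(m1), m1 * p, bands.dk_x)
    o2 = shift_band(tfset.get(m2), m2 * p, bands.dk_x)
    mask, weights = overlap_support(o1, o2, mask_threshold)
    num = b1 * o2
    den = b2 * o1
    dmax2 = np.max(np.abs(den[mask]) ** 2)
    if dmax2 == 0:
        raise RetrievalError("denominator vanishes over the whole overlap support")
    ratio = np.zeros_like(num)
    ratio[mask] = num[mask] * np.conj(den[mask]) / (np.abs(den[mask]) ** 2 + eps * dmax2)
    return OverlapRatioField(ratio=ratio, mask=mask, weights=weights, pair=pair)


def residual_phase_metric(R: OverlapRatioField, phi_candidate: float) -> float:
    """Weighted circular deviation of arg R from the candidate's constant term."""
    dm = R.pair[0] - R.pair[1]
    z = R.phase_concentration()
    return float(1.0 - (z * np.exp(-1j * dm * phi_candidate)).real)


def build_residual_phase_map(
    bands: SeparatedBands,
    library: TFLibrary,
    phi_grid: Optional[np.ndarray] = None,
    pairs: Tuple[Tuple[int, int], ...] = DEFAULT_PAIRS,
    *,
    p: Optional[float] = None,
    mask_threshold: float = 1e-3,
) -> ResidualPhaseMap:
    """Metric surface over every library offset and lateral-phase candidate.

    Pairs contribute with equal weight.  ``p`` defaults to the library
    geometry's grid-snapped lateral fundamental.
    """
    if len(library) == 0:
        raise RetrievalError("transfer-function library is empty")
    if phi_grid is None:
        phi_grid = default_phi_grid()
    phi_grid = np.asarray(phi_grid, dtype=float)
    if p is None:
        p = bands.p_used if bands.p_used is not None else library.geometry.p_grid
    metric = np.zeros((len(library), phi_grid.size))
    for i, entry in enumerate(library.entries):
        acc = np.zeros(phi_grid.size)
        for pair in pairs:
            R = compute_overlap_ratio(bands, entry, pair, p, mask_threshold=mask_threshold)
            z = R.phase_concentration()
            dm = pair[0] - pair[1]
            acc += 1.0 - (z * np.exp(-1j * dm * phi_grid)).real
        metric[i] = acc / len(pairs)
    return ResidualPhaseMap(
        metric=metric,
        dz_um=library.dz_um,
        dz_pi=library.dz_pi,
        phi_grid=phi_grid,
        pairs_used=tuple(pairs),
    )


def _masked_min(metric: np.ndarray, dz_um: np.ndarray, col_mask: np.ndarray):
    """Grid minimum over allowed φ columns; ties broken toward smaller |dz|."""
    sub = metric[:, col_mask]
    mmin = sub.min()
    rows, cols = np.nonzero(sub <= mmin + 1e-15)
    if len(rows) > 1:
        order = np.lexsort((np.abs(dz_um[rows]),))
        if not np.allclose(np.abs(dz_um[rows]), np.abs(dz_um[rows[order[0]]])):
            warnings.warn("tied metric minima; breaking tie toward smaller |dz|")
        rows, cols = rows[order], cols[order]
    col_idx = np.nonzero(col_mask)[0]
    return int(rows[0]), int(col_idx[cols[0]]), float(mmin)


def find_minimum(
    pmap: ResidualPhaseMap,
    lateral_range: Tuple[float, float] = (-np.pi / 2, np.pi / 2),
    *,
    refine: bool = False,
) -> OffsetEstimate:
    """Locate the metric minimum with φ restricted to ``lateral_range``.

    The unrestricted complementary minimum (the half-period-off twin) is
    reported as ``secondary_min`` together with the ambiguity ratio: the
    metric gap between the two minima normalized by the full map range.
    """
    if not np.all(np.isfinite(pmap.metric)):
        raise RetrievalError("residual-phase map contains non-finite values")
    lo, hi = lateral_range
    allowed = (pmap.phi_grid > lo) & (pmap.phi_grid <= hi)
    if not allowed.any():
        raise RetrievalError("lateral search range contains no φ candidates")
    map_range = float(pmap.metric.max() - pmap.metric.min())
    degenerate = map_range < 1e-12
    i, j, m0 = _masked_min(pmap.metric, pmap.dz_um, allowed)

    secondary = None
    ambiguity = 0.0
    if (~allowed).any():
        i2, j2, m2 = _masked_min(pmap.metric, pmap.dz_um, ~allowed)
        secondary = {
            "dz_um": float(pmap.dz_um[i2]),
            "dz_pi": float(pmap.dz_pi[i2]),
            "phi_rad": float(pmap.phi_grid[j2]),
            "metric": m2,
        }
        if not degenerate:
            ambiguity = (m2 - m0) / map_range

    dz_um = float(pmap.dz_um[i])
    dz_pi = float(pmap.dz_pi[i])
    if refine and 0 < i < len(pmap.dz_um) - 1:
        y0, y1, y2 = pmap.metric[i - 1, j], pmap.metric[i, j], pmap.metric[i + 1, j]
        denom = y0 - 2 * y1 + y2
        if denom > 0:
            delta = 0.5 * (y0 - y2) / denom
            dz_um = dz_um + delta * (pmap.dz_um[i + 1] - pmap.dz_um[i])
            dz_pi = dz_pi + delta * (pmap.dz_pi[i + 1] - pmap.dz_pi[i])
    if degenerate:
        warnings.warn("residual-phase map is flat; estimate is degenerate")
    return OffsetEstimate(
        dz_um=dz_um,
        dz_pi=dz_pi,
        phi_rad=float(pmap.phi_grid[j]),
        metric_at_min=m0,
        secondary_min=secondary,
        ambiguity_ratio=float(ambiguity),
        search_range_lateral=(float(lo), float(hi)),
        degenerate=degenerate,
        map=pmap,
    )


def retrieve_offset(
    stack: RawSIMStack,
    library: TFLibrary,
    *,
    phi_grid: Optional[np.ndarray] = None,
    pairs: Tuple[Tuple[int, int], ...] = DEFAULT_PAIRS,
    lateral_range: Tuple[float, float] = (-np.pi / 2, np.pi / 2),
    mask_threshold: float = 1e-3,
    refine: bool = False,
    check_hash: bool = True,
) -> OffsetEstimate:
    """End-to-end retrieval: separate -> overlap ratios -> 2D map -> minimum."""
    stack_hash = stack.meta.get("config_hash")
    if check_hash and stack_hash is not None and stack_hash != library.config_hash:
        raise RetrievalError(
            "stack and transfer-function library were produced under different "
            f"optical configurations ({stack_hash} vs {library.config_hash})"
        )
    bands = separate_orders(stack, p_used=library.geometry.p_grid)
    pmap = build_residual_phase_map(
        bands, library, phi_grid=phi_grid, pairs=pairs, mask_threshold=mask_threshold
    )
    return find_minimum(pmap, lateral_range, refine=refine)
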