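"""Local writhe maps and profiles of discretized curves.

The segment-to-segment (StS) writhe ``w_StS(x, y)`` is the Gauss linking
density of a curve with itself, resolved per pair of polygonal segments:
each entry is the signed solid angle spanned by segments ``x`` and ``y``
divided by 4*pi (the Klenin--Langowski skew-quadrilateral formula), so
that the full pair sum equals twice the global writhe Wr.  The
segment-to-all (StA) writhe ``w_StA(x)`` is the contour sum of
``w_StS(x, y)`` over ``y``, optionally window-smoothed; it measures how
geometrically entangled segment ``x`` is with the whole curve, with sign
encoding chirality (right-handed crossings positive).

Consecutive polygonal segments are coplanar and contribute exactly zero
to the Gauss integral, so the exclusion band (default: self and nearest
neighbours) removes only singular/ill-defined algebra, not writhe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np

from .conformation import InvalidGeometryError, RingConformation

__all__ = [
    "WritheMap",
    "WritheProfile",
    "sts_writhe",
    "sta_writhe",
    "global_writhe",
    "total_curvature",
    "local_curvature_profile",
    "local_density_profile",
    "smooth_profile",
]


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@numba.njit(cache=False, fastmath=False)
def _pair_solid_angle(p1, p2, q1, q2):
    """Signed Gauss-integral contribution of segment pair (p1p2, q1q2).

    Exact solid angle of the skew quadrilateral, divided by 4*pi, with
    sign from the right-hand rule (right-handed crossings positive).
    """
    r12 = p2 - p1
    r34 = q2 - q1
    r13 = q1 - p1
    r14 = q2 - p1
    r23 = q1 - p2
    r24 = q2 - p2

    n1 = np.cross(r13, r14)
    n2 = np.cross(r14, r24)
    n3 = np.cross(r24, r23)
    n4 = np.cross(r23, r13)

    a1 = np.sqrt(n1[0] ** 2 + n1[1] ** 2 + n1[2] ** 2)
    a2 = np.sqrt(n2[0] ** 2 + n2[1] ** 2 + n2[2] ** 2)
    a3 = np.sqrt(n3[0] ** 2 + n3[1] ** 2 + n3[2] ** 2)
    a4 = np.sqrt(n4[0] ** 2 + n4[1] ** 2 + n4[2] ** 2)
    if a1 < 1e-12 or a2 < 1e-12 or a3 < 1e-12 or a4 < 1e-12:
        return 0.0  # coplanar / touching pair: zero Gauss contribution
    n1 = n1 / a1
    n2 = n2 / a2
    n3 = n3 / a3
    n4 = n4 / a4

    s = 0.0
    for d in (
        n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2],
        n2[0] * n3[0] + n2[1] * n3[1] + n2[2] * n3[2],
        n3[0] * n4[0] + n3[1] * n4[1] + n3[2] * n4[2],
        n4[0] * n1[0] + n4[1] * n1[1] + n4[2] * n1[2],
    ):
        if d > 1.0:
            d = 1.0
        elif d < -1.0:
            d = -1.0
        s += np.arcsin(d)

    # Both traversal orders (x, y) and (y, x) contribute equally to the
    # Gauss double integral, so the per-entry normalization is 1/(2*pi):
    # summing the full (symmetric) map then equals twice the writhe.
    c = np.cross(r34, r12)
    sign = c[0] * r13[0] + c[1] * r13[1] + c[2] * r13[2]
    if sign > 0.0:
        return s / (2.0 * np.pi)
    elif sign < 0.0:
        return -s / (2.0 * np.pi)
    return 0.0


@numba.njit(cache=False)
def _sts_matrix(pos, closed, exclusion):
    n_beads = pos.shape[0]
    m = n_beads if closed else n_beads - 1
    out = np.zeros((m, m))
    for i in range(m):
        i2 = (i + 1) % n_beads
        for j in range(i + 1, m):
            if closed:
                d = j - i
                if d > m - d:
                    d = m - d
            else:
                d = j - i
            if d < exclusion:
                continue
            j2 = (j + 1) % n_beads
            w = _pair_solid_angle(pos[i], pos[i2], pos[j], pos[j2])
            out[i, j] = w
            out[j, i] = w
    return out


@numba.njit(cache=False)
def _density_counts(pos, radius):
    n = pos.shape[0]
    out = np.zeros(n)
    r2 = radius * radius
    for i in range(n):
        c = 0
        for j in range(n):
            if i == j:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if dx * dx + dy * dy + dz * dz <= r2:
                c += 1
        out[i] = c
    return out


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class WritheMap:
    """N x N StS writhe matrix with its window and exclusion metadata."""

    values: np.ndarray
    window_length: float
    exclusion_band: int

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class WritheProfile:
    """Length-N StA writhe profile."""

    values: np.ndarray
    window_length: float
    signed: bool

    @property
    def n(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def _validated(curve: RingConformation) -> np.ndarray:
    lengths = curve.bond_lengths()
    if np.any(lengths < 1e-9):
        raise InvalidGeometryError("coincident consecutive beads")
    return curve.positions


def smooth_profile(values: np.ndarray, window_beads: int, periodic: bool) -> np.ndarray:
    """Centred moving average of odd width ``2*(window_beads//2) + 1``.

    Periodic for rings; truncated (partial windows renormalized) at the
    ends of open chains.
    """
    half = max(int(window_beads) // 2, 0)
    if half == 0:
        return np.asarray(values, dtype=float).copy()
    v = np.asarray(values, dtype=float)
    n = v.shape[0]
    kernel = np.ones(2 * half + 1)
    if periodic:
        padded = np.concatenate([v[-half:], v, v[:half]])
        return np.convolve(padded, kernel / kernel.size, mode="valid")
    smoothed = np.convolve(v, kernel, mode="same")
    norm = np.convolve(np.ones(n), kernel, mode="same")
    return smoothed / norm


def _window_beads(curve: RingConformation, window: float) -> int:
    return max(int(round(window / curve.bead_spacing_target)), 1)


def smooth_map(values: np.ndarray, window_beads: int,
               periodic: bool = True) -> np.ndarray:
    """Separable centred moving average of a square map (both indices).

    The periodic 2D box filter commutes with row summation, so the
    row sums of the smoothed map equal the smoothed row sums of the raw
    map — the smoothed StS map stays consistent with the StA profile.
    """
    from scipy.ndimage import uniform_filter
    half = max(int(window_beads) // 2, 0)
    if half == 0:
        return np.asarray(values, dtype=float).copy()
    size = 2 * half + 1
    mode = "wrap" if periodic else "nearest"
    return uniform_filter(np.asarray(values, dtype=float), size=size, mode=mode)


def sts_writhe(curve: RingConformation, window: float = 10.0,
               exclusion: int = 2) -> WritheMap:
    """Segment-to-segment writhe map of a curve.

    Parameters
    ----------
    curve
        Closed or open discretized curve.
    window
        Window length ``l_w`` in sigma recorded on the map (StA smoothing
        is applied when profiles are derived, not to the raw map).
    exclusion
        Number of neighbouring segment indices (each side, including
        self) whose entries are fixed at zero.
    """
    if exclusion < 1:
        raise ValueError("exclusion must be >= 1")
    m = curve.n_segments
    if exclusion >= m // 2:
        raise ValueError(f"exclusion {exclusion} too large for {m} segments")
    if window < curve.bead_spacing_target:
        raise ValueError("window must be at least one bead spacing")
    pos = _validated(curve)
    values = _sts_matrix(pos, curve.closed, exclusion)
    return WritheMap(values, float(window), int(exclusion))


def sta_writhe(curve: RingConformation, window: float = 10.0,
               signed: bool = True, exclusion: int = 2) -> WritheProfile:
    """Segment-to-all writhe profile (contour sum of the StS map, smoothed).

    For ``signed=False`` the absolute values of pairwise contributions are
    summed before smoothing; chirality information is discarded.
    """
    wmap = sts_writhe(curve, window=window, exclusion=exclusion)
    raw = np.abs(wmap.values).sum(axis=1) if not signed else wmap.values.sum(axis=1)
    smoothed = smooth_profile(raw, _window_beads(curve, window), periodic=curve.closed)
    return WritheProfile(smoothed, float(window), bool(signed))


def raw_sta(curve: RingConformation, exclusion: int = 2) -> np.ndarray:
    """Unsmoothed signed StA vector; its half-sum is the global writhe."""
    wmap = sts_writhe(curve, window=curve.bead_spacing_target, exclusion=exclusion)
    return wmap.values.sum(axis=1)


def global_writhe(curve: RingConformation) -> float:
    """Global writhe Wr of a closed curve, in turns.

    Equals half the sum of the unsmoothed signed StA vector: the pair sum
    of the StS map is normalized to ``2 * Wr``.
    """
    if not curve.closed:
        raise ValueError("global writhe is defined for closed curves; close the chain first")
    return 0.5 * float(raw_sta(curve).sum())


def total_curvature(curve: RingConformation) -> float:
    """Total absolute curvature: sum of exterior turning angles, radians.

    For any non-trivially knotted closed curve this exceeds 4*pi
    (Fary--Milnor); a convex planar polygon gives exactly 2*pi.
    """
    _validated(curve)
    t = curve.tangents()
    if curve.closed:
        t_next = np.roll(t, -1, axis=0)
    else:
        t_next = t[1:]
        t = t[:-1]
    dots = np.clip((t * t_next).sum(axis=1), -1.0, 1.0)
    return float(np.arccos(dots).sum())


def local_curvature_profile(curve: RingConformation) -> np.ndarray:
    """Per-bead turning angle per unit contour length.

    Bead ``x`` reports the angle between segments ``x-1`` and ``x``
    divided by the bead spacing; end beads of open chains report zero.
    """
    _validated(curve)
    t = curve.tangents()
    n = curve.n_beads
    out = np.zeros(n)
    if curve.closed:
        dots = np.clip((np.roll(t, 1, axis=0) * t).sum(axis=1), -1.0, 1.0)
        out[:] = np.arccos(dots)
    else:
        dots = np.clip((t[:-1] * t[1:]).sum(axis=1), -1.0, 1.0)
        out[1:-1] = np.arccos(dots)
    return out / curve.bead_spacing_target


def local_density_profile(curve: RingConformation, radius: float = 2.0) -> np.ndarray:
    """Fraction of beads within ``radius`` of each bead (self excluded)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    pos = _validated(curve)
    return _density_counts(pos, float(radius)) / curve.n_beads
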