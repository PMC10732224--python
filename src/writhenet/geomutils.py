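"""Small geometry helpers shared by the atlas builder and fixtures."""

from __future__ import annotations

import numpy as np

__all__ = ["resample_closed", "resample_open", "min_nonadjacent_distance"]


def _cumlen(points: np.ndarray, closed: bool) -> np.ndarray:
    if closed:
        seg = np.linalg.norm(np.roll(points, -1, axis=0) - points, axis=1)
    else:
        seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polygon to ``n`` vertices equally spaced in arc length.

    Chord lengths of the result are nearly equal (exactly equal arc-length
    spacing along the input polygon); a few rounds of spacing relaxation
    even out residual chord variation.
    """
    points = np.asarray(points, dtype=float)
    cl = _cumlen(points, closed=True)
    total = cl[-1]
    ext = np.vstack([points, points[:1]])
    targets = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 3))
    for k, s in enumerate(targets):
        i = np.searchsorted(cl, s, side="right") - 1
        i = min(i, len(points) - 1)
        span = cl[i + 1] - cl[i]
        f = 0.0 if span <= 0 else (s - cl[i]) / span
        out[k] = (1 - f) * ext[i] + f * ext[i + 1]
    # even out chord lengths
    for _ in range(12):
        seg = np.roll(out, -1, axis=0) - out
        lens = np.linalg.norm(seg, axis=1)
        if lens.max() - lens.min() < 1e-3 * lens.mean():
            break
        out = _respace_once(out)
    return out


def _respace_once(out: np.ndarray) -> np.ndarray:
    cl = _cumlen(out, closed=True)
    total = cl[-1]
    ext = np.vstack([out, out[:1]])
    n = out.shape[0]
    targets = np.linspace(0.0, total, n, endpoint=False)
    idx = np.clip(np.searchsorted(cl, targets, side="right") - 1, 0, n - 1)
    span = cl[idx + 1] - cl[idx]
    f = np.where(span > 0, (targets - cl[idx]) / np.where(span > 0, span, 1.0), 0.0)
    return (1 - f)[:, None] * ext[idx] + f[:, None] * ext[idx + 1]


def resample_open(points: np.ndarray, n: int) -> np.ndarray:
    """Resample an open polyline to ``n`` vertices equally spaced in arc length."""
    points = np.asarray(points, dtype=float)
    cl = _cumlen(points, closed=False)
    targets = np.linspace(0.0, cl[-1], n)
    out = np.empty((n, 3))
    for k, s in enumerate(targets):
        i = np.clip(np.searchsorted(cl, s, side="right") - 1, 0, len(points) - 2)
        span = cl[i + 1] - cl[i]
        f = 0.0 if span <= 0 else (s - cl[i]) / span
        out[k] = (1 - f) * points[i] + f * points[i + 1]
    return out


def min_nonadjacent_distance(points: np.ndarray, closed: bool = True,
                             skip: int = 2) -> float:
    """Minimum distance between beads more than ``skip`` apart along the chain."""
    n = len(points)
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    idx = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    if closed:
        idx = np.minimum(idx, n - idx)
    d[idx <= skip] = np.inf
    return float(d.min())
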