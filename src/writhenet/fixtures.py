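"""Deterministic tiny curves for tests and examples."""

from __future__ import annotations

import numpy as np

from .conformation import RingConformation
from .geomutils import resample_closed, resample_open

__all__ = ["fixture_generator", "circle", "regular_polygon", "parametric_knot",
           "tight_trefoil_in_loop", "open_trefoil_arc"]


def circle(n: int = 100) -> RingConformation:
    """Planar circle with unit bead spacing."""
    s = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = 1.0 / (2 * np.sin(np.pi / n))  # chord length exactly 1
    pos = np.column_stack([r * np.cos(s), r * np.sin(s), np.zeros(n)])
    return RingConformation(pos, closed=True, bead_spacing_target=1.0)


def regular_polygon(n: int) -> RingConformation:
    """Regular planar n-gon (total turning angle exactly 2*pi)."""
    return circle(max(n, 12))


_PARAMETRIC = {
    "3_1": lambda s: np.column_stack([(2 + np.cos(3 * s)) * np.cos(2 * s),
                                      (2 + np.cos(3 * s)) * np.sin(2 * s),
                                      -np.sin(3 * s)]),
    "4_1": lambda s: np.column_stack([(2 + np.cos(2 * s)) * np.cos(3 * s),
                                      (2 + np.cos(2 * s)) * np.sin(3 * s),
                                      np.sin(4 * s)]),
    "5_1": lambda s: np.column_stack([(2 + np.cos(5 * s)) * np.cos(2 * s),
                                      (2 + np.cos(5 * s)) * np.sin(2 * s),
                                      -np.sin(5 * s)]),
}


def parametric_knot(name: str, n: int = 200) -> RingConformation:
    """Smooth torus-curve embedding resampled to n beads, unit spacing."""
    fn = _PARAMETRIC[name]
    s = np.linspace(0, 2 * np.pi, 3000, endpoint=False)
    pos = resample_closed(fn(s), n)
    lengths = np.linalg.norm(np.roll(pos, -1, axis=0) - pos, axis=1)
    pos = pos / lengths.mean()
    return RingConformation(pos, closed=True, bead_spacing_target=1.0)


def open_trefoil_arc(n: int = 60) -> RingConformation:
    """Open chain tracing a trefoil with well-separated termini."""
    s = np.linspace(0.25, 2 * np.pi - 0.25, 3000)
    pts = _PARAMETRIC["3_1"](s)
    pos = resample_open(pts, n)
    lengths = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    pos = pos / lengths.mean()
    return RingConformation(pos, closed=False, bead_spacing_target=1.0)


def tight_trefoil_in_loop(n: int = 100, start: int = 10,
                          end: int = 40) -> RingConformation:
    """Tight trefoil occupying beads [start, end] of an otherwise planar loop.

    The knotted part is a verified trefoil seed embedding cut open at
    its most exposed bead, so the arc genuinely carries the knot; the
    localisation oracle's ground-truth mask should sit on (about) these
    beads.
    """
    from .atlas import seed_embedding

    arc_beads = end - start + 1
    ring = seed_embedding("3_1", arc_beads + 1).conformation.positions
    # cut at the most exposed bead (max distance from centroid)
    cut = int(np.argmax(np.linalg.norm(ring - ring.mean(axis=0), axis=1)))
    knot = np.roll(ring, -cut - 1, axis=0)[:arc_beads]  # open arc
    a, b = knot[-1], knot[0]
    centroid = knot.mean(axis=0)
    # return loop through waypoints well clear of the knot body
    loop_beads = n - arc_beads
    away = (a + b) / 2 - centroid
    away = away / max(np.linalg.norm(away), 1e-9)
    radius = max(loop_beads / np.pi * 0.45, 8.0)
    centre = centroid + away * (np.linalg.norm(knot - centroid, axis=1).max() + 3.0)
    perp = np.cross(away, np.array([0.0, 0.0, 1.0]))
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(away, np.array([0.0, 1.0, 0.0]))
    perp = perp / np.linalg.norm(perp)
    waypoints = np.vstack([
        a,
        centre + perp * radius,
        centre + away * radius * 1.3,
        centre - perp * radius,
        b,
    ])
    ret = resample_open(waypoints, loop_beads + 2)[1:-1]
    pos = np.vstack([knot, ret])
    pos = np.roll(pos, start, axis=0)
    return RingConformation(pos, closed=True, bead_spacing_target=1.0,
                            validate=False)


_REGISTRY = {
    "circle": circle,
    "ngon": regular_polygon,
    "parametric_31": lambda n=200: parametric_knot("3_1", n),
    "parametric_41": lambda n=200: parametric_knot("4_1", n),
    "parametric_51": lambda n=250: parametric_knot("5_1", n),
    "tight_31_in_loop": tight_trefoil_in_loop,
    "open_trefoil": open_trefoil_arc,
}


def fixture_generator(name: str, *args, **kwargs) -> RingConformation:
    """Deterministic fixture curves by name (see module registry)."""
    if name not in _REGISTRY:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(_REGISTRY)}")
    return _REGISTRY[name](*args, **kwargs)
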