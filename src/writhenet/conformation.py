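"""Discretized polymer curves.

A :class:`RingConformation` holds the ordered bead positions of a closed
(ring) or open polymer curve, with bead spacing measured in units of the
bead diameter sigma.  Segment ``x`` runs from bead ``x`` to bead ``x+1``
(modulo ``N`` for rings), and the tangent at segment ``x`` is the unit
vector along that bond.  All geometric observables in
:mod:`writhenet.writhe` are defined on these segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RingConformation", "InvalidGeometryError"]

#: Kremer-Grest-style tolerance on bond lengths relative to the target spacing.
BOND_RANGE = (0.8, 1.2)


class InvalidGeometryError(ValueError):
    """Raised for degenerate or inconsistent curve geometry."""


@dataclass
class RingConformation:
    """Ordered 3D bead positions of a discretized curve.

    Parameters
    ----------
    positions
        ``(N, 3)`` array of bead positions, in units of sigma.
    closed
        Whether the curve is a ring (bond between bead ``N-1`` and bead 0).
    bead_spacing_target
        Nominal bond length in sigma.  Ring bonds must lie within
        ``[0.8, 1.2]`` times this value.
    """

    positions: np.ndarray
    closed: bool = True
    bead_spacing_target: float = 1.0
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise InvalidGeometryError("positions must be an (N, 3) array")
        if self.validate:
            self._check_invariants()

    # -- invariants -----------------------------------------------------

    def _check_invariants(self) -> None:
        if not np.all(np.isfinite(self.positions)):
            raise InvalidGeometryError("non-finite coordinates")
        if self.n_beads < 12:
            raise InvalidGeometryError(f"need at least 12 beads, got {self.n_beads}")
        lengths = self.bond_lengths()
        if np.any(lengths < 1e-9):
            raise InvalidGeometryError("coincident consecutive beads")
        if self.closed:
            lo, hi = BOND_RANGE
            t = self.bead_spacing_target
            if lengths.min() < lo * t or lengths.max() > hi * t:
                raise InvalidGeometryError(
                    "ring bond lengths outside "
                    f"[{lo * t:.3g}, {hi * t:.3g}]: "
                    f"range [{lengths.min():.3g}, {lengths.max():.3g}]"
                )

    # -- accessors ------------------------------------------------------

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def n_segments(self) -> int:
        return self.n_beads if self.closed else self.n_beads - 1

    def bonds(self) -> np.ndarray:
        """Bond vectors, one per segment."""
        if self.closed:
            return np.roll(self.positions, -1, axis=0) - self.positions
        return np.diff(self.positions, axis=0)

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.bonds(), axis=1)

    def tangents(self) -> np.ndarray:
        """Unit tangents, one per segment."""
        b = self.bonds()
        return b / np.linalg.norm(b, axis=1, keepdims=True)

    def r(self, x: int) -> np.ndarray:
        """Position of bead ``x`` (modular for rings)."""
        return self.positions[x % self.n_beads if self.closed else x]

    def t(self, x: int) -> np.ndarray:
        """Unit tangent at segment ``x`` (modular for rings)."""
        return self.tangents()[x % self.n_segments if self.closed else x]

    # -- transforms -----------------------------------------------------

    def mirror(self) -> "RingConformation":
        """Mirror image (z -> -z); reverses chirality."""
        p = self.positions.copy()
        p[:, 2] *= -1.0
        return RingConformation(p, self.closed, self.bead_spacing_target)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "RingConformation":
        p = self.positions
        if rotation is not None:
            p = p @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            p = p + np.asarray(translation, dtype=float)
        return RingConformation(p, self.closed, self.bead_spacing_target)

    def centred(self) -> "RingConformation":
        """Centre-of-mass-corrected copy."""
        return self.transformed(translation=-self.positions.mean(axis=0))

    def canonicalized(self) -> "RingConformation":
        """Centred, principal axes aligned with x >= y >= z variance."""
        p = self.positions - self.positions.mean(axis=0)
        cov = p.T @ p
        w, v = np.linalg.eigh(cov)
        v = v[:, ::-1]  # descending variance
        if np.linalg.det(v) < 0:  # keep a proper rotation: no chirality flip
            v[:, 2] *= -1.0
        return RingConformation(p @ v, self.closed, self.bead_spacing_target)

    def radius_of_gyration(self) -> float:
        p = self.positions - self.positions.mean(axis=0)
        return float(np.sqrt((p ** 2).sum(axis=1).mean()))
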