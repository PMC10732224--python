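"""Shared fixtures: parametric curves, small thermal ensembles, oracles."""

from __future__ import annotations

import numpy as np
import pytest

from writhenet import RingConformation
from writhenet.experiments import FIVE_KNOTS, generate_ensembles
from writhenet.geomutils import resample_closed


# ---------------------------------------------------------------------------
# parametric curves
# ---------------------------------------------------------------------------

def _parametric(fn, n):
    s = np.linspace(0, 2 * np.pi, 3000, endpoint=False)
    pos = resample_closed(fn(s), n)
    lengths = np.linalg.norm(np.roll(pos, -1, axis=0) - pos, axis=1)
    return RingConformation(pos, True, float(lengths.mean()))


def trefoil_curve(s):
    return np.column_stack([(2 + np.cos(3 * s)) * np.cos(2 * s),
                            (2 + np.cos(3 * s)) * np.sin(2 * s),
                            np.sin(3 * s)])


def figure_eight_curve(s):
    return np.column_stack([(2 + np.cos(2 * s)) * np.cos(3 * s),
                            (2 + np.cos(2 * s)) * np.sin(3 * s),
                            np.sin(4 * s)])


def gentle_unknot_curve(s):
    # low-torsion non-planar unknot: polygonal writhe converges fast
    return np.column_stack([(3 + 0.3 * np.cos(2 * s)) * np.cos(s),
                            (3 + 0.3 * np.cos(2 * s)) * np.sin(s),
                            0.5 * np.sin(2 * s)])


def wiggly_unknot_curve(s):
    return np.column_stack([np.cos(s) * (3 + 0.5 * np.sin(7 * s)),
                            np.sin(s) * (3 + 0.4 * np.cos(5 * s)),
                            0.6 * np.sin(9 * s)])


@pytest.fixture(scope="session")
def trefoil200():
    return _parametric(trefoil_curve, 200)


@pytest.fixture(scope="session")
def trefoil400():
    return _parametric(trefoil_curve, 400)


@pytest.fixture(scope="session")
def figure_eight200():
    return _parametric(figure_eight_curve, 200)


@pytest.fixture(scope="session")
def wiggly_unknot150():
    return _parametric(wiggly_unknot_curve, 150)


# ---------------------------------------------------------------------------
# independent quadrature oracle for the writhe of smooth parametric curves
# ---------------------------------------------------------------------------

def gauss_writhe_quadrature(fn, n_grid: int = 1200) -> float:
    """Dense double-trapezoid evaluation of the Gauss writhe integral."""
    s = np.linspace(0, 2 * np.pi, n_grid, endpoint=False)
    r = fn(s)
    dr = (fn(s + 1e-6) - fn(s - 1e-6)) / 2e-6
    diff = r[:, None, :] - r[None, :, :]
    d3 = np.linalg.norm(diff, axis=-1) ** 3
    num = (np.cross(dr[:, None, :], dr[None, :, :]) * diff).sum(-1)
    np.fill_diagonal(d3, np.inf)
    h = 2 * np.pi / n_grid
    return float((num / d3).sum() * h * h / (4 * np.pi))


@pytest.fixture(scope="session")
def quadrature_oracle():
    return gauss_writhe_quadrature


# ---------------------------------------------------------------------------
# thermal ensembles (shared across the suite; generation is the slow part)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def five_knot_ensembles():
    """160 audited conformations per class for the 5 simplest knots."""
    return generate_ensembles(FIVE_KNOTS, 160, n_beads=100, seed=101)


@pytest.fixture(scope="session")
def figure_eight_ensemble_500(five_knot_ensembles):
    """>= 500 thermalized 4_1 conformations (extends the shared ensemble)."""
    extra = generate_ensembles(["4_1"], 340, n_beads=100, seed=102)
    return five_knot_ensembles["4_1"] + extra["4_1"]


@pytest.fixture(scope="session")
def trefoil_ensemble(five_knot_ensembles):
    return five_knot_ensembles["3_1"]
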