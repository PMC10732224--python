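"""Knot atlas: named knot types and verified seed embeddings.

The atlas enumerates the unknot, all 249 prime knots up to 10 crossings
(Rolfsen naming: 1, 1, 2, 3, 7, 21, 49, 165 knots at 3..10 crossings),
the square/granny composites and the Conway / Kinoshita--Terasaka
11-crossing mutant pair.  Seed embeddings — closed polygonal curves with
unit bead spacing, verified by the topology oracle — are constructed for
the subset backed by packaged recipes:

* parametric torus curves (3_1, 5_1, 7_1, 8_19, 10_124);
* rational (2-bridge) knots from Conway notation, realized as 3D
  tangle closures (all remaining knots to 7 crossings);
* pretzel curves (8_20);
* connected sums (square = 3_1^l # 3_1^r, granny = 3_1^l # 3_1^l);
* packaged fixture curves for the 11-crossing mutants, regenerable with
  ``scripts/build_mutant_fixtures.py``.

Entries without a packaged recipe (8-, 9- and most 10-crossing primes)
carry their name and crossing number only; requesting a seed raises
``ConstructionError``.  Rational reference determinants come from the
continued fraction (independent of the oracle); every constructed seed
must reproduce its reference ``|Delta(-1)|`` or construction fails.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .conformation import RingConformation
from .geomutils import resample_closed, min_nonadjacent_distance
from .oracle import classify_by_determinant
from .tangles import (continued_fraction, inflate, pretzel_curve,
                      rational_curve, smooth)

__all__ = ["KnotClass", "SeedEmbedding", "ConstructionError", "atlas_table",
           "seed_embedding", "connected_sum", "get_entry", "constructible_names"]


class ConstructionError(RuntimeError):
    """Seed construction failed or no recipe is packaged for the knot."""


@dataclass(frozen=True)
class KnotClass:
    """Topological label: Rolfsen-style name, chirality, composite factors."""

    name: str
    chirality: str = "unspecified"  # left / right / achiral / unspecified
    factors: tuple = ()

    @property
    def is_composite(self) -> bool:
        return len(self.factors) > 0


@dataclass
class SeedEmbedding:
    """Verified initial conformation for a named knot type."""

    knot: KnotClass
    conformation: RingConformation
    provenance: str  # parametric / tangle_closure / composite_sum / fixture_file
    reference_det1: int | None = None
    reference_det2: int | None = None


@dataclass(frozen=True)
class AtlasEntry:
    name: str
    crossing_number: int
    det1: int | None = None
    det2: int | None = None
    conway: tuple = ()
    construction: str | None = None
    chirality: str = "unspecified"
    factors: tuple = ()


# ---------------------------------------------------------------------------
# roster and recipes
# ---------------------------------------------------------------------------

_PRIME_COUNTS = {3: 1, 4: 1, 5: 2, 6: 3, 7: 7, 8: 21, 9: 49, 10: 165}

#: Conway notation for every rational knot up to 7 crossings.
_CONWAY = {
    "3_1": (3,), "4_1": (2, 2), "5_1": (5,), "5_2": (3, 2),
    "6_1": (4, 2), "6_2": (3, 1, 2), "6_3": (2, 1, 1, 2),
    "7_1": (7,), "7_2": (5, 2), "7_3": (4, 3), "7_4": (3, 1, 3),
    # 7_5 uses the equivalent fraction 17/5 (b(17,5) = b(17,7), 5*7 = 1 mod 17):
    # the 17/7 realization coarsens badly
    "7_5": (2, 2, 3), "7_6": (2, 2, 1, 2), "7_7": (2, 1, 1, 1, 2),
}

_TORUS = {"3_1": (2, 3), "5_1": (2, 5), "7_1": (2, 7),
          "8_19": (3, 4), "10_124": (3, 5)}

_PRETZEL = {"8_20": (3, -3, 2)}

# |Delta(-1)| of the torus/pretzel entries (Delta_{T(p,q)} evaluations)
_SPECIAL_DET1 = {"8_19": 3, "8_20": 9, "10_124": 1}

_MUTANT_FILES = {"K11n34": "k11_mutant_a.xyz", "K11n42": "k11_mutant_b.xyz"}


def _roster() -> list[AtlasEntry]:
    entries = [AtlasEntry("0_1", 0, det1=1, det2=1, construction="parametric",
                          chirality="achiral")]
    for c, count in _PRIME_COUNTS.items():
        for i in range(1, count + 1):
            name = f"{c}_{i}"
            conway = _CONWAY.get(name, ())
            det1 = det2 = None
            kind = None
            if conway:
                det1 = continued_fraction(list(conway))[0]
                kind = "tangle_closure"
            if name in _TORUS:
                kind = "parametric"
                det1 = det1 if det1 is not None else _SPECIAL_DET1.get(name)
            if name in _PRETZEL:
                p = _PRETZEL[name]
                det1 = abs(p[0] * p[1] + p[1] * p[2] + p[2] * p[0])
                kind = "tangle_closure"
            entries.append(AtlasEntry(name, c, det1=det1, det2=det2,
                                      conway=conway, construction=kind))
    entries.append(AtlasEntry("square", 6, det1=9, det2=49,
                              construction="composite_sum",
                              factors=("3_1^l", "3_1^r"), chirality="achiral"))
    entries.append(AtlasEntry("granny", 6, det1=9, det2=49,
                              construction="composite_sum",
                              factors=("3_1^l", "3_1^l"), chirality="left"))
    for name in _MUTANT_FILES:
        entries.append(AtlasEntry(name, 11, det1=1, det2=1,
                                  construction="fixture_file"))
    return entries


@functools.lru_cache(maxsize=1)
def atlas_table() -> tuple:
    """All atlas entries: unknot + 249 primes to 10 crossings + composites
    + the two 11-crossing mutants."""
    return tuple(_roster())


@functools.lru_cache(maxsize=None)
def get_entry(name: str) -> AtlasEntry:
    for e in atlas_table():
        if e.name == name:
            return e
    raise ConstructionError(f"unknown knot name {name!r}")


def constructible_names() -> list[str]:
    """Names with a packaged construction recipe, by crossing number."""
    return [e.name for e in atlas_table() if e.construction is not None]


_MUTANT_DIAGRAMS = {"K11n34": "k11_mutant_a_diagram.json",
                    "K11n42": "k11_mutant_b_diagram.json"}


def mutant_diagram(name: str):
    """Certified minimal (11-crossing) diagram of a packaged mutant.

    Returns ``(CrossingDiagram, metadata)``; the metadata records the
    plat word the embedding was built from and the stored homomorphism
    counts (recomputable with :func:`writhenet.grouprep.count_homomorphisms`).
    """
    import json

    from .oracle import CrossingDiagram

    if name not in _MUTANT_DIAGRAMS:
        raise ConstructionError(f"no packaged diagram for {name!r}")
    ref = resources.files("writhenet.data") / _MUTANT_DIAGRAMS[name]
    meta = json.loads(ref.read_text())
    k = meta["n_crossings"]
    events = meta["events"]
    signs = np.array(meta["signs"], dtype=np.int64)
    event_crossing = np.array([c for c, _ in events], dtype=int)
    event_is_over = np.array([o for _, o in events], dtype=bool)
    over = np.full(k, -1, dtype=int)
    under = np.full(k, -1, dtype=int)
    for idx, (c, o) in enumerate(events):
        if o:
            over[c] = idx
        else:
            under[c] = idx
    crossings = [(int(over[c]), int(under[c]), int(signs[c])) for c in range(k)]
    diag = CrossingDiagram(k, crossings, event_crossing, event_is_over,
                           generic=True, signs=signs)
    return diag, meta


# ---------------------------------------------------------------------------
# raw curve recipes
# ---------------------------------------------------------------------------

def _torus_curve(p: int, q: int, n_points: int = 2000) -> np.ndarray:
    s = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    r = 2.0 + np.cos(q * s)
    return np.column_stack([r * np.cos(p * s), r * np.sin(p * s), -np.sin(q * s)])


def _circle(n_points: int = 400) -> np.ndarray:
    s = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    return np.column_stack([np.cos(s), np.sin(s), np.zeros_like(s)])


def _raw_curve(name: str) -> np.ndarray:
    if name == "0_1":
        return _circle()
    if name in _TORUS:
        return _torus_curve(*_TORUS[name])
    if name in _PRETZEL:
        return pretzel_curve(list(_PRETZEL[name]))
    entry = get_entry(name)
    if entry.conway:
        return rational_curve(list(entry.conway))
    if name in _MUTANT_FILES:
        from .io import read_xyz
        ref = resources.files("writhenet.data") / _MUTANT_FILES[name]
        with resources.as_file(ref) as path:
            frames = read_xyz(path, validate=False)
        return frames[0][0].positions
    raise ConstructionError(
        f"no construction recipe packaged for {name!r} "
        f"(atlas lists it by name only)")


# ---------------------------------------------------------------------------
# embedding pipeline: fine resample -> unit bonds -> staged coarsening
# ---------------------------------------------------------------------------

def _unit_bond(points: np.ndarray, n: int) -> np.ndarray:
    p = resample_closed(points, n)
    lengths = np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1)
    return p / lengths.mean()


def _coarsen_verified(points: np.ndarray, n_target: int, det_ref: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Stepwise coarsening with re-inflation and determinant checks."""
    cur = points
    while cur.shape[0] > n_target:
        # unit bonds: bead-pair floors below ~0.71 sigma cannot exclude
        # segment passage, so floors stay high and the oracle re-checks
        # the determinant after every stage (retrying gentler if needed)
        for ratio, lam, sweeps in ((1.15, 0.2, 40), (1.08, 0.08, 25),
                                   (1.04, 0.03, 12), (1.02, 0.01, 6)):
            n_next = max(int(cur.shape[0] / ratio), n_target)
            cand = smooth(cur, lam=lam, floor=0.8, sweeps=sweeps)
            cand, _ = inflate(cand, target=1.3, floor=0.75)
            cand = _unit_bond(cand, n_next)
            cand, clearance = inflate(cand, target=1.05, floor=0.75)
            if clearance < 1.0:
                continue
            conf = RingConformation(cand, closed=True, bead_spacing_target=1.0,
                                    validate=False)
            det = classify_by_determinant(conf, n_directions=5, rng=rng,
                                          fast=True).det1
            if det == det_ref:
                break
        else:
            raise ConstructionError(
                f"coarsening below {cur.shape[0]} beads kept breaking "
                f"|Delta(-1)| = {det_ref}")
        cur = cand
    return cur


def _embed(points: np.ndarray, n_beads: int, det_ref: int,
           seed: int = 2718) -> np.ndarray:
    # fine stage: enough beads that unit-bond scaling gives wide clearance
    seg = np.linalg.norm(np.roll(points, -1, axis=0) - points, axis=1).sum()
    clearance_raw = min_nonadjacent_distance(
        resample_closed(points, max(3 * n_beads, 240)), True, 3)
    n_fine = int(np.ceil(2.5 * seg / max(clearance_raw, 1e-6)))
    n_fine = max(n_fine, 2 * n_beads)
    fine = _unit_bond(points, n_fine)
    fine, clearance = inflate(fine, target=1.05, floor=0.5)
    if clearance < 1.0:
        raise ConstructionError("could not open the fine embedding")
    conf = RingConformation(fine, closed=True, bead_spacing_target=1.0,
                            validate=False)
    last_err = None
    for attempt in range(4):  # deterministic ladder of relaxation streams
        rng = np.random.default_rng(seed + attempt)
        det = classify_by_determinant(conf, n_directions=3, rng=rng,
                                      fast=True).det1
        if det != det_ref:
            raise ConstructionError(
                f"fine embedding has |Delta(-1)| {det}, reference {det_ref}")
        try:
            return _coarsen_verified(fine, n_beads, det_ref, rng)
        except ConstructionError as err:
            last_err = err
    raise last_err


def _canonical(points: np.ndarray) -> np.ndarray:
    conf = RingConformation(points, closed=True, bead_spacing_target=1.0,
                            validate=False).canonicalized()
    return conf.positions


@functools.lru_cache(maxsize=64)
def _seed_cached(name: str, n_beads: int) -> tuple:
    entry = get_entry(name)
    if entry.construction is None:
        raise ConstructionError(f"no packaged construction for {name!r}")
    min_beads = max(8 * max(entry.crossing_number, 1), 12)
    if n_beads < min_beads:
        raise ConstructionError(
            f"{name} needs at least {min_beads} beads "
            f"({entry.crossing_number} crossings at >= 8 beads/crossing)")
    if entry.construction == "composite_sum":
        return _composite_seed(entry, n_beads)
    raw = _raw_curve(name)
    det_ref = entry.det1
    pos = _embed(raw, n_beads, det_ref)
    pos = _canonical(pos)
    conf = RingConformation(pos, closed=True, bead_spacing_target=1.0)
    # final verification incl. |Delta(-2)| where a reference is known
    label = classify_by_determinant(conf, n_directions=3,
                                    rng=np.random.default_rng(99))
    if label.det1 != det_ref:
        raise ConstructionError(f"{name}: verification failed ({label})")
    if entry.det2 is not None and label.det2 != entry.det2:
        raise ConstructionError(f"{name}: |Delta(-2)| {label.det2} != {entry.det2}")
    return (pos, entry.construction, det_ref, label.det2)


def seed_embedding(knot: str | KnotClass, n_beads: int) -> SeedEmbedding:
    """Deterministic, oracle-verified seed embedding of a named knot.

    The embedding is canonicalized (centred, principal axes aligned),
    has unit bead spacing and non-adjacent clearance >= 1 sigma, ready
    for the thermal sampler.
    """
    name = knot.name if isinstance(knot, KnotClass) else str(knot)
    pos, provenance, det1, det2 = _seed_cached(name, int(n_beads))
    entry = get_entry(name)
    kc = KnotClass(name, chirality=entry.chirality, factors=entry.factors)
    conf = RingConformation(pos.copy(), closed=True, bead_spacing_target=1.0)
    return SeedEmbedding(kc, conf, provenance, det1, det2)


# ---------------------------------------------------------------------------
# connected sums
# ---------------------------------------------------------------------------

def _splice(a: np.ndarray, b: np.ndarray, gap: float = 3.0) -> np.ndarray:
    """Cut-and-splice two rings along facing, nearly parallel strands."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    ia = int(np.argmax(a[:, 0]))
    ib = int(np.argmin(b[:, 0]))
    shift = np.array([a[:, 0].max() - b[:, 0].min() + gap, 0.0, 0.0])
    # align the cut bonds roughly side by side in y/z
    shift[1] = a[ia, 1] - b[ib, 1]
    shift[2] = a[ia, 2] - b[ib, 2]
    b = b + shift
    a_roll = np.roll(a, -(ia + 1), axis=0)   # a_roll[-1] = a[ia]
    b_roll = np.roll(b, -(ib + 1), axis=0)   # b_roll[-1] = b[ib]

    def bridge(p, q):
        d = np.linalg.norm(q - p)
        k = max(int(round(d)), 1)
        ts = np.linspace(0, 1, k + 1)[1:-1]
        return p + ts[:, None] * (q - p)

    out = np.vstack([
        a_roll,
        bridge(a_roll[-1], b_roll[0]),
        b_roll,
        bridge(b_roll[-1], a_roll[0]),
    ])
    return out


def _composite_seed(entry: AtlasEntry, n_beads: int) -> tuple:
    half = max(n_beads // 2, 50)
    base = seed_embedding("3_1", half).conformation.positions
    if entry.name == "square":
        other = RingConformation(base, validate=False).mirror().positions
    else:
        other = base.copy()
    det_ref = entry.det1
    last_err = None
    for orientation in (1, -1):
        o = other if orientation == 1 else other[::-1].copy()
        try:
            spliced = _splice(base, o)
            pos = _embed(spliced, n_beads, det_ref)
            pos = _canonical(pos)
            conf = RingConformation(pos, closed=True, bead_spacing_target=1.0)
            label = classify_by_determinant(conf, n_directions=3,
                                            rng=np.random.default_rng(98))
            if label.det1 == det_ref and (entry.det2 is None or
                                          label.det2 == entry.det2):
                return (pos, "composite_sum", det_ref, label.det2)
            last_err = ConstructionError(f"{entry.name}: got {label}")
        except ConstructionError as err:
            last_err = err
    raise last_err


def connected_sum(a: SeedEmbedding, b: SeedEmbedding,
                  n_beads: int | None = None) -> SeedEmbedding:
    """Connected sum of two seed embeddings, verified multiplicative.

    ``|Delta(-1)|`` of the result must equal the product of the factor
    determinants (Alexander polynomials multiply under connected sum).
    """
    if not (a.conformation.closed and b.conformation.closed):
        raise ValueError("connected sum needs closed embeddings")
    n_beads = n_beads or (a.conformation.n_beads + b.conformation.n_beads)
    det_ref = (a.reference_det1 or 1) * (b.reference_det1 or 1)
    last_err = None
    for orientation in (1, -1):
        pb = b.conformation.positions
        pb = pb if orientation == 1 else pb[::-1].copy()
        try:
            spliced = _splice(a.conformation.positions.copy(), pb.copy())
            pos = _canonical(_embed(spliced, n_beads, det_ref))
            conf = RingConformation(pos, closed=True, bead_spacing_target=1.0)
            label = classify_by_determinant(conf, n_directions=3,
                                            rng=np.random.default_rng(97))
            if label.det1 == det_ref:
                kc = KnotClass(f"{a.knot.name}#{b.knot.name}",
                               factors=(a.knot.name, b.knot.name))
                return SeedEmbedding(kc, conf, "composite_sum", det_ref, label.det2)
            last_err = ConstructionError(
                f"connected sum determinant {label.det1}, expected {det_ref}")
        except ConstructionError as err:
            last_err = err
    raise last_err
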