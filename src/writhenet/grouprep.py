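"""Counting knot-group homomorphisms into small finite groups.

The number of homomorphisms from a knot group (Wirtinger presentation
read off a crossing diagram) into a fixed finite group is a knot
invariant: different counts certify different knots.  This is the tool
that separates the two packaged 11-crossing mutants — they share every
polynomial invariant this package computes, but their groups admit
different numbers of homomorphisms into PSL(2, 7).

Counting enumerates images for a small seed set of arcs (chosen so
constraint propagation along the under-strand relations determines the
rest) with a numba kernel; group multiplication tables are built once
per group.
"""

from __future__ import annotations

import functools
from itertools import permutations

import numba
import numpy as np

__all__ = ["count_homomorphisms", "GROUPS"]

GROUPS = ("S4", "A5", "S5", "PSL27")


def _parity(p) -> int:
    n = len(p)
    seen = [False] * n
    par = 0
    for i in range(n):
        if seen[i]:
            continue
        j = i
        c = 0
        while not seen[j]:
            seen[j] = True
            j = p[j]
            c += 1
        par ^= (c - 1) & 1
    return par


def _psl27_elements():
    """PSL(2,7) as fractional-linear permutations of the projective
    line over F7 (8 points)."""
    pts = list(range(7)) + ["inf"]
    idx = {p: i for i, p in enumerate(pts)}
    perms = set()
    for a in range(7):
        for b in range(7):
            for c in range(7):
                for d in range(7):
                    if (a * d - b * c) % 7 != 1:
                        continue
                    im = []
                    for p in pts:
                        if p == "inf":
                            q = "inf" if c == 0 else (a * pow(c, 5, 7)) % 7
                        else:
                            num = (a * p + b) % 7
                            den = (c * p + d) % 7
                            q = "inf" if den == 0 else (num * pow(den, 5, 7)) % 7
                        im.append(idx[q])
                    perms.add(tuple(im))
    return sorted(perms)


@functools.lru_cache(maxsize=None)
def _group_tables(name: str):
    if name == "S4":
        els = list(permutations(range(4)))
    elif name == "A5":
        els = [p for p in permutations(range(5)) if _parity(p) == 0]
    elif name == "S5":
        els = list(permutations(range(5)))
    elif name == "PSL27":
        els = _psl27_elements()
    else:
        raise ValueError(f"unknown group {name!r}; choose from {GROUPS}")
    index = {p: i for i, p in enumerate(els)}
    n = len(els)
    mul = np.empty((n, n), dtype=np.int64)
    inv = np.empty(n, dtype=np.int64)
    for i, p in enumerate(els):
        ip = tuple(int(x) for x in np.argsort(p))
        inv[i] = index[ip]
        for j, q in enumerate(els):
            mul[i, j] = index[tuple(p[q[k]] for k in range(len(q)))]
    return mul, inv


def _seed_set_once(rels, k, order):
    seeds = []
    known = [False] * k
    while True:
        changed = True
        while changed:
            changed = False
            for (o, i, j, s) in rels:
                if known[o] and known[i] and not known[j]:
                    known[j] = True
                    changed = True
                if known[o] and known[j] and not known[i]:
                    known[i] = True  # the relation is invertible in x_in
                    changed = True
        if all(known):
            return seeds
        scores = [0] * k
        for (o, i, j, s) in rels:
            for a in (o, i, j):
                if not known[a]:
                    scores[a] += 1
        best = max(order, key=lambda a: (not known[a], scores[a]))
        seeds.append(best)
        known[best] = True


def _seed_set(rels, k, restarts: int = 40):
    import random
    rng = random.Random(0)
    order = list(range(k))
    best = None
    for _ in range(restarts):
        s = _seed_set_once(rels, k, order)
        if best is None or len(s) < len(best):
            best = s
        rng.shuffle(order)
    return best


@numba.njit(cache=False)
def _count_kernel(mul, inv, rels, seeds, k, n_el):
    m = rels.shape[0]
    n_seeds = seeds.shape[0]
    total = 1
    for _ in range(n_seeds):
        total *= n_el
    assign = np.empty(k, dtype=np.int64)
    count = 0
    for t in range(total):
        tt = t
        for q in range(k):
            assign[q] = -1
        for q in range(n_seeds):
            assign[seeds[q]] = tt % n_el
            tt //= n_el
        ok = True
        changed = True
        while changed and ok:
            changed = False
            for r in range(m):
                o = rels[r, 0]
                i = rels[r, 1]
                j = rels[r, 2]
                s = rels[r, 3]
                go = assign[o]
                if go < 0:
                    continue
                if assign[i] >= 0:
                    if s > 0:
                        val = mul[mul[go, assign[i]], inv[go]]
                    else:
                        val = mul[mul[inv[go], assign[i]], go]
                    if assign[j] < 0:
                        assign[j] = val
                        changed = True
                    elif assign[j] != val:
                        ok = False
                        break
                elif assign[j] >= 0:
                    if s > 0:
                        val = mul[mul[inv[go], assign[j]], go]
                    else:
                        val = mul[mul[go, assign[j]], inv[go]]
                    assign[i] = val
                    changed = True
        if not ok:
            continue
        full = True
        for q in range(k):
            if assign[q] < 0:
                full = False
                break
        if not full:
            continue
        good = True
        for r in range(m):
            o = rels[r, 0]
            i = rels[r, 1]
            j = rels[r, 2]
            s = rels[r, 3]
            if s > 0:
                val = mul[mul[assign[o], assign[i]], inv[assign[o]]]
            else:
                val = mul[mul[inv[assign[o]], assign[i]], assign[o]]
            if val != assign[j]:
                good = False
                break
        if good:
            count += 1
    return count


def count_homomorphisms(diagram, group: str = "A5") -> int:
    """Number of homomorphisms of the diagram's knot group into ``group``.

    Includes the |G| abelian (cyclic-image) homomorphisms; only
    differences between knots matter.  Cost grows as |G|^(seed-set
    size); diagrams with few crossings (after simplification) are
    strongly preferred.
    """
    from .oracle import _arc_structure
    mul, inv = _group_tables(group)
    rels_list = _arc_structure(diagram)
    k = diagram.n_crossings
    if k == 0:
        return mul.shape[0]
    seeds = _seed_set(rels_list, k)
    return int(_count_kernel(mul, inv,
                             np.array(rels_list, dtype=np.int64),
                             np.array(seeds, dtype=np.int64), k,
                             mul.shape[0]))
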