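"""3D tangle algebra for constructing knot embeddings.

Conway's tangle calculus realized directly as 3D polylines: an integer
tangle is a horizontal double helix of half-twists, ``rotate`` turns a
tangle by 90 degrees in the projection plane (turning ``n`` into the
vertical tangle ``1/n``), ``tangle_sum`` places tangles side by side,
and the numerator closure joins the top and bottom port pairs.  Because
over/under information lives in the z offsets and every operation
preserves them, the planar diagram of the assembled curve is the
intended one by construction; the topology oracle re-verifies every
embedding anyway.

Rational knots C(a1, ..., ak) are built by the continued-fraction
recursion T -> int(a_i) + 1/T, pretzels P(p, q, r, ...) as the closure
of a sum of vertical twist tangles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba
import numpy as np

__all__ = [
    "Tangle",
    "integer_tangle",
    "rotate_tangle",
    "tangle_sum",
    "numerator_closure",
    "rational_curve",
    "pretzel_curve",
    "continued_fraction",
    "inflate",
]

# port ids
NW, NE, SW, SE = 0, 1, 2, 3


@dataclass
class Tangle:
    """Two-string tangle: open strands in a box with 4 corner ports."""

    strands: list  # list of (port_a, port_b, points (m,3) from a to b)
    width: float
    height: float

    def port_xy(self, port: int) -> np.ndarray:
        x = 0.0 if port in (NW, SW) else self.width
        y = self.height if port in (NW, NE) else 0.0
        return np.array([x, y, 0.0])

    @property
    def n_crossings(self) -> int:
        # crossings are only created inside twist regions; tracked on build
        return self._crossings

    _crossings: int = field(default=0)


def integer_tangle(n: int, z_amp: float = 0.35) -> Tangle:
    """Horizontal integer tangle: |n| half-twists, sign = handedness.

    n = 0 gives two parallel horizontal strands.
    """
    height = 2.0
    if n == 0:
        width = 1.0
        a = np.array([[0.0, height, 0.0], [width, height, 0.0]])
        b = np.array([[0.0, 0.0, 0.0], [width, 0.0, 0.0]])
        t = Tangle([(NW, NE, a), (SW, SE, b)], width, height)
        t._crossings = 0
        return t
    k = abs(n)
    width = 1.2 * k
    pts_per_half = 6
    m = k * pts_per_half + 1
    phi = np.linspace(0.0, k * np.pi, m)
    x = np.linspace(0.0, width, m)
    r = height / 2.0
    cy = height / 2.0
    sgn = 1.0 if n > 0 else -1.0
    # strand A starts at the top (NW), strand B at the bottom (SW)
    ya = cy + r * np.cos(phi)
    za = z_amp * np.sin(phi) * sgn
    yb = cy - r * np.cos(phi)
    zb = -z_amp * np.sin(phi) * sgn
    a = np.column_stack([x, ya, za])
    b = np.column_stack([x, yb, zb])
    # pin the ends exactly onto the ports
    a[0] = [0.0, height, 0.0]
    b[0] = [0.0, 0.0, 0.0]
    if k % 2 == 0:
        a[-1] = [width, height, 0.0]
        b[-1] = [width, 0.0, 0.0]
        strands = [(NW, NE, a), (SW, SE, b)]
    else:
        a[-1] = [width, 0.0, 0.0]
        b[-1] = [width, height, 0.0]
        strands = [(NW, SE, a), (SW, NE, b)]
    t = Tangle(strands, width, height)
    t._crossings = k
    return t


_ROT_PORT = {NW: NE, NE: SE, SE: SW, SW: NW}  # 90 deg clockwise in-plane


def rotate_tangle(t: Tangle) -> Tangle:
    """Rotate 90 degrees clockwise in the projection plane: T -> -1/T."""
    strands = []
    cx, cy = t.width / 2.0, t.height / 2.0
    for pa, pb, pts in t.strands:
        p = pts.copy()
        x = p[:, 0] - cx
        y = p[:, 1] - cy
        # clockwise: (x, y) -> (y, -x); z (over/under) unchanged
        p[:, 0] = y + t.height / 2.0
        p[:, 1] = -x + t.width / 2.0
        strands.append((_ROT_PORT[pa], _ROT_PORT[pb], p))
    out = Tangle(strands, t.height, t.width)
    out._crossings = t._crossings
    return out


def mirror_tangle(t: Tangle) -> Tangle:
    """Flip every crossing (z -> -z): T -> -T."""
    strands = [(pa, pb, pts * np.array([1.0, 1.0, -1.0]))
               for pa, pb, pts in t.strands]
    out = Tangle(strands, t.width, t.height)
    out._crossings = t._crossings
    return out


def invert_tangle(t: Tangle) -> Tangle:
    """T -> 1/T (mirror of the 90-degree rotation)."""
    return mirror_tangle(rotate_tangle(t))


def rotate_ccw(t: Tangle) -> Tangle:
    """Rotate 90 degrees counterclockwise in the projection plane."""
    return rotate_tangle(rotate_tangle(rotate_tangle(t)))


def vertical_sum(t1: Tangle, t2: Tangle) -> Tangle:
    """Stack t2 below t1 (south ports of t1 joined to north ports of t2).

    In Conway's fraction calculus this is the tangle product:
    F = 1/(1/F1 + 1/F2).
    """
    return rotate_tangle(tangle_sum(rotate_ccw(t1), rotate_ccw(t2)))


def _rescale_height(t: Tangle, target: float) -> Tangle:
    """Uniform rescale so the box height matches ``target``.

    Uniform scaling (x, y and z together) cannot change the diagram, so
    nested compositions stay topologically faithful.
    """
    if abs(t.height - target) < 1e-12:
        return t
    f = target / t.height
    strands = []
    for pa, pb, pts in t.strands:
        strands.append((pa, pb, pts * f))
    out = Tangle(strands, t.width * f, target)
    out._crossings = t._crossings
    return out


def tangle_sum(t1: Tangle, t2: Tangle, gap: float = 0.6) -> Tangle:
    """Side-by-side sum: east ports of t1 joined to west ports of t2."""
    h = 2.0
    t1 = _rescale_height(t1, h)
    t2 = _rescale_height(t2, h)
    dx = t1.width + gap
    # strand records: (end_a, end_b, points); ends are ('port', id) or
    # ('joint', 'top'|'bot')
    recs = []
    for pa, pb, pts in t1.strands:
        ends = []
        for port in (pa, pb):
            if port == NE:
                ends.append(("joint", "top"))
            elif port == SE:
                ends.append(("joint", "bot"))
            else:
                ends.append(("port", port))
        recs.append((ends[0], ends[1], pts.copy()))
    for pa, pb, pts in t2.strands:
        p = pts.copy()
        p[:, 0] += dx
        ends = []
        for port in (pa, pb):
            if port == NW:
                ends.append(("joint", "top"))
            elif port == SW:
                ends.append(("joint", "bot"))
            else:
                ends.append(("port", port))
        recs.append((ends[0], ends[1], p))

    # stitch across the two joints; each joint pairs exactly two strand ends
    joint_ends: dict[str, list[tuple[int, int]]] = {"top": [], "bot": []}
    for idx, (ea, eb, _) in enumerate(recs):
        for e, end in enumerate((ea, eb)):
            if end[0] == "joint":
                joint_ends[end[1]].append((idx, e))
    for key, lst in joint_ends.items():
        if len(lst) != 2:
            raise ValueError(f"joint {key} has degree {len(lst)}")

    used = [False] * len(recs)
    strands = []
    for start, (ea, eb, pts) in enumerate(recs):
        if used[start]:
            continue
        if ea[0] == "joint" and eb[0] == "joint":
            continue  # reached via a walk from a port
        used[start] = True
        if ea[0] == "port":
            port_a = ea[1]
            pieces = [pts]
            cur = eb
        else:
            port_a = eb[1]
            pieces = [pts[::-1]]
            cur = ea
        while cur[0] == "joint":
            idx = e = None
            for cand_idx, cand_e in joint_ends[cur[1]]:
                if not used[cand_idx]:
                    idx, e = cand_idx, cand_e
                    break
            if idx is None:
                raise ValueError("dangling joint in tangle sum")
            used[idx] = True
            nxt_pts = recs[idx][2]
            pieces.append(nxt_pts if e == 0 else nxt_pts[::-1])
            cur = recs[idx][1 - e]
        port_b = cur[1]
        strands.append((port_a, port_b, np.vstack(pieces)))
    t = Tangle(strands, t1.width + gap + t2.width, h)
    t._crossings = t1._crossings + t2._crossings
    return t


def numerator_closure(t: Tangle) -> np.ndarray:
    """Close NW-NE above and SW-SE below; return one closed polyline.

    Raises ValueError if the closure has more than one component (link).
    """
    h = t.height
    w = t.width
    top = np.array([[0.0, h, 0.0], [-0.8, h + 1.0, 0.0],
                    [w / 2, h + 1.4, 0.0], [w + 0.8, h + 1.0, 0.0],
                    [w, h, 0.0]])
    bot = np.array([[0.0, 0.0, 0.0], [-0.8, -1.0, 0.0],
                    [w / 2, -1.4, 0.0], [w + 0.8, -1.0, 0.0],
                    [w, 0.0, 0.0]])
    connectors = {frozenset((NW, NE)): top, frozenset((SW, SE)): bot}

    # traverse: strands + 2 connector arcs form the closed curve(s)
    pieces = []
    for pa, pb, pts in t.strands:
        pieces.append((pa, pb, pts))
    for ports, arc in connectors.items():
        pa, pb = sorted(ports)
        pieces.append((pa, pb, arc))
    # port endpoints must match t.port_xy
    adj: dict[int, list[int]] = {}
    for i, (pa, pb, _) in enumerate(pieces):
        adj.setdefault(pa, []).append(i)
        adj.setdefault(pb, []).append(i)
    for port, lst in adj.items():
        if len(lst) != 2:
            raise ValueError(f"port {port} has degree {len(lst)}")
    used = [False] * len(pieces)
    loop_pts = []
    cur_piece = 0
    pa, pb, pts = pieces[0]
    used[0] = True
    loop_pts.append(pts)
    cur_port = pb
    n_used = 1
    while True:
        nxt = None
        for i in adj[cur_port]:
            if not used[i]:
                nxt = i
                break
        if nxt is None:
            break
        pa, pb, pts = pieces[nxt]
        used[nxt] = True
        n_used += 1
        if pa == cur_port:
            loop_pts.append(pts)
            cur_port = pb
        else:
            loop_pts.append(pts[::-1])
            cur_port = pa
    if n_used != len(pieces):
        raise ValueError("closure has more than one component (link, not knot)")
    out = [loop_pts[0]]
    for seg in loop_pts[1:]:
        out.append(seg[1:] if np.allclose(seg[0], out[-1][-1], atol=1e-5) else seg)
    return np.vstack(out)


def continued_fraction(a: list[int]) -> tuple[int, int]:
    """Fraction p/q of the rational tangle C(a1, ..., ak); |p| is the knot
    determinant."""
    from fractions import Fraction
    f = Fraction(a[0])
    for ai in a[1:]:
        f = Fraction(ai) + (Fraction(1) / f if f != 0 else Fraction(0))
    return abs(f.numerator), abs(f.denominator)


def vertical_twist(n: int) -> Tangle:
    """Vertical twist tangle with fraction 1/n."""
    return rotate_tangle(integer_tangle(-n))


def rational_tangle(a: list[int]) -> Tangle:
    """Rational tangle C(a1, ..., ak): a1 is the innermost (vertical)
    region, regions alternate vertical/horizontal.

    The tangle fraction is built by F -> a_i + F (horizontal sum) and
    F -> 1/(a_i + 1/F) (vertical stack); closure parity is handled by
    :func:`rational_curve`.
    """
    t = vertical_twist(a[0])
    horizontal = True
    for ai in a[1:]:
        if horizontal:
            t = tangle_sum(t, integer_tangle(ai))
        else:
            t = vertical_sum(t, vertical_twist(ai))
        horizontal = not horizontal
    return t


def rational_curve(a: list[int]) -> np.ndarray:
    """Closed polyline of the 2-bridge knot with Conway notation C(a1..ak).

    The determinant of the resulting knot is the numerator of the
    continued fraction [ak; a(k-1), ..., a1] (see
    :func:`continued_fraction`); the topology oracle re-verifies it for
    every embedding the atlas hands out.
    """
    t = rational_tangle(a)
    if len(a) % 2 == 1:
        # last region vertical: denominator closure = numerator of rotation
        t = rotate_tangle(t)
    return numerator_closure(t)


def pretzel_curve(twists: list[int]) -> np.ndarray:
    """Closed polyline of the pretzel knot P(p, q, r, ...)."""
    t = vertical_twist(twists[0])
    for n in twists[1:]:
        t = tangle_sum(t, vertical_twist(n))
    return numerator_closure(t)


# ---------------------------------------------------------------------------
# plat closures of braid words
# ---------------------------------------------------------------------------

def plat_components(word: list[int], n_strands: int) -> int:
    """Number of link components of the plat closure of a braid word.

    Strands are capped in adjacent pairs (0-1, 2-3, ...) at top and
    bottom; ``word`` entries are signed generators (+k / -k for sigma_k,
    1-based columns k, k+1).
    """
    if n_strands % 2:
        raise ValueError("plats need an even number of strands")
    perm = list(range(n_strands))
    for g in word:
        k = abs(g) - 1
        perm[k], perm[k + 1] = perm[k + 1], perm[k]
    # perm[i] = bottom position of the strand now at top position i
    top_of_bottom = [0] * n_strands
    for top, bot in enumerate(perm):
        top_of_bottom[bot] = top
    cap = lambda i: i + 1 if i % 2 == 0 else i - 1
    seen = [False] * n_strands
    comps = 0
    for start in range(n_strands):
        if seen[start]:
            continue
        comps += 1
        b = start
        while not seen[b]:
            seen[b] = True
            t = top_of_bottom[b]
            t2 = cap(t)
            # descend the strand that ends at top position t2
            b2 = perm[t2]
            seen[b2] = True
            b = cap(b2)
    return comps


def plat_curve(word: list[int], n_strands: int = 6, z_amp: float = 0.4) -> np.ndarray:
    """Closed 3D polyline of the plat closure of a braid word.

    The canonical projection (+z) of the curve shows exactly
    ``len(word)`` crossings, one per braid letter, with over/under
    chosen by the generator sign.  Raises ValueError when the closure
    has more than one component.
    """
    if plat_components(word, n_strands) != 1:
        raise ValueError("plat closure is a link, not a knot")
    # wires[c]: growing list of points for the strand currently at column c
    wires = [[np.array([float(c), 0.0, 0.0])] for c in range(n_strands)]
    height = 0.0
    for g in word:
        k = abs(g) - 1
        height += 1.0
        y0 = height - 1.0
        # idle strands rise straight
        for c in range(n_strands):
            if c != k and c != k + 1:
                wires[c].append(np.array([float(c), height, 0.0]))
        # crossing strands swap with z bumps; sign picks which is over
        za = z_amp if g > 0 else -z_amp
        phases = np.linspace(0.0, 1.0, 5)[1:]
        a_pts = [np.array([k + f, y0 + f, za * np.sin(np.pi * f)]) for f in phases]
        b_pts = [np.array([k + 1 - f, y0 + f, -za * np.sin(np.pi * f)]) for f in phases]
        wires[k].extend(a_pts)
        wires[k + 1].extend(b_pts)
        wires[k], wires[k + 1] = wires[k + 1], wires[k]
    # stitch wires with caps (adjacent pairs) at bottom and top
    pieces = {}
    for c, w in enumerate(wires):
        pieces[c] = np.array(w)
    cap = lambda i: i + 1 if i % 2 == 0 else i - 1

    def cap_arc(p, q, bulge):
        mid = (p + q) / 2 + np.array([0.0, bulge, 0.0])
        return np.vstack([p, (p + mid) / 2 + [0, bulge * 0.35, 0], mid,
                          (q + mid) / 2 + [0, bulge * 0.35, 0], q])

    # traverse: start at column 0 going up
    out = []
    col = 0
    direction = "up"
    visited = set()
    while True:
        if col in visited:
            break
        visited.add(col)
        pts = pieces[col]
        out.append(pts if direction == "up" else pts[::-1])
        if direction == "up":
            end_col = col  # top position of this wire is its final column
            nxt = cap(end_col)
            # top cap joins top of end_col to top of nxt; then descend
            p = out[-1][-1]
            q = pieces[nxt][-1]
            out.append(cap_arc(p, q, 1.2)[1:-1])
            col = nxt
            direction = "down"
        else:
            # at the bottom of this wire: find which column it started at
            start_x = int(round(pieces[col][0][0]))
            nxt = cap(start_x)
            # bottom cap: from bottom of this wire to bottom of the wire
            # that STARTS at column nxt
            src = None
            for c2, pts2 in pieces.items():
                if int(round(pts2[0][0])) == nxt:
                    src = c2
                    break
            p = out[-1][-1]
            q = pieces[src][0]
            out.append(cap_arc(p, q, -1.2)[1:-1])
            col = src
            direction = "up"
    curve = np.vstack(out)
    # deduplicate consecutive repeats
    keep = np.ones(len(curve), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(curve, axis=0), axis=1) > 1e-9
    return curve[keep]


# ---------------------------------------------------------------------------
# topology-safe relaxation (inflation)
# ---------------------------------------------------------------------------

@numba.njit(cache=False)
def _inflate_sweeps(pos, target, step, floor, n_sweeps):
    """Push non-adjacent beads apart to >= target while keeping bonds ~1.

    Moves are capped at ``step`` per sweep and any displacement is vetoed
    when it would bring a non-adjacent bead pair below ``floor`` (strand
    passage requires the distance to cross zero, so keeping it above a
    positive floor with small steps preserves topology).
    Returns the final minimum non-adjacent distance.
    """
    n = pos.shape[0]
    disp = np.zeros((n, 3))
    for sweep in range(n_sweeps):
        disp[:] = 0.0
        worst = 1e18
        for i in range(n):
            for j in range(i + 2, n):
                if i == 0 and j == n - 1:
                    continue
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                d = np.sqrt(dx * dx + dy * dy + dz * dz)
                if d < worst:
                    worst = d
                if d < target and d > 1e-9:
                    f = 0.5 * (target - d) / d
                    disp[i, 0] += f * dx
                    disp[i, 1] += f * dy
                    disp[i, 2] += f * dz
                    disp[j, 0] -= f * dx
                    disp[j, 1] -= f * dy
                    disp[j, 2] -= f * dz
        if worst >= target:
            return worst
        # cap displacements
        for i in range(n):
            m = np.sqrt(disp[i, 0] ** 2 + disp[i, 1] ** 2 + disp[i, 2] ** 2)
            if m > step:
                disp[i, 0] *= step / m
                disp[i, 1] *= step / m
                disp[i, 2] *= step / m
        # veto check: no pair may fall below the floor after the move
        ok = True
        for i in range(n):
            for j in range(i + 2, n):
                if i == 0 and j == n - 1:
                    continue
                dx = pos[i, 0] + disp[i, 0] - pos[j, 0] - disp[j, 0]
                dy = pos[i, 1] + disp[i, 1] - pos[j, 1] - disp[j, 1]
                dz = pos[i, 2] + disp[i, 2] - pos[j, 2] - disp[j, 2]
                if dx * dx + dy * dy + dz * dz < floor * floor:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            # halve the step for this sweep
            for i in range(n):
                disp[i, 0] *= 0.5
                disp[i, 1] *= 0.5
                disp[i, 2] *= 0.5
        pos += disp
        # restore bond lengths toward 1 (closed chain)
        for _ in range(4):
            for i in range(n):
                j = (i + 1) % n
                dx = pos[j, 0] - pos[i, 0]
                dy = pos[j, 1] - pos[i, 1]
                dz = pos[j, 2] - pos[i, 2]
                d = np.sqrt(dx * dx + dy * dy + dz * dz)
                if d > 1e-9:
                    corr = 0.5 * (d - 1.0) / d
                    pos[i, 0] += corr * dx
                    pos[i, 1] += corr * dy
                    pos[i, 2] += corr * dz
                    pos[j, 0] -= corr * dx
                    pos[j, 1] -= corr * dy
                    pos[j, 2] -= corr * dz
    # final min distance
    worst = 1e18
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d < worst:
                worst = d
    return worst


def inflate(pos: np.ndarray, target: float = 1.05, step: float = 0.05,
            floor: float = 0.2, max_sweeps: int = 2000) -> tuple[np.ndarray, float]:
    """Relax a closed unit-bond polygon to non-adjacent clearance >= target."""
    p = np.ascontiguousarray(pos, dtype=np.float64).copy()
    worst = _inflate_sweeps(p, target, step, floor, max_sweeps)
    return p, float(worst)


@numba.njit(cache=False)
def _smooth_sweeps(pos, lam, floor, n_sweeps):
    """Curvature-reducing relaxation with a hard pair-distance floor.

    Each bead moves a fraction ``lam`` toward its neighbours' midpoint;
    a sweep is vetoed bead-by-bead when it would push any non-adjacent
    pair below ``floor`` (same topology-safety argument as inflation).
    Bond lengths are restored toward 1 after every sweep.
    """
    n = pos.shape[0]
    for _ in range(n_sweeps):
        for i in range(n):
            im = (i - 1) % n
            ip = (i + 1) % n
            tx = 0.5 * (pos[im, 0] + pos[ip, 0])
            ty = 0.5 * (pos[im, 1] + pos[ip, 1])
            tz = 0.5 * (pos[im, 2] + pos[ip, 2])
            nx = pos[i, 0] + lam * (tx - pos[i, 0])
            ny = pos[i, 1] + lam * (ty - pos[i, 1])
            nz = pos[i, 2] + lam * (tz - pos[i, 2])
            ok = True
            for j in range(n):
                dj = (j - i) % n
                if dj <= 1 or dj >= n - 1:
                    continue
                dx = nx - pos[j, 0]
                dy = ny - pos[j, 1]
                dz = nz - pos[j, 2]
                if dx * dx + dy * dy + dz * dz < floor * floor:
                    ok = False
                    break
            if ok:
                pos[i, 0] = nx
                pos[i, 1] = ny
                pos[i, 2] = nz
        for _ in range(3):
            for i in range(n):
                j = (i + 1) % n
                dx = pos[j, 0] - pos[i, 0]
                dy = pos[j, 1] - pos[i, 1]
                dz = pos[j, 2] - pos[i, 2]
                d = np.sqrt(dx * dx + dy * dy + dz * dz)
                if d > 1e-9:
                    corr = 0.5 * (d - 1.0) / d
                    pos[i, 0] += corr * dx
                    pos[i, 1] += corr * dy
                    pos[i, 2] += corr * dz
                    pos[j, 0] -= corr * dx
                    pos[j, 1] -= corr * dy
                    pos[j, 2] -= corr * dz


def smooth(pos: np.ndarray, lam: float = 0.2, floor: float = 0.3,
           sweeps: int = 30) -> np.ndarray:
    """Topology-safe curvature smoothing of a closed unit-bond polygon."""
    p = np.ascontiguousarray(pos, dtype=np.float64).copy()
    _smooth_sweeps(p, lam, floor, sweeps)
    return p
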