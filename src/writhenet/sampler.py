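"""Topology-preserving thermal sampling of ring polymers.

The production engine is a crankshaft Monte Carlo: a random arc of the
ring is rigidly rotated about the chord through its two pivot beads,
subject to a hard-core excluded volume (non-bonded beads may not
approach below 0.9 sigma, checked at the half-rotated and fully rotated
positions) and a Metropolis test on the discrete worm-like-chain bending
energy ``E = k_bend * sum_x (1 - cos theta_x)`` with
``k_bend = l_p * kT / sigma``.  Bond lengths are exactly preserved by
construction.  Because a hard core of 0.9 sigma at bond length 1 sigma
cannot strictly forbid strand passage during large rotations, every
emitted snapshot is audited by the topology oracle (Alexander
determinant against the seed's reference); snapshots that fail are
discarded and the chain restored to the last verified state.

A Kremer--Grest Langevin engine (FENE bonds, WCA excluded volume,
cosine bending, BAOAB integration) is provided as an alternative; the
Monte Carlo engine is the dataset default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numba
import numpy as np

from .conformation import RingConformation
from .oracle import classify_by_determinant

__all__ = ["SamplerConfig", "SamplerInstabilityError", "thermalize",
           "decorrelation_check", "fit_persistence_length"]


class SamplerInstabilityError(RuntimeError):
    """Raised when too many audited snapshots fail topology verification."""


@dataclass
class SamplerConfig:
    """Sampling parameters; lengths in sigma, energies in kT.

    ``decorrelation_interval`` and ``equilibration`` are measured in
    Monte Carlo sweeps (N attempted moves each) for the crankshaft
    engine, or in integration steps for the Langevin engine.
    """

    n_beads: int = 100
    persistence_length: float = 10.0
    temperature: float = 1.0
    bead_spacing: float = 1.0
    n_conformations: int = 100
    decorrelation_interval: int = 30
    equilibration: int = 500
    seed: int = 0
    engine: str = "crankshaft_mc"
    audit_fraction: float = 1.0
    hard_core: float = 0.9
    max_rotation: float = 1.3  # radians
    max_arc_fraction: float = 0.5
    langevin_dt: float = 0.005
    langevin_gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.n_conformations < 1:
            raise ValueError("n_conformations must be >= 1")
        if self.engine not in ("crankshaft_mc", "langevin"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if not 0.0 <= self.audit_fraction <= 1.0:
            raise ValueError("audit_fraction in [0, 1]")
        if not 1.0 <= self.persistence_length <= 10.0:
            # the method was exercised at l_p between 1 and 10 sigma;
            # values outside are extrapolation
            import warnings
            warnings.warn("persistence length outside the tested 1-10 sigma range")


# ---------------------------------------------------------------------------
# crankshaft Monte Carlo kernel
# ---------------------------------------------------------------------------

@numba.njit(cache=False, fastmath=True, inline="always")
def _overlap_active(pos, moved_idx, active_idx, n_active, cand, n_cand,
                    hard2, n_wrap):
    """Check the flagged (collision-capable) moved beads against candidates."""
    for q in range(n_active):
        i = moved_idx[active_idx[q]]
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        for b in range(n_cand):
            j = cand[b]
            dj = i - j
            if dj == 1 or dj == -1 or dj == n_wrap or dj == -n_wrap:
                continue
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            if dx * dx + dy * dy + dz * dz < hard2:
                return False
    return True


@numba.njit(cache=False)
def _seed_kernel_rng(seed):
    # numba keeps its own RNG state; seeding must happen in jitted code
    np.random.seed(seed)


@numba.njit(cache=False)
def _bend_energy_at(pos, x, n, kbend):
    xm = (x - 1) % n
    xp = (x + 1) % n
    b1x = pos[x, 0] - pos[xm, 0]
    b1y = pos[x, 1] - pos[xm, 1]
    b1z = pos[x, 2] - pos[xm, 2]
    b2x = pos[xp, 0] - pos[x, 0]
    b2y = pos[xp, 1] - pos[x, 1]
    b2z = pos[xp, 2] - pos[x, 2]
    n1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
    n2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
    c = (b1x * b2x + b1y * b2y + b1z * b2z) / (n1 * n2)
    return kbend * (1.0 - c)


@numba.njit(cache=False, fastmath=True)
def _crankshaft_sweeps(pos, n_sweeps, kbend, hard_core, max_arc, amax, temperature):
    """Run n_sweeps * n crankshaft move attempts in place; returns acceptance.

    The rotation is applied through checkpoints spaced so that no bead
    travels more than ~0.35 sigma between successive hard-core checks;
    passage through the 0.9 sigma core would then require a jump the
    checks must see.  Rigid rotation preserves bond lengths and
    moved-moved distances exactly, so only moved-fixed pairs are
    checked.
    """
    n = pos.shape[0]
    hard2 = hard_core * hard_core
    accepted = 0
    attempted = n_sweeps * n
    work = np.empty((n, 3))
    moved_idx = np.empty(n, dtype=np.int64)
    is_moved = np.zeros(n, dtype=np.bool_)
    cand = np.empty(n, dtype=np.int64)
    active_idx = np.empty(n, dtype=np.int64)
    for _ in range(attempted):
        i = np.random.randint(0, n)
        # bias toward short arcs: cheap moves relax local modes, the
        # occasional long arc reorients globally
        u = np.random.random()
        arc = 2 + int(u * u * (max_arc - 2))
        j = i + arc
        if j >= n:
            j -= n
        ux = pos[j, 0] - pos[i, 0]
        uy = pos[j, 1] - pos[i, 1]
        uz = pos[j, 2] - pos[i, 2]
        norm = np.sqrt(ux * ux + uy * uy + uz * uz)
        if norm < 1e-9:
            continue
        ux /= norm
        uy /= norm
        uz /= norm
        m = arc - 1
        rmax2 = 0.0
        cx0 = 0.0
        cy0 = 0.0
        cz0 = 0.0
        for a in range(m):
            idx = i + 1 + a
            if idx >= n:
                idx -= n
            moved_idx[a] = idx
            is_moved[idx] = True
            work[a, 0] = pos[idx, 0]
            work[a, 1] = pos[idx, 1]
            work[a, 2] = pos[idx, 2]
            cx0 += pos[idx, 0]
            cy0 += pos[idx, 1]
            cz0 += pos[idx, 2]
            px = work[a, 0] - pos[i, 0]
            py = work[a, 1] - pos[i, 1]
            pz = work[a, 2] - pos[i, 2]
            dot = px * ux + py * uy + pz * uz
            r2 = px * px + py * py + pz * pz - dot * dot
            if r2 > rmax2:
                rmax2 = r2
        rmax = np.sqrt(rmax2) if rmax2 > 1e-12 else 0.0
        theta = (np.random.random() * 2.0 - 1.0) * amax
        # checkpoints spaced so arc travel per step <= 0.35 sigma
        n_checks = 1 + int(rmax * np.abs(theta) / 0.5)
        if n_checks > 16:
            theta *= 16.0 / n_checks
            n_checks = 16
        # candidate fixed beads: within reach of the arc's swept sphere
        cx0 /= m
        cy0 /= m
        cz0 /= m
        reach2 = 0.0
        for a in range(m):
            dx = work[a, 0] - cx0
            dy = work[a, 1] - cy0
            dz = work[a, 2] - cz0
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > reach2:
                reach2 = r2
        # moved beads stay within sqrt(reach2)+|rot|; rotation keeps them
        # within the sphere about the chord, so the swept ball radius is
        # bounded by arc radius about its centroid + rmax + core
        reach = np.sqrt(reach2) + 2.0 * rmax + hard_core + 0.5
        reach2 = reach * reach
        n_cand = 0
        for jj in range(n):
            if is_moved[jj]:
                continue
            dx = pos[jj, 0] - cx0
            dy = pos[jj, 1] - cy0
            dz = pos[jj, 2] - cz0
            if dx * dx + dy * dy + dz * dz < reach2:
                cand[n_cand] = jj
                n_cand += 1
        # per-bead clearance flags: a moved bead whose distance to every
        # candidate exceeds its own maximum travel (its rotation-circle
        # diameter) plus the core can never collide during this move
        n_active = 0
        abs_theta = np.abs(theta)
        for a in range(m):
            px = work[a, 0] - pos[i, 0]
            py = work[a, 1] - pos[i, 1]
            pz = work[a, 2] - pos[i, 2]
            dot = px * ux + py * uy + pz * uz
            r_a = np.sqrt(max(px * px + py * py + pz * pz - dot * dot, 0.0))
            travel = min(r_a * abs_theta, 2.0 * r_a)
            thresh = travel + hard_core + 1e-3
            t2 = thresh * thresh
            d2min = 1e18
            for b in range(n_cand):
                jj = cand[b]
                dx = work[a, 0] - pos[jj, 0]
                dy = work[a, 1] - pos[jj, 1]
                dz = work[a, 2] - pos[jj, 2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 < d2min:
                    d2min = d2
                    if d2min < t2:
                        break
            if d2min < t2:
                active_idx[n_active] = a
                n_active += 1
        e_old = _bend_energy_at(pos, i, n, kbend) + _bend_energy_at(pos, j, n, kbend)
        ok = True
        steps_needed = n_checks if n_active > 0 else 1
        for step in range(1, steps_needed + 1):
            ang = theta * step / steps_needed
            ca = np.cos(ang)
            sa = np.sin(ang)
            final = step == steps_needed
            for a in range(m):
                if not final:
                    # intermediate checkpoints only need the active beads
                    in_active = False
                    for q in range(n_active):
                        if active_idx[q] == a:
                            in_active = True
                            break
                    if not in_active:
                        continue
                px = work[a, 0] - pos[i, 0]
                py = work[a, 1] - pos[i, 1]
                pz = work[a, 2] - pos[i, 2]
                dot = px * ux + py * uy + pz * uz
                ccx = uy * pz - uz * py
                ccy = uz * px - ux * pz
                ccz = ux * py - uy * px
                idx = moved_idx[a]
                pos[idx, 0] = pos[i, 0] + px * ca + ccx * sa + ux * dot * (1 - ca)
                pos[idx, 1] = pos[i, 1] + py * ca + ccy * sa + uy * dot * (1 - ca)
                pos[idx, 2] = pos[i, 2] + pz * ca + ccz * sa + uz * dot * (1 - ca)
            if not _overlap_active(pos, moved_idx, active_idx, n_active,
                                   cand, n_cand, hard2, n - 1):
                ok = False
                break
        if ok:
            e_new = _bend_energy_at(pos, i, n, kbend) + _bend_energy_at(pos, j, n, kbend)
            de = (e_new - e_old) / temperature
            if de <= 0.0 or np.random.random() < np.exp(-de):
                accepted += 1
                for a in range(m):
                    is_moved[moved_idx[a]] = False
                continue
        # reject: restore
        for a in range(m):
            idx = moved_idx[a]
            pos[idx, 0] = work[a, 0]
            pos[idx, 1] = work[a, 1]
            pos[idx, 2] = work[a, 2]
            is_moved[idx] = False
    return accepted / max(attempted, 1)


# ---------------------------------------------------------------------------
# Kremer-Grest Langevin kernel
# ---------------------------------------------------------------------------

@numba.njit(cache=False)
def _kg_forces(pos, kbend, out):
    """FENE (k=30, R0=1.5) + WCA (eps=1) + cosine bending forces."""
    n = pos.shape[0]
    out[:] = 0.0
    # FENE bonds
    for i in range(n):
        j = (i + 1) % n
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        # FENE attractive part
        fene = -30.0 / (1.0 - r2 / 2.25)
        fx = fene * dx
        fy = fene * dy
        fz = fene * dz
        out[i, 0] -= fx
        out[i, 1] -= fy
        out[i, 2] -= fz
        out[j, 0] += fx
        out[j, 1] += fy
        out[j, 2] += fz
    # WCA between all pairs (including bonded, per Kremer-Grest)
    cut2 = 2.0 ** (1.0 / 3.0)
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < cut2 and r2 > 1e-12:
                ir2 = 1.0 / r2
                ir6 = ir2 * ir2 * ir2
                f = 24.0 * ir2 * ir6 * (2.0 * ir6 - 1.0)
                out[i, 0] -= f * dx
                out[i, 1] -= f * dy
                out[i, 2] -= f * dz
                out[j, 0] += f * dx
                out[j, 1] += f * dy
                out[j, 2] += f * dz
    # cosine bending: E = kbend * (1 - cos theta); F = kbend * grad(cos theta)
    if kbend > 0.0:
        for x in range(n):
            xm = (x - 1) % n
            xp = (x + 1) % n
            b1 = pos[x] - pos[xm]
            b2 = pos[xp] - pos[x]
            n1 = np.sqrt(b1[0] ** 2 + b1[1] ** 2 + b1[2] ** 2)
            n2 = np.sqrt(b2[0] ** 2 + b2[1] ** 2 + b2[2] ** 2)
            c = (b1[0] * b2[0] + b1[1] * b2[1] + b1[2] * b2[2]) / (n1 * n2)
            if c > 1.0:
                c = 1.0
            if c < -1.0:
                c = -1.0
            for k in range(3):
                d1 = b2[k] / (n1 * n2) - c * b1[k] / (n1 * n1)
                d2 = b1[k] / (n1 * n2) - c * b2[k] / (n2 * n2)
                out[xm, k] -= kbend * d1
                out[x, k] += kbend * (d1 - d2)
                out[xp, k] += kbend * d2
    return out


@numba.njit(cache=False)
def _langevin_steps(pos, vel, n_steps, kbend, dt, gamma, temperature):
    n = pos.shape[0]
    forces = np.empty((n, 3))
    _kg_forces(pos, kbend, forces)
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * temperature)
    for _ in range(n_steps):
        # BAOAB
        vel += 0.5 * dt * forces
        pos += 0.5 * dt * vel
        for i in range(n):
            for k in range(3):
                vel[i, k] = c1 * vel[i, k] + c2 * np.random.normal()
        pos += 0.5 * dt * vel
        _kg_forces(pos, kbend, forces)
        vel += 0.5 * dt * forces


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def thermalize(seed_conf, config: SamplerConfig,
               reference_det1: int | None = None) -> Iterator[RingConformation]:
    """Yield thermalized, decorrelated, topology-audited ring conformations.

    ``seed_conf`` is a :class:`RingConformation` (or an atlas
    ``SeedEmbedding``, whose conformation and reference determinant are
    used automatically).  Snapshots are taken every
    ``config.decorrelation_interval`` sweeps after equilibration.  The
    audit compares ``|Delta(-1)|`` of each audited snapshot with the
    seed's reference; failures restore the last verified state.  More
    than 1% audit failures raises :class:`SamplerInstabilityError`.
    """
    if hasattr(seed_conf, "conformation"):  # SeedEmbedding
        if reference_det1 is None and getattr(seed_conf, "reference_det1", None) is not None:
            reference_det1 = seed_conf.reference_det1
        seed_conf = seed_conf.conformation
    if not seed_conf.closed:
        raise ValueError("thermalize expects a closed ring")
    rng = np.random.default_rng(config.seed)
    if reference_det1 is None:
        reference_det1 = classify_by_determinant(
            seed_conf, n_directions=3, rng=rng, fast=True).det1

    pos = seed_conf.positions.copy()
    n = config.n_beads
    if pos.shape[0] != n:
        raise ValueError(f"seed has {pos.shape[0]} beads, config expects {n}")
    kbend = config.persistence_length * config.temperature / config.bead_spacing
    max_arc = max(int(config.max_arc_fraction * n), 3)

    if config.engine == "langevin":
        vel = rng.normal(scale=np.sqrt(config.temperature), size=pos.shape)

    def run(n_units: int, mc_seed: int) -> None:
        _seed_kernel_rng(mc_seed % (2 ** 31 - 1))
        if config.engine == "crankshaft_mc":
            _crankshaft_sweeps(pos, n_units, kbend, config.hard_core,
                               max_arc, config.max_rotation, config.temperature)
        else:
            _langevin_steps(pos, vel, n_units, kbend, config.langevin_dt,
                            config.langevin_gamma, config.temperature)

    run(config.equilibration, int(rng.integers(2 ** 31 - 1)))
    last_good = pos.copy()
    emitted = 0
    audited = 0
    failures = 0
    while emitted < config.n_conformations:
        run(config.decorrelation_interval, int(rng.integers(2 ** 31 - 1)))
        snap = RingConformation(pos.copy(), closed=True,
                                bead_spacing_target=config.bead_spacing,
                                validate=(config.engine == "crankshaft_mc"))
        do_audit = rng.random() < config.audit_fraction
        if do_audit:
            audited += 1
            det1 = classify_by_determinant(snap, n_directions=1, rng=rng,
                                           fast=True).det1
            if det1 != reference_det1:
                # one retry with more votes to rule out projection flukes
                det1 = classify_by_determinant(snap, n_directions=3, rng=rng,
                                               fast=True).det1
            if det1 != reference_det1:
                failures += 1
                if audited >= 20 and failures / audited > 0.01:
                    raise SamplerInstabilityError(
                        f"{failures}/{audited} audited snapshots changed topology "
                        f"(engine={config.engine}, l_p={config.persistence_length})")
                pos[:] = last_good
                continue
            last_good[:] = pos
        emitted += 1
        yield snap


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def _autocorr(series: np.ndarray, lags: np.ndarray) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    var = (x * x).mean()
    out = np.empty(len(lags))
    for idx, lag in enumerate(lags):
        if lag >= len(x):
            out[idx] = np.nan
        elif var <= 0:
            out[idx] = 0.0
        else:
            out[idx] = (x[:-lag] * x[lag:]).mean() / var if lag else 1.0
    return out


def decorrelation_check(conformations: list[RingConformation],
                        lag_grid: tuple[int, ...] = (1, 2, 5, 10),
                        threshold: float = 0.2) -> dict:
    """Autocorrelation of radius of gyration and global writhe.

    Flags the snapshot stream as correlated when the lag-1
    autocorrelation of either observable exceeds ``threshold``.
    """
    from .writhe import global_writhe

    lags = np.asarray(lag_grid, dtype=int)
    if len(conformations) <= int(lags.max()):
        raise ValueError("stream shorter than the lag grid")
    rg = np.array([c.radius_of_gyration() for c in conformations])
    wr = np.array([global_writhe(c) for c in conformations])
    acf_rg = _autocorr(rg, lags)
    acf_wr = _autocorr(wr, lags)
    return {
        "lags": lags,
        "acf_rg": acf_rg,
        "acf_writhe": acf_wr,
        "correlated": bool(acf_rg[0] > threshold or acf_wr[0] > threshold),
    }


def fit_persistence_length(conformations: list[RingConformation],
                           max_lag: int | None = None) -> float:
    """Persistence length from tangent-tangent correlations on sub-arcs.

    Fits ``<t(x) . t(x+s)> = exp(-s * spacing / l_p)`` over contour lags
    up to ``max_lag`` (default: a quarter of the ring, where closure
    effects stay mild) by linear regression on the log.
    """
    n = conformations[0].n_beads
    if max_lag is None:
        max_lag = max(min(n // 8, int(2 * 10)), 4)
    corr = np.zeros(max_lag + 1)
    for conf in conformations:
        t = conf.tangents()
        for lag in range(max_lag + 1):
            corr[lag] += float((t * np.roll(t, -lag, axis=0)).sum(axis=1).mean())
    corr /= len(conformations)
    corr = np.clip(corr / corr[0], 1e-6, None)
    lags = np.arange(max_lag + 1)
    good = corr > 0.05
    slope = np.polyfit(lags[good], np.log(corr[good]), 1)[0]
    spacing = conformations[0].bead_spacing_target
    return float(-spacing / slope) if slope < 0 else float("inf")
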