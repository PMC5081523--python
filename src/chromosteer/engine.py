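"""Langevin dynamics for the bead-spring chromatin model.

The force field is the Kremer-Grest bead-spring model: FENE bonds
(K = 30 eps/sigma^2, R0 = 1.5 sigma) plus purely repulsive WCA excluded
volume between all bead pairs, a Kratky-Porod bending term
U = kappa (1 - cos theta) whose default kappa = 5 eps targets the 150 nm
persistence length of the 30 nm chromatin fiber, a harmonic wall confining
beads inside the spherical nucleus, a short-range attractive (cut-shifted
Lennard-Jones) interaction between centromeric beads of the same chain, and
optional harmonic restraints between centres of mass of bead groups (the
steering machinery).

Units: the engine integrates in reduced Lennard-Jones units (sigma = 1,
eps = k_B T_ref = 1, m = 1, so tau_LJ = sigma sqrt(m/eps) = 1). The public
API speaks nanometres and k_B T; conversion happens at the boundary.
Integration uses the BAOAB splitting of underdamped Langevin dynamics,
which reduces to velocity Verlet when gamma = 0 (the NVE limit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import SimulationError
from .system import BeadSystem, Trajectory

_WCA_RC2 = 2.0 ** (1.0 / 3.0)  # squared WCA cutoff, sigma^2


@dataclass
class ForceFieldParams:
    """Force-field and integrator parameters (reduced units except noted)."""

    epsilon: float = 1.0          # energy unit, k_B T
    sigma: float = 30.0           # bead diameter, nm
    fene_k: float = 30.0          # eps / sigma^2
    fene_r0: float = 1.5          # sigma
    kappa: float = 5.0            # eps; l_p ~ kappa * sigma = 150 nm
    wall_k: float = 100.0         # eps / sigma^2
    wall_fmax: float = 20.0       # eps / sigma; cap on the wall force
    restraint_fmax: float = 10.0  # eps / sigma; cap on each COM restraint
    centromere_eps: float = 1.0   # eps; 0 disables the attraction
    centromere_cutoff: float = 1.5  # sigma
    gamma: float = 0.5            # friction, 1 / tau_LJ
    dt: float = 0.012             # tau_LJ
    temperature: float = 1.0      # eps / k_B

    def __post_init__(self) -> None:
        if self.fene_r0 <= 1.0:
            raise ValueError("FENE R0 must exceed sigma")
        if self.dt > 0.012 + 1e-12:
            raise ValueError("dt above 0.012 tau_LJ is unstable for this force field")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


# ---------------------------------------------------------------------------
# numba kernels (reduced units)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _build_pairs(x, rc, pairs):
    """Cell-list neighbour search; fills `pairs`, returns the pair count
    (may exceed capacity, in which case only the first `cap` are valid)."""
    n = x.shape[0]
    cap = pairs.shape[0]
    rc2 = rc * rc
    xmin = np.empty(3)
    xmax = np.empty(3)
    for d in range(3):
        lo = x[0, d]
        hi = x[0, d]
        for i in range(1, n):
            if x[i, d] < lo:
                lo = x[i, d]
            if x[i, d] > hi:
                hi = x[i, d]
        xmin[d] = lo
        xmax[d] = hi + 1e-9
    nc = np.empty(3, dtype=np.int64)
    for d in range(3):
        m = int((xmax[d] - xmin[d]) / rc)
        if m < 1:
            m = 1
        if m > 64:
            m = 64
        nc[d] = m
    ncell = nc[0] * nc[1] * nc[2]
    cell = np.empty(n, dtype=np.int64)
    for i in range(n):
        cx = int((x[i, 0] - xmin[0]) / (xmax[0] - xmin[0]) * nc[0])
        cy = int((x[i, 1] - xmin[1]) / (xmax[1] - xmin[1]) * nc[1])
        cz = int((x[i, 2] - xmin[2]) / (xmax[2] - xmin[2]) * nc[2])
        if cx >= nc[0]:
            cx = nc[0] - 1
        if cy >= nc[1]:
            cy = nc[1] - 1
        if cz >= nc[2]:
            cz = nc[2] - 1
        cell[i] = (cx * nc[1] + cy) * nc[2] + cz
    count = np.zeros(ncell + 1, dtype=np.int64)
    for i in range(n):
        count[cell[i] + 1] += 1
    for c in range(ncell):
        count[c + 1] += count[c]
    order = np.empty(n, dtype=np.int64)
    fill = count[:ncell].copy()
    for i in range(n):
        order[fill[cell[i]]] = i
        fill[cell[i]] += 1

    npairs = 0
    for i in range(n):
        ci = cell[i]
        cz0 = ci % nc[2]
        cy0 = (ci // nc[2]) % nc[1]
        cx0 = ci // (nc[1] * nc[2])
        for ox in range(-1, 2):
            cx = cx0 + ox
            if cx < 0 or cx >= nc[0]:
                continue
            for oy in range(-1, 2):
                cy = cy0 + oy
                if cy < 0 or cy >= nc[1]:
                    continue
                for oz in range(-1, 2):
                    cz = cz0 + oz
                    if cz < 0 or cz >= nc[2]:
                        continue
                    cc = (cx * nc[1] + cy) * nc[2] + cz
                    for k in range(count[cc], count[cc + 1]):
                        j = order[k]
                        if j <= i:
                            continue
                        dx = x[i, 0] - x[j, 0]
                        dy = x[i, 1] - x[j, 1]
                        dz = x[i, 2] - x[j, 2]
                        if dx * dx + dy * dy + dz * dz < rc2:
                            if npairs < cap:
                                pairs[npairs, 0] = i
                                pairs[npairs, 1] = j
                            npairs += 1
    return npairs


@njit(cache=True)
def _forces(x, f, bonds, acent, pairs, npairs, is_cen, chain_id,
            fene_k, fene_r02, kappa, cen_eps, cen_rc2, cen_shift,
            wall_r, wall_k, wall_fmax, comp_f,
            rmembers, roffsets, rpairs, rk, rd0, rfmax):
    """Fill per-bead forces; return (potential energy, ok flag)."""
    n = x.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    e = 0.0

    # FENE bonds
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= fene_r02:
            return e, False
        denom = 1.0 - r2 / fene_r02
        e += -0.5 * fene_k * fene_r02 * math.log(denom)
        fmag = -fene_k / denom
        f[i, 0] += fmag * dx
        f[i, 1] += fmag * dy
        f[i, 2] += fmag * dz
        f[j, 0] -= fmag * dx
        f[j, 1] -= fmag * dy
        f[j, 2] -= fmag * dz

    # WCA / centromere LJ over the neighbour list
    for p in range(npairs):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < 1e-12:
            return e, False
        cen_pair = (cen_eps > 0.0 and is_cen[i] and is_cen[j]
                    and chain_id[i] == chain_id[j])
        if cen_pair:
            if r2 < cen_rc2:
                ir2 = 1.0 / r2
                ir6 = ir2 * ir2 * ir2
                ir12 = ir6 * ir6
                e += 4.0 * cen_eps * (ir12 - ir6) - cen_shift
                fmag = cen_eps * (48.0 * ir12 - 24.0 * ir6) * ir2
                f[i, 0] += fmag * dx
                f[i, 1] += fmag * dy
                f[i, 2] += fmag * dz
                f[j, 0] -= fmag * dx
                f[j, 1] -= fmag * dy
                f[j, 2] -= fmag * dz
        elif r2 < _WCA_RC2:
            ir2 = 1.0 / r2
            ir6 = ir2 * ir2 * ir2
            ir12 = ir6 * ir6
            e += 4.0 * (ir12 - ir6) + 1.0
            fmag = (48.0 * ir12 - 24.0 * ir6) * ir2
            f[i, 0] += fmag * dx
            f[i, 1] += fmag * dy
            f[i, 2] += fmag * dz
            f[j, 0] -= fmag * dx
            f[j, 1] -= fmag * dy
            f[j, 2] -= fmag * dz

    # Kratky-Porod bending
    if kappa > 0.0:
        for a in range(acent.shape[0]):
            i = acent[a]
            ux = x[i, 0] - x[i - 1, 0]
            uy = x[i, 1] - x[i - 1, 1]
            uz = x[i, 2] - x[i - 1, 2]
            vx = x[i + 1, 0] - x[i, 0]
            vy = x[i + 1, 1] - x[i, 1]
            vz = x[i + 1, 2] - x[i, 2]
            nu2 = ux * ux + uy * uy + uz * uz
            nv2 = vx * vx + vy * vy + vz * vz
            nu = math.sqrt(nu2)
            nv = math.sqrt(nv2)
            inv = 1.0 / (nu * nv)
            c = (ux * vx + uy * vy + uz * vz) * inv
            if c > 1.0:
                c = 1.0
            elif c < -1.0:
                c = -1.0
            e += kappa * (1.0 - c)
            # dc/du and dc/dv
            dcux = vx * inv - c * ux / nu2
            dcuy = vy * inv - c * uy / nu2
            dcuz = vz * inv - c * uz / nu2
            dcvx = ux * inv - c * vx / nv2
            dcvy = uy * inv - c * vy / nv2
            dcvz = uz * inv - c * vz / nv2
            f[i - 1, 0] -= kappa * dcux
            f[i - 1, 1] -= kappa * dcuy
            f[i - 1, 2] -= kappa * dcuz
            f[i, 0] += kappa * (dcux - dcvx)
            f[i, 1] += kappa * (dcuy - dcvy)
            f[i, 2] += kappa * (dcuz - dcvz)
            f[i + 1, 0] += kappa * dcvx
            f[i + 1, 1] += kappa * dcvy
            f[i + 1, 2] += kappa * dcvz

    # spherical wall + optional radial compression; the restoring force is
    # capped so deeply protruding beads do not pick up unstable speeds
    if wall_r > 0.0:
        dr_cap = wall_fmax / wall_k
        for i in range(n):
            r2 = x[i, 0] ** 2 + x[i, 1] ** 2 + x[i, 2] ** 2
            r = math.sqrt(r2)
            if r > wall_r:
                dr = r - wall_r
                if dr <= dr_cap:
                    e += 0.5 * wall_k * dr * dr + comp_f * dr
                    fmag = wall_k * dr + comp_f
                else:
                    e += (0.5 * wall_k * dr_cap * dr_cap
                          + wall_fmax * (dr - dr_cap) + comp_f * dr)
                    fmag = wall_fmax + comp_f
                fr = -fmag / r
                f[i, 0] += fr * x[i, 0]
                f[i, 1] += fr * x[i, 1]
                f[i, 2] += fr * x[i, 2]

    # COM harmonic restraints
    for ridx in range(rpairs.shape[0]):
        ga = rpairs[ridx, 0]
        gb = rpairs[ridx, 1]
        na = roffsets[ga + 1] - roffsets[ga]
        nb = roffsets[gb + 1] - roffsets[gb]
        ax = ay = az = 0.0
        for k in range(roffsets[ga], roffsets[ga + 1]):
            m = rmembers[k]
            ax += x[m, 0]
            ay += x[m, 1]
            az += x[m, 2]
        ax /= na
        ay /= na
        az /= na
        bx = by = bz = 0.0
        for k in range(roffsets[gb], roffsets[gb + 1]):
            m = rmembers[k]
            bx += x[m, 0]
            by += x[m, 1]
            bz += x[m, 2]
        bx /= nb
        by /= nb
        bz /= nb
        dx = ax - bx
        dy = ay - by
        dz = az - bz
        dist = math.sqrt(dx * dx + dy * dy + dz * dz)
        if dist < 1e-12:
            continue
        dev = dist - rd0[ridx]
        # capped-force pulling: harmonic near the target, constant-force
        # beyond the cap, so distant targets cannot destabilize the run
        dev_cap = rfmax / rk[ridx] if rk[ridx] > 0 else 0.0
        if abs(dev) <= dev_cap or rk[ridx] <= 0:
            e += 0.5 * rk[ridx] * dev * dev
            fmag_r = rk[ridx] * dev
        else:
            e += (0.5 * rk[ridx] * dev_cap * dev_cap
                  + rfmax * (abs(dev) - dev_cap))
            fmag_r = rfmax if dev > 0 else -rfmax
        fa = -fmag_r / dist / na
        fb = fmag_r / dist / nb
        for k in range(roffsets[ga], roffsets[ga + 1]):
            m = rmembers[k]
            f[m, 0] += fa * dx
            f[m, 1] += fa * dy
            f[m, 2] += fa * dz
        for k in range(roffsets[gb], roffsets[gb + 1]):
            m = rmembers[k]
            f[m, 0] += fb * dx
            f[m, 1] += fb * dy
            f[m, 2] += fb * dz
    return e, True


@njit(cache=True)
def _run_chunk(x, v, f, nsteps, dt, gamma, temp, noise,
               bonds, acent, is_cen, chain_id,
               fene_k, fene_r02, kappa, cen_eps, cen_rc2, cen_shift,
               wall_r, wall_k, wall_fmax, comp_f,
               rmembers, roffsets, rpairs, rk, rd0, rfmax,
               pairs, npairs_in, x_snap, rc_list, skin):
    """BAOAB Langevin chunk. ``noise`` is (nsteps, n, 3) standard normals
    (generated by the caller). Returns (status, npairs).

    status: 0 ok, 1 bond over-extension, 2 per-step displacement > sigma,
    3 neighbour-list overflow."""
    n = x.shape[0]
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(max(0.0, (1.0 - c1 * c1) * temp))
    half = 0.5 * dt
    npairs = npairs_in
    cap = pairs.shape[0]
    thresh2 = (0.5 * skin) ** 2
    for step in range(nsteps):
        # B: half kick
        for i in range(n):
            v[i, 0] += half * f[i, 0]
            v[i, 1] += half * f[i, 1]
            v[i, 2] += half * f[i, 2]
        # A: half drift
        for i in range(n):
            x[i, 0] += half * v[i, 0]
            x[i, 1] += half * v[i, 1]
            x[i, 2] += half * v[i, 2]
        # O: friction + noise
        if gamma > 0.0:
            for i in range(n):
                v[i, 0] = c1 * v[i, 0] + c2 * noise[step, i, 0]
                v[i, 1] = c1 * v[i, 1] + c2 * noise[step, i, 1]
                v[i, 2] = c1 * v[i, 2] + c2 * noise[step, i, 2]
        # A: half drift
        maxv2 = 0.0
        for i in range(n):
            x[i, 0] += half * v[i, 0]
            x[i, 1] += half * v[i, 1]
            x[i, 2] += half * v[i, 2]
            v2 = v[i, 0] ** 2 + v[i, 1] ** 2 + v[i, 2] ** 2
            if v2 > maxv2:
                maxv2 = v2
        if maxv2 * dt * dt > 1.0:
            return 2, npairs
        # neighbour-list maintenance
        maxd2 = 0.0
        for i in range(n):
            d2 = ((x[i, 0] - x_snap[i, 0]) ** 2
                  + (x[i, 1] - x_snap[i, 1]) ** 2
                  + (x[i, 2] - x_snap[i, 2]) ** 2)
            if d2 > maxd2:
                maxd2 = d2
        if maxd2 > thresh2:
            npairs = _build_pairs(x, rc_list, pairs)
            if npairs > cap:
                return 3, npairs
            for i in range(n):
                x_snap[i, 0] = x[i, 0]
                x_snap[i, 1] = x[i, 1]
                x_snap[i, 2] = x[i, 2]
        # B: forces + half kick
        e, ok = _forces(x, f, bonds, acent, pairs, npairs, is_cen, chain_id,
                        fene_k, fene_r02, kappa, cen_eps, cen_rc2, cen_shift,
                        wall_r, wall_k, wall_fmax, comp_f,
                        rmembers, roffsets, rpairs, rk, rd0, rfmax)
        if not ok:
            return 1, npairs
        for i in range(n):
            v[i, 0] += half * f[i, 0]
            v[i, 1] += half * f[i, 1]
            v[i, 2] += half * f[i, 2]
    return 0, npairs


# ---------------------------------------------------------------------------
# public interface
# ---------------------------------------------------------------------------

_EMPTY_I = np.zeros(0, dtype=np.int64)
_EMPTY_P = np.zeros((0, 2), dtype=np.int64)
_EMPTY_F = np.zeros(0, dtype=np.float64)


class Simulation:
    """Stateful Langevin simulation of a :class:`BeadSystem`.

    Coordinates live in the system (nm); the simulation keeps a reduced-unit
    working copy plus velocities, and writes back after every run.
    """

    def __init__(self, system: BeadSystem, params: ForceFieldParams | None = None,
                 seed: int = 0, confined: bool = True,
                 compress_force: float = 0.0):
        self.system = system
        self.params = params or ForceFieldParams()
        self._rng = np.random.default_rng(seed)
        s = self.params.sigma
        self._x = np.ascontiguousarray(system.coords / s)
        self._v = (self._rng.standard_normal((system.n_beads, 3))
                   * math.sqrt(self.params.temperature))
        self._f = np.zeros_like(self._x)
        self._bonds = system.bonds()
        self._acent = system.angle_centers()
        self._is_cen = system.centromere.astype(np.bool_)
        self._chain_id = system.chain_index
        self._confined = confined and np.isfinite(system.nucleus_radius)
        self._wall_r = (system.nucleus_radius / s - 0.5) if self._confined else -1.0
        self.compress_force = compress_force  # reduced units, eps/sigma
        self._rmembers = _EMPTY_I
        self._roffsets = np.zeros(1, dtype=np.int64)
        self._rpairs = _EMPTY_P
        self._rk = _EMPTY_F
        self._rd0 = _EMPTY_F
        self._skin = 0.4
        interaction_rc = math.sqrt(_WCA_RC2)
        if self.params.centromere_eps > 0 and self._is_cen.any():
            interaction_rc = max(interaction_rc, self.params.centromere_cutoff)
        self._rc_list = interaction_rc + self._skin
        cap = max(1024, system.n_beads * 100)
        self._pairs = np.zeros((cap, 2), dtype=np.int64)
        self._x_snap = self._x.copy()
        self._npairs = _build_pairs(self._x, self._rc_list, self._pairs)
        if self._npairs > cap:
            raise SimulationError("neighbour list overflow at startup")
        self.time = 0.0  # tau_LJ
        self._refresh_forces()

    # -- restraints ---------------------------------------------------------

    def set_restraints(self, groups: list[np.ndarray],
                       pairs: np.ndarray, k_nm: np.ndarray,
                       d0_nm: np.ndarray) -> None:
        """Install COM harmonic restraints.

        ``groups``: list of bead-index arrays; ``pairs``: (R, 2) indices into
        ``groups``; ``k_nm`` in k_B T / nm^2; ``d0_nm`` in nm.
        """
        s = self.params.sigma
        if len(groups):
            self._rmembers = np.concatenate(groups).astype(np.int64)
            self._roffsets = np.concatenate(
                [[0], np.cumsum([len(g) for g in groups])]).astype(np.int64)
        else:
            self._rmembers = _EMPTY_I
            self._roffsets = np.zeros(1, dtype=np.int64)
        self._rpairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        self._rk = np.asarray(k_nm, dtype=np.float64) * s * s
        self._rd0 = np.asarray(d0_nm, dtype=np.float64) / s
        self._refresh_forces()

    def update_restraints(self, k_nm=None, d0_nm=None) -> None:
        s = self.params.sigma
        if k_nm is not None:
            self._rk = np.asarray(k_nm, dtype=np.float64) * s * s
        if d0_nm is not None:
            self._rd0 = np.asarray(d0_nm, dtype=np.float64) / s

    def clear_restraints(self) -> None:
        self.set_restraints([], _EMPTY_P, _EMPTY_F, _EMPTY_F)

    # -- running ------------------------------------------------------------

    def _force_args(self):
        p = self.params
        cen_rc2 = p.centromere_cutoff ** 2
        irc6 = 1.0 / p.centromere_cutoff ** 6
        cen_shift = 4.0 * p.centromere_eps * (irc6 * irc6 - irc6)
        return (self._bonds, self._acent, self._is_cen, self._chain_id,
                p.fene_k, p.fene_r0 ** 2, p.kappa,
                p.centromere_eps, cen_rc2, cen_shift,
                self._wall_r, p.wall_k, p.wall_fmax, self.compress_force,
                self._rmembers, self._roffsets, self._rpairs,
                self._rk, self._rd0, p.restraint_fmax)

    def _eval_forces(self, f: np.ndarray):
        a = self._force_args()
        return _forces(self._x, f, a[0], a[1], self._pairs, self._npairs,
                       *a[2:])

    def _refresh_forces(self) -> None:
        e, ok = self._eval_forces(self._f)
        if not ok:
            raise SimulationError("invalid starting configuration "
                                  "(over-extended bond or overlapping beads)")
        self._last_energy = e

    def run_steps(self, n_steps: int, sub_chunk: int = 500) -> None:
        if n_steps <= 0:
            return
        p = self.params
        args = self._force_args()
        n = self.system.n_beads
        done = 0
        while done < n_steps:
            m = min(sub_chunk, n_steps - done)
            if p.gamma > 0 and p.temperature > 0:
                noise = self._rng.standard_normal((m, n, 3))
            else:
                noise = np.zeros((m, n, 3))
            status, npairs = _run_chunk(
                self._x, self._v, self._f, m, p.dt, p.gamma, p.temperature,
                noise, *args, self._pairs, self._npairs, self._x_snap,
                self._rc_list, self._skin)
            self._npairs = min(npairs, self._pairs.shape[0])
            if status != 0:
                self._sync()
                msg = {1: "bond extension reached FENE R0 (blow-up)",
                       2: "per-step displacement exceeded sigma",
                       3: "neighbour list overflow"}[status]
                raise SimulationError(msg)
            done += m
            self.time += m * p.dt
        self._sync()

    def run_tau(self, tau: float) -> None:
        self.run_steps(int(round(tau / self.params.dt)))

    def _sync(self) -> None:
        self.system.coords[:] = self._x * self.params.sigma

    # -- observables --------------------------------------------------------

    @property
    def potential_energy(self) -> float:
        """Current potential energy in k_B T."""
        e, _ = self._eval_forces(np.zeros_like(self._f))
        return float(e)

    @property
    def kinetic_energy(self) -> float:
        return float(0.5 * np.sum(self._v ** 2))

    def zero_velocities(self) -> None:
        self._v[:] = 0.0


def compute_forces(system: BeadSystem, params: ForceFieldParams | None = None,
                   confined: bool = True, restraints=None):
    """Forces (k_B T / nm) and potential energy (k_B T) of a configuration.

    ``restraints``: optional tuple (groups, pairs, k_nm, d0_nm) as in
    :meth:`Simulation.set_restraints`.
    """
    sim = Simulation(system, params, seed=0, confined=confined)
    if restraints is not None:
        sim.set_restraints(*restraints)
    f = np.zeros_like(sim._x)
    e, ok = sim._eval_forces(f)
    if not ok:
        raise SimulationError("invalid configuration")
    return f / sim.params.sigma, float(e)


def relax(system: BeadSystem, params: ForceFieldParams | None = None,
          duration_tau: float = 120_000.0, seed: int = 0,
          checkpoint_every_tau: float | None = None,
          confined: bool = True) -> Trajectory:
    """Relaxation phase: free Langevin evolution during which centromeres
    compact under their mutual attraction while arms expand from the initial
    rod-like state. Returns a trajectory of checkpoints (first = start,
    last = end). Production duration is 120,000 tau_LJ; desk-scale runs pass
    a smaller value."""
    params = params or ForceFieldParams()
    sim = Simulation(system, params, seed=seed, confined=confined)
    traj = Trajectory()
    traj.append(0.0, system.coords)
    if duration_tau <= 0:
        return traj
    every = checkpoint_every_tau or max(duration_tau / 10.0, params.dt)
    t = 0.0
    while t < duration_tau - 1e-9:
        step = min(every, duration_tau - t)
        sim.run_tau(step)
        t += step
        traj.append(sim.time, system.coords)
    return traj
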