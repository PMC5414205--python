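"""Overdamped Langevin dynamics of bead-spring chromosome chains in the nucleus.

Units: lengths in nm, energies in kT, friction coefficient 1 per bead, so one
time unit equals the time over which a free bead diffuses sqrt(6) nm.  The
integrator is first-order (Brownian dynamics): equilibrium statistics do not
depend on the friction model, and locus dynamics are mapped to physical time
afterwards by a single fitted scale factor.

Potentials:

* bonds — finitely extensible nonlinear springs centred on the rest length
  (sum of the two bead radii) and diverging at +/- half the rest length,
* bending — discrete worm-like-chain penalty ``kb (1 - cos theta)`` per
  triplet, with ``kb`` chosen from the persistence length P,
* excluded volume — purely repulsive truncated-and-shifted 12-6 core (WCA)
  with per-pair contact distance equal to the mean of the two bead diameters,
* confinement — harmonic wall on the excess radius beyond ``R_N - W/2``,
* SPB tether — harmonic spring of rest length L between each centromeric bead
  and the spindle pole body on the envelope,
* telomere attraction — constant outward radial force on telomeric beads,
  active only within a thin shell below the envelope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from numba import njit
from scipy.optimize import brentq

from .genome import BeadChain, NucleusGeometry, ParameterPoint

__all__ = [
    "ForceField",
    "System",
    "SimulationState",
    "Trajectory",
    "bending_constant_from_P",
    "build_system",
    "free_chain_system",
    "init_configuration",
    "langevin_step",
    "run_simulation",
]


def bending_constant_from_P(P: float, bond_length: float, exact: bool = False) -> float:
    """Bending constant (kT) for the ``kb (1 - cos theta)`` triplet penalty.

    The leading-order discretization is ``kb = P / b``, which reproduces the
    tangent-correlation decay ``exp(-s/P)`` for ``b << P``.  With
    ``exact=True`` the discrete chain is matched exactly by solving
    ``coth(kb) - 1/kb = exp(-b/P)`` for the mean joint cosine; the force field
    uses this form so finite-``b/P`` chains realize the requested P.
    """
    if P <= 0 or bond_length <= 0:
        raise ValueError("P and bond_length must be positive")
    if not exact:
        return P / bond_length
    g = math.exp(-bond_length / P)

    def langevin_gap(k):
        return 1.0 / math.tanh(k) - 1.0 / k - g

    return brentq(langevin_gap, 1e-9, 1e5)


@dataclass(frozen=True)
class ForceField:
    """Force-field scales, all in kT / nm units."""

    spring_k: float = 2.0            # kT/nm^2, FENE-centred bond stiffness
    spring_max_stretch: float = 0.5  # divergence at +/- this fraction of rest length
    epsilon: float = 1.0             # kT, excluded-volume energy scale (0 = phantom)
    wall_k: float = 1.0              # kT/nm^2, confinement (0/None geometry = free)
    spb_k: float = 0.5               # kT/nm^2, centromere-SPB tether
    telomere_force: float = 0.2      # kT/nm, outward radial force on telomeric beads
    telomere_shell: float = 100.0    # nm, active-shell thickness below the envelope
    temperature: float = 1.0         # kT
    friction: float = 1.0            # per-bead friction coefficient


@dataclass
class System:
    """A fully assembled simulation system (chains + geometry + force arrays)."""

    chains: Sequence[BeadChain]
    geometry: Optional[NucleusGeometry]
    params: ParameterPoint
    force_field: ForceField
    n_beads: int = 0
    offsets: np.ndarray = None          # start index of each chain
    diameters: np.ndarray = None
    bond_i: np.ndarray = None
    bond_j: np.ndarray = None
    bond_r0: np.ndarray = None
    ang_mid: np.ndarray = None          # middle bead of each triplet
    ang_k: np.ndarray = None
    cen_beads: np.ndarray = None        # global centromere bead indices
    tel_beads: np.ndarray = None        # global telomere bead indices
    rdna_beads: np.ndarray = None       # global rDNA bead indices (may be empty)

    def chain_slice(self, chain_index: int) -> slice:
        start = self.offsets[chain_index]
        return slice(start, start + self.chains[chain_index].bead_count)

    def global_bead(self, chain_index: int, bead_index: int) -> int:
        return int(self.offsets[chain_index] + bead_index)


@dataclass
class SimulationState:
    positions: np.ndarray
    rng_seed: int
    step: int = 0


@dataclass
class Trajectory:
    """Equally spaced post-equilibration samples of all bead positions."""

    times: np.ndarray                    # step indices
    positions: np.ndarray                # (n_samples, n_beads, 3), nm
    system: System = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.positions.shape[0]


def build_system(
    chains: Sequence[BeadChain],
    geometry: Optional[NucleusGeometry],
    params: ParameterPoint,
    force_field: ForceField | None = None,
) -> System:
    ff = force_field or ForceField()
    offsets = np.zeros(len(chains), dtype=np.int64)
    n = 0
    for c, chain in enumerate(chains):
        offsets[c] = n
        n += chain.bead_count
    diameters = np.concatenate([np.asarray(ch.bead_diameters, float) for ch in chains])

    bond_i, bond_j, bond_r0 = [], [], []
    ang_mid, ang_k = [], []
    for c, chain in enumerate(chains):
        o = offsets[c]
        for b in range(chain.bead_count - 1):
            bond_i.append(o + b)
            bond_j.append(o + b + 1)
            bond_r0.append(0.5 * (diameters[o + b] + diameters[o + b + 1]))
        for b in range(1, chain.bead_count - 1):
            # mean of the two adjacent bond rest lengths for this joint
            left = 0.5 * (diameters[o + b - 1] + diameters[o + b])
            right = 0.5 * (diameters[o + b] + diameters[o + b + 1])
            b0 = 0.5 * (left + right)
            ang_mid.append(o + b)
            ang_k.append(bending_constant_from_P(params.P, b0, exact=True) if params.P > 0 else 0.0)

    cen = np.array([offsets[c] + ch.centromere_bead_index for c, ch in enumerate(chains)], dtype=np.int64)
    tel = np.array(
        [offsets[c] + t for c, ch in enumerate(chains) for t in ch.telomere_bead_indices], dtype=np.int64
    )
    rdna = []
    for c, ch in enumerate(chains):
        if ch.rdna_bead_range is not None:
            rdna.extend(range(offsets[c] + ch.rdna_bead_range[0], offsets[c] + ch.rdna_bead_range[1]))

    if geometry is not None:
        total_bead_volume = np.sum((np.pi / 6.0) * diameters**3)
        sphere = (4.0 / 3.0) * np.pi * geometry.R_N**3
        if total_bead_volume >= sphere:
            raise ValueError(
                f"chains do not fit in nucleus: bead volume {total_bead_volume:.3g} nm^3 "
                f">= sphere volume {sphere:.3g} nm^3"
            )

    return System(
        chains=list(chains),
        geometry=geometry,
        params=params,
        force_field=ff,
        n_beads=n,
        offsets=offsets,
        diameters=diameters,
        bond_i=np.array(bond_i, dtype=np.int64),
        bond_j=np.array(bond_j, dtype=np.int64),
        bond_r0=np.array(bond_r0, dtype=float),
        ang_mid=np.array(ang_mid, dtype=np.int64),
        ang_k=np.array(ang_k, dtype=float),
        cen_beads=cen,
        tel_beads=tel,
        rdna_beads=np.array(rdna, dtype=np.int64),
    )


def free_chain_system(
    n_beads: int,
    P: float = 0.0,
    W: float = 30.0,
    C: float = 50.0,
    excluded_volume: bool = False,
    force_field: ForceField | None = None,
) -> System:
    """A single unconfined chain; ``P=0`` gives a freely jointed (Rouse) chain."""
    params = ParameterPoint(P=max(P, 1e-9), C=C, W=W, L=300.0)
    chain = BeadChain(
        chromosome="free",
        bead_count=n_beads,
        bead_diameters=[W] * n_beads,
        bp_per_bead=params.bp_per_bead,
        centromere_bead_index=n_beads // 2,
        telomere_bead_indices=(0, n_beads - 1),
        bead_bp_edges=[i * params.bp_per_bead for i in range(n_beads + 1)],
    )
    ff = force_field or ForceField(epsilon=1.0 if excluded_volume else 0.0)
    if not excluded_volume:
        ff = replace(ff, epsilon=0.0)
    system = build_system([chain], None, params, ff)
    if P <= 0:
        system.ang_k[:] = 0.0
    return system


# ---------------------------------------------------------------------------
# Initial configuration


def _wlc_direction(rng: np.random.Generator, prev_dir: np.ndarray | None, kb: float) -> np.ndarray:
    """Draw a bond direction from the discrete worm-like-chain transfer
    density p(cos) ~ exp(kb * cos) around ``prev_dir`` (uniform if None or
    kb ~ 0)."""
    if prev_dir is None or kb < 1e-6:
        u = rng.standard_normal(3)
        return u / np.linalg.norm(u)
    # inverse-CDF sample of cos(theta) for p ~ exp(kb cos)
    u = rng.uniform()
    cos_t = 1.0 + np.log(u + (1.0 - u) * math.exp(-2.0 * kb)) / kb
    cos_t = min(1.0, max(-1.0, cos_t))
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    phi = rng.uniform(0.0, 2.0 * np.pi)
    # orthonormal frame around prev_dir
    a = np.array([1.0, 0.0, 0.0]) if abs(prev_dir[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(prev_dir, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(prev_dir, e1)
    return cos_t * prev_dir + sin_t * (math.cos(phi) * e1 + math.sin(phi) * e2)


def init_configuration(system: System, seed: int, max_retries: int = 300) -> SimulationState:
    """Self-avoiding-walk placement of all chains.

    Chains grow as worm-like-chain walks with step length equal to the bond
    rest length and joint angles drawn from the equilibrium transfer density,
    so an unconfined phantom chain starts in its equilibrium ensemble.  Inside
    a nucleus each chain starts from its centromeric bead, placed within 2L of
    the SPB, and both arms are grown outwards; beads are redrawn if they leave
    the sphere or overlap an already placed bead (the overlap tolerance
    relaxes as retries accumulate, and a fully stuck chain is restarted).
    """
    rng = np.random.default_rng(seed)
    geom = system.geometry
    pos = np.zeros((system.n_beads, 3))
    check_overlap = system.force_field.epsilon > 0

    # rough mean bending constant per chain joint for proposal statistics
    def joint_k(b0):
        return bending_constant_from_P(system.params.P, b0, exact=True) if system.params.P > 1e-6 else 0.0

    placed = np.zeros((system.n_beads, 3))
    placed_d = np.zeros(system.n_beads)
    n_placed = 0

    def ok(x, diam, frac):
        if geom is not None and np.linalg.norm(x) > geom.R_N - diam / 2.0:
            return False
        if check_overlap and n_placed:
            dd = frac * 0.5 * (placed_d[:n_placed] + diam)
            if np.any(np.einsum("ij,ij->i", placed[:n_placed] - x, placed[:n_placed] - x) < dd * dd):
                return False
        return True

    def grow_chain(chain, o):
        nonlocal n_placed
        nb = chain.bead_count
        diam = np.asarray(chain.bead_diameters, float)
        start = n_placed
        if geom is not None:
            spb = np.asarray(geom.spb_position)
            L = system.params.L
            cen = chain.centromere_bead_index
            for attempt in range(max_retries):
                u = rng.standard_normal(3)
                x0 = spb + u / np.linalg.norm(u) * rng.uniform(0.3 * L, 2.0 * L)
                if np.linalg.norm(x0) <= geom.R_N - diam[cen] / 2.0 and ok(x0, diam[cen], 0.5):
                    break
            else:
                return False
        else:
            cen = 0
            x0 = np.zeros(3)
        pos[o + cen] = x0
        placed[n_placed] = x0
        placed_d[n_placed] = diam[cen]
        n_placed += 1
        for direction in (1, -1):
            prev = x0
            prev_dir = None
            idx_range = range(cen + 1, nb) if direction == 1 else range(cen - 1, -1, -1)
            prev_idx = cen
            for b in idx_range:
                b0 = 0.5 * (diam[prev_idx] + diam[b])
                kb = joint_k(b0)
                for attempt in range(max_retries):
                    frac = 0.5 * max(0.1, 1.0 - attempt / (0.75 * max_retries))
                    d = _wlc_direction(rng, prev_dir if attempt < max_retries // 2 else None, kb)
                    x = prev + d * b0
                    if ok(x, diam[b], frac):
                        break
                else:
                    n_placed = start  # discard this chain and retry from scratch
                    return False
                pos[o + b] = x
                placed[n_placed] = x
                placed_d[n_placed] = diam[b]
                n_placed += 1
                prev_dir = d
                prev, prev_idx = x, b
        return True

    for c, chain in enumerate(system.chains):
        o = system.offsets[c]
        for chain_attempt in range(20):
            if grow_chain(chain, o):
                break
        else:
            raise RuntimeError(
                f"placement failure for {chain.chromosome} after 20 restarts (overcrowded system?)"
            )
    return SimulationState(positions=pos, rng_seed=seed, step=0)


# ---------------------------------------------------------------------------
# Numba kernels


@njit(cache=True)
def _pair_neighbor_list(pos, diameters, cutoff_scale, skin, pairs_out):
    n = pos.shape[0]
    count = 0
    maxp = pairs_out.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            sij = 0.5 * (diameters[i] + diameters[j])
            cut = cutoff_scale * sij + skin
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if dx * dx + dy * dy + dz * dz < cut * cut:
                if count < maxp:
                    pairs_out[count, 0] = i
                    pairs_out[count, 1] = j
                count += 1
    return count


@njit(cache=True)
def _forces(
    pos,
    frc,
    diameters,
    bond_i,
    bond_j,
    bond_r0,
    max_stretch,
    spring_k,
    ang_mid,
    ang_k,
    epsilon,
    pairs,
    n_pairs,
    has_wall,
    R_N,
    wall_k,
    cen_beads,
    spb,
    spb_k,
    L_rest,
    tel_beads,
    tel_force,
    tel_shell,
):
    n = pos.shape[0]
    for i in range(n):
        frc[i, 0] = 0.0
        frc[i, 1] = 0.0
        frc[i, 2] = 0.0

    # bonds: FENE centred at r0, divergence at +/- max_stretch * r0
    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        r0 = bond_r0[b]
        dm = max_stretch * r0
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        d = r - r0
        x = d / dm
        if x > 0.97:
            x = 0.97
        elif x < -0.97:
            x = -0.97
        f = -spring_k * d / (1.0 - x * x)  # along bond, >0 means push j outward
        fx = f * dx / r
        fy = f * dy / r
        fz = f * dz / r
        frc[j, 0] += fx
        frc[j, 1] += fy
        frc[j, 2] += fz
        frc[i, 0] -= fx
        frc[i, 1] -= fy
        frc[i, 2] -= fz

    # bending: U = k (1 - cos theta) on consecutive bond pairs
    for a in range(ang_mid.shape[0]):
        j = ang_mid[a]
        k = ang_k[a]
        if k == 0.0:
            continue
        i = j - 1
        l = j + 1
        b1x = pos[j, 0] - pos[i, 0]
        b1y = pos[j, 1] - pos[i, 1]
        b1z = pos[j, 2] - pos[i, 2]
        b2x = pos[l, 0] - pos[j, 0]
        b2y = pos[l, 1] - pos[j, 1]
        b2z = pos[l, 2] - pos[j, 2]
        n1 = math.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
        n2 = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if n1 < 1e-12 or n2 < 1e-12:
            continue
        e1x, e1y, e1z = b1x / n1, b1y / n1, b1z / n1
        e2x, e2y, e2z = b2x / n2, b2y / n2, b2z / n2
        c = e1x * e2x + e1y * e2y + e1z * e2z
        # dU/dr = -k dc/dr ; F = k dc/dr
        gix = -(e2x - c * e1x) / n1
        giy = -(e2y - c * e1y) / n1
        giz = -(e2z - c * e1z) / n1
        glx = (e1x - c * e2x) / n2
        gly = (e1y - c * e2y) / n2
        glz = (e1z - c * e2z) / n2
        frc[i, 0] += k * gix
        frc[i, 1] += k * giy
        frc[i, 2] += k * giz
        frc[l, 0] += k * glx
        frc[l, 1] += k * gly
        frc[l, 2] += k * glz
        frc[j, 0] -= k * (gix + glx)
        frc[j, 1] -= k * (giy + gly)
        frc[j, 2] -= k * (giz + glz)

    # excluded volume: WCA with per-pair sigma
    if epsilon > 0.0:
        for p in range(n_pairs):
            i = pairs[p, 0]
            j = pairs[p, 1]
            sij = 0.5 * (diameters[i] + diameters[j])
            cut2 = 1.2599210498948732 * sij * sij  # (2^(1/6) s)^2
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < cut2 and r2 > 1e-12:
                sr2 = sij * sij / r2
                sr6 = sr2 * sr2 * sr2
                fmag = 24.0 * epsilon * (2.0 * sr6 * sr6 - sr6) / r2  # F/r
                # cap the core force for integrator stability
                fcap = 50.0 / math.sqrt(r2)
                if fmag > fcap:
                    fmag = fcap
                frc[i, 0] += fmag * dx
                frc[i, 1] += fmag * dy
                frc[i, 2] += fmag * dz
                frc[j, 0] -= fmag * dx
                frc[j, 1] -= fmag * dy
                frc[j, 2] -= fmag * dz

    if has_wall:
        # confinement wall + telomere shell force + SPB tethers
        for i in range(n):
            r = math.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
            if r < 1e-12:
                continue
            lim = R_N - 0.5 * diameters[i]
            if r > lim:
                f = -wall_k * (r - lim) / r
                frc[i, 0] += f * pos[i, 0]
                frc[i, 1] += f * pos[i, 1]
                frc[i, 2] += f * pos[i, 2]
        for t in range(tel_beads.shape[0]):
            i = tel_beads[t]
            r = math.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
            if r < 1e-12:
                continue
            lim = R_N - 0.5 * diameters[i]
            if r > lim - tel_shell:
                f = tel_force / r
                frc[i, 0] += f * pos[i, 0]
                frc[i, 1] += f * pos[i, 1]
                frc[i, 2] += f * pos[i, 2]
        for t in range(cen_beads.shape[0]):
            i = cen_beads[t]
            dx = pos[i, 0] - spb[0]
            dy = pos[i, 1] - spb[1]
            dz = pos[i, 2] - spb[2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            if r < 1e-12:
                continue
            f = -spb_k * (r - L_rest) / r
            frc[i, 0] += f * dx
            frc[i, 1] += f * dy
            frc[i, 2] += f * dz


@njit(cache=True)
def _sim_block(
    pos,
    frc,
    noise,
    noise_off,
    n_block,
    mob,
    kick,
    ref_pos,
    skin2,
    diameters,
    bond_i,
    bond_j,
    bond_r0,
    max_stretch,
    spring_k,
    ang_mid,
    ang_k,
    epsilon,
    pairs,
    n_pairs,
    has_wall,
    R_N,
    wall_k,
    cen_beads,
    spb,
    spb_k,
    L_rest,
    tel_beads,
    tel_force,
    tel_shell,
):
    """Advance up to ``n_block`` steps; returns steps done (early exit when the
    neighbor list needs rebuilding)."""
    n = pos.shape[0]
    ni = noise_off
    for step in range(n_block):
        _forces(
            pos,
            frc,
            diameters,
            bond_i,
            bond_j,
            bond_r0,
            max_stretch,
            spring_k,
            ang_mid,
            ang_k,
            epsilon,
            pairs,
            n_pairs,
            has_wall,
            R_N,
            wall_k,
            cen_beads,
            spb,
            spb_k,
            L_rest,
            tel_beads,
            tel_force,
            tel_shell,
        )
        maxd2 = 0.0
        for i in range(n):
            pos[i, 0] += mob * frc[i, 0] + kick * noise[ni]
            pos[i, 1] += mob * frc[i, 1] + kick * noise[ni + 1]
            pos[i, 2] += mob * frc[i, 2] + kick * noise[ni + 2]
            ni += 3
            if epsilon > 0.0:
                dx = pos[i, 0] - ref_pos[i, 0]
                dy = pos[i, 1] - ref_pos[i, 1]
                dz = pos[i, 2] - ref_pos[i, 2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 > maxd2:
                    maxd2 = d2
        if epsilon > 0.0 and maxd2 > skin2:
            return step + 1
    return n_block


def _run_kernel(
    pos,
    *,
    diameters,
    bond_i,
    bond_j,
    bond_r0,
    max_stretch,
    spring_k,
    ang_mid,
    ang_k,
    epsilon,
    has_wall,
    R_N,
    wall_k,
    cen_beads,
    spb,
    spb_k,
    L_rest,
    tel_beads,
    tel_force,
    tel_shell,
    dt,
    kT,
    gamma,
    n_steps,
    sample_every,
    first_sample_step,
    samples,
    seed,
    skin,
):
    """Python driver around the compiled step kernel.

    Runs the dynamics in blocks of a few hundred steps, regenerating the
    Gaussian noise buffer per block and rebuilding the excluded-volume
    neighbor list whenever any bead has moved more than half the skin since
    the last build.  The per-block Python overhead is negligible against the
    compiled inner loop.
    """
    rng = np.random.default_rng(seed)
    n = pos.shape[0]
    frc = np.zeros((n, 3))
    max_pairs = 96 * n + 4096
    pairs = np.zeros((max_pairs, 2), dtype=np.int64)
    n_pairs = 0
    ref_pos = pos.copy()
    mob = dt / gamma
    kick = math.sqrt(2.0 * kT * dt / gamma)
    sample_idx = 0
    need_rebuild = True
    skin2 = 0.25 * skin * skin
    chunk = 256
    noise = rng.standard_normal(chunk * n * 3)
    noise_off = 0
    done = 0
    next_sample = first_sample_step
    ev = epsilon > 0.0
    while done < n_steps:
        if ev and need_rebuild:
            n_pairs = _pair_neighbor_list(pos, diameters, 1.122462048309373, skin, pairs)
            if n_pairs > max_pairs:
                return -2, sample_idx
            ref_pos[:, :] = pos
            need_rebuild = False
        blk = min(chunk, n_steps - done)
        if next_sample > done:
            blk = min(blk, next_sample - done)
        if noise_off + 3 * n * blk > noise.shape[0]:
            noise = rng.standard_normal(chunk * n * 3)
            noise_off = 0
        did = _sim_block(
            pos,
            frc,
            noise,
            noise_off,
            blk,
            mob,
            kick,
            ref_pos,
            skin2,
            diameters,
            bond_i,
            bond_j,
            bond_r0,
            max_stretch,
            spring_k,
            ang_mid,
            ang_k,
            epsilon,
            pairs,
            n_pairs,
            has_wall,
            R_N,
            wall_k,
            cen_beads,
            spb,
            spb_k,
            L_rest,
            tel_beads,
            tel_force,
            tel_shell,
        )
        noise_off += 3 * n * did
        done += did
        if did < blk:
            need_rebuild = True
        if done == next_sample:
            if not math.isfinite(pos[0, 0]):
                return -done, sample_idx
            if sample_idx < samples.shape[0]:
                samples[sample_idx] = pos
                sample_idx += 1
            next_sample += sample_every
    if not np.all(np.isfinite(pos)):
        return -done, sample_idx
    return 0, sample_idx


def _kernel_args(system: System):
    geom = system.geometry
    has_wall = geom is not None
    ff = system.force_field
    if has_wall:
        R_N = geom.R_N
        spb = np.asarray(geom.spb_position, float)
    else:
        R_N = 0.0
        spb = np.zeros(3)
    return dict(
        diameters=system.diameters,
        bond_i=system.bond_i,
        bond_j=system.bond_j,
        bond_r0=system.bond_r0,
        max_stretch=ff.spring_max_stretch,
        spring_k=ff.spring_k,
        ang_mid=system.ang_mid,
        ang_k=system.ang_k,
        epsilon=ff.epsilon,
        has_wall=has_wall,
        R_N=R_N,
        wall_k=ff.wall_k if has_wall else 0.0,
        cen_beads=system.cen_beads if has_wall else np.zeros(0, dtype=np.int64),
        spb=spb,
        spb_k=ff.spb_k,
        L_rest=system.params.L,
        tel_beads=system.tel_beads if has_wall else np.zeros(0, dtype=np.int64),
        tel_force=ff.telomere_force,
        tel_shell=ff.telomere_shell,
    )


def default_dt(system: System) -> float:
    """Time step from the stability bound of the stiffest potential.

    Chosen so that ``k_max * dt / friction <= 0.1`` and the RMS random step is
    far below W/10.
    """
    ff = system.force_field
    k_max = max(ff.spring_k, ff.wall_k, ff.spb_k, 1.0)
    dt = 0.04 * ff.friction / k_max
    rms_step = math.sqrt(6.0 * ff.temperature * dt / ff.friction)
    if rms_step > system.params.W / 10.0 * 3.0:
        dt = (system.params.W * 0.3) ** 2 * ff.friction / (6.0 * ff.temperature)
    return dt


def langevin_step(
    state: SimulationState, system: System, dt: float, n_steps: int = 1, seed: int | None = None
) -> SimulationState:
    """Advance ``n_steps`` overdamped Langevin steps and return the new state."""
    seed = state.rng_seed if seed is None else seed
    pos = state.positions.copy()
    samples = np.zeros((1, system.n_beads, 3))
    ff = system.force_field
    status, _ = _run_kernel(
        pos,
        **_kernel_args(system),
        dt=dt,
        kT=ff.temperature,
        gamma=ff.friction,
        n_steps=n_steps,
        sample_every=max(n_steps, 1),
        first_sample_step=n_steps,
        samples=samples,
        seed=(seed + state.step) % 2**31,
        skin=15.0,
    )
    if status < 0:
        raise FloatingPointError(f"integration diverged near step {-status} (dt too large?)")
    return SimulationState(positions=pos, rng_seed=state.rng_seed, step=state.step + n_steps)


def run_simulation(
    system: System,
    n_steps: int,
    sample_every: int,
    equilibration_steps: int = 0,
    seed: int = 0,
    dt: float | None = None,
    initial_state: SimulationState | None = None,
) -> Trajectory:
    """Run Langevin dynamics and return post-equilibration samples.

    Samples are recorded every ``sample_every`` steps once
    ``equilibration_steps`` have elapsed.  An equilibration diagnostic (linear
    trend of the radius of gyration across samples) is stored in
    ``Trajectory.metadata`` and triggers a warning, not an error.
    """
    if n_steps <= equilibration_steps:
        raise ValueError("n_steps must exceed equilibration_steps")
    if dt is None:
        dt = default_dt(system)
    state = initial_state or init_configuration(system, seed)
    pos = state.positions.copy()
    first = equilibration_steps + sample_every
    n_samples = (n_steps - equilibration_steps) // sample_every
    samples = np.zeros((n_samples, system.n_beads, 3))
    ff = system.force_field
    status, got = _run_kernel(
        pos,
        **_kernel_args(system),
        dt=dt,
        kT=ff.temperature,
        gamma=ff.friction,
        n_steps=n_steps,
        sample_every=sample_every,
        first_sample_step=first,
        samples=samples,
        seed=seed % 2**31,
        skin=15.0,
    )
    if status < 0:
        raise FloatingPointError(f"integration diverged near step {-status} (dt too large?)")
    samples = samples[:got]
    times = first + sample_every * np.arange(got)

    meta = {
        "seed": seed,
        "dt": dt,
        "sample_every": sample_every,
        "equilibration_steps": equilibration_steps,
        "n_steps": n_steps,
        "params": system.params,
        "geometry": system.geometry,
    }
    meta["equilibration"] = _equilibration_diagnostic(samples)
    if not meta["equilibration"]["converged"]:
        warnings.warn(
            "radius-of-gyration trend suggests incomplete equilibration "
            f"(t-stat {meta['equilibration']['t_stat']:.1f})",
            RuntimeWarning,
            stacklevel=2,
        )
    return Trajectory(times=times, positions=samples, system=system, metadata=meta)


def _equilibration_diagnostic(samples: np.ndarray) -> dict:
    """Trend test on the whole-system radius of gyration across samples."""
    if samples.shape[0] < 8:
        return {"converged": True, "t_stat": 0.0, "rg2": float("nan")}
    com = samples.mean(axis=1, keepdims=True)
    rg2 = ((samples - com) ** 2).sum(axis=2).mean(axis=1)
    from scipy import stats

    x = np.arange(rg2.size)
    res = stats.linregress(x, rg2)
    # crude effective-sample correction: block the series into 10 chunks
    blocks = np.array_split(rg2, 10)
    bm = np.array([b.mean() for b in blocks])
    resb = stats.linregress(np.arange(10), bm)
    t = resb.slope / (resb.stderr + 1e-300)
    if not math.isfinite(t):  # degenerate series (e.g. single immobile bead)
        t = 0.0
    return {"converged": bool(abs(t) < 5.0), "t_stat": float(t), "rg2": float(rg2.mean()), "slope": float(res.slope)}
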