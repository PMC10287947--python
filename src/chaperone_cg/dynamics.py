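"""Langevin time propagation and restraints.

The integrator is the BAOAB splitting of underdamped Langevin dynamics at
the source model's constants (step 0.3 τ, T = 300 K, friction 0.843 /τ).
Bead masses are uniform (kinetics are only interpreted as relative event
frequencies, never as physical rates).  Runs execute in legs of one
snapshot stride, each leg with a seed derived from the master seed, which
makes checkpoints at any recorded frame exactly resumable.

Restraints: harmonic position anchors (optionally moving, which implements
the translocase pulling protocol), a torus-shaped translocase treated as a
smooth repulsive surface, a harmonic COM-distance umbrella, and a
flat-bottom spherical confinement for open-boundary binding simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .cg_model import CGStructure, CGTopology
from .constants import kt
from .energy import EnergyReport, ForceFieldParams, nonbonded_exclusions

ENERGY_TERM_NAMES = ("bonded", "contact", "excluded_volume", "electrostatic",
                     "restraint", "kinetic")


@dataclass
class SimulationParams:
    """Integrator constants; dt in internal time units τ."""

    dt: float = 0.3
    temperature: float = 300.0
    friction: float = 0.843
    n_steps: int = 10_000
    snapshot_stride: int = 10_000
    seed: int = 0
    mass: float = 200.0          # uniform bead mass, internal units
    neighbor_rebuild: int = 10   # steps between Verlet-list rebuilds
    neighbor_skin: float = 3.0   # Å

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.temperature < 0 or self.friction < 0:
            raise ValueError("dt must be positive; T and γ non-negative")
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if self.snapshot_stride <= 0:
            raise ValueError("snapshot stride must be positive")

    @property
    def kt(self) -> float:
        return kt(self.temperature)


# --------------------------------------------------------------------------
# restraints
# --------------------------------------------------------------------------

@dataclass
class PositionAnchor:
    """Anchor a bead set to a reference point: U = k Σ |x_i − ref_i|².

    Per-bead reference positions preserve the set's internal geometry
    (ref_i = point + (x_i(0) − centroid)); ``velocity`` (Å/step) turns the
    anchor into the moving handle used for translocase pulling.
    """

    beads: np.ndarray
    references: np.ndarray
    k: float
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @classmethod
    def to_point(cls, structure_positions, beads, point, k,
                 velocity=(0.0, 0.0, 0.0)) -> "PositionAnchor":
        beads = np.asarray(beads, dtype=np.int64)
        if beads.size == 0:
            raise ValueError("anchor bead set is empty")
        if k <= 0:
            raise ValueError("anchor spring constant must be positive")
        xyz = np.asarray(structure_positions, float)[beads]
        refs = np.asarray(point, float) + (xyz - xyz.mean(axis=0))
        return cls(beads=beads, references=refs, k=float(k),
                   velocity=np.asarray(velocity, float))

    def energy_forces(self, positions, step_time: float = 0.0):
        pos = np.asarray(positions, float)
        forces = np.zeros_like(pos)
        refs = self.references + self.velocity * step_time
        d = pos[self.beads] - refs
        energy = self.k * float(np.sum(d * d))
        forces[self.beads] = -2.0 * self.k * d
        return energy, forces


@dataclass
class Torus:
    """Repulsive torus (translocase stand-in): smooth tube surface.

    Beads inside the tube (distance d from the circle of radius
    ``major_radius`` about ``axis`` below ``tube_radius``) feel a
    harmonic repulsion U = A·((r_t − d)/r_t)², which caps the maximum
    force at 2A/r_t — a bounded wall that blocks the nucleosome without
    launching beads that get pressed against it.  DNA passes through
    the pore of radius ``major_radius − tube_radius``.
    """

    center: np.ndarray
    axis: np.ndarray
    major_radius: float = 25.0
    tube_radius: float = 15.0
    strength: float = 300.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, float)
        self.axis = np.asarray(self.axis, float)
        self.axis = self.axis / np.linalg.norm(self.axis)
        if self.tube_radius <= 0 or self.major_radius <= self.tube_radius * 0.2:
            raise ValueError("torus radii invalid")

    def param_vector(self) -> np.ndarray:
        return np.concatenate([self.center, self.axis,
                               [self.major_radius, self.tube_radius,
                                self.strength]])

    def energy_forces(self, positions, step_time: float = 0.0):
        pos = np.asarray(positions, float)
        forces = np.zeros_like(pos)
        v = pos - self.center
        z = v @ self.axis
        p = v - np.outer(z, self.axis)
        rho = np.linalg.norm(p, axis=1)
        d = np.sqrt((rho - self.major_radius) ** 2 + z**2)
        rt = self.tube_radius
        mask = (d < rt) & (d > 1e-9)
        u = (rt - d[mask]) / rt
        energy = self.strength * float(np.sum(u * u))
        dU_dd = -2.0 * self.strength * u / rt
        with np.errstate(invalid="ignore", divide="ignore"):
            phat = np.where(rho[:, None] > 1e-9, p / rho[:, None], 0.0)
        grad = ((rho - self.major_radius)[:, None] * phat
                + np.outer(z, self.axis)) / d[:, None]
        forces[mask] = -(dU_dd[:, None] * grad[mask])
        return energy, forces


@dataclass
class Umbrella:
    """Harmonic COM-distance bias U = k (d − d0)² (no ½ prefactor)."""

    group_a: np.ndarray
    group_b: np.ndarray
    d0: float
    k: float = 1.0

    def __post_init__(self) -> None:
        self.group_a = np.asarray(self.group_a, dtype=np.int64)
        self.group_b = np.asarray(self.group_b, dtype=np.int64)
        if self.k <= 0:
            raise ValueError("umbrella spring constant must be positive")
        if np.intersect1d(self.group_a, self.group_b).size:
            raise ValueError("umbrella groups overlap")

    def distance(self, positions) -> float:
        pos = np.asarray(positions, float)
        return float(np.linalg.norm(pos[self.group_a].mean(axis=0)
                                    - pos[self.group_b].mean(axis=0)))

    def energy_forces(self, positions, step_time: float = 0.0):
        pos = np.asarray(positions, float)
        forces = np.zeros_like(pos)
        ca = pos[self.group_a].mean(axis=0)
        cb = pos[self.group_b].mean(axis=0)
        dvec = ca - cb
        d = np.linalg.norm(dvec)
        energy = self.k * (d - self.d0) ** 2
        if d > 1e-9:
            g = 2.0 * self.k * (d - self.d0) * dvec / d
            forces[self.group_a] -= g / len(self.group_a)
            forces[self.group_b] += g / len(self.group_b)
        return float(energy), forces


@dataclass
class SphericalConfinement:
    """Flat-bottom sphere: U = k (|x − c| − R)² outside radius R."""

    radius: float
    k: float = 0.1
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, float)
        if self.radius <= 0 or self.k <= 0:
            raise ValueError("confinement radius and k must be positive")

    def energy_forces(self, positions, step_time: float = 0.0):
        pos = np.asarray(positions, float)
        forces = np.zeros_like(pos)
        d = pos - self.center
        r = np.linalg.norm(d, axis=1)
        mask = r > self.radius
        dev = r[mask] - self.radius
        energy = self.k * float(np.sum(dev * dev))
        forces[mask] = (-2.0 * self.k * dev / r[mask])[:, None] * d[mask]
        return energy, forces


def apply_restraints(positions, restraints, step_time: float = 0.0):
    """Total restraint energy and forces (python reference path)."""
    pos = np.asarray(positions, float)
    total = 0.0
    forces = np.zeros_like(pos)
    for r in restraints:
        e, f = r.energy_forces(pos, step_time)
        total += e
        forces += f
    return total, forces


# --------------------------------------------------------------------------
# trajectory container and state
# --------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Snapshot frames with per-term energies.

    ``positions``: (n_frames, n_beads, 3) Å; ``energies``: (n_frames, 6)
    kcal/mol in :data:`ENERGY_TERM_NAMES` order; ``steps``: MD step of each
    frame; ``umbrella_distance`` is 0 where no umbrella was active.
    """

    positions: np.ndarray
    energies: np.ndarray
    steps: np.ndarray
    umbrella_distance: np.ndarray
    dt: float
    seed: int
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_beads(self) -> int:
        return self.positions.shape[1]

    def energy_report(self, frame: int) -> EnergyReport:
        e = self.energies[frame]
        return EnergyReport(bonded=e[0], contact=e[1], excluded_volume=e[2],
                            electrostatic=e[3], restraint=e[4])

    def term(self, name: str) -> np.ndarray:
        return self.energies[:, ENERGY_TERM_NAMES.index(name)]

    def extend(self, other: "Trajectory") -> "Trajectory":
        if other.n_beads != self.n_beads:
            raise ValueError("bead count mismatch")
        return Trajectory(
            positions=np.concatenate([self.positions, other.positions[1:]]),
            energies=np.concatenate([self.energies, other.energies[1:]]),
            steps=np.concatenate([self.steps, other.steps[1:]]),
            umbrella_distance=np.concatenate(
                [self.umbrella_distance, other.umbrella_distance[1:]]),
            dt=self.dt, seed=self.seed, metadata=dict(self.metadata))


@dataclass
class SimulationState:
    """Exactly resumable propagation state."""

    positions: np.ndarray
    velocities: np.ndarray
    step: int
    master_seed: int


# --------------------------------------------------------------------------
# system packing and the run driver
# --------------------------------------------------------------------------

class PackedSystem:
    """Arrays extracted once from (structure, topology, force field)."""

    def __init__(self, structure: CGStructure, topology: CGTopology,
                 ff: ForceFieldParams, frozen=None):
        topology.validate(structure.n_beads)
        n = structure.n_beads
        self.n_beads = n
        self.charges = structure.charges
        self.ff = ff

        def _pack(terms, width, default_k):
            idx = np.zeros((len(terms), width), dtype=np.int64)
            val = np.zeros(len(terms))
            kval = np.full(len(terms), default_k)
            for r, term in enumerate(terms):
                idx[r] = term[:width]
                val[r] = term[width]
                if len(term) > width + 1:
                    kval[r] = term[width + 1]
            return idx, val, kval

        self.bonds_idx, self.bonds_b0, self.bonds_k = _pack(
            topology.bonds, 2, ff.k_bond)
        self.angles_idx, self.angles_t0, self.angles_k = _pack(
            topology.angles, 3, ff.k_angle)
        self.flex_idx = np.zeros((len(topology.flex_angles), 3), dtype=np.int64)
        for r, term in enumerate(topology.flex_angles):
            self.flex_idx[r] = term
        self.dih_idx, self.dih_p0, self.dih_k = _pack(
            topology.dihedrals, 4, ff.k_dihedral)

        mult = ff.class_multipliers
        ncon = len(topology.contacts)
        self.con_idx = np.zeros((ncon, 2), dtype=np.int64)
        self.con_r0 = np.zeros(ncon)
        self.con_eps = np.zeros(ncon)
        for r, c in enumerate(topology.contacts):
            self.con_idx[r] = (c.i, c.j)
            self.con_r0[r] = c.r0
            self.con_eps[r] = c.epsilon * mult.get(c.contact_class, 1.0)

        ev_excl, dh_excl = nonbonded_exclusions(structure, topology)
        self.ev_excl_keys = np.array(sorted(i * n + j for i, j in ev_excl),
                                     dtype=np.int64)
        self.dh_excl_keys = np.array(sorted(i * n + j for i, j in dh_excl),
                                     dtype=np.int64)

        self.frozen = np.zeros(n, dtype=bool)
        if frozen is not None:
            self.frozen[np.asarray(frozen, dtype=np.int64)] = True


def _split_restraints(restraints, positions):
    anchors = [r for r in restraints if isinstance(r, PositionAnchor)]
    tori = [r for r in restraints if isinstance(r, Torus)]
    umbrellas = [r for r in restraints if isinstance(r, Umbrella)]
    spheres = [r for r in restraints if isinstance(r, SphericalConfinement)]
    if len(tori) > 1 or len(umbrellas) > 1 or len(spheres) > 1:
        raise ValueError("at most one torus/umbrella/confinement supported")
    n_anchor_beads = sum(len(a.beads) for a in anchors)
    a_idx = np.zeros(n_anchor_beads, dtype=np.int64)
    a_ref = np.zeros((n_anchor_beads, 3))
    a_k = np.zeros(n_anchor_beads)
    a_vel = np.zeros((n_anchor_beads, 3))
    row = 0
    for a in anchors:
        m = len(a.beads)
        a_idx[row:row + m] = a.beads
        a_ref[row:row + m] = a.references
        a_k[row:row + m] = a.k
        a_vel[row:row + m] = a.velocity
        row += m
    if tori:
        torus_param, torus_on = tori[0].param_vector(), 1
    else:
        torus_param, torus_on = np.zeros(9), 0
    if umbrellas:
        u = umbrellas[0]
        umb = (u.group_a, u.group_b, u.d0, u.k, 1)
    else:
        umb = (np.zeros(1, dtype=np.int64), np.zeros(1, dtype=np.int64),
               0.0, 0.0, 0)
    if spheres:
        s = spheres[0]
        sph = (s.center, s.radius, s.k, 1)
    else:
        sph = (np.zeros(3), 0.0, 0.0, 0)
    return (a_idx, a_ref, a_k, a_vel), (torus_param, torus_on), umb, sph


def _leg_seed(master_seed: int, leg: int) -> int:
    """Decorrelated per-leg RNG seed (splitmix64 of master and leg).

    Plain arithmetic seed derivation leaves nearby Mersenne-Twister
    streams measurably correlated, which biases long-run diffusion; the
    avalanche hash removes that.
    """
    mask = 0xFFFFFFFFFFFFFFFF
    x = ((master_seed & mask) * 0x9E3779B97F4A7C15 + leg + 0x632BE59BD9B4E019) & mask
    x ^= x >> 30
    x = (x * 0xBF58476D1CE4E5B9) & mask
    x ^= x >> 27
    x = (x * 0x94D049BB133111EB) & mask
    x ^= x >> 31
    return int(x % (2**31 - 1))


def initial_velocities(n_beads: int, params: SimulationParams,
                       frozen=None) -> np.ndarray:
    rng = np.random.default_rng(_leg_seed(params.seed, -1) % 2**31)
    vel = rng.normal(0.0, np.sqrt(params.kt / params.mass), size=(n_beads, 3))
    if frozen is not None:
        vel[np.asarray(frozen, dtype=np.int64)] = 0.0
    return vel


def run_simulation(structure: CGStructure, topology: CGTopology,
                   params: SimulationParams, restraints=(),
                   forcefield: ForceFieldParams | None = None,
                   state: SimulationState | None = None,
                   frozen=None) -> tuple[Trajectory, SimulationState]:
    """Propagate and record a trajectory.

    Returns (trajectory, final state).  Passing the returned state back in
    continues the run exactly (legs are seeded from the master seed and
    the absolute leg index, so a chained run is bitwise identical to an
    unbroken one on the same platform).
    """
    ff = forcefield or ForceFieldParams(temperature=params.temperature)
    packed = PackedSystem(structure, topology, ff, frozen=frozen)
    n = packed.n_beads

    if state is None:
        pos = structure.positions.copy()
        vel = initial_velocities(n, params, frozen=np.flatnonzero(packed.frozen))
        step0 = 0
    else:
        pos = np.array(state.positions, dtype=float, copy=True)
        vel = np.array(state.velocities, dtype=float, copy=True)
        step0 = state.step

    inv_mass = np.full(n, 1.0 / params.mass)
    inv_mass[packed.frozen] = 0.0

    (a_idx, a_ref, a_k, a_vel), (torus_param, torus_on), \
        (umb_a, umb_b, umb_d0, umb_k, umb_on), \
        (sph_c, sph_R, sph_k, sph_on) = _split_restraints(restraints, pos)

    stride = min(params.snapshot_stride, max(params.n_steps, 1))
    n_frames = params.n_steps // stride + 1
    frames_pos = np.zeros((n_frames, n, 3))
    frames_en = np.zeros((n_frames, _kernels.N_ENERGY_TERMS))
    frames_umb = np.zeros(n_frames)
    frames_steps = np.zeros(n_frames, dtype=np.int64)

    leg_out_pos = np.zeros((2, n, 3))
    leg_out_en = np.zeros((2, _kernels.N_ENERGY_TERMS))
    leg_out_umb = np.zeros(2)

    dh_pref = _dh_prefactor(ff)
    lam = ff.debye_length()

    # initial frame (leg of 0 steps evaluates energies once)
    status, bad = _run_leg(packed, pos, vel, inv_mass, 0, stride, params,
                           a_idx, a_ref, a_k, a_vel, torus_param, torus_on,
                           umb_a, umb_b, umb_d0, umb_k, umb_on,
                           sph_c, sph_R, sph_k, sph_on,
                           dh_pref, lam, _leg_seed(params.seed, 0), step0,
                           leg_out_pos, leg_out_en, leg_out_umb)
    frames_pos[0] = leg_out_pos[0]
    frames_en[0] = leg_out_en[0]
    frames_umb[0] = leg_out_umb[0]
    frames_steps[0] = step0

    done = 0
    frame = 1
    while done < params.n_steps:
        leg_steps = min(stride, params.n_steps - done)
        leg_index = (step0 + done) // stride
        seed = _leg_seed(params.seed, leg_index + 1)
        status, bad = _run_leg(packed, pos, vel, inv_mass, leg_steps,
                               leg_steps, params,
                               a_idx, a_ref, a_k, a_vel, torus_param,
                               torus_on, umb_a, umb_b, umb_d0, umb_k, umb_on,
                               sph_c, sph_R, sph_k, sph_on,
                               dh_pref, lam, seed, step0 + done,
                               leg_out_pos, leg_out_en, leg_out_umb)
        if status != _kernels.OK:
            raise FloatingPointError(
                f"non-finite coordinate for bead {bad} at step "
                f"{step0 + done + leg_steps}")
        done += leg_steps
        frames_pos[frame] = leg_out_pos[1]
        frames_en[frame] = leg_out_en[1]
        frames_umb[frame] = leg_out_umb[1]
        frames_steps[frame] = step0 + done
        frame += 1

    traj = Trajectory(positions=frames_pos[:frame], energies=frames_en[:frame],
                      steps=frames_steps[:frame],
                      umbrella_distance=frames_umb[:frame],
                      dt=params.dt, seed=params.seed,
                      metadata={"temperature": params.temperature,
                                "friction": params.friction,
                                "stride": stride,
                                "mass": params.mass,
                                "n_restraints": len(restraints)})
    final = SimulationState(positions=pos.copy(), velocities=vel.copy(),
                            step=step0 + params.n_steps,
                            master_seed=params.seed)
    return traj, final


def _dh_prefactor(ff: ForceFieldParams) -> float:
    from .constants import COULOMB
    return COULOMB / ff.dielectric


def _run_leg(packed, pos, vel, inv_mass, n_steps, stride, params,
             a_idx, a_ref, a_k, a_vel, torus_param, torus_on,
             umb_a, umb_b, umb_d0, umb_k, umb_on,
             sph_c, sph_R, sph_k, sph_on,
             dh_pref, lam, seed, step_offset,
             out_pos, out_en, out_umb):
    ff = packed.ff
    return _kernels.run_langevin(
        pos, vel, inv_mass, packed.charges,
        packed.bonds_idx, packed.bonds_b0, packed.bonds_k,
        packed.angles_idx, packed.angles_t0, packed.angles_k,
        packed.flex_idx, ff.theta0_flex, ff.k_flex_angle,
        packed.dih_idx, packed.dih_p0, packed.dih_k,
        packed.con_idx, packed.con_r0, packed.con_eps,
        packed.ev_excl_keys, packed.dh_excl_keys,
        ff.sigma_ev, ff.epsilon_ev, ff.ev_cutoff,
        dh_pref, lam, ff.dh_cutoff,
        a_idx, a_ref, a_k, a_vel,
        torus_param, torus_on,
        umb_a, umb_b, umb_d0, umb_k, umb_on,
        sph_c, sph_R, sph_k, sph_on,
        params.dt, params.friction, params.kt,
        n_steps, max(stride, 1), params.neighbor_rebuild,
        params.neighbor_skin, seed, step_offset,
        out_pos, out_en, out_umb)


def langevin_step(state: SimulationState, structure: CGStructure,
                  topology: CGTopology, params: SimulationParams,
                  restraints=(), forcefield: ForceFieldParams | None = None,
                  n_steps: int = 1) -> SimulationState:
    """Advance a handful of steps; thin wrapper over the leg driver."""
    p = SimulationParams(dt=params.dt, temperature=params.temperature,
                         friction=params.friction, n_steps=n_steps,
                         snapshot_stride=n_steps, seed=params.seed,
                         mass=params.mass,
                         neighbor_rebuild=params.neighbor_rebuild,
                         neighbor_skin=params.neighbor_skin)
    _, new_state = run_simulation(structure, topology, p, restraints,
                                  forcefield, state=state)
    return new_state


# --------------------------------------------------------------------------
# translocase pulling
# --------------------------------------------------------------------------

def pull_through_torus(structure: CGStructure, topology: CGTopology,
                       params: SimulationParams, torus: Torus,
                       drag_beads, bp_bead_map: dict,
                       target_bp: int,
                       forcefield: ForceFieldParams | None = None,
                       pull_rate: float = 0.005,
                       anchor_k: float = 2.0,
                       tolerance: float = 12.0,
                       max_stages: int = 150,
                       stage_steps: int = 2_000,
                       extra_restraints=(),
                       stop_when=None):
    """Drag upstream DNA through the torus until ``target_bp`` reaches it.

    A moving anchor on ``drag_beads`` (the upstream terminal base pair)
    translates along the torus axis at ``pull_rate`` Å/step; the run is
    staged so progress can be checked.  The default stopping rule is the
    centroid of the target base pair (``bp_bead_map[target_bp]``) coming
    within ``tolerance`` Å of the torus centre; a custom predicate
    ``stop_when(positions)`` (e.g. an unwrap-boundary check) overrides
    it.  Raises RuntimeError (reporting the closest approach) if the
    step budget is exhausted.
    """
    ff = forcefield or ForceFieldParams(temperature=params.temperature)
    pos = structure.positions
    if target_bp not in bp_bead_map:
        raise ValueError(f"target bp {target_bp} not in the bead map")
    target_beads = np.asarray(bp_bead_map[target_bp], dtype=np.int64)

    def target_gap(xyz):
        return float(np.linalg.norm(xyz[target_beads].mean(axis=0)
                                    - torus.center))

    done = (stop_when if stop_when is not None
            else lambda xyz: target_gap(xyz) <= tolerance)
    if done(pos):
        return structure.copy(), None

    direction = -torus.axis  # pull away from the nucleosome side
    drag_beads = np.asarray(drag_beads, dtype=np.int64)
    state = None
    best = np.inf
    out = structure.copy()
    for stage in range(max_stages):
        # re-reference the handle to wherever the dragged end actually is,
        # so the pulling force stays bounded (the handle never runs far
        # ahead of a snagged or slowly yielding chain); the reference is
        # back-shifted because the anchor clock runs on absolute steps
        steps_so_far = 0 if state is None else state.step
        cur = out.positions
        refs = (cur[drag_beads]
                - direction * pull_rate * steps_so_far)
        anchor = PositionAnchor(beads=drag_beads, references=refs,
                                k=anchor_k,
                                velocity=direction * pull_rate)
        p = SimulationParams(dt=params.dt, temperature=params.temperature,
                             friction=params.friction, n_steps=stage_steps,
                             snapshot_stride=stage_steps,
                             seed=params.seed, mass=params.mass,
                             neighbor_rebuild=params.neighbor_rebuild,
                             neighbor_skin=params.neighbor_skin)
        traj, state = run_simulation(out, topology, p,
                                     restraints=[anchor, torus,
                                                 *extra_restraints],
                                     forcefield=ff, state=state)
        out.positions = state.positions
        best = min(best, target_gap(state.positions))
        if done(state.positions):
            return out, state
    raise RuntimeError(
        f"pulling did not bring bp {target_bp} to the torus centre within "
        f"{max_stages * stage_steps} steps (closest approach {best:.1f} Å)")
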