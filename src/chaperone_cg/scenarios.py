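"""Simulation-scenario assembly.

Builds the study conditions: a nucleosome (core + wrapped DNA + linker
arms), a torus-shaped translocase threaded on the upstream linker, the
translocase-collision protocol that peels nucleosomal DNA to a target
base pair upstream of the dyad, static anchoring that maintains the
partial unwrapping, and placement of a chaperone dimer near the exposed
histone-dimer face.  Scenario bundles are pure functions of (spec, seed).

Base-pair coordinates are dyad-centred: the central base pair of the
wrap is 0 and upstream positions are negative, so "unwrapped to −31"
reads exactly as in the unwrapping literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cg_model import CGStructure, CGTopology
from .dynamics import (PositionAnchor, SimulationParams, SphericalConfinement,
                       Torus, pull_through_torus)
from .energy import ForceFieldParams

SCENARIO_NAMES = (
    "fully_wrapped",
    "fully_wrapped_nap1",
    "partial_unwrapped",
    "partial_unwrapped_nap1",
    "partial_unwrapped_nap1dC",
    "solution_nap1_dimer",
    "solution_nap1dC_dimer",
)


@dataclass
class ScenarioSpec:
    """One named simulation condition.

    ``salt`` is the monovalent ionic strength in mol/L (0.3 default,
    0.35 for the salt-sensitivity variant).  ``chaperone_distance`` is
    the initial chaperone-COM placement from the exposed dimer COM; the
    nominal solution concentration is metadata only — every box holds a
    single chaperone copy.
    """

    name: str
    salt: float = 0.3
    replicates: int = 20
    production_steps: int = 200_000
    chaperone_distance: float = 80.0
    target_bp: int | None = None       # None → system default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(
                f"unknown scenario {self.name!r}; choose from "
                f"{SCENARIO_NAMES}")
        if self.salt <= 0:
            raise ValueError("salt concentration must be positive")

    @property
    def has_chaperone(self) -> bool:
        return "nap1" in self.name

    @property
    def chaperone_truncated(self) -> bool:
        return "dC" in self.name

    @property
    def unwrapped(self) -> bool:
        return self.name.startswith("partial_unwrapped")

    @property
    def in_solution(self) -> bool:
        return self.name.startswith("solution")


@dataclass
class NucleosomeSystem:
    """A ready-to-run assembly: structure, topology, named bead groups.

    ``groups`` names at least ``dimer_proximal``, ``dimer_distal``,
    ``tetramer``, ``dna``; chaperone groups are added on placement.
    ``bp_bead_map`` maps dyad-centred bp coordinate → bead indices of
    that base pair (all six beads, or fewer at 5′ ends).
    """

    structure: CGStructure
    topology: CGTopology
    groups: dict = field(default_factory=dict)
    bp_bead_map: dict = field(default_factory=dict)
    entry_bp: int = 0
    exit_bp: int = 0
    forcefield: ForceFieldParams = field(default_factory=ForceFieldParams)
    restraints: list = field(default_factory=list)
    torus: Torus | None = None
    metadata: dict = field(default_factory=dict)

    def copy(self) -> "NucleosomeSystem":
        return NucleosomeSystem(
            structure=self.structure.copy(),
            topology=self.topology,
            groups={k: np.array(v) for k, v in self.groups.items()},
            bp_bead_map={k: np.array(v) for k, v in self.bp_bead_map.items()},
            entry_bp=self.entry_bp, exit_bp=self.exit_bp,
            forcefield=self.forcefield,
            restraints=list(self.restraints), torus=self.torus,
            metadata=dict(self.metadata))

    def group_com(self, name: str) -> np.ndarray:
        return self.structure.positions[self.groups[name]].mean(axis=0)

    def histone_core_beads(self) -> np.ndarray:
        return np.concatenate([self.groups["dimer_proximal"],
                               self.groups["dimer_distal"],
                               self.groups["tetramer"]])

    def all_restraints(self) -> list:
        out = list(self.restraints)
        if self.torus is not None:
            out.append(self.torus)
        return out


def assemble_nucleosome_system(system: NucleosomeSystem,
                               upstream_bp: int, downstream_bp: int,
                               torus_major_radius: float = 25.0,
                               torus_tube_radius: float = 15.0,
                               torus_strength: float = 5.0,
                               clash_tolerance: float = 1.0
                               ) -> NucleosomeSystem:
    """Place the translocase torus on the upstream linker and verify the
    assembly.

    The incoming system must already carry its linker arms (the DNA
    builder grafts them tangentially at the entry/exit).  The torus is
    centred mid-linker with its axis along the local DNA direction, and
    linker/core steric clashes are rejected.
    """
    bp_coords = sorted(system.bp_bead_map)
    have_up = system.entry_bp - min(bp_coords)
    have_down = max(bp_coords) - system.exit_bp
    if have_up < upstream_bp or have_down < downstream_bp:
        raise ValueError(
            f"system carries {have_up}/{have_down} linker bp, requested "
            f"{upstream_bp}/{downstream_bp}")
    out = system.copy()
    pos = out.structure.positions
    if upstream_bp > 0:
        mid = min(bp_coords) + max(upstream_bp // 4, 1)
        a = pos[out.bp_bead_map[mid]].mean(axis=0)
        b = pos[out.bp_bead_map[mid + 2]].mean(axis=0)
        axis = b - a
        axis /= np.linalg.norm(axis)
        out.torus = Torus(center=a, axis=axis,
                          major_radius=torus_major_radius,
                          tube_radius=torus_tube_radius,
                          strength=torus_strength)
    core = out.histone_core_beads()
    linker = [i for bp in bp_coords
              if bp < out.entry_bp or bp > out.exit_bp
              for i in out.bp_bead_map[bp]]
    if linker:
        from scipy.spatial import cKDTree
        dmin = cKDTree(pos[core]).query(pos[linker])[0].min()
        if dmin < clash_tolerance:
            raise ValueError(
                f"linker grafting clashes with the core (min distance "
                f"{dmin:.2f} Å)")
    out.metadata["upstream_bp"] = upstream_bp
    out.metadata["downstream_bp"] = downstream_bp
    return out


def prepare_partially_unwrapped(system: NucleosomeSystem,
                                params: SimulationParams,
                                target_bp: int,
                                anchor_k: float = 2.0,
                                pull_rate: float = 0.005,
                                stage_steps: int = 2_000,
                                max_stages: int = 150) -> NucleosomeSystem:
    """Peel nucleosomal DNA to ``target_bp`` and anchor it there.

    Runs the translocase-pulling protocol (moving anchor dragging the
    upstream terminal base pair through the torus), then replaces the
    moving anchor with a static one holding the target base pair at the
    torus centre so the partial unwrapping is maintained.  ``target_bp``
    must lie upstream of the dyad.
    """
    if target_bp >= 0:
        raise ValueError("anchor target must be upstream of the dyad "
                         f"(negative bp), got {target_bp}")
    if system.torus is None:
        raise ValueError("system has no torus; assemble it first")
    bp_coords = sorted(system.bp_bead_map)
    drag = system.bp_bead_map[bp_coords[0]]
    out = system.copy()

    from .analysis import unwrap_extent

    def boundary_reached(xyz):
        b = unwrap_extent(xyz, system)
        # boundary moves from the entry (most negative) toward the dyad
        return b != "fully dissociated" and b >= target_bp

    structure, _state = pull_through_torus(
        out.structure, out.topology, params, out.torus, drag,
        out.bp_bead_map, target_bp, forcefield=out.forcefield,
        pull_rate=pull_rate, anchor_k=anchor_k, stage_steps=stage_steps,
        max_stages=max_stages,
        extra_restraints=[r for r in out.restraints
                          if not isinstance(r, PositionAnchor)],
        stop_when=boundary_reached)
    out.structure = structure
    # anchor the target base pair where the collision left it — adjacent
    # to the translocase, holding the unwrap boundary in place — and the
    # entry base pair on the far side of the ring, so the peeled segment
    # stays threaded taut through the translocase instead of sagging
    # back onto the exposed dimer
    anchors = []
    for bp in (target_bp, system.entry_bp):
        beads = np.asarray(out.bp_bead_map[bp], dtype=np.int64)
        anchors.append(PositionAnchor.to_point(
            structure.positions, beads,
            structure.positions[beads].mean(axis=0), anchor_k))
    out.restraints = [r for r in out.restraints
                      if not isinstance(r, PositionAnchor)] + anchors
    out.metadata["unwrapped_to_bp"] = target_bp

    # the released drag end leaves the linker stretched and the peel can
    # drag the exposed dimer off its seam; relax under the static
    # anchors with the dimer temporarily tethered to its seated
    # (pre-pull) pose, then release the tether and relax again
    from .dynamics import run_simulation
    dimer = np.asarray(out.groups["dimer_proximal"], dtype=np.int64)
    reseat = PositionAnchor(
        beads=dimer,
        references=system.structure.positions[dimer].copy(),
        k=0.5)
    relax = SimulationParams(dt=params.dt, temperature=params.temperature,
                             friction=params.friction, n_steps=25_000,
                             snapshot_stride=25_000, seed=params.seed,
                             mass=params.mass)
    _, state = run_simulation(out.structure, out.topology, relax,
                              restraints=out.all_restraints() + [reseat],
                              forcefield=out.forcefield)
    out.structure.positions = state.positions
    _, state = run_simulation(out.structure, out.topology, relax,
                              restraints=out.all_restraints(),
                              forcefield=out.forcefield)
    out.structure.positions = state.positions

    from .analysis import unwrap_extent
    boundary = unwrap_extent(out.structure.positions, out)
    if boundary == "fully dissociated" or boundary > target_bp + 3:
        raise RuntimeError(
            f"pulling finished but the unwrap boundary is {boundary}, "
            f"target {target_bp}")
    return out


def place_chaperone(system: NucleosomeSystem, chaperone: CGStructure,
                    chaperone_topology: CGTopology,
                    distance: float = 80.0, seed: int = 0,
                    clearance: float = 2.5, max_tries: int = 80
                    ) -> NucleosomeSystem:
    """Place the chaperone COM ``distance`` Å from the exposed dimer COM.

    The approach direction is the outward normal of the exposed face
    (proximal-dimer COM minus histone-core COM); the chaperone
    orientation is a uniform random rotation drawn from ``seed``,
    re-drawn on steric clashes.  Adds groups ``chaperone``,
    ``chaperone_core`` and ``chaperone_tail`` (tail = flexible beads).
    """
    from scipy.spatial import cKDTree
    from scipy.spatial.transform import Rotation

    from .cg_model import merge_topologies

    out = system.copy()
    pos = out.structure.positions
    dimer_com = out.group_com("dimer_proximal")
    core_com = pos[out.histone_core_beads()].mean(axis=0)
    normal = dimer_com - core_com
    nn = np.linalg.norm(normal)
    normal = normal / nn if nn > 1e-9 else np.array([1.0, 0.0, 0.0])

    rng = np.random.default_rng(seed)
    tree = cKDTree(pos)
    chap_pos0 = chaperone.positions
    chap_com = chap_pos0.mean(axis=0)
    placed = None
    for attempt in range(max_tries):
        # keep the approach near the outward normal, but tilt away when
        # the direct line is blocked (e.g. by the translocase ring)
        if attempt == 0:
            direction = normal
        else:
            direction = normal + 0.6 * rng.normal(size=3)
            direction /= np.linalg.norm(direction)
        target = dimer_com + direction * distance
        rot = Rotation.random(rng=rng)
        cand = rot.apply(chap_pos0 - chap_com) + target
        if tree.query(cand)[0].min() < clearance:
            continue
        if system.torus is not None:
            e_torus, _ = system.torus.energy_forces(cand)
            if e_torus > 1.0:
                continue
        placed = cand
        break
    if placed is None:
        raise ValueError(
            f"could not place the chaperone at {distance} Å without "
            f"steric clashes after {max_tries} orientations")
    n0 = out.structure.n_beads
    chap = chaperone.copy()
    chap.positions = placed
    out.structure = out.structure.merged_with(chap)
    out.topology = merge_topologies(out.topology, chaperone_topology, n0)
    chap_idx = np.arange(n0, n0 + chap.n_beads)
    flex = chap.flexible_flags
    out.groups["chaperone"] = chap_idx
    out.groups["chaperone_core"] = chap_idx[~flex]
    out.groups["chaperone_tail"] = chap_idx[flex]
    out.metadata["chaperone_distance"] = distance
    out.metadata["chaperone_construct"] = chap.metadata.get("construct", "")
    return out


# --------------------------------------------------------------------------
# scenario bundles (desk scale, built on the synthetic fixtures)
# --------------------------------------------------------------------------

_UNWRAP_CACHE: dict = {}


def build_scenario(spec: ScenarioSpec, confinement_radius: float = 150.0
                   ) -> NucleosomeSystem:
    """Deterministic ready-to-run bundle for a named scenario.

    Desk-scale bundles are built on the synthetic mini-nucleosome and
    toy chaperone; atomic-structure systems prepared through
    :mod:`chaperone_cg.cg_model` follow the same protocol.  Solution
    scenarios contain only the chaperone and a free histone-dimer
    analogue inside a weak spherical confinement.  The partially
    unwrapped reference structure is produced once by the pulling
    protocol and cached (all replicates of a condition start from the
    same unwrapped structure, diverging only through their thermal
    seeds).
    """
    from . import synthetic_fixtures as fx

    if spec.in_solution:
        sys_ = fx.make_solution_pair(
            with_tail=not spec.chaperone_truncated, seed=spec.seed,
            separation=min(spec.chaperone_distance, 35.0), salt=spec.salt)
        sys_.restraints.append(SphericalConfinement(
            radius=min(confinement_radius, 60.0), k=0.2,
            center=sys_.structure.positions.mean(axis=0)))
        sys_.metadata["scenario"] = spec.name
        return sys_

    mini = fx.make_mini_nucleosome(salt=spec.salt)
    mini.forcefield = replace(mini.forcefield, ionic_strength=spec.salt)

    if spec.unwrapped:
        target = (spec.target_bp if spec.target_bp is not None
                  else mini.metadata["default_target_bp"])
        key = ("unwrap", round(spec.salt, 4), target)
        if key not in _UNWRAP_CACHE:
            params = SimulationParams(seed=0, n_steps=0)
            _UNWRAP_CACHE[key] = prepare_partially_unwrapped(
                mini, params, target)
        mini = _UNWRAP_CACHE[key].copy()
    else:
        mini.torus = None
        mini.restraints = [r for r in mini.restraints
                           if not isinstance(r, PositionAnchor)]

    if spec.has_chaperone:
        chap, chap_topo = fx.make_toy_chaperone(
            with_tail=not spec.chaperone_truncated, seed=spec.seed)
        mini = place_chaperone(mini, chap, chap_topo,
                               distance=spec.chaperone_distance,
                               seed=spec.seed)
    center = mini.structure.positions[mini.histone_core_beads()].mean(axis=0)
    extent = float(np.linalg.norm(mini.structure.positions - center,
                                  axis=1).max())
    mini.restraints.append(SphericalConfinement(
        radius=max(confinement_radius, extent + 20.0), k=0.1,
        center=center))
    mini.metadata["scenario"] = spec.name
    mini.metadata["salt"] = spec.salt
    return mini
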