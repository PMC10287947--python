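"""Download-free synthetic test systems.

These fixtures reproduce, at desk scale, the statistical structure the
simulator and analyses assume: a folded bead chain with a native-contact
network (integrator and energy checks), a mini-nucleosome whose DNA
superhelix is wrapped on a positively charged four-chain core and held
by histone–DNA contacts against bending strain and electrostatic
repulsion, a toy chaperone with a highly acidic flexible tail (72%
acidic, emulating the C-terminal tail of an H2A/H2B-binding chaperone
dimer), and a toy binding pair whose standard binding free energy is
computable by two independent routes.

All fixtures are deterministic functions of their parameters and seed.
Geometry ratios (superhelix pitch, wrap turns, patch placement) are
approximations of the real nucleosome, not fits.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, replace

import numpy as np

from .analysis import unwrap_extent
from .cg_model import (AMINO_ACID, BASE, DEFAULT_RADII, PHOSPHATE, SUGAR,
                       BeadRecord, CGStructure, CGTopology, NativeContactSet,
                       _angle, assign_charges, dna_topology,
                       extract_native_contacts, merge_topologies,
                       protein_topology)
from .constants import kt
from .dynamics import SimulationParams, run_simulation
from .energy import ForceFieldParams
from .scenarios import NucleosomeSystem, assemble_nucleosome_system

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class FixtureSpec:
    """Declarative fixture request (used by the CLI)."""

    name: str
    seed: int = 0
    options: dict | None = None


# --------------------------------------------------------------------------
# toy helix
# --------------------------------------------------------------------------

def make_toy_helix(n_beads: int = 20, seed: int = 0
                   ) -> tuple[CGStructure, CGTopology]:
    """Ideal α-helical bead chain with (i, i+4) native contacts.

    Geometry: 2.3 Å helical radius, 100.3° per residue, 1.5 Å rise —
    the (i, i+4) pairs fall within the 7 Å contact cutoff and nothing
    else does.  Used for the integrator / force-correctness checks.
    """
    if n_beads < 8:
        raise ValueError("toy helix needs at least 8 beads")
    s = CGStructure(metadata={"fixture": "toy_helix", "seed": seed})
    for i in range(n_beads):
        p = [2.3 * np.cos(1.75 * i), 2.3 * np.sin(1.75 * i), 1.5 * i]
        s.beads.append(BeadRecord("A", i + 1, AMINO_ACID, "ALA", p))
    s.validate()
    topo = protein_topology(s)
    topo.contacts = extract_native_contacts(s, heavy_atom_cutoff=7.0)
    return s, topo


# --------------------------------------------------------------------------
# serpentine bundles (compact rigid bodies)
# --------------------------------------------------------------------------

def _block(nx: int, ny: int, nz: int, spacing: float = 3.4) -> np.ndarray:
    """Compact nx×ny×nz bead block walked in serpentine order (layer by
    layer along x), centred on the origin.  Adjacent path beads are one
    ``spacing`` apart, so the chain is bondable and the body is a small
    rigid brick rather than a tall slab."""
    pos = []
    for ix in range(nx):
        for iy in range(ny):
            yy = iy if ix % 2 == 0 else ny - 1 - iy
            for iz in range(nz):
                zz = iz if (iy + ix) % 2 == 0 else nz - 1 - iz
                pos.append([ix * spacing, yy * spacing, zz * spacing])
    pos = np.asarray(pos, float)
    return pos - pos.mean(axis=0)


def _bundle_structure(chain_id: str, positions: np.ndarray, names,
                      flexible=None) -> CGStructure:
    s = CGStructure()
    for i, p in enumerate(positions):
        s.beads.append(BeadRecord(chain_id, i + 1, AMINO_ACID, names[i], p,
                                  flexible=bool(flexible[i])
                                  if flexible is not None else False))
    s.validate()
    return s


def make_toy_histone_dimer(n_beads: int = 30, seed: int = 0,
                           chain_id: str = "HD"
                           ) -> tuple[CGStructure, CGTopology]:
    """Rigid 2×3×5 bead brick with one fully basic (Lys) face — the
    histone-dimer analogue whose basic face binds DNA in the
    mini-nucleosome and the chaperone's acidic patch in solution."""
    if n_beads != 30:
        raise ValueError("the dimer analogue is a fixed 2×3×5 brick")
    pos = _block(2, 3, 5)
    # first x-layer is the basic face; checkerboard occupancy keeps the
    # surface charge density moderate
    names = ["LYS" if (i < 15 and i % 2 == 0) else "ALA"
             for i in range(n_beads)]
    s = _bundle_structure(chain_id, pos, names)
    s.metadata.update({"fixture": "toy_histone_dimer", "seed": seed})
    s = assign_charges(s)
    topo = protein_topology(s)
    topo.contacts = extract_native_contacts(s, heavy_atom_cutoff=7.0)
    return s, topo


def make_toy_chaperone(core_beads: int = 60, tail_len: int = 20,
                       tail_acidic_fraction: float = 0.72,
                       with_tail: bool = True, seed: int = 0,
                       chain_id: str = "CH"
                       ) -> tuple[CGStructure, CGTopology]:
    """Toy chaperone: rigid four-column core with an acidic bottom patch
    and, optionally, a flexible acidic tail.

    The tail carries ``round(tail_acidic_fraction · tail_len)`` Glu
    beads (default 72%, the acidity of the emulated chaperone tail),
    placed evenly; it is flagged flexible, so it gets no native contacts
    and only the weak generic bending potential.  ``with_tail=False``
    yields the ΔC analogue.
    """
    if not 0.0 <= tail_acidic_fraction <= 1.0:
        raise ValueError("tail acidic fraction must lie in [0, 1]")
    if core_beads != 60:
        raise ValueError("the chaperone core is a fixed 3×5×4 brick")
    pos = _block(3, 5, 4)
    # first x-layer is the acidic binding patch; its outward normal is
    # −x, the approach direction of the binding partner
    names = ["GLU" if i < 20 else "SER" for i in range(core_beads)]
    flexible = [False] * core_beads
    if with_tail and tail_len > 0:
        n_acid = int(round(tail_acidic_fraction * tail_len))
        acid_slots = set(np.round(np.linspace(0, tail_len - 1,
                                              n_acid)).astype(int))
        start = pos[-1]
        for t in range(tail_len):
            names.append("GLU" if t in acid_slots else "SER")
            flexible.append(True)
            # compact coil hugging the back face of the core: clear of a
            # partner placed against the acidic patch
            ang = 1.3 * (t + 1)
            pos = np.vstack([pos, start + [2.4 * np.cos(ang) + 4.2,
                                           2.4 * np.sin(ang),
                                           1.1 * (t + 1) + 1.5]])
    s = _bundle_structure(chain_id, pos, names, flexible)
    s.metadata.update({
        "fixture": "toy_chaperone", "seed": seed,
        "construct": "full" if with_tail else "dC",
        "tail_len": tail_len if with_tail else 0})
    s = assign_charges(s)
    topo = protein_topology(s)
    topo.contacts = extract_native_contacts(s, heavy_atom_cutoff=7.0)
    return s, topo


def make_solution_pair(with_tail: bool = True, seed: int = 0,
                       separation: float = 35.0, salt: float = 0.3
                       ) -> NucleosomeSystem:
    """Chaperone + free histone-dimer analogue in open solution.

    The chaperone's acidic patch faces the dimer's basic face across
    ``separation`` Å (COM to COM).  Only electrostatics and excluded
    volume act between the two molecules — deliberately no native
    contacts, mirroring how the chaperone–histone interaction is
    modelled throughout.
    """
    dimer, dimer_topo = make_toy_histone_dimer(seed=seed)
    # rotate the dimer π about z so its basic face points +x, toward
    # the approaching chaperone
    dpos = dimer.positions
    dimer.positions = dpos * [-1.0, -1.0, 1.0]
    chap, chap_topo = make_toy_chaperone(with_tail=with_tail, seed=seed)
    # the chaperone's acidic patch already faces −x (the dimer side)
    cpos = chap.positions
    core_com = cpos[:60].mean(axis=0)
    chap.positions = cpos - core_com + np.array([separation, 0.0, 0.0])

    structure = dimer.merged_with(chap)
    topo = merge_topologies(dimer_topo, chap_topo, dimer.n_beads)
    n_d = dimer.n_beads
    chap_idx = np.arange(n_d, structure.n_beads)
    flex = structure.flexible_flags
    empty = np.empty(0, dtype=np.int64)
    system = NucleosomeSystem(
        structure=structure, topology=topo,
        groups={
            "dimer_proximal": np.arange(n_d),
            "dimer_distal": empty,
            "tetramer": empty,
            "dna": empty,
            "chaperone": chap_idx,
            "chaperone_core": chap_idx[~flex[chap_idx]],
            "chaperone_tail": chap_idx[flex[chap_idx]],
        },
        forcefield=ForceFieldParams(ionic_strength=salt),
        metadata={"fixture": "solution_pair", "seed": seed,
                  "with_tail": with_tail})
    return system


# --------------------------------------------------------------------------
# toy binding pair (free-energy oracle)
# --------------------------------------------------------------------------

def make_binding_pair(well_depth: float = 3.0, seed: int = 0,
                      separation: float = 10.0):
    """Two rigid bodies (centred tetrahedra) with a tunable central
    cross-contact.

    Each body is a tetrahedron plus a central bead; the attraction is a
    single centre–centre native contact of depth ``well_depth``
    (kcal/mol; 0 gives a purely repulsive pair).  Binding is therefore
    isotropic — the distance PMF does not depend on slow body
    reorientation — and the bodies carry no charge, making this the
    cleanest configuration for validating the umbrella + WHAM +
    standard-state pipeline against a long unbiased run.
    Returns (structure, topology, groups).
    """
    if well_depth < 0:
        raise ValueError("well depth must be non-negative")
    edge = 4.2
    tet = np.array([[0, 0, 0],
                    [1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                   float) * (edge / np.sqrt(8.0))
    pos_a = tet
    pos_b = tet * [-1.0, 1.0, 1.0] + np.array([separation, 0.0, 0.0])
    s = CGStructure(metadata={"fixture": "binding_pair", "seed": seed,
                              "well_depth": well_depth})
    for i, p in enumerate(pos_a):
        s.beads.append(BeadRecord("A", i + 1, AMINO_ACID, "ALA", p))
    for i, p in enumerate(pos_b):
        s.beads.append(BeadRecord("B", i + 1, AMINO_ACID, "ALA", p))
    topo = CGTopology()
    pos = s.positions
    for chain0 in (0, 5):
        for i in range(5):
            for j in range(i + 1, 5):
                a, b = chain0 + i, chain0 + j
                topo.bonds.append((a, b,
                                   float(np.linalg.norm(pos[a] - pos[b]))))
    if well_depth > 0:
        topo.contacts.add(0, 5, float(separation), well_depth,
                          "protein_protein")
    groups = {"A": np.arange(5), "B": np.arange(5, 10)}
    return s, topo, groups


# --------------------------------------------------------------------------
# mini-nucleosome
# --------------------------------------------------------------------------

_R_BASE, _R_SUGAR, _R_PHOS = 2.8, 6.9, 8.9
_OFF_BASE, _OFF_SUGAR, _OFF_PHOS = 0.0, 0.25, 0.45


def _bdna_on_frames(sequence: str, stations: np.ndarray,
                    normals: np.ndarray, binormals: np.ndarray,
                    twist_deg: float = 34.3,
                    chain_ids=("DI", "DJ")) -> CGStructure:
    """Three-site DNA beads laid on arbitrary base-pair frames.

    With straight frames this reproduces the ideal B-DNA builder bead
    for bead, so a topology extracted from the straight reference
    applies unchanged to the curved realisation.
    """
    n = len(sequence)
    tw = np.deg2rad(twist_deg)

    def site(bp, sign, radius, offset, phase):
        phi = bp * tw + phase + sign * offset
        return (stations[bp] + radius * np.cos(phi) * normals[bp]
                + radius * np.sin(phi) * binormals[bp])

    s = CGStructure(metadata={"sequence": sequence})
    for strand, (cid, phase, sign) in enumerate(
            [(chain_ids[0], 0.0, +1.0), (chain_ids[1], np.pi, -1.0)]):
        for k in range(n):
            bp = k if strand == 0 else n - 1 - k
            base_code = (sequence[bp] if strand == 0
                         else _COMPLEMENT[sequence[bp]])
            rid = k + 1
            if k > 0:
                s.beads.append(BeadRecord(cid, rid, PHOSPHATE, "",
                                          site(bp, sign, _R_PHOS, _OFF_PHOS,
                                               phase),
                                          radius=DEFAULT_RADII[PHOSPHATE]))
            s.beads.append(BeadRecord(cid, rid, SUGAR, "",
                                      site(bp, sign, _R_SUGAR, _OFF_SUGAR,
                                           phase),
                                      radius=DEFAULT_RADII[SUGAR]))
            s.beads.append(BeadRecord(cid, rid, BASE, base_code,
                                      site(bp, sign, _R_BASE, _OFF_BASE,
                                           phase),
                                      radius=DEFAULT_RADII[BASE]))
    s.validate()
    return s


def _superhelix_frames(wrap_bp: int, upstream_bp: int, downstream_bp: int,
                       radius: float = 17.0, pitch: float = 27.0,
                       rise: float = 3.38):
    """Base-pair stations and parallel-transported frames for a wrap arc
    with straight tangent linker arms."""
    dtheta = rise / np.sqrt(radius**2 + (pitch / (2 * np.pi))**2)
    dz = pitch * dtheta / (2 * np.pi)
    m = np.arange(wrap_bp)
    theta = m * dtheta
    z = (m - (wrap_bp - 1) / 2) * dz
    wrap = np.stack([radius * np.cos(theta), radius * np.sin(theta), z],
                    axis=1)
    tang = np.stack([-radius * np.sin(theta) * dtheta,
                     radius * np.cos(theta) * dtheta,
                     np.full(wrap_bp, dz)], axis=1)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    up = [wrap[0] - tang[0] * rise * (upstream_bp - k)
          for k in range(upstream_bp)]
    down = [wrap[-1] + tang[-1] * rise * (k + 1)
            for k in range(downstream_bp)]
    stations = np.vstack([up, wrap, down]) if upstream_bp or downstream_bp \
        else wrap
    tangents = np.vstack([np.tile(tang[0], (upstream_bp, 1)), tang,
                          np.tile(tang[-1], (downstream_bp, 1))])
    # parallel transport a normal along the path
    n = np.array([np.cos(0.0), np.sin(0.0), 0.0])
    n = n - (n @ tangents[0]) * tangents[0]
    n /= np.linalg.norm(n)
    normals = np.zeros_like(stations)
    binormals = np.zeros_like(stations)
    for k in range(len(stations)):
        t = tangents[k]
        n = n - (n @ t) * t
        n /= np.linalg.norm(n)
        normals[k] = n
        binormals[k] = np.cross(t, n)
    return stations, tangents, normals, binormals, dtheta


_CORE_SEGMENTS = (  # (group, chain id, bp-coordinate range on a 41-bp wrap)
    ("dimer_proximal", "D1", (-20, -11)),
    ("tetramer", "T1", (-10, 0)),
    ("tetramer", "T2", (1, 10)),
    ("dimer_distal", "D2", (11, 20)),
)

_MINI_CACHE: dict = {}


def make_mini_nucleosome(wrap_bp: int = 41, beads_per_chain: int = 30,
                         upstream_bp: int = 16, downstream_bp: int = 8,
                         salt: float = 0.3, seed: int = 0,
                         calibration_steps: int = 200_000
                         ) -> NucleosomeSystem:
    """Mini-nucleosome: 41 bp DNA superhelix on a four-chain core.

    The DNA's bonded terms and intra-DNA contacts come from a straight
    reference duplex, so the wrapped state is strained and the wrap is
    held only by the histone–DNA native contacts (plus Lys/phosphate
    electrostactics) against bending energy and DNA self-repulsion.
    Two core chains are the "dimer" analogues (entry- and exit-side)
    and two the "tetramer"; every chain is a compact serpentine block
    facing its DNA segment, with a fully basic DNA-facing row on the
    dimer chains.

    The histone–DNA contact-strength multiplier is calibrated once so
    the fully wrapped state survives an unbiased ``calibration_steps``
    run at 300 mM, and the result is cached for the session.
    """
    key = (wrap_bp, beads_per_chain, upstream_bp, downstream_bp)
    if key not in _MINI_CACHE:
        base = _build_mini(wrap_bp, beads_per_chain, upstream_bp,
                           downstream_bp)
        mult = _calibrate_wrap(base, calibration_steps)
        base.forcefield = replace(
            base.forcefield,
            class_multipliers={**base.forcefield.class_multipliers,
                               "histone_dna": mult})
        base.metadata["histone_dna_multiplier"] = mult
        _MINI_CACHE[key] = base
    out = _MINI_CACHE[key].copy()
    out.forcefield = replace(out.forcefield, ionic_strength=salt)
    out.metadata["seed"] = seed
    return out


def _build_mini(wrap_bp: int, beads_per_chain: int, upstream_bp: int,
                downstream_bp: int) -> NucleosomeSystem:
    if wrap_bp < 21 or wrap_bp % 2 == 0:
        raise ValueError("wrap_bp must be an odd number ≥ 21")
    total = upstream_bp + wrap_bp + downstream_bp
    rng = np.random.default_rng(12345)
    seq = "".join(rng.choice(list("ACGT")) for _ in range(total))
    stations, tangents, normals, binormals, dtheta = _superhelix_frames(
        wrap_bp, upstream_bp, downstream_bp)

    # straight reference for the DNA topology (relaxed bonded terms)
    z = np.arange(total) * 3.38
    straight_st = np.stack([np.zeros(total), np.zeros(total), z], axis=1)
    ex = np.tile([1.0, 0.0, 0.0], (total, 1))
    ey = np.tile([0.0, 1.0, 0.0], (total, 1))
    straight = _bdna_on_frames(seq, straight_st, ex, ey)
    dna_topo = dna_topology(straight)
    dna = _bdna_on_frames(seq, stations, normals, binormals)
    dna = assign_charges(dna)

    half = wrap_bp // 2
    # core chains: compact 3-D blocks (arc positions × z levels × radial
    # layers) facing their DNA segment; bead spacing stays ≥ ~2.2 Å so
    # no pathological short bonds arise.  The DNA-facing outer layer of
    # the dimer chains is fully basic (the buried binding face exposed
    # on unwrapping); the tetramer chains are half basic.
    core_structs = []
    scale = wrap_bp / 41.0
    dz_per_bp = 27.0 * dtheta / (2 * np.pi)
    for group, cid, (lo, hi) in _CORE_SEGMENTS:
        lo_i = int(round((lo + 20) * scale))
        hi_i = int(round((hi + 20) * scale))
        th_lo = (lo_i + 0.7) * dtheta
        th_hi = (hi_i - 0.7) * dtheta
        z_c = ((lo_i + hi_i) / 2 - (wrap_bp - 1) / 2) * dz_per_bp
        n_arc, n_z, n_r = 5, 3, 2
        arc = np.linspace(th_lo, th_hi, n_arc)
        zlv = z_c + np.array([-3.2, 0.0, 3.2])
        radii = (7.0, 4.2)
        pos = []
        names = []
        order = 0
        for ir, radius in enumerate(radii):
            for iz in range(n_z):
                zz = zlv[iz] if ir == 0 else zlv[n_z - 1 - iz]
                a = arc if (order % 2 == 0) else arc[::-1]
                for th in a:
                    pos.append([radius * np.cos(th), radius * np.sin(th),
                                zz])
                    if ir == 0:
                        if group.startswith("dimer"):
                            names.append("LYS")
                        else:
                            names.append("LYS" if len(pos) % 2 == 0
                                         else "ALA")
                    else:
                        names.append("ALA")
                order += 1
        pos = np.asarray(pos)
        cs = _bundle_structure(cid, pos, names)
        core_structs.append((group, cs))

    structure = dna
    groups = {"dna": np.arange(dna.n_beads)}
    topo = dna_topo
    for group, cs in core_structs:
        n0 = structure.n_beads
        cs = assign_charges(cs)
        structure = structure.merged_with(cs)
        ct = protein_topology(cs, chain_ids=[cs.beads[0].chain_id])
        topo = merge_topologies(topo, ct, n0)
        idx = np.arange(n0, structure.n_beads)
        groups.setdefault(group, np.empty(0, dtype=np.int64))
        groups[group] = np.concatenate([groups[group], idx])

    # native contacts of the assembled reference: intra-protein and
    # protein-protein from a 7 Å bead scan; intra-DNA base pairing comes
    # from the straight reference (bending stays strained); histone-DNA
    # contacts are the designed per-bp anchoring — the closest few
    # core-bead partners of every wrapped base pair.
    assembled = extract_native_contacts(
        structure, heavy_atom_cutoff=7.0,
        class_epsilon={"intra_protein": 1.2, "protein_protein": 0.4,
                       "histone_dna": 1.0, "intra_dna": 1.0})
    merged = NativeContactSet(list(topo.contacts.contacts))
    wrap_lo, wrap_hi = upstream_bp, upstream_bp + wrap_bp - 1

    def nucleotide_index(bead_idx):
        b = structure.beads[bead_idx]
        if b.chain_id == "DI":
            return b.residue_index - 1
        return total - b.residue_index

    dimer_chains = {"D1", "D2"}
    for c in assembled:
        if c.contact_class in ("intra_dna", "histone_dna"):
            continue
        eps = c.epsilon
        if c.contact_class == "protein_protein":
            ci = structure.beads[c.i].chain_id
            cj = structure.beads[c.j].chain_id
            if (ci in dimer_chains) != (cj in dimer_chains):
                # dimer-tetramer seam: moderate — collectively it must
                # outweigh the per-bp DNA grip so the translocase peels
                # DNA off the dimer rather than the dimer off the core
                eps = 0.35
        merged.add(c.i, c.j, c.r0, eps, c.contact_class)
    topo.contacts = merged
    _ = (wrap_lo, wrap_hi, nucleotide_index)

    bp_map = {}
    for m in range(total):
        coord = m - upstream_bp - half
        beads = [i for i, b in enumerate(structure.beads)
                 if i < dna.n_beads and (
                     (b.chain_id == "DI" and b.residue_index == m + 1)
                     or (b.chain_id == "DJ"
                         and b.residue_index == total - m))]
        bp_map[coord] = np.array(beads, dtype=np.int64)

    system = NucleosomeSystem(
        structure=structure, topology=topo, groups=groups,
        bp_bead_map=bp_map, entry_bp=-half, exit_bp=half,
        # 25 Å DH cutoff ≈ 4.5 Debye lengths at 300 mM: negligible tail,
        # much cheaper neighbour lists at this system size
        forcefield=ForceFieldParams(dh_cutoff=25.0),
        metadata={"fixture": "mini_nucleosome", "wrap_bp": wrap_bp,
                  "default_target_bp": -(half // 2),
                  "torus_major_radius": 19.5, "torus_tube_radius": 6.5})
    system = assemble_nucleosome_system(
        system, upstream_bp=upstream_bp, downstream_bp=downstream_bp,
        torus_major_radius=19.5, torus_tube_radius=6.5)
    # designed per-bp anchoring: the 3 closest DNA-bead/core-bead pairs
    # of every wrapped base pair become full-strength histone-DNA native
    # contacts — the zipper that the translocase breaks bp by bp.  Every
    # other DNA/core pair inside 6 Å gets a weak blanket contact (a pair
    # that is native in the wrapped reference must not be left to the
    # excluded-volume core, where it would start the run deeply
    # strained), kept weak so the dimer's total DNA grip stays below the
    # collectively loaded dimer-tetramer seam.
    core = system.histone_core_beads()
    pos = structure.positions
    seen = topo.contacts.pairs()
    for bp in range(-half, half + 1):
        beads = bp_map[bp]
        dmat = np.linalg.norm(pos[beads][:, None] - pos[core][None], axis=2)
        order = np.argsort(dmat, axis=None)
        picked = 0
        for kk in order:
            bi, ci = np.unravel_index(kk, dmat.shape)
            d = float(dmat[bi, ci])
            if picked >= 3 and d > 6.0:
                break
            pair = (min(int(beads[bi]), int(core[ci])),
                    max(int(beads[bi]), int(core[ci])))
            if pair not in seen:
                eps = 1.0 if picked < 3 else 0.15
                topo.contacts.add(*pair, d, eps, "histone_dna")
                seen.add(pair)
            picked += 1
    return system


def _calibrate_wrap(system: NucleosomeSystem, calibration_steps: int,
                    multipliers=(1.0, 1.5, 2.25, 3.4, 5.0, 7.5)) -> float:
    """Smallest histone-DNA multiplier keeping the wrap intact over an
    unbiased run at 300 mM (boundary within 2 bp of the entry)."""
    for mult in multipliers:
        ff = replace(system.forcefield,
                     class_multipliers={**system.forcefield.class_multipliers,
                                        "histone_dna": mult})
        params = SimulationParams(n_steps=calibration_steps,
                                  snapshot_stride=calibration_steps // 10,
                                  seed=2024)
        traj, _ = run_simulation(system.structure, system.topology, params,
                                 restraints=[], forcefield=ff)
        boundary = unwrap_extent(traj.positions[-1], system)
        if (boundary != "fully dissociated"
                and boundary <= system.entry_bp + 2):
            log.info("mini-nucleosome wrap calibrated: histone_dna ×%.2f",
                     mult)
            return mult
    raise RuntimeError(
        "wrap calibration failed: histone-DNA multiplier bounds exhausted")


# --------------------------------------------------------------------------
# the dismantling ordering experiment
# --------------------------------------------------------------------------

FIXTURE_CONDITIONS = ("fully_wrapped_nap1", "partial_unwrapped",
                      "partial_unwrapped_nap1dC", "partial_unwrapped_nap1")


def dismantling_experiment(conditions=FIXTURE_CONDITIONS,
                           n_replicates: int = 5,
                           production_steps: int = 60_000,
                           stride: int = 1_500,
                           chaperone_distance: float = 18.0,
                           mass: float = 50.0,
                           salt: float = 0.3, seed: int = 1,
                           criteria=None) -> dict:
    """Replicated production runs per condition with dismantling calls.

    Desk-scale analogue of the condition matrix behind the dismantling
    statistics: fully wrapped + chaperone, partially unwrapped without
    chaperone, partially unwrapped + tail-less chaperone, partially
    unwrapped + full chaperone.  Returns per condition a dict with the
    dismantling fraction, counts and the EventRecords.
    """
    from .analysis import (DismantlingCriteria, detect_dismantling,
                           dismantling_fraction)
    from .scenarios import ScenarioSpec, build_scenario

    # desk scale: the contact rule alone — the extracted dimer/chaperone
    # complex diffuses only a few Å per run, so the large COM-distance
    # threshold of the full-scale definition is not informative here
    criteria = criteria or DismantlingCriteria(
        persistence_frames=10, distance=28.0, rule="contact")
    results = {}
    for cond in conditions:
        events = []
        for rep in range(n_replicates):
            spec = ScenarioSpec(cond, salt=salt,
                                chaperone_distance=chaperone_distance,
                                seed=seed * 1000 + rep)
            system = build_scenario(spec)
            cond_tag = zlib.crc32(cond.encode()) % 1000
            params = SimulationParams(
                n_steps=production_steps, snapshot_stride=stride,
                mass=mass,
                seed=(seed * 7919 + cond_tag + rep * 13) % (2**31))
            traj, _ = run_simulation(system.structure, system.topology,
                                     params,
                                     restraints=system.all_restraints(),
                                     forcefield=system.forcefield)
            events.append(detect_dismantling(traj, system, criteria))
        frac, k, n = dismantling_fraction(events)
        results[cond] = {"fraction": frac, "events": k, "n": n,
                         "records": events}
    return results
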