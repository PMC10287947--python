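"""Coarse-grained structure and topology building.

Proteins are reduced to one bead per residue placed on the Cα atom; DNA is
reduced to three beads per nucleotide (base, sugar, phosphate), with the
5′-terminal phosphate of each strand omitted so that a duplex of ``n`` base
pairs carries ``2·(3n − 1)`` beads.  Native-contact networks are extracted
from a reference structure with a heavy-atom distance criterion and are the
basis of the structure-based (Gō) potential.

Charges follow a uniform integer scheme: Asp/Glu −1, Lys/Arg +1, every
other amino acid 0, phosphate −1 (optionally scaled), which is the standard
treatment for disordered regions applied here to all residues.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .constants import RESIDUE_CHARGES, STANDARD_RESIDUES

log = logging.getLogger(__name__)

# bead kinds
AMINO_ACID = "amino_acid"
BASE = "base"
SUGAR = "sugar"
PHOSPHATE = "phosphate"
TORUS_SITE = "torus_site"

PROTEIN_KINDS = (AMINO_ACID,)
DNA_KINDS = (BASE, SUGAR, PHOSPHATE)

#: default excluded-volume radius per bead kind, Å (residue beads fall in
#: the conventional 1.9–2.6 Å range)
DEFAULT_RADII = {AMINO_ACID: 2.3, BASE: 2.6, SUGAR: 2.6, PHOSPHATE: 2.3, TORUS_SITE: 2.5}

DNA_BASES = {"A", "C", "G", "T", "DA", "DC", "DG", "DT"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class BeadRecord:
    """A single coarse-grained bead.

    ``residue_index`` keeps the source-structure (author) numbering so that
    construct ranges such as Nap1ΔC (1–365) can be applied verbatim.
    """

    chain_id: str
    residue_index: int
    bead_kind: str
    name: str  # residue / base name, "" for sugar/phosphate/torus
    position: np.ndarray
    charge: float = 0.0
    radius: float = 2.3
    flexible: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("bead position must be a 3-vector")
        if self.radius <= 0:
            raise ValueError("bead radius must be positive")


@dataclass
class CGStructure:
    """An ordered collection of beads grouped into chains."""

    beads: list[BeadRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    # ------------------------------------------------------------------ views
    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def positions(self) -> np.ndarray:
        return np.array([b.position for b in self.beads], dtype=float).reshape(-1, 3)

    @positions.setter
    def positions(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.n_beads, 3):
            raise ValueError("position array shape mismatch")
        for bead, row in zip(self.beads, xyz):
            bead.position = row.copy()

    @property
    def charges(self) -> np.ndarray:
        return np.array([b.charge for b in self.beads], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([b.radius for b in self.beads], dtype=float)

    @property
    def flexible_flags(self) -> np.ndarray:
        return np.array([b.flexible for b in self.beads], dtype=bool)

    @property
    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for b in self.beads:
            if not out or out[-1] != b.chain_id:
                out.append(b.chain_id)
        return out

    def chain_table(self) -> dict[str, tuple[int, int]]:
        """Chain id → half-open bead-index range."""
        table: dict[str, tuple[int, int]] = {}
        for i, b in enumerate(self.beads):
            if b.chain_id not in table:
                table[b.chain_id] = (i, i + 1)
            else:
                lo, hi = table[b.chain_id]
                if i != hi:
                    raise ValueError(f"chain {b.chain_id!r} is not contiguous")
                table[b.chain_id] = (lo, i + 1)
        return table

    def chain_indices(self, chain_id: str) -> np.ndarray:
        lo, hi = self.chain_table()[chain_id]
        return np.arange(lo, hi)

    def bead_index_array(self) -> np.ndarray:
        """Integer chain label per bead (for kernels)."""
        labels = {c: k for k, c in enumerate(self.chain_table())}
        return np.array([labels[b.chain_id] for b in self.beads], dtype=np.int64)

    def residue_selection(self, chain_id: str, lo: int, hi: int) -> np.ndarray:
        """Bead indices of chain ``chain_id`` with residue index in [lo, hi]."""
        idx = [
            i
            for i in self.chain_indices(chain_id)
            if lo <= self.beads[i].residue_index <= hi
        ]
        return np.array(idx, dtype=np.int64)

    # ------------------------------------------------------------ operations
    def validate(self) -> None:
        table = self.chain_table()
        for cid, (lo, hi) in table.items():
            if hi <= lo:
                raise ValueError(f"chain {cid!r} is empty")
            prev = None
            for b in self.beads[lo:hi]:
                if prev is not None and b.residue_index < prev:
                    raise ValueError(
                        f"residue indices not increasing in chain {cid!r}"
                    )
                prev = b.residue_index

    def copy(self) -> "CGStructure":
        return CGStructure(
            beads=[replace(b, position=b.position.copy()) for b in self.beads],
            metadata=dict(self.metadata),
        )

    def translated(self, shift) -> "CGStructure":
        out = self.copy()
        out.positions = self.positions + np.asarray(shift, dtype=float)
        return out

    def merged_with(self, other: "CGStructure") -> "CGStructure":
        """Concatenate two structures; chain ids must not collide."""
        overlap = set(self.chain_table()) & set(other.chain_table())
        if overlap:
            raise ValueError(f"chain id collision: {sorted(overlap)}")
        out = self.copy()
        out.beads.extend(replace(b, position=b.position.copy()) for b in other.beads)
        out.metadata.update({k: v for k, v in other.metadata.items() if k not in out.metadata})
        return out

    def set_flexible(self, chain_id: str, lo: int, hi: int, flag: bool = True) -> None:
        for i in self.residue_selection(chain_id, lo, hi):
            self.beads[i].flexible = flag


@dataclass
class Contact:
    i: int
    j: int
    r0: float
    epsilon: float
    contact_class: str  # intra_protein | protein_protein | histone_dna | intra_dna


CONTACT_CLASSES = ("intra_protein", "protein_protein", "histone_dna", "intra_dna")


@dataclass
class NativeContactSet:
    contacts: list[Contact] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.contacts)

    def __iter__(self):
        return iter(self.contacts)

    def add(self, i: int, j: int, r0: float, epsilon: float, contact_class: str) -> None:
        if i >= j:
            i, j = j, i
        if r0 <= 0 or epsilon <= 0:
            raise ValueError("contact r0 and epsilon must be positive")
        if contact_class not in CONTACT_CLASSES:
            raise ValueError(f"unknown contact class {contact_class!r}")
        self.contacts.append(Contact(i, j, r0, epsilon, contact_class))

    def pairs(self) -> set[tuple[int, int]]:
        return {(c.i, c.j) for c in self.contacts}

    def by_class(self, contact_class: str) -> "NativeContactSet":
        return NativeContactSet(
            [c for c in self.contacts if c.contact_class == contact_class]
        )

    def arrays(self):
        n = len(self.contacts)
        idx = np.zeros((n, 2), dtype=np.int64)
        r0 = np.zeros(n)
        eps = np.zeros(n)
        for k, c in enumerate(self.contacts):
            idx[k] = (c.i, c.j)
            r0[k] = c.r0
            eps[k] = c.epsilon
        return idx, r0, eps


@dataclass
class CGTopology:
    """Bonded terms plus the native-contact network of a system.

    Per-term force constants may be overridden per entry (``k`` arrays);
    ``None`` entries fall back to the force-field defaults.  Angles and
    dihedrals inside flexible regions carry no native bias — they are
    listed in ``flex_angles`` and get only the weak generic bending term.
    """

    bonds: list[tuple[int, int, float]] = field(default_factory=list)
    angles: list[tuple[int, int, int, float]] = field(default_factory=list)
    dihedrals: list[tuple[int, int, int, int, float]] = field(default_factory=list)
    flex_angles: list[tuple[int, int, int]] = field(default_factory=list)
    contacts: NativeContactSet = field(default_factory=NativeContactSet)

    def validate(self, n_beads: int) -> None:
        for term in self.bonds:
            if not (0 <= term[0] < n_beads and 0 <= term[1] < n_beads):
                raise ValueError(f"bond {term} references invalid bead")
        for term in self.angles:
            if not all(0 <= t < n_beads for t in term[:3]):
                raise ValueError(f"angle {term} references invalid bead")
        for term in self.dihedrals:
            if not all(0 <= t < n_beads for t in term[:4]):
                raise ValueError(f"dihedral {term} references invalid bead")
        for c in self.contacts:
            if not (0 <= c.i < c.j < n_beads):
                raise ValueError(f"contact ({c.i},{c.j}) invalid")

    def bonded_exclusions(self) -> set[tuple[int, int]]:
        """Pairs separated by 1–3 bonds (1-2, 1-3, 1-4), excluded from
        nonbonded interactions."""
        adj: dict[int, set[int]] = {}
        for term in self.bonds:
            i, j = term[0], term[1]
            adj.setdefault(i, set()).add(j)
            adj.setdefault(j, set()).add(i)
        excl: set[tuple[int, int]] = set()
        for i in adj:
            frontier = {i}
            seen = {i}
            for _ in range(3):
                frontier = {k for f in frontier for k in adj.get(f, ())} - seen
                seen |= frontier
                for j in frontier:
                    excl.add((min(i, j), max(i, j)))
        return excl


def merge_topologies(a: CGTopology, b: CGTopology, offset: int) -> CGTopology:
    """Concatenate topology ``b`` (bead indices shifted by ``offset``) onto ``a``."""
    out = CGTopology(
        bonds=list(a.bonds),
        angles=list(a.angles),
        dihedrals=list(a.dihedrals),
        flex_angles=list(a.flex_angles),
        contacts=NativeContactSet(list(a.contacts.contacts)),
    )
    out.bonds += [(t[0] + offset, t[1] + offset, *t[2:]) for t in b.bonds]
    out.angles += [(t[0] + offset, t[1] + offset, t[2] + offset, *t[3:])
                   for t in b.angles]
    out.dihedrals += [
        (t[0] + offset, t[1] + offset, t[2] + offset, t[3] + offset, *t[4:])
        for t in b.dihedrals
    ]
    out.flex_angles += [(i + offset, j + offset, k + offset) for i, j, k in b.flex_angles]
    for c in b.contacts:
        out.contacts.add(c.i + offset, c.j + offset, c.r0, c.epsilon, c.contact_class)
    return out


# --------------------------------------------------------------------------
# coarse-graining from atomic models (biotite AtomArray)
# --------------------------------------------------------------------------

_BASE_ATOM_PREFIXES = ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9",
                       "O2", "O4", "O6", "N2", "N4", "N6")


def _residue_groups(atoms, chain_id: str):
    """Yield (res_id, res_name, AtomArray slice) for one chain, in order."""
    mask = atoms.chain_id == chain_id
    sub = atoms[mask]
    if sub.array_length() == 0:
        raise ValueError(f"chain {chain_id!r} not found in atomic model")
    res_ids = sub.res_id
    order = []
    seen = set()
    for rid in res_ids:
        if rid not in seen:
            seen.add(rid)
            order.append(rid)
    for rid in order:
        rmask = res_ids == rid
        yield int(rid), str(sub.res_name[rmask][0]), sub[rmask]


def coarse_grain_protein(atomic_model, chain_selection) -> CGStructure:
    """One bead per residue at the Cα position.

    Parameters
    ----------
    atomic_model : biotite.structure.AtomArray
        Heavy-atom model (hydrogens, if present, are ignored for placement).
    chain_selection : str or sequence of str
        Chains to convert, in output order.
    """
    if isinstance(chain_selection, str):
        chain_selection = [chain_selection]
    chain_selection = list(chain_selection)
    if not chain_selection:
        raise ValueError("empty chain selection")
    structure = CGStructure(metadata={"source": "atomic"})
    for cid in chain_selection:
        count = 0
        for rid, rname, res in _residue_groups(atomic_model, cid):
            ca = res[res.atom_name == "CA"]
            if ca.array_length() == 0:
                raise ValueError(
                    f"residue {rid} ({rname}) in chain {cid!r} has no CA atom"
                )
            structure.beads.append(
                BeadRecord(
                    chain_id=cid,
                    residue_index=rid,
                    bead_kind=AMINO_ACID,
                    name=rname,
                    position=np.asarray(ca.coord[0], dtype=float),
                    radius=DEFAULT_RADII[AMINO_ACID],
                )
            )
            count += 1
        if count == 0:
            raise ValueError(f"chain {cid!r} contributed no residues")
    structure.validate()
    return structure


def coarse_grain_dna(atomic_model, chain_selection=None) -> CGStructure:
    """Three beads per nucleotide: base centroid, sugar centroid, P position.

    The 5′-terminal nucleotide of each strand carries no phosphate bead, so
    an ``n`` bp duplex yields ``2·(3n − 1)`` beads.
    """
    if chain_selection is None:
        chain_selection = []
        for cid in atomic_model.chain_id:
            if cid not in chain_selection:
                chain_selection.append(cid)
    if len(chain_selection) != 2:
        raise ValueError("DNA coarse-graining expects exactly two strands")
    lengths = []
    for cid in chain_selection:
        lengths.append(sum(1 for _ in _residue_groups(atomic_model, cid)))
    if lengths[0] != lengths[1]:
        raise ValueError(
            f"strand lengths differ: {lengths[0]} vs {lengths[1]}"
        )
    structure = CGStructure(metadata={"source": "atomic"})
    for cid in chain_selection:
        first = True
        for rid, rname, res in _residue_groups(atomic_model, cid):
            base_code = rname.lstrip("D")
            if rname not in DNA_BASES and base_code not in _COMPLEMENT:
                raise ValueError(f"unknown base {rname!r} at {cid}:{rid}")
            names = res.atom_name
            is_sugar = np.array(["'" in n for n in names])
            is_phosphate = np.isin(names, ("P", "OP1", "OP2", "O1P", "O2P"))
            is_base = ~is_sugar & ~is_phosphate
            if not first:
                p = res[names == "P"]
                if p.array_length():
                    structure.beads.append(
                        BeadRecord(cid, rid, PHOSPHATE, "", np.asarray(p.coord[0], float),
                                   radius=DEFAULT_RADII[PHOSPHATE]))
            sugar_atoms = res[is_sugar]
            base_atoms = res[is_base]
            if sugar_atoms.array_length() == 0 or base_atoms.array_length() == 0:
                raise ValueError(f"incomplete nucleotide at {cid}:{rid}")
            structure.beads.append(
                BeadRecord(cid, rid, SUGAR, "", sugar_atoms.coord.mean(axis=0),
                           radius=DEFAULT_RADII[SUGAR]))
            structure.beads.append(
                BeadRecord(cid, rid, BASE, base_code, base_atoms.coord.mean(axis=0),
                           radius=DEFAULT_RADII[BASE]))
            first = False
    structure.validate()
    return structure


# --------------------------------------------------------------------------
# ideal B-DNA builder (CG-level, no atomic intermediate)
# --------------------------------------------------------------------------

def build_ideal_bdna(
    sequence: str,
    rise: float = 3.38,
    twist: float = 34.3,
    chain_ids: tuple[str, str] = ("DI", "DJ"),
) -> tuple[CGStructure, CGTopology]:
    """Straight ideal B-form duplex from a sequence.

    Base-pair centers lie on the z axis spaced by ``rise`` and rotated by
    ``twist`` degrees per step; bead radial offsets approximate the base /
    sugar / phosphate geometry of B-DNA.  Intra-DNA bonds, angles and
    native contacts are derived from the generated geometry so the duplex
    is stable under the structure-based potential.
    """
    sequence = sequence.upper()
    if not sequence or any(c not in _COMPLEMENT for c in sequence):
        raise ValueError(f"sequence must be non-empty over ACGT, got {sequence!r}")
    n = len(sequence)
    tw = np.deg2rad(twist)
    r_base, r_sugar, r_phos = 2.8, 6.9, 8.9
    # phase offsets put the two backbones ~128 deg apart (minor groove)
    off_base, off_sugar, off_phos = 0.0, 0.25, 0.45

    def site(bp: int, strand_sign: float, radius: float, offset: float, phase: float):
        phi = bp * tw + phase + strand_sign * offset
        return np.array([radius * np.cos(phi), radius * np.sin(phi), bp * rise])

    structure = CGStructure(metadata={"source": "ideal_bdna", "sequence": sequence})
    # strand I: 5'->3' with increasing bp index; strand J antiparallel
    for strand, (cid, phase, sign) in enumerate(
        [(chain_ids[0], 0.0, +1.0), (chain_ids[1], np.pi, -1.0)]
    ):
        for k in range(n):
            bp = k if strand == 0 else n - 1 - k
            base_code = sequence[bp] if strand == 0 else _COMPLEMENT[sequence[bp]]
            rid = k + 1
            if k > 0:
                structure.beads.append(
                    BeadRecord(cid, rid, PHOSPHATE, "",
                               site(bp, sign, r_phos, off_phos, phase),
                               radius=DEFAULT_RADII[PHOSPHATE]))
            structure.beads.append(
                BeadRecord(cid, rid, SUGAR, "",
                           site(bp, sign, r_sugar, off_sugar, phase),
                           radius=DEFAULT_RADII[SUGAR]))
            structure.beads.append(
                BeadRecord(cid, rid, BASE, base_code,
                           site(bp, sign, r_base, off_base, phase),
                           radius=DEFAULT_RADII[BASE]))
    structure.validate()
    topology = dna_topology(structure, chain_ids=chain_ids)
    return structure, topology


def dna_topology(
    structure: CGStructure,
    chain_ids=None,
    pairing_cutoff: float = 12.0,
    epsilon: float = 1.0,
    k_bond_dna: float = 20.0,
    k_angle_dna: float = 8.0,
) -> CGTopology:
    """Backbone bonds/angles plus cross-strand base-pairing contacts.

    Backbone connectivity per strand: sugar–base, phosphate–sugar (same
    nucleotide), sugar–phosphate (next nucleotide 5'→3'), with
    sugar–phosphate–sugar and phosphate–sugar–phosphate angles.  The
    backbone carries its own, softer force constants (DNA must bend at
    nucleosomal curvature without the strain exploding).  Native
    contacts (class ``intra_dna``) pair base beads across the two
    strands within the same or adjacent base pairs — the annealing term;
    stacking stiffness lives entirely in the backbone angles.
    """
    topo = CGTopology()
    table = structure.chain_table()
    if chain_ids is None:
        chain_ids = [c for c in table
                     if structure.beads[table[c][0]].bead_kind in DNA_KINDS]
    pos = structure.positions
    base_by_chain: dict[str, list[int]] = {}
    for cid in chain_ids:
        lo, hi = table[cid]
        by_res: dict[int, dict[str, int]] = {}
        for i in range(lo, hi):
            b = structure.beads[i]
            by_res.setdefault(b.residue_index, {})[b.bead_kind] = i
        res_order = sorted(by_res)
        base_by_chain[cid] = [by_res[r][BASE] for r in res_order]
        for ri, rid in enumerate(res_order):
            beads = by_res[rid]
            s = beads[SUGAR]
            topo.bonds.append((s, beads[BASE],
                               float(np.linalg.norm(pos[s] - pos[beads[BASE]])),
                               k_bond_dna))
            if PHOSPHATE in beads:
                p = beads[PHOSPHATE]
                topo.bonds.append((p, s,
                                   float(np.linalg.norm(pos[p] - pos[s])),
                                   k_bond_dna))
            if ri + 1 < len(res_order):
                nxt = by_res[res_order[ri + 1]]
                p_next = nxt[PHOSPHATE]
                topo.bonds.append((s, p_next,
                                   float(np.linalg.norm(pos[s] - pos[p_next])),
                                   k_bond_dna))
                topo.angles.append((s, p_next, nxt[SUGAR],
                                    _angle(pos[s], pos[p_next],
                                           pos[nxt[SUGAR]]), k_angle_dna))
                if PHOSPHATE in beads:
                    topo.angles.append((beads[PHOSPHATE], s, p_next,
                                        _angle(pos[beads[PHOSPHATE]], pos[s],
                                               pos[p_next]), k_angle_dna))
    if len(chain_ids) == 2:
        b1 = base_by_chain[chain_ids[0]]
        b2 = base_by_chain[chain_ids[1]]
        n = len(b1)
        for k in range(n):
            partner = n - 1 - k  # strand J is antiparallel
            for dk in (-1, 0, 1):
                m = partner + dk
                if not 0 <= m < n:
                    continue
                i, j = b1[k], b2[m]
                r0 = float(np.linalg.norm(pos[i] - pos[j]))
                if r0 <= pairing_cutoff:
                    topo.contacts.add(i, j, r0, epsilon, "intra_dna")
    return topo


def _angle(a, b, c) -> float:
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def protein_topology(
    structure: CGStructure,
    chain_ids=None,
    contact_structure: NativeContactSet | None = None,
) -> CGTopology:
    """Cα backbone bonds/angles/dihedrals from current geometry.

    Folded residues get native angle and dihedral biases; stretches flagged
    flexible get bonds plus the weak generic bending term only.
    """
    topo = CGTopology()
    table = structure.chain_table()
    if chain_ids is None:
        chain_ids = [c for c in table
                     if structure.beads[table[c][0]].bead_kind == AMINO_ACID]
    pos = structure.positions
    flex = structure.flexible_flags
    for cid in chain_ids:
        lo, hi = table[cid]
        for i in range(lo, hi - 1):
            topo.bonds.append((i, i + 1, float(np.linalg.norm(pos[i] - pos[i + 1]))))
        for i in range(lo, hi - 2):
            trip = (i, i + 1, i + 2)
            if flex[list(trip)].any():
                topo.flex_angles.append(trip)
            else:
                topo.angles.append((*trip, _angle(pos[i], pos[i + 1], pos[i + 2])))
        for i in range(lo, hi - 3):
            quad = (i, i + 1, i + 2, i + 3)
            if flex[list(quad)].any():
                continue
            # the dihedral gradient is singular at collinear bond pairs;
            # quadruples that are nearly straight in the native state get
            # no dihedral bias
            a1 = _angle(pos[quad[0]], pos[quad[1]], pos[quad[2]])
            a2 = _angle(pos[quad[1]], pos[quad[2]], pos[quad[3]])
            if min(np.sin(a1), np.sin(a2)) < 0.25:
                continue
            topo.dihedrals.append((*quad, _dihedral(pos, *quad)))
    if contact_structure is not None:
        topo.contacts = contact_structure
    return topo


def _dihedral(pos, i, j, k, l) -> float:
    b1, b2, b3 = pos[j] - pos[i], pos[k] - pos[j], pos[l] - pos[k]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))


# --------------------------------------------------------------------------
# native contacts
# --------------------------------------------------------------------------

def extract_native_contacts(
    cg_structure: CGStructure,
    atomic_model=None,
    heavy_atom_cutoff: float = 6.5,
    min_seq_sep: int = 4,
    epsilon: float = 1.0,
    class_epsilon: dict | None = None,
) -> NativeContactSet:
    """Native contacts from a reference structure.

    A bead pair is a contact iff any heavy-atom pair of the two residues /
    nucleotide units lies within ``heavy_atom_cutoff`` and the beads are at
    least ``min_seq_sep`` apart along a chain (any separation across
    chains).  With ``atomic_model=None`` the beads themselves act as the
    heavy atoms (used for synthetic systems, where ``heavy_atom_cutoff``
    is then a bead-distance cutoff).  Beads flagged flexible never carry
    native contacts.  ``r0`` is the bead–bead distance in the reference.
    """
    pos = cg_structure.positions
    n = cg_structure.n_beads
    if atomic_model is None:
        atom_xyz = pos
        atom_bead = np.arange(n)
    else:
        atom_xyz, atom_bead = _map_atoms_to_beads(cg_structure, atomic_model)
    tree = cKDTree(atom_xyz)
    candidate = set()
    for a, b in tree.query_pairs(heavy_atom_cutoff):
        i, j = int(atom_bead[a]), int(atom_bead[b])
        if i == j:
            continue
        if i > j:
            i, j = j, i
        candidate.add((i, j))
    chain_rank = {}
    for cid, (lo, hi) in cg_structure.chain_table().items():
        for rank, i in enumerate(range(lo, hi)):
            chain_rank[i] = (cid, rank)
    flex = cg_structure.flexible_flags
    out = NativeContactSet()
    eps_by_class = dict(class_epsilon or {})
    for i, j in sorted(candidate):
        ci, ri = chain_rank[i]
        cj, rj = chain_rank[j]
        if ci == cj and abs(ri - rj) < min_seq_sep:
            continue
        if flex[i] or flex[j]:
            continue
        cls = _classify_pair(cg_structure.beads[i], cg_structure.beads[j])
        eps = eps_by_class.get(cls, epsilon)
        out.add(i, j, float(np.linalg.norm(pos[i] - pos[j])), eps, cls)
    return out


def _classify_pair(a: BeadRecord, b: BeadRecord) -> str:
    a_dna = a.bead_kind in DNA_KINDS
    b_dna = b.bead_kind in DNA_KINDS
    if a_dna and b_dna:
        return "intra_dna"
    if a_dna != b_dna:
        return "histone_dna"
    if a.chain_id == b.chain_id:
        return "intra_protein"
    return "protein_protein"


def _map_atoms_to_beads(cg_structure: CGStructure, atomic_model):
    """Heavy-atom coordinates labelled with the owning bead index."""
    key_to_bead: dict[tuple, int] = {}
    for idx, bead in enumerate(cg_structure.beads):
        key_to_bead[(bead.chain_id, bead.residue_index, bead.bead_kind)] = idx
    coords = []
    owner = []
    for k in range(atomic_model.array_length()):
        if atomic_model.element[k] == "H":
            continue
        cid = str(atomic_model.chain_id[k])
        rid = int(atomic_model.res_id[k])
        name = str(atomic_model.atom_name[k])
        if (cid, rid, AMINO_ACID) in key_to_bead:
            bead = key_to_bead[(cid, rid, AMINO_ACID)]
        else:
            if "'" in name:
                kind = SUGAR
            elif name in ("P", "OP1", "OP2", "O1P", "O2P"):
                kind = PHOSPHATE
            else:
                kind = BASE
            bead = key_to_bead.get((cid, rid, kind))
            if bead is None and kind == PHOSPHATE:
                continue  # truncated 5' phosphate
            if bead is None:
                raise ValueError(
                    f"atomic model atom {cid}:{rid}:{name} has no CG bead"
                )
        coords.append(atomic_model.coord[k])
        owner.append(bead)
    if not coords:
        raise ValueError("atomic model contributed no heavy atoms")
    return np.asarray(coords, dtype=float), np.asarray(owner, dtype=np.int64)


# --------------------------------------------------------------------------
# charges and constructs
# --------------------------------------------------------------------------

def assign_charges(cg_structure: CGStructure, scale: float = 1.0) -> CGStructure:
    """Integer charges: Asp/Glu −1, Lys/Arg +1, phosphate −1, rest 0.

    ``scale`` multiplies every assigned charge (a calibration knob for the
    uniform-integer scheme); the operation is idempotent.  Unrecognised
    residue names get charge 0 with a logged warning.
    """
    out = cg_structure.copy()
    for bead in out.beads:
        if bead.bead_kind == AMINO_ACID:
            q = RESIDUE_CHARGES.get(bead.name, 0.0)
            if q == 0.0 and bead.name not in STANDARD_RESIDUES:
                log.warning("unknown residue name %r: assigning charge 0", bead.name)
                warnings.warn(f"unknown residue name {bead.name!r}: charge 0",
                              stacklevel=2)
            bead.charge = q * scale
        elif bead.bead_kind == PHOSPHATE:
            bead.charge = -1.0 * scale
        else:
            bead.charge = 0.0
    return out


def make_construct(
    cg_structure: CGStructure,
    keep_ranges: dict,
    topology: CGTopology | None = None,
    label: str | None = None,
):
    """Truncation construct: keep only listed residue ranges.

    ``keep_ranges`` maps chain id → list of inclusive (lo, hi) residue
    ranges; chains not mentioned are kept whole.  Topology terms that
    reference removed beads are dropped and indices remapped.  Returns the
    new structure (and topology, if one was given).
    """
    keep_mask = np.ones(cg_structure.n_beads, dtype=bool)
    for cid, ranges in keep_ranges.items():
        if isinstance(ranges, tuple) and len(ranges) == 2 and np.isscalar(ranges[0]):
            ranges = [ranges]
        chain_idx = cg_structure.chain_indices(cid)
        keep_mask[chain_idx] = False
        for lo, hi in ranges:
            if lo > hi:
                raise ValueError(f"invalid range ({lo},{hi}) for chain {cid!r}")
            keep_mask[cg_structure.residue_selection(cid, lo, hi)] = True
    if not keep_mask.any():
        raise ValueError("construct would be empty")
    new_index = np.full(cg_structure.n_beads, -1, dtype=np.int64)
    new_index[keep_mask] = np.arange(int(keep_mask.sum()))
    out = CGStructure(
        beads=[replace(b, position=b.position.copy())
               for b, keep in zip(cg_structure.beads, keep_mask) if keep],
        metadata=dict(cg_structure.metadata),
    )
    if label is not None:
        out.metadata["construct"] = label
    out.validate()
    if topology is None:
        return out
    new_topo = CGTopology()
    for t in topology.bonds:
        i, j = t[0], t[1]
        if keep_mask[i] and keep_mask[j]:
            new_topo.bonds.append((int(new_index[i]), int(new_index[j]),
                                   *t[2:]))
    for t in topology.angles:
        i, j, k = t[0], t[1], t[2]
        if keep_mask[i] and keep_mask[j] and keep_mask[k]:
            new_topo.angles.append((int(new_index[i]), int(new_index[j]),
                                    int(new_index[k]), *t[3:]))
    for i, j, k in topology.flex_angles:
        if keep_mask[i] and keep_mask[j] and keep_mask[k]:
            new_topo.flex_angles.append((int(new_index[i]), int(new_index[j]),
                                         int(new_index[k])))
    for t in topology.dihedrals:
        i, j, k, l = t[0], t[1], t[2], t[3]
        if keep_mask[i] and keep_mask[j] and keep_mask[k] and keep_mask[l]:
            new_topo.dihedrals.append((int(new_index[i]), int(new_index[j]),
                                       int(new_index[k]), int(new_index[l]),
                                       *t[4:]))
    for c in topology.contacts:
        if keep_mask[c.i] and keep_mask[c.j]:
            new_topo.contacts.add(int(new_index[c.i]), int(new_index[c.j]),
                                  c.r0, c.epsilon, c.contact_class)
    return out, new_topo
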