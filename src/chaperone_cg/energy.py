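"""Potential-energy terms and analytic forces.

The potential is a standard structure-based (Gō) form:

* harmonic bonds and angles about native values, ``U = k (x − x0)²``
  (note: no ½ prefactor, consistent with the umbrella convention),
* periodic dihedral bias ``U = k_d [1 − cos(φ − φ0)]`` in folded regions,
* weak generic bending for flexible (disordered) stretches,
* 10–12 native-contact attraction ``U = ε [5 (r0/r)¹² − 6 (r0/r)¹⁰]``,
* purely repulsive ``(σ/r)¹²`` excluded volume, truncated and shifted,
* Debye–Hückel screened electrostatics, truncated and shifted.

Everything here is the plain-NumPy O(N²) reference path; the Langevin
driver in :mod:`chaperone_cg._kernels` re-implements the same terms with
neighbour lists and is cross-checked against this module in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cg_model import CGStructure, CGTopology
from .constants import COULOMB, E_CHARGE, EPS0, KB_SI, N_AVOGADRO, kt


@dataclass
class ForceFieldParams:
    """Force-field constants (kcal/mol, Å, K).

    ``class_multipliers`` scales the contact ε per contact class; the
    ``histone_dna`` entry stands in for the directional histone–DNA
    hydrogen-bond term of the source model and is calibrated on the
    mini-nucleosome fixture so a fully wrapped state survives an unbiased
    run at 300 mM.
    """

    k_bond: float = 50.0            # kcal/mol/Å², U = k (b−b0)²
    k_angle: float = 20.0           # kcal/mol/rad²
    k_dihedral: float = 1.0         # kcal/mol
    k_flex_angle: float = 2.0       # kcal/mol/rad², disordered stretches
    theta0_flex: float = np.deg2rad(130.0)
    epsilon_contact: float = 1.0    # kcal/mol default contact depth
    epsilon_ev: float = 0.2         # kcal/mol
    sigma_ev: float = 4.0           # Å
    ev_cutoff: float = 8.0          # Å (2 σ)
    dielectric: float = 78.0
    ionic_strength: float = 0.3     # mol/L monovalent
    temperature: float = 300.0      # K (sets the Debye length)
    dh_cutoff: float = 50.0         # Å
    class_multipliers: dict = field(default_factory=lambda: {"histone_dna": 1.0})

    def __post_init__(self) -> None:
        for name in ("k_bond", "k_angle", "k_dihedral", "k_flex_angle",
                     "epsilon_contact", "epsilon_ev", "sigma_ev", "ev_cutoff",
                     "dielectric", "temperature", "dh_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ionic_strength <= 0:
            raise ValueError("ionic strength must be positive")

    @property
    def kt(self) -> float:
        return kt(self.temperature)

    def debye_length(self) -> float:
        """Debye screening length λ_D in Å for a monovalent electrolyte."""
        number_density = self.ionic_strength * 1000.0 * N_AVOGADRO  # 1/m³
        lam_sq = (EPS0 * self.dielectric * KB_SI * self.temperature
                  / (2.0 * E_CHARGE**2 * number_density))
        return float(np.sqrt(lam_sq) * 1e10)


@dataclass
class EnergyReport:
    """Per-term potential-energy totals, kcal/mol."""

    bonded: float = 0.0
    contact: float = 0.0
    excluded_volume: float = 0.0
    electrostatic: float = 0.0
    restraint: float = 0.0

    @property
    def total(self) -> float:
        return (self.bonded + self.contact + self.excluded_volume
                + self.electrostatic + self.restraint)

    def as_dict(self) -> dict:
        return {
            "bonded": self.bonded,
            "contact": self.contact,
            "excluded_volume": self.excluded_volume,
            "electrostatic": self.electrostatic,
            "restraint": self.restraint,
            "total": self.total,
        }


# --------------------------------------------------------------------------
# bonded terms
# --------------------------------------------------------------------------

def bonded_energy_forces(positions, topology: CGTopology, params: ForceFieldParams):
    """Bonds + angles + dihedrals (+ flexible bending); energy and forces."""
    pos = np.asarray(positions, dtype=float)
    forces = np.zeros_like(pos)
    energy = 0.0

    for term in topology.bonds:
        i, j, b0 = term[:3]
        kb = term[3] if len(term) > 3 else params.k_bond
        d = pos[j] - pos[i]
        r = np.linalg.norm(d)
        energy += kb * (r - b0) ** 2
        f = 2.0 * kb * (r - b0) * d / r
        forces[i] += f
        forces[j] -= f

    for term in topology.angles:
        i, j, k, t0 = term[:4]
        ka = term[4] if len(term) > 4 else params.k_angle
        energy += _angle_term(pos, forces, i, j, k, t0, ka)
    for i, j, k in topology.flex_angles:
        energy += _angle_term(pos, forces, i, j, k, params.theta0_flex,
                              params.k_flex_angle)
    for term in topology.dihedrals:
        i, j, k, l, p0 = term[:5]
        kd = term[5] if len(term) > 5 else params.k_dihedral
        energy += _dihedral_term(pos, forces, i, j, k, l, p0, kd)
    return float(energy), forces


def _angle_term(pos, forces, i, j, k, theta0, kang) -> float:
    u = pos[i] - pos[j]
    v = pos[k] - pos[j]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    theta = np.arccos(c)
    s = max(np.sqrt(1.0 - c * c), 1e-8)
    dU = 2.0 * kang * (theta - theta0)
    dthet_di = (c * u / nu - v / nv) / (nu * s)
    dthet_dk = (c * v / nv - u / nu) / (nv * s)
    forces[i] -= dU * dthet_di
    forces[k] -= dU * dthet_dk
    forces[j] += dU * (dthet_di + dthet_dk)
    return kang * (theta - theta0) ** 2


def _dihedral_term(pos, forces, i, j, k, l, phi0, kdih) -> float:
    b1 = pos[j] - pos[i]
    b2 = pos[k] - pos[j]
    b3 = pos[l] - pos[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    n1sq = np.dot(n1, n1)
    n2sq = np.dot(n2, n2)
    # near-collinear bond pairs: the dihedral is ill-defined and its
    # gradient diverges — the term is switched off there
    if (n1sq < 0.01 * np.dot(b1, b1) * nb2**2
            or n2sq < 0.01 * np.dot(b3, b3) * nb2**2):
        return 0.0
    phi = np.arctan2(np.dot(np.cross(n1, n2), b2 / nb2), np.dot(n1, n2))
    dU = kdih * np.sin(phi - phi0)
    dphi_di = -nb2 / n1sq * n1
    dphi_dl = nb2 / n2sq * n2
    c12 = np.dot(b1, b2) / nb2**2
    c32 = np.dot(b3, b2) / nb2**2
    dphi_dj = -(1.0 + c12) * dphi_di + c32 * dphi_dl
    dphi_dk = c12 * dphi_di - (1.0 + c32) * dphi_dl
    forces[i] -= dU * dphi_di
    forces[j] -= dU * dphi_dj
    forces[k] -= dU * dphi_dk
    forces[l] -= dU * dphi_dl
    return kdih * (1.0 - np.cos(phi - phi0))


# --------------------------------------------------------------------------
# nonbonded terms
# --------------------------------------------------------------------------

def contact_energy_forces(positions, contacts, params: ForceFieldParams | None = None):
    """10–12 native-contact term; minimum −ε at r = r0."""
    pos = np.asarray(positions, dtype=float)
    forces = np.zeros_like(pos)
    energy = 0.0
    for c in contacts:
        d = pos[c.j] - pos[c.i]
        r = np.linalg.norm(d)
        if r < 1e-9:
            raise ValueError(f"overlapping beads in contact ({c.i},{c.j})")
        x = c.r0 / r
        x10 = x**10
        x12 = x10 * x * x
        energy += c.epsilon * (5.0 * x12 - 6.0 * x10)
        # dU/dr = eps*(-60 x^12 + 60 x^10)/r
        dU_dr = 60.0 * c.epsilon * (x10 - x12) / r
        f = -dU_dr * d / r
        forces[c.i] -= f
        forces[c.j] += f
    return float(energy), forces


def _pair_lists(n_beads: int, exclusions) -> np.ndarray:
    """All unordered pairs minus exclusions; exclusions is a set of (i,j)."""
    iu, ju = np.triu_indices(n_beads, k=1)
    if exclusions:
        keys = {i * n_beads + j for i, j in exclusions}
        mask = np.array([i * n_beads + j not in keys for i, j in zip(iu, ju)])
        iu, ju = iu[mask], ju[mask]
    return np.stack([iu, ju], axis=1)


def excluded_volume_energy_forces(positions, params: ForceFieldParams,
                                 pairs=None, exclusions=None):
    """Truncated-shifted (σ/r)¹² repulsion over non-excluded pairs."""
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    if pairs is None:
        pairs = _pair_lists(n, exclusions or set())
    forces = np.zeros_like(pos)
    if len(pairs) == 0:
        return 0.0, forces
    pairs = np.asarray(pairs)
    d = pos[pairs[:, 1]] - pos[pairs[:, 0]]
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 1e-9):
        raise ValueError("overlapping beads in excluded-volume pair")
    rc = params.ev_cutoff
    shift = (params.sigma_ev / rc) ** 12
    fshift = 12.0 * shift / rc  # shift-force: F continuous at the cutoff
    mask = r < rc
    x12 = (params.sigma_ev / r[mask]) ** 12
    energy = params.epsilon_ev * float(
        np.sum(x12 - shift + fshift * (r[mask] - rc)))
    dU_dr = params.epsilon_ev * (-12.0 * x12 / r[mask] + fshift)
    fvec = (-dU_dr / r[mask])[:, None] * d[mask]
    np.add.at(forces, pairs[mask, 1], fvec)
    np.add.at(forces, pairs[mask, 0], -fvec)
    return energy, forces


def debye_huckel_energy_forces(positions, charges, params: ForceFieldParams,
                               pairs=None, exclusions=None):
    """Screened Coulomb term, truncated and shifted at the DH cutoff."""
    pos = np.asarray(positions, dtype=float)
    q = np.asarray(charges, dtype=float)
    n = len(pos)
    forces = np.zeros_like(pos)
    if pairs is None:
        charged = np.flatnonzero(q != 0.0)
        iu, ju = np.meshgrid(charged, charged, indexing="ij")
        mask = iu < ju
        pairs = np.stack([iu[mask], ju[mask]], axis=1)
        if exclusions:
            keys = {i * n + j for i, j in exclusions}
            keep = np.array([i * n + j not in keys for i, j in pairs])
            pairs = pairs[keep] if len(pairs) else pairs
    pairs = np.asarray(pairs).reshape(-1, 2)
    if len(pairs) == 0:
        return 0.0, forces
    lam = params.debye_length()
    rc = params.dh_cutoff
    pref = COULOMB / params.dielectric
    d = pos[pairs[:, 1]] - pos[pairs[:, 0]]
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 1e-9):
        raise ValueError("overlapping charged beads")
    qq = q[pairs[:, 0]] * q[pairs[:, 1]]
    mask = (r < rc) & (qq != 0.0)
    r_m = r[mask]
    shift = np.exp(-rc / lam) / rc
    gprime_rc = -np.exp(-rc / lam) * (1.0 / (lam * rc) + 1.0 / rc**2)
    u = pref * qq[mask] * (np.exp(-r_m / lam) / r_m - shift
                           - gprime_rc * (r_m - rc))
    energy = float(np.sum(u))
    # shift-force: dU/dr = pref*qq*(g'(r) − g'(rc)), zero at the cutoff
    dU_dr = pref * qq[mask] * (
        np.exp(-r_m / lam) * (-1.0 / (lam * r_m) - 1.0 / r_m**2)
        - gprime_rc)
    fvec = (-dU_dr / r_m)[:, None] * d[mask]
    np.add.at(forces, pairs[mask, 1], fvec)
    np.add.at(forces, pairs[mask, 0], -fvec)
    return energy, forces


# --------------------------------------------------------------------------
# assembled system evaluation
# --------------------------------------------------------------------------

def nonbonded_exclusions(structure: CGStructure, topology: CGTopology):
    """(ev_exclusions, dh_exclusions): EV skips bonded 1-2/1-3/1-4 pairs and
    native-contact pairs (contacts carry their own repulsive core); DH
    skips bonded pairs only."""
    bonded = topology.bonded_exclusions()
    ev = set(bonded)
    ev |= topology.contacts.pairs()
    return ev, set(bonded)


def total_energy_forces(structure: CGStructure, topology: CGTopology,
                        params: ForceFieldParams, positions=None):
    """Full potential (no restraints): EnergyReport and forces."""
    pos = structure.positions if positions is None else np.asarray(positions, float)
    ev_excl, dh_excl = nonbonded_exclusions(structure, topology)
    e_b, f_b = bonded_energy_forces(pos, topology, params)
    e_c, f_c = contact_energy_forces(pos, topology.contacts, params)
    e_v, f_v = excluded_volume_energy_forces(pos, params, exclusions=ev_excl)
    e_e, f_e = debye_huckel_energy_forces(pos, structure.charges, params,
                                          exclusions=dh_excl)
    report = EnergyReport(bonded=e_b, contact=e_c, excluded_volume=e_v,
                          electrostatic=e_e)
    return report, f_b + f_c + f_v + f_e


def group_interaction_energy(positions, structure: CGStructure,
                             topology: CGTopology, params: ForceFieldParams,
                             group_A, group_B) -> float:
    """Cross-group interaction energy, kcal/mol.

    Sums contact, excluded-volume and electrostatic terms between beads of
    the two (disjoint) groups only — no intra-group or bonded terms.  This
    is the quantity behind the interaction-energy ledger of the
    dismantling analysis.
    """
    group_A = np.asarray(group_A, dtype=np.int64)
    group_B = np.asarray(group_B, dtype=np.int64)
    if np.intersect1d(group_A, group_B).size:
        raise ValueError("groups must be disjoint")
    pos = np.asarray(positions, dtype=float)
    in_A = np.zeros(structure.n_beads, dtype=bool)
    in_B = np.zeros(structure.n_beads, dtype=bool)
    in_A[group_A] = True
    in_B[group_B] = True

    cross_contacts = [c for c in topology.contacts
                      if (in_A[c.i] and in_B[c.j]) or (in_B[c.i] and in_A[c.j])]
    e_c, _ = contact_energy_forces(pos, cross_contacts, params)

    ev_excl, dh_excl = nonbonded_exclusions(structure, topology)
    ia, ib = np.meshgrid(group_A, group_B, indexing="ij")
    pairs = np.stack([ia.ravel(), ib.ravel()], axis=1)
    pairs = np.sort(pairs, axis=1)
    n = structure.n_beads
    keys = pairs[:, 0] * n + pairs[:, 1]
    ev_keys = np.array(sorted(i * n + j for i, j in ev_excl), dtype=np.int64)
    dh_keys = np.array(sorted(i * n + j for i, j in dh_excl), dtype=np.int64)
    ev_pairs = pairs[~np.isin(keys, ev_keys)]
    dh_pairs = pairs[~np.isin(keys, dh_keys)]
    e_v, _ = excluded_volume_energy_forces(pos, params, pairs=ev_pairs)
    e_e, _ = debye_huckel_energy_forces(pos, structure.charges, params,
                                        pairs=dh_pairs)
    return float(e_c + e_v + e_e)
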