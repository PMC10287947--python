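"""Trajectory-derived observables.

Per-residue contact probabilities (mean over frames, mean ± SD across
replicate simulations — never across frames), comparison against a
reference contact set, COM-distance series and distributions, the DNA
unwrapping extent in dyad-centred base pairs, group–group interaction
energy time courses and state ledgers, and the dismantling / hexasome
event calls that summarise whether the chaperone stripped the exposed
histone dimer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .dynamics import Trajectory
from .energy import ForceFieldParams, group_interaction_energy

FULLY_DISSOCIATED = "fully dissociated"


@dataclass
class ContactCriterion:
    """Residue-level contact definition: centre-to-centre distance below
    ``cutoff`` (10 Å for 1.9–2.6 Å-radius beads), intra-chain pairs
    separated by at least ``min_seq_sep`` beads."""

    cutoff: float = 10.0
    min_seq_sep: int = 3
    frame_stride: int = 1

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("contact cutoff must be positive")


@dataclass
class ContactProfile:
    """Per-residue contact probability with replicate SDs."""

    bead_indices: np.ndarray
    residue_indices: np.ndarray
    probability: np.ndarray
    sd: np.ndarray
    n_trajectories: int
    metadata: dict = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bead": self.bead_indices,
            "residue": self.residue_indices,
            "probability": self.probability,
            "sd": self.sd,
        })


@dataclass
class DismantlingCriteria:
    """Operational definition of a dismantling event.

    A trajectory dismantles when, for ``persistence_frames`` consecutive
    recorded frames, the proximal dimer keeps (a) zero native contacts
    with the rest of the histone core and the DNA within
    ``contact_scale``·r0 and (b) a dimer↔core COM distance above
    ``distance``.  ``rule`` selects contact-only, distance-only, or the
    conjunction (default) — both are reported because either convention
    appears in the literature.
    """

    persistence_frames: int = 50
    distance: float = 60.0
    contact_scale: float = 1.2
    rule: str = "both"

    def __post_init__(self) -> None:
        if self.rule not in ("both", "contact", "distance"):
            raise ValueError("rule must be 'both', 'contact' or 'distance'")


@dataclass
class EventRecord:
    """Per-trajectory event summary."""

    dismantled: bool
    first_frame: int | None
    detached_series: np.ndarray        # per frame: criteria satisfied
    chaperone_bound_series: np.ndarray  # empty if no chaperone
    chaperone_stably_bound: bool
    final_composition: str
    n_frames: int


# --------------------------------------------------------------------------
# contacts
# --------------------------------------------------------------------------

def _frames_of(traj) -> np.ndarray:
    if isinstance(traj, Trajectory):
        return traj.positions
    return np.asarray(traj, float)


def contact_probability(trajectories, group_a, group_b, structure=None,
                        criterion: ContactCriterion | None = None
                        ) -> ContactProfile:
    """Probability per residue of ``group_a`` of touching any bead of
    ``group_b``.

    A residue is in contact in a frame when any bead of B lies within the
    cutoff of its bead.  Probabilities are frame fractions per
    trajectory; the profile reports their mean and SD across the
    replicate trajectories (matching how replicate error bars are drawn
    in contact-map figures).
    """
    criterion = criterion or ContactCriterion()
    group_a = np.asarray(group_a, dtype=np.int64)
    group_b = np.asarray(group_b, dtype=np.int64)
    if len(trajectories) == 0:
        raise ValueError("no trajectories given")
    per_traj = []
    for traj in trajectories:
        frames = _frames_of(traj)[::criterion.frame_stride]
        if frames.shape[0] == 0:
            raise ValueError("empty trajectory")
        hits = np.zeros(len(group_a))
        for xyz in frames:
            tree = cKDTree(xyz[group_b])
            d, _ = tree.query(xyz[group_a], k=1,
                              distance_upper_bound=criterion.cutoff)
            hits += np.isfinite(d)
        per_traj.append(hits / frames.shape[0])
    stack = np.vstack(per_traj)
    if structure is not None:
        residues = np.array([structure.beads[i].residue_index
                             for i in group_a])
    else:
        residues = group_a.copy()
    return ContactProfile(
        bead_indices=group_a, residue_indices=residues,
        probability=stack.mean(axis=0),
        sd=stack.std(axis=0, ddof=0),
        n_trajectories=len(trajectories),
        metadata={"cutoff": criterion.cutoff})


def single_frame_contacts(xyz, group_a, group_b, cutoff: float = 10.0
                          ) -> np.ndarray:
    """Boolean per-residue contact indicator for one frame (brute-force
    friendly reference: equals an all-pairs scan)."""
    xyz = np.asarray(xyz, float)
    tree = cKDTree(xyz[np.asarray(group_b, dtype=np.int64)])
    d, _ = tree.query(xyz[np.asarray(group_a, dtype=np.int64)], k=1,
                      distance_upper_bound=cutoff)
    return np.isfinite(d)


def compare_to_reference(profile: ContactProfile, reference_residues,
                         threshold: float = 0.5) -> pd.DataFrame:
    """Classify residues as simulation±/reference± at a probability
    threshold; ``reference_residues`` are residue indices in contact in
    the reference structure."""
    ref = set(int(r) for r in reference_residues)
    sim_pos = profile.probability >= threshold
    rows = []
    for res, sp in zip(profile.residue_indices, sim_pos):
        rp = int(res) in ref
        category = {
            (True, True): "sim+/ref+",
            (True, False): "sim+/ref-",
            (False, True): "sim-/ref+",
            (False, False): "sim-/ref-",
        }[(bool(sp), rp)]
        rows.append((int(res), bool(sp), rp, category))
    return pd.DataFrame(rows, columns=["residue", "simulation_positive",
                                       "reference_positive", "category"])


# --------------------------------------------------------------------------
# geometry observables
# --------------------------------------------------------------------------

def com_distance(traj_or_frame, group_a, group_b):
    """Unweighted-bead COM distance (Å); series for trajectories, scalar
    for single frames."""
    group_a = np.asarray(group_a, dtype=np.int64)
    group_b = np.asarray(group_b, dtype=np.int64)
    if group_a.size == 0 or group_b.size == 0:
        raise ValueError("COM groups must be non-empty")
    frames = _frames_of(traj_or_frame)
    single = frames.ndim == 2
    if single:
        frames = frames[None]
    d = np.linalg.norm(frames[:, group_a].mean(axis=1)
                       - frames[:, group_b].mean(axis=1), axis=1)
    return float(d[0]) if single else d


def unwrap_extent(frame, system, contact_scale: float = 1.2):
    """First unwrapped upstream base pair, dyad-centred.

    A base pair counts as wrapped while any of its native histone–DNA
    contacts remains within ``contact_scale``·r0.  Returns the entry bp
    for a fully wrapped frame, the bp just upstream of the wrapped
    boundary otherwise, and the sentinel ``"fully dissociated"`` when no
    histone–DNA contact survives anywhere.
    """
    xyz = np.asarray(frame, float)
    hd = system.topology.contacts.by_class("histone_dna")
    if len(hd) == 0:
        return FULLY_DISSOCIATED
    bead_to_bp = {}
    for bp, beads in system.bp_bead_map.items():
        for i in beads:
            bead_to_bp[int(i)] = bp
    wrapped = set()
    for c in hd:
        r = np.linalg.norm(xyz[c.i] - xyz[c.j])
        if r <= contact_scale * c.r0:
            bp = bead_to_bp.get(c.i, bead_to_bp.get(c.j))
            if bp is not None:
                wrapped.add(bp)
    if not wrapped:
        return FULLY_DISSOCIATED
    boundary = min(wrapped)
    if boundary <= system.entry_bp:
        return system.entry_bp
    return boundary - 1


# --------------------------------------------------------------------------
# energies
# --------------------------------------------------------------------------

def energy_time_course(traj, structure, topology, params: ForceFieldParams,
                       group_pairs: dict) -> pd.DataFrame:
    """Cross-group interaction energy per recorded frame.

    ``group_pairs`` maps a column name to (group_A, group_B); one row
    per frame, plus the frame step.  Thin aggregation over
    :func:`chaperone_cg.energy.group_interaction_energy`.
    """
    frames = _frames_of(traj)
    steps = (traj.steps if isinstance(traj, Trajectory)
             else np.arange(frames.shape[0]))
    data = {"step": steps}
    for name, (ga, gb) in group_pairs.items():
        data[name] = [group_interaction_energy(xyz, structure, topology,
                                               params, ga, gb)
                      for xyz in frames]
    return pd.DataFrame(data)


def energy_ledger(time_courses: dict, equilibration_fraction: float = 0.2
                  ) -> pd.DataFrame:
    """State-resolved time averages ± SD.

    ``time_courses``: state label → per-frame energy array (or list of
    arrays, one per replicate; replicate means are averaged and their
    spread is the SD).  The first ``equilibration_fraction`` of each
    series is discarded.
    """
    rows = []
    for label, series in time_courses.items():
        if isinstance(series, np.ndarray):
            series = [series]
        means = []
        for s in series:
            s = np.asarray(s, float)
            cut = int(len(s) * equilibration_fraction)
            means.append(s[cut:].mean())
        means = np.asarray(means)
        rows.append((label, means.mean(),
                     means.std(ddof=0) if len(means) > 1 else 0.0,
                     len(means)))
    return pd.DataFrame(rows, columns=["state", "mean", "sd", "n"])


# --------------------------------------------------------------------------
# event calls
# --------------------------------------------------------------------------

def _intact_cross_contacts(xyz, contacts_idx, contacts_r0, scale):
    if contacts_idx.shape[0] == 0:
        return 0
    d = np.linalg.norm(xyz[contacts_idx[:, 1]] - xyz[contacts_idx[:, 0]],
                       axis=1)
    return int(np.sum(d <= scale * contacts_r0))


def detect_dismantling(traj, system,
                       criteria: DismantlingCriteria | None = None
                       ) -> EventRecord:
    """Call a dismantling event for the proximal (exposed) dimer.

    See :class:`DismantlingCriteria` for the operational definition.
    Also tracks whether a chaperone, if present, stays bound to the
    dimer (any bead pair within 10 Å) for the full production run.
    """
    criteria = criteria or DismantlingCriteria()
    frames = _frames_of(traj)
    dimer = np.asarray(system.groups["dimer_proximal"], dtype=np.int64)
    rest_core = np.concatenate([system.groups["dimer_distal"],
                                system.groups["tetramer"]])
    rest_all = set(np.concatenate([rest_core, system.groups["dna"]]))
    if len(set(dimer) & rest_all):
        raise ValueError("ambiguous dimer assignment: groups overlap")

    in_dimer = np.zeros(system.structure.n_beads, dtype=bool)
    in_dimer[dimer] = True
    in_rest = np.zeros(system.structure.n_beads, dtype=bool)
    in_rest[list(rest_all)] = True
    cross = [(c.i, c.j, c.r0) for c in system.topology.contacts
             if (in_dimer[c.i] and in_rest[c.j])
             or (in_rest[c.i] and in_dimer[c.j])]
    cidx = np.array([(i, j) for i, j, _ in cross], dtype=np.int64
                    ).reshape(-1, 2)
    cr0 = np.array([r for _, _, r in cross])

    chap = system.groups.get("chaperone", np.empty(0, dtype=np.int64))
    n_frames = frames.shape[0]
    detached = np.zeros(n_frames, dtype=bool)
    bound = np.zeros(n_frames, dtype=bool)
    for f, xyz in enumerate(frames):
        no_contact = _intact_cross_contacts(
            xyz, cidx, cr0, criteria.contact_scale) == 0
        far = com_distance(xyz, dimer, rest_core) > criteria.distance
        if criteria.rule == "contact":
            detached[f] = no_contact
        elif criteria.rule == "distance":
            detached[f] = far
        else:
            detached[f] = no_contact and far
        if chap.size:
            tree = cKDTree(xyz[chap])
            d, _ = tree.query(xyz[dimer], k=1, distance_upper_bound=10.0)
            bound[f] = bool(np.isfinite(d).any())

    first = None
    run = 0
    need = min(criteria.persistence_frames, max(n_frames - 1, 1))
    for f in range(n_frames):
        run = run + 1 if detached[f] else 0
        if run >= need:
            first = f - need + 1
            break
    dismantled = first is not None
    stably_bound = bool(chap.size and bound[max(1, n_frames // 5):].all())
    comp = hexasome_composition(frames[-1], system,
                                contact_scale=criteria.contact_scale)
    return EventRecord(dismantled=dismantled, first_frame=first,
                       detached_series=detached,
                       chaperone_bound_series=bound if chap.size
                       else np.empty(0, dtype=bool),
                       chaperone_stably_bound=stably_bound,
                       final_composition=comp, n_frames=n_frames)


def dismantling_fraction(events) -> tuple[float, int, int]:
    """(fraction, events, trials) over replicate EventRecords."""
    k = sum(1 for e in events if e.dismantled)
    n = len(events)
    return (k / n if n else 0.0), k, n


def hexasome_composition(frame, system, contact_scale: float = 1.2) -> str:
    """Label the final state by which histone groups retain native
    contacts to the rest of the complex: ``nucleosome``,
    ``hexasome+free-dimer`` (one dimer detached) or ``other``."""
    xyz = np.asarray(frame, float)
    detached = 0
    present = 0
    for name in ("dimer_proximal", "dimer_distal"):
        members = np.asarray(system.groups[name], dtype=np.int64)
        if members.size == 0:
            continue
        present += 1
        grp = np.zeros(system.structure.n_beads, dtype=bool)
        grp[members] = True
        others = np.zeros_like(grp)
        for other in ("dimer_proximal", "dimer_distal", "tetramer", "dna"):
            if other != name:
                others[np.asarray(system.groups[other], dtype=np.int64)] = True
        intact = 0
        for c in system.topology.contacts:
            if (grp[c.i] and others[c.j]) or (grp[c.j] and others[c.i]):
                if (np.linalg.norm(xyz[c.i] - xyz[c.j])
                        <= contact_scale * c.r0):
                    intact += 1
        if intact == 0:
            detached += 1
    if detached == 0:
        return "nucleosome"
    if detached == 1 and present > 0:
        return "hexasome+free-dimer"
    return "other"
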