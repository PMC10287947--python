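"""Umbrella sampling, WHAM, and standard-state binding free energies.

The reaction coordinate is the distance d between the centres of mass of
two bead groups (chaperone globular domains vs histone-dimer globular
domains in the headline application).  Umbrella windows place a harmonic
bias U_i(d) = k (d − d0_i)² — note the no-½ convention, matching the
umbrella restraint of :mod:`chaperone_cg.dynamics` — at d0 = 25 + 2i Å,
i = 0…43, with k = 1.0 kcal/(mol Å²) and five replicates per window for
the full-scale protocol; scaled-down window sets are configurable.

WHAM solves the standard self-consistent equations on a fixed bin grid.
For three-dimensional COM-separation data the radial Jacobian can be
removed (``jacobian="radial"``), yielding the orientation-PMF W(d) that
enters the standard-state formula

    ΔG° = −kT ln [ ∫_bound S(d) e^{−(W(d)−W_plateau)/kT} dd / V° ]

with S(d) = 4π d² the spherical cross-section and V° = 1661 Å³ the 1 M
standard-state volume per molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .constants import STANDARD_VOLUME, kt
from .dynamics import SimulationParams, Umbrella, run_simulation


@dataclass
class UmbrellaWindow:
    """One biased-sampling setup with its sampled distance series."""

    index: int
    d0: float
    k: float = 1.0
    replicate: int = 1
    series: np.ndarray = field(default_factory=lambda: np.empty(0))

    def bias(self, d) -> np.ndarray:
        return self.k * (np.asarray(d, float) - self.d0) ** 2


def generate_windows(n_windows: int = 44, d0_start: float = 25.0,
                     spacing: float = 2.0, k: float = 1.0,
                     replicates: int = 5) -> list[UmbrellaWindow]:
    """Deterministic window grid d0 = d0_start + spacing·i, one entry per
    (window, replicate)."""
    return [UmbrellaWindow(index=i, d0=d0_start + spacing * i, k=k,
                           replicate=r + 1)
            for i in range(n_windows) for r in range(replicates)]


@dataclass
class FreeEnergyProfile:
    """PMF on a bin grid, minimum shifted to zero."""

    bin_centers: np.ndarray
    free_energy: np.ndarray
    errors: np.ndarray
    temperature: float
    metadata: dict = field(default_factory=dict)

    def value_at(self, d: float) -> float:
        return float(np.interp(d, self.bin_centers, self.free_energy))

    @property
    def minimum_position(self) -> float:
        return float(self.bin_centers[np.argmin(self.free_energy)])


@dataclass
class BindingFreeEnergy:
    """Standard binding free energy and its decomposition (kcal/mol)."""

    dg0: float
    well_depth: float
    concentration_correction: float
    perpendicular_correction: float
    bound_cutoff: float
    plateau_value: float

    def components_sum(self) -> float:
        return (self.well_depth + self.concentration_correction
                + self.perpendicular_correction)


# --------------------------------------------------------------------------
# WHAM
# --------------------------------------------------------------------------

def wham(windows, temperature: float = 300.0, bin_width: float = 0.5,
         tol: float = 1e-7, max_iter: int = 100_000,
         jacobian: str = "none", bin_range=None) -> FreeEnergyProfile:
    """Self-consistent WHAM reconstruction from umbrella windows.

    ``jacobian="radial"`` divides the unbiased distribution by d² so the
    returned profile is the orientation-PMF of a 3-D separation vector;
    ``"none"`` returns −kT ln p(d) as sampled.  Raises ValueError when the
    pooled histograms leave an interior gap (non-overlapping windows) —
    no silent extrapolation.
    """
    windows = [w for w in windows if w.series.size > 0]
    if not windows:
        raise ValueError("no window carries samples")
    if jacobian not in ("none", "radial"):
        raise ValueError("jacobian must be 'none' or 'radial'")
    kT = kt(temperature)
    all_d = np.concatenate([w.series for w in windows])
    lo, hi = (all_d.min(), all_d.max()) if bin_range is None else bin_range
    n_bins = max(int(np.ceil((hi - lo) / bin_width)), 1)
    edges = lo + np.arange(n_bins + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])

    hist = np.zeros(n_bins)
    n_w = len(windows)
    counts = np.zeros(n_w)
    bias = np.zeros((n_w, n_bins))
    for wi, w in enumerate(windows):
        h, _ = np.histogram(w.series, bins=edges)
        hist += h
        counts[wi] = w.series.size
        bias[wi] = w.bias(centers)

    occupied = np.flatnonzero(hist > 0)
    interior = hist[occupied[0]:occupied[-1] + 1]
    # a wide interior gap means disjoint window histograms (single empty
    # bins are tolerated: they are masked, not extrapolated)
    gap = 0
    for k, h in enumerate(interior):
        gap = gap + 1 if h == 0 else 0
        if gap >= 3:
            raise ValueError(
                f"umbrella histograms do not overlap: empty bins near d ≈ "
                f"{centers[occupied[0] + k]:.1f} Å — add windows or samples")

    boltz = np.exp(-bias / kT)            # (n_w, n_bins)
    f = np.zeros(n_w)                     # window free-energy constants
    for _ in range(max_iter):
        denom = (counts * np.exp(f / kT)) @ boltz     # (n_bins,)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, hist / denom, 0.0)
        p /= p.sum()
        with np.errstate(divide="ignore"):
            f_new = -kT * np.log(boltz @ p)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            break
    else:
        raise RuntimeError(f"WHAM failed to converge below {tol}")

    mask = p > 0
    if jacobian == "radial":
        with np.errstate(divide="ignore"):
            dens = np.where(mask, p / centers**2, 0.0)
    else:
        dens = p
    F = np.full(n_bins, np.inf)
    F[mask] = -kT * np.log(dens[mask])
    F -= F[mask].min()
    return FreeEnergyProfile(
        bin_centers=centers[mask], free_energy=F[mask],
        errors=np.zeros(int(mask.sum())), temperature=temperature,
        metadata={"bin_width": bin_width, "jacobian": jacobian,
                  "n_windows": n_w, "converged_delta": float(delta)})


def split_sample_errors(windows, n_splits: int = 3, seed: int = 0,
                        temperature: float = 300.0, bin_width: float = 0.5,
                        jacobian: str = "none") -> FreeEnergyProfile:
    """Error bars by random division of every window's samples into
    ``n_splits`` subdatasets: the per-bin SD across the sub-profiles.

    Returns the full-data profile with the ``errors`` field filled.
    """
    rng = np.random.default_rng(seed)
    for w in windows:
        if w.series.size < n_splits:
            raise ValueError(
                f"window {w.index} rep {w.replicate} has too few samples "
                f"to split into {n_splits}")
    all_d = np.concatenate([w.series for w in windows if w.series.size])
    bin_range = (all_d.min(), all_d.max())
    full = wham(windows, temperature, bin_width, jacobian=jacobian,
                bin_range=bin_range)
    profiles = []
    for s in range(n_splits):
        sub = []
        for w in windows:
            perm = rng.permutation(w.series.size)
            take = perm[s::n_splits]
            sub.append(UmbrellaWindow(w.index, w.d0, w.k, w.replicate,
                                      w.series[take]))
        profiles.append(wham(sub, temperature, bin_width, jacobian=jacobian,
                             bin_range=bin_range))
    grid = full.bin_centers
    stack = np.vstack([np.interp(grid, p.bin_centers, p.free_energy)
                       for p in profiles])
    full.errors = stack.std(axis=0, ddof=0)
    full.metadata["n_splits"] = n_splits
    return full


# --------------------------------------------------------------------------
# standard-state binding free energy
# --------------------------------------------------------------------------

def standard_binding_dG(profile: FreeEnergyProfile,
                        bound_cutoff: float | None = None,
                        temperature: float | None = None,
                        standard_volume: float = STANDARD_VOLUME,
                        cross_section=None,
                        plateau_window: float = 10.0,
                        plateau_slope_tol: float = 0.08) -> BindingFreeEnergy:
    """Standard-state ΔG° from a (Jacobian-corrected) distance PMF.

    ``cross_section``: callable S(d) in Ų; default 4π d² (free relative
    orientation of the binding partners).  The profile must plateau over
    its last ``plateau_window`` Å (|mean slope| below
    ``plateau_slope_tol`` kcal/mol/Å) or the windows did not reach the
    unbound regime.  ``bound_cutoff`` defaults to the barrier top between
    the global minimum and the plateau, or minimum + 10 Å if no barrier.

    Components: well depth (W_min − W_plateau), concentration correction
    (−kT ln of the 1-D bound length against V°) and perpendicular
    correction (−kT ln of the effective cross-section); they sum to ΔG°.
    """
    T = temperature if temperature is not None else profile.temperature
    kT = kt(T)
    d = profile.bin_centers
    W = profile.free_energy
    tail = d >= d.max() - plateau_window
    if tail.sum() < 3:
        raise ValueError("profile too short to establish a plateau")
    slope = np.polyfit(d[tail], W[tail], 1)[0]
    if abs(slope) > plateau_slope_tol:
        raise ValueError(
            f"no plateau: mean slope {slope:.3f} kcal/mol/Å over the last "
            f"{plateau_window} Å — extend the window range or sampling")
    W_plateau = float(W[tail].mean())
    i_min = int(np.argmin(W))
    if bound_cutoff is None:
        after = W[i_min:]
        barrier = int(np.argmax(after))
        if after[barrier] > W_plateau + 0.5:
            bound_cutoff = float(d[i_min + barrier])
        else:
            bound_cutoff = float(d[i_min]) + 10.0
    S = cross_section if cross_section is not None else (
        lambda x: 4.0 * np.pi * x**2)
    bound = d <= bound_cutoff
    if bound.sum() < 2:
        raise ValueError("bound region contains fewer than two bins")
    W_min = float(W[bound].min())
    w_rel = W[bound] - W_min
    integrand_v = S(d[bound]) * np.exp(-w_rel / kT)
    integrand_l = np.exp(-w_rel / kT)
    V_eff = float(np.trapezoid(integrand_v, d[bound]))
    L_eff = float(np.trapezoid(integrand_l, d[bound]))
    S_eff = V_eff / L_eff
    well_depth = W_min - W_plateau
    concentration = -kT * np.log(L_eff * 1.0 / standard_volume)  # ×1 Ų
    perpendicular = -kT * np.log(S_eff / 1.0)                    # /1 Ų
    dg0 = well_depth + concentration + perpendicular
    return BindingFreeEnergy(dg0=dg0, well_depth=well_depth,
                             concentration_correction=concentration,
                             perpendicular_correction=perpendicular,
                             bound_cutoff=float(bound_cutoff),
                             plateau_value=W_plateau)


def dissociation_constant(dg0: float, temperature: float = 300.0) -> float:
    """Kd in mol/L from the elementary relation ΔG° = kT ln(Kd / 1 M)."""
    return float(np.exp(dg0 / kt(temperature)))


# --------------------------------------------------------------------------
# umbrella-sampling driver
# --------------------------------------------------------------------------

def run_umbrella_windows(structure, topology, params: SimulationParams,
                         group_a, group_b, windows,
                         forcefield=None, equil_steps: int = 2_000,
                         sample_steps: int = 20_000, stride: int = 100,
                         extra_restraints=(), frozen=None,
                         start_positions=None) -> list[UmbrellaWindow]:
    """Run one biased simulation per (window, replicate) and fill series.

    Windows of one replicate are run in order of their reference
    distance, each starting from the final configuration of its
    neighbour (steered initialisation — dropping a window bias far from
    the current separation would dump the full harmonic energy into the
    system at once).  The first window starts from ``start_positions``
    (default: the structure as built).  Each window equilibrates under
    its own bias before sampling the COM distance every ``stride``
    steps.  Seeds derive from ``params.seed``, the window index and the
    replicate id.
    """
    by_replicate: dict[int, list] = {}
    for w in windows:
        by_replicate.setdefault(w.replicate, []).append(w)
    out = []
    for replicate, reps in sorted(by_replicate.items()):
        s = structure.copy()
        if start_positions is not None:
            s.positions = start_positions
        d_start = float(np.linalg.norm(
            s.positions[np.asarray(group_a)].mean(axis=0)
            - s.positions[np.asarray(group_b)].mean(axis=0)))
        upper = sorted([w for w in reps if w.d0 >= d_start],
                       key=lambda w: w.d0)
        lower = sorted([w for w in reps if w.d0 < d_start],
                       key=lambda w: -w.d0)
        for branch in (upper, lower):
            chained = None
            for w in branch:
                umb = Umbrella(group_a=group_a, group_b=group_b, d0=w.d0, k=w.k)
                seed = int((params.seed * 7919 + w.index * 131 + w.replicate)
                           % (2**31 - 1))
                p_eq = SimulationParams(
                    dt=params.dt, temperature=params.temperature,
                    friction=params.friction, n_steps=equil_steps,
                    snapshot_stride=max(equil_steps, 1), seed=seed,
                    mass=params.mass,
                    neighbor_rebuild=params.neighbor_rebuild,
                    neighbor_skin=params.neighbor_skin)
                _, state = run_simulation(s, topology, p_eq,
                                          restraints=[umb, *extra_restraints],
                                          forcefield=forcefield,
                                          state=chained, frozen=frozen)
                p_run = SimulationParams(
                    dt=params.dt, temperature=params.temperature,
                    friction=params.friction, n_steps=sample_steps,
                    snapshot_stride=stride, seed=seed + 1, mass=params.mass,
                    neighbor_rebuild=params.neighbor_rebuild,
                    neighbor_skin=params.neighbor_skin)
                traj, state = run_simulation(s, topology, p_run,
                                             restraints=[umb,
                                                         *extra_restraints],
                                             forcefield=forcefield,
                                             state=state, frozen=frozen)
                chained = state
                out.append(UmbrellaWindow(w.index, w.d0, w.k, w.replicate,
                                          traj.umbrella_distance[1:].copy()))
    return out


# --------------------------------------------------------------------------
# 1-D overdamped sampler (oracle support for analytic potentials)
# --------------------------------------------------------------------------

@njit(cache=True)
def _brownian_1d(coeffs, d0, k_umb, x0, n_steps, stride, dt, kT, seed):
    """Overdamped Langevin on U(x) = Σ coeffs[p]·x^p + k(x−d0)²."""
    np.random.seed(seed)
    n_out = n_steps // stride
    out = np.empty(n_out)
    x = x0
    noise = np.sqrt(2.0 * kT * dt)
    for step in range(1, n_steps + 1):
        grad = 0.0
        xp = 1.0
        for p in range(1, coeffs.shape[0]):
            grad += p * coeffs[p] * xp
            xp *= x
        grad += 2.0 * k_umb * (x - d0)
        x += -grad * dt + noise * np.random.standard_normal()
        if step % stride == 0:
            out[step // stride - 1] = x
    return out


def sample_windows_1d(coeffs, windows, n_steps: int = 60_000,
                      stride: int = 10, dt: float = 0.002,
                      temperature: float = 300.0, seed: int = 0):
    """Fill window series by overdamped sampling of the polynomial
    potential U(x) = Σ coeffs[p] x^p plus each window's bias (unit
    mobility; dt in the sampler's own time unit)."""
    coeffs = np.asarray(coeffs, float)
    kT = kt(temperature)
    out = []
    for w in windows:
        s = int((seed * 2654435761 + w.index * 97 + w.replicate)
                % (2**31 - 1))
        series = _brownian_1d(coeffs, w.d0, w.k, w.d0, n_steps, stride,
                              dt, kT, s)
        out.append(UmbrellaWindow(w.index, w.d0, w.k, w.replicate, series))
    return out
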