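"""Headline desk-scale experiments.

Each function runs one of the package's main computations end to end on
the synthetic fixtures and returns plain floats: the WHAM oracle on
analytic potentials, the dual-route standard binding free energy of the
toy pair (umbrella + WHAM vs long-run occupancy), the chaperone-tail
effect on the solution binding free energy, the dismantling condition
matrix, and the interaction-energy ledger across wrapping states.  The
test suite and the acceptance script both call these entry points.

Solution and toy-pair simulations use a bead mass of 50 (kinetics are
not interpreted; the lighter beads shorten diffusive correlation times
fourfold at identical stability), while the mini-nucleosome runs keep
the default mass.
"""

from __future__ import annotations

from math import comb

import numpy as np

from . import free_energy as fe
from . import synthetic_fixtures as fx
from .analysis import com_distance, energy_ledger, energy_time_course
from .constants import STANDARD_VOLUME, kt
from .dynamics import (SimulationParams, SphericalConfinement,
                       run_simulation)


def _derived_seed(seed: int, salt: int) -> int:
    return int((seed * 2654435761 + salt) % (2**31 - 1))


# --------------------------------------------------------------------------
# WHAM oracle on analytic 1-D potentials
# --------------------------------------------------------------------------

def parabola_coeffs(a: float = 0.2, x0: float = 40.0) -> np.ndarray:
    return np.array([0.5 * a * x0**2, -a * x0, 0.5 * a])


def double_well_coeffs(height: float = 2.0, x0: float = 40.0,
                       half_sep: float = 6.0) -> np.ndarray:
    """U(x) = h·((x−x0)² − s²)² / s⁴ expanded in powers of x."""
    s2 = half_sep**2
    poly_y = np.array([s2**2, 0.0, -2.0 * s2, 0.0, 1.0]) * height / s2**2
    out = np.zeros(5)
    for k, ck in enumerate(poly_y):
        for m in range(k + 1):
            out[m] += ck * comb(k, m) * (-x0) ** (k - m)
    return out


def wham_oracle_rms(coeffs, seed: int = 1, n_windows: int = 16,
                    d0_start: float = 25.0, spacing: float = 2.0,
                    n_steps: int = 6_000_000, stride: int = 50,
                    x0: float = 40.0, half_width: float = 10.0) -> float:
    """RMS deviation (kcal/mol) of the WHAM reconstruction from the
    analytic potential over the central ±``half_width`` Å."""
    coeffs = np.asarray(coeffs, float)
    wins = fe.generate_windows(n_windows=n_windows, d0_start=d0_start,
                               spacing=spacing, k=1.0, replicates=1)
    wins = fe.sample_windows_1d(coeffs, wins, n_steps=n_steps,
                                stride=stride, dt=0.001, seed=seed)
    prof = fe.wham(wins, temperature=300.0, bin_width=0.5)
    d = prof.bin_centers
    ref = sum(coeffs[k] * d**k for k in range(len(coeffs)))
    ref = ref - ref.min()
    central = np.abs(d - x0) <= half_width
    return float(np.sqrt(np.mean(
        (prof.free_energy[central] - ref[central]) ** 2)))


# --------------------------------------------------------------------------
# toy binding pair: umbrella ΔG° vs occupancy ΔG°
# --------------------------------------------------------------------------

def binding_pair_dual_route(well_depth: float = 3.0, seed: int = 1,
                            confine_radius: float = 25.0,
                            umbrella_sample_steps: int = 120_000,
                            unbiased_steps: int = 6_000_000,
                            bound_cutoff: float = 14.0) -> dict:
    """ΔG° of the toy pair by two independent routes.

    Route 1: umbrella windows along the COM distance + WHAM (radial
    Jacobian) + the standard-state formula.  Route 2: the distance PMF
    histogrammed directly from one long unbiased run, pushed through the
    same standard-state formula — so the comparison isolates the
    umbrella + WHAM unbiasing.  Body A is frozen in both routes; the
    weak confinement sphere of the unbiased run only acts beyond the
    analysed range.  Returns both estimates with split/block SDs.
    """
    structure, topology, groups = fx.make_binding_pair(
        well_depth=well_depth, seed=seed)
    ga, gb = groups["A"], groups["B"]
    sphere = SphericalConfinement(radius=confine_radius, k=0.5,
                                  center=structure.positions[ga].mean(axis=0))
    params = SimulationParams(seed=_derived_seed(seed, 11), mass=50.0)
    kT = kt(params.temperature)

    wins = fe.generate_windows(n_windows=11, d0_start=6.0, spacing=2.0,
                               k=1.0, replicates=1)
    # no confinement in the biased runs: the umbrella itself restrains
    # the separation, and the sphere wall would distort the plateau
    wins = fe.run_umbrella_windows(
        structure, topology, params, ga, gb, wins, equil_steps=8_000,
        sample_steps=umbrella_sample_steps, stride=20, frozen=ga)
    prof = fe.split_sample_errors(wins, n_splits=3,
                                  seed=_derived_seed(seed, 13),
                                  bin_width=0.5, jacobian="radial")
    dg_umb = fe.standard_binding_dG(prof, bound_cutoff=bound_cutoff,
                                    plateau_window=6.0,
                                    plateau_slope_tol=0.5)
    # split-sample SD on the ΔG° itself
    rng = np.random.default_rng(_derived_seed(seed, 17))
    dg_splits = []
    for s in range(3):
        sub = []
        for w in wins:
            perm = rng.permutation(w.series.size)
            sub.append(fe.UmbrellaWindow(w.index, w.d0, w.k, w.replicate,
                                         w.series[perm[s::3]]))
        p = fe.wham(sub, bin_width=0.5, jacobian="radial")
        dg_splits.append(fe.standard_binding_dG(
            p, bound_cutoff=bound_cutoff, plateau_window=6.0,
            plateau_slope_tol=0.8).dg0)
    sd_umb = float(np.std(dg_splits, ddof=0))

    # unbiased route: the distance PMF straight from a long free run
    # (the sphere only matters beyond ~confine_radius; the analysed
    # range stops well short of the wall), pushed through the identical
    # standard-state machinery — so the comparison isolates the
    # umbrella + WHAM unbiasing itself
    p_run = SimulationParams(n_steps=unbiased_steps, snapshot_stride=200,
                             seed=_derived_seed(seed, 19), mass=50.0)
    traj, _ = run_simulation(structure, topology, p_run,
                             restraints=[sphere], frozen=ga)
    d_series = com_distance(traj, ga, gb)[1:]
    # stop well short of the wall: the sphere acts on B's outer beads,
    # so the COM distribution feels it a few Å inside the nominal radius
    d_max = confine_radius - 6.0

    def occupancy_dg(series, slope_tol=0.8):
        edges = np.arange(series.min(), d_max + 0.5, 0.5)
        hist, edges = np.histogram(series, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        mask = hist > 0
        W = -kT * np.log(hist[mask] / centers[mask] ** 2)
        W -= W.min()
        prof = fe.FreeEnergyProfile(centers[mask], W,
                                    np.zeros(int(mask.sum())), 300.0)
        return fe.standard_binding_dG(prof, bound_cutoff=bound_cutoff,
                                      plateau_window=6.0,
                                      plateau_slope_tol=slope_tol).dg0

    dg_occ = occupancy_dg(d_series)
    block_dgs = []
    for b in np.array_split(d_series, 4):
        try:
            # quarter blocks may sample the plateau thinly; a failed
            # block is dropped from the error estimate
            block_dgs.append(occupancy_dg(b, slope_tol=2.0))
        except ValueError:
            continue
    if len(block_dgs) >= 2:
        sd_occ = float(np.std(block_dgs, ddof=0) / np.sqrt(len(block_dgs)))
    else:
        sd_occ = 0.3  # conservative fallback
    return {"dg_umbrella": float(dg_umb.dg0), "sd_umbrella": sd_umb,
            "dg_occupancy": float(dg_occ), "sd_occupancy": sd_occ,
            "well_depth": well_depth,
            "bound_fraction": float(np.mean(d_series < bound_cutoff))}


# --------------------------------------------------------------------------
# chaperone-tail effect on the solution binding free energy
# --------------------------------------------------------------------------

def tail_effect_experiment(seed: int = 1, replicates: int = 1,
                           sample_steps: int = 40_000) -> dict:
    """Solution binding free energy of the toy chaperone with and
    without its acidic tail, plus a long-range attraction metric.

    The attraction-range metric is the distance by which the profile has
    completed 90% of its rise to the plateau — the fuzzy tail tether
    stretches it outward.
    """
    out = {}
    for label, with_tail in (("tail", True), ("dC", False)):
        sysp = fx.make_solution_pair(with_tail=with_tail,
                                     seed=seed, separation=14.0)
        ga = sysp.groups["chaperone_core"]
        gb = sysp.groups["dimer_proximal"]
        params = SimulationParams(seed=_derived_seed(seed, 31), mass=50.0)
        wins = fe.generate_windows(n_windows=28, d0_start=10.0, spacing=2.0,
                                   k=1.0, replicates=replicates)
        wins = fe.run_umbrella_windows(
            sysp.structure, sysp.topology, params, ga, gb, wins,
            forcefield=sysp.forcefield, equil_steps=8_000,
            sample_steps=sample_steps, stride=50)
        prof = fe.wham(wins, bin_width=1.0, jacobian="radial")
        dg = fe.standard_binding_dG(prof, plateau_window=14.0,
                                    plateau_slope_tol=0.35)
        d = prof.bin_centers
        plateau = dg.plateau_value
        target = 0.9 * plateau
        above = np.flatnonzero(prof.free_energy >= target)
        rise_done = float(d[above[0]]) if above.size else float(d[-1])
        out[label] = {"dg0": float(dg.dg0),
                      "well_depth": float(dg.well_depth),
                      "minimum_position": prof.minimum_position,
                      "rise_completion_distance": rise_done,
                      "profile": (d.tolist(),
                                  prof.free_energy.tolist())}
    return out


# --------------------------------------------------------------------------
# interaction-energy ledger across wrapping states
# --------------------------------------------------------------------------

def energy_ledger_experiment(seed: int = 1, replicates: int = 2,
                             production_steps: int = 60_000,
                             stride: int = 2_000) -> dict:
    """Average interaction energy of the exposed dimer with the rest of
    the system, per wrapping state.

    States: fully wrapped nucleosome, partially unwrapped nucleosome,
    partially unwrapped + chaperone, and the dimer–chaperone solution
    complex.  Mirrors the thermodynamic argument for dismantling: the
    dimer gains more interaction energy with the chaperone in solution
    than it keeps in the partially unwrapped nucleosome.
    """
    from .scenarios import ScenarioSpec, build_scenario

    states = {
        "fully_wrapped": "fully_wrapped",
        "partial_unwrapped": "partial_unwrapped",
        "partial_unwrapped_nap1": "partial_unwrapped_nap1",
        "solution_nap1": "solution_nap1_dimer",
    }
    courses: dict[str, list] = {k: [] for k in states}
    for label, scenario in states.items():
        for rep in range(replicates):
            spec = ScenarioSpec(scenario, chaperone_distance=18.0,
                                seed=seed * 100 + rep)
            system = build_scenario(spec)
            params = SimulationParams(
                n_steps=production_steps, snapshot_stride=stride,
                seed=_derived_seed(seed, 100 + rep * 7 + len(label)))
            traj, _ = run_simulation(system.structure, system.topology,
                                     params,
                                     restraints=system.all_restraints(),
                                     forcefield=system.forcefield)
            dimer = system.groups["dimer_proximal"]
            rest = np.setdiff1d(np.arange(system.structure.n_beads), dimer)
            table = energy_time_course(
                traj, system.structure, system.topology, system.forcefield,
                {"dimer_vs_rest": (dimer, rest)})
            courses[label].append(table["dimer_vs_rest"].to_numpy())
    ledger = energy_ledger(courses)
    return {row["state"]: {"mean": float(row["mean"]), "sd": float(row["sd"])}
            for _, row in ledger.iterrows()}
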