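"""Trajectory observables: contacts, distances, unwrap extent, events."""

import numpy as np
import pandas as pd
import pytest

from chaperone_cg import analysis
from chaperone_cg.analysis import (ContactCriterion, DismantlingCriteria,
                                   com_distance, compare_to_reference,
                                   contact_probability, detect_dismantling,
                                   dismantling_fraction, energy_ledger,
                                   hexasome_composition, unwrap_extent)
from chaperone_cg.cg_model import (AMINO_ACID, BeadRecord, CGStructure,
                                   CGTopology)
from chaperone_cg.scenarios import NucleosomeSystem


class TestContactProbability:
    def test_far_groups_have_zero_probability(self, rng):
        frames = np.tile(rng.normal(size=(10, 3)), (5, 1, 1))
        frames[:, 5:] += 500.0
        prof = contact_probability([frames], np.arange(5), np.arange(5, 10))
        assert prof.probability.max() == 0.0
        assert prof.sd.max() == 0.0

    def test_single_frame_equals_brute_force(self, rng):
        xyz = rng.uniform(0, 25, size=(60, 3))
        ga, gb = np.arange(25), np.arange(25, 60)
        prof = contact_probability([xyz[None]], ga, gb,
                                   criterion=ContactCriterion(cutoff=10.0))
        expected = np.array([
            any(np.linalg.norm(xyz[i] - xyz[j]) <= 10.0 for j in gb)
            for i in ga], dtype=float)
        np.testing.assert_array_equal(prof.probability, expected)

    def test_replicate_sd_semantics(self, rng):
        """SD is computed across the replicate trajectories (one value
        per residue), never across frames."""
        trajs = []
        for rep in range(20):
            base = rng.uniform(0, 30, size=(8, 3))
            trajs.append(np.tile(base, (4, 1, 1)))
        prof = contact_probability(trajs, np.arange(4), np.arange(4, 8))
        assert prof.probability.shape == (4,)
        assert prof.sd.shape == (4,)
        assert prof.n_trajectories == 20
        # static frames within a trajectory: per-traj probability is 0/1,
        # so the SD reflects purely the across-replicate spread
        assert np.all((prof.sd >= 0) & (prof.sd <= 0.5))

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            contact_probability([np.empty((0, 4, 3))], [0], [1])


class TestReferenceComparison:
    @staticmethod
    def _profile(probs, residues=None):
        n = len(probs)
        residues = residues if residues is not None else np.arange(1, n + 1)
        return analysis.ContactProfile(
            bead_indices=np.arange(n), residue_indices=np.array(residues),
            probability=np.array(probs, float), sd=np.zeros(n),
            n_trajectories=1)

    def test_perfect_agreement(self):
        prof = self._profile([1.0, 0.0, 1.0, 0.0])
        table = compare_to_reference(prof, {1, 3}, threshold=0.5)
        assert set(table["category"]) == {"sim+/ref+", "sim-/ref-"}

    def test_empty_reference_marks_all_positives_novel(self):
        prof = self._profile([1.0, 0.9, 0.0])
        table = compare_to_reference(prof, set(), threshold=0.5)
        assert list(table["category"]) == ["sim+/ref-", "sim+/ref-",
                                           "sim-/ref-"]

    def test_impossible_threshold_yields_no_positives(self):
        prof = self._profile([1.0, 1.0])
        table = compare_to_reference(prof, {1, 2}, threshold=1.01)
        assert not table["simulation_positive"].any()


class TestComDistance:
    def test_identical_groups_zero(self, rng):
        xyz = rng.normal(size=(5, 3))
        assert com_distance(xyz, [0, 1], [0, 1]) == 0.0

    def test_pythagorean_pair(self):
        xyz = np.array([[0.0, 0, 0], [3.0, 4.0, 0]])
        assert com_distance(xyz, [0], [1]) == pytest.approx(5.0)

    def test_translation_invariance(self, rng):
        xyz = rng.normal(size=(6, 3))
        d0 = com_distance(xyz, [0, 1, 2], [3, 4, 5])
        d1 = com_distance(xyz + 17.3, [0, 1, 2], [3, 4, 5])
        assert d0 == pytest.approx(d1)

    def test_empty_group_rejected(self, rng):
        with pytest.raises(ValueError):
            com_distance(rng.normal(size=(4, 3)), [], [0])


def _toy_system(n_bp=5, wrapped=True):
    """Minimal nucleosome-like system: one DNA 'bead' pair per bp plus a
    two-bead core, with one histone-DNA contact per bp."""
    s = CGStructure()
    topo = CGTopology()
    bp_map = {}
    half = n_bp // 2
    for m in range(n_bp):
        coord = m - half
        xyz = (3.4 * m, 0.0, 0.0) if wrapped else (3.4 * m, 50.0, 0.0)
        s.beads.append(BeadRecord("D", m + 1, "phosphate", "", xyz))
        bp_map[coord] = np.array([m])
    core0 = n_bp
    s.beads.append(BeadRecord("C", 1, AMINO_ACID, "LYS",
                              (3.4 * half, 3.0, 0)))
    s.beads.append(BeadRecord("C", 2, AMINO_ACID, "ALA",
                              (3.4 * half, 6.0, 0)))
    for m in range(n_bp):
        r0 = np.linalg.norm(np.array([3.4 * m, 0, 0])
                            - np.array([3.4 * half, 3.0, 0]))
        topo.contacts.add(m, core0, r0, 1.0, "histone_dna")
    groups = {"dna": np.arange(n_bp),
              "dimer_proximal": np.array([core0]),
              "dimer_distal": np.empty(0, dtype=np.int64),
              "tetramer": np.array([core0 + 1])}
    return NucleosomeSystem(structure=s, topology=topo, groups=groups,
                            bp_bead_map=bp_map, entry_bp=-half,
                            exit_bp=half)


class TestUnwrapExtent:
    def test_native_frame_reports_entry(self):
        sys_ = _toy_system()
        assert unwrap_extent(sys_.structure.positions, sys_) == -2

    def test_partially_detached_boundary(self):
        sys_ = _toy_system()
        xyz = sys_.structure.positions
        xyz[0] += (0, 40, 0)   # bp −2 detached
        xyz[1] += (0, 40, 0)   # bp −1 detached
        assert unwrap_extent(xyz, sys_) == -1

    def test_all_contacts_lost_is_sentinel(self):
        sys_ = _toy_system(wrapped=False)
        assert (unwrap_extent(sys_.structure.positions, sys_)
                == analysis.FULLY_DISSOCIATED)

    def test_no_histone_dna_contacts_is_sentinel(self):
        sys_ = _toy_system()
        sys_.topology = CGTopology()
        assert (unwrap_extent(sys_.structure.positions, sys_)
                == analysis.FULLY_DISSOCIATED)


class TestEnergyLedger:
    def test_static_series_average(self):
        table = energy_ledger({"s": np.full(10, -7.5)},
                              equilibration_fraction=0.2)
        assert table.loc[0, "mean"] == pytest.approx(-7.5)
        assert table.loc[0, "sd"] == 0.0

    def test_replicate_mean_and_spread(self):
        table = energy_ledger({"s": [np.full(10, -10.0),
                                     np.full(10, -20.0)]})
        assert table.loc[0, "mean"] == pytest.approx(-15.0)
        assert table.loc[0, "sd"] == pytest.approx(5.0)
        assert table.loc[0, "n"] == 2

    def test_two_state_series_weighted_mean(self):
        series = np.concatenate([np.full(40, -10.0), np.full(40, -30.0)])
        table = energy_ledger({"s": series}, equilibration_fraction=0.0)
        assert table.loc[0, "mean"] == pytest.approx(-20.0)


class TestEventCalls:
    def test_static_trajectory_never_dismantles(self):
        sys_ = _toy_system()
        frames = np.tile(sys_.structure.positions, (60, 1, 1))
        ev = detect_dismantling(frames, sys_,
                                DismantlingCriteria(persistence_frames=5,
                                                    distance=10.0))
        assert not ev.dismantled
        assert ev.final_composition == "nucleosome"

    def test_teleported_dimer_detected_at_jump_frame(self):
        sys_ = _toy_system()
        frames = np.tile(sys_.structure.positions, (60, 1, 1))
        frames[30:, 5] += (0.0, 200.0, 0.0)  # dimer bead leaves at frame 30
        ev = detect_dismantling(frames, sys_,
                                DismantlingCriteria(persistence_frames=5,
                                                    distance=50.0))
        assert ev.dismantled
        assert ev.first_frame == 30
        assert ev.final_composition == "hexasome+free-dimer"

    def test_transient_excursion_below_persistence_ignored(self):
        sys_ = _toy_system()
        frames = np.tile(sys_.structure.positions, (60, 1, 1))
        frames[30:32, 5] += (0.0, 200.0, 0.0)  # 2-frame blip
        ev = detect_dismantling(frames, sys_,
                                DismantlingCriteria(persistence_frames=5,
                                                    distance=50.0))
        assert not ev.dismantled

    def test_fraction_arithmetic(self):
        events = [analysis.EventRecord(True, 0, np.empty(0), np.empty(0),
                                       False, "other", 10)] * 45 \
            + [analysis.EventRecord(False, None, np.empty(0), np.empty(0),
                                    False, "nucleosome", 10)] * 5
        frac, k, n = dismantling_fraction(events)
        assert (frac, k, n) == (0.9, 45, 50)

    def test_hexasome_labels(self):
        sys_ = _toy_system()
        xyz = sys_.structure.positions
        assert hexasome_composition(xyz, sys_) == "nucleosome"
        far = xyz.copy()
        far[5] += (0, 300, 0)
        assert hexasome_composition(far, sys_) == "hexasome+free-dimer"

    def test_overlapping_groups_rejected(self):
        sys_ = _toy_system()
        sys_.groups["dimer_proximal"] = np.array([0, 5])  # overlaps DNA
        frames = sys_.structure.positions[None]
        with pytest.raises(ValueError, match="ambiguous"):
            detect_dismantling(frames, sys_)


class TestEnergyTimeCourse:
    def test_static_trajectory_constant_series(self, mini_system):
        sys_ = mini_system
        frames = np.tile(sys_.structure.positions, (3, 1, 1))
        dimer = sys_.groups["dimer_proximal"]
        rest = np.setdiff1d(np.arange(sys_.structure.n_beads), dimer)
        table = analysis.energy_time_course(
            frames, sys_.structure, sys_.topology, sys_.forcefield,
            {"dimer": (dimer, rest)})
        assert isinstance(table, pd.DataFrame)
        assert table["dimer"].nunique() == 1
        assert table["dimer"].iloc[0] < 0
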