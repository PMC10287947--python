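"""Umbrella windows, WHAM reconstruction, standard-state ΔG°."""

import numpy as np
import pytest

from chaperone_cg import acceptance_support as acc
from chaperone_cg import free_energy as fe
from chaperone_cg.constants import STANDARD_VOLUME, kt


class TestWindows:
    def test_reference_grid_matches_protocol(self):
        wins = fe.generate_windows()
        d0 = sorted({w.d0 for w in wins})
        assert d0[0] == 25.0
        assert d0[-1] == 25.0 + 2 * 43 == 111.0
        assert len(wins) == 44 * 5 == 220
        assert {w.replicate for w in wins} == {1, 2, 3, 4, 5}

    def test_bias_is_no_half_harmonic(self):
        w = fe.UmbrellaWindow(0, 25.0, k=1.0)
        assert w.bias(27.0) == pytest.approx(4.0)


class TestWham:
    def test_single_unbiased_window_is_boltzmann_inversion(self, rng):
        kT = kt(300.0)
        samples = rng.normal(40.0, 2.0, size=40_000)
        win = fe.UmbrellaWindow(0, 40.0, k=1e-12, series=samples)
        prof = fe.wham([win], bin_width=0.5)
        hist, edges = np.histogram(samples,
                                   bins=np.arange(samples.min(),
                                                  samples.max() + 0.5, 0.5))
        centers = 0.5 * (edges[:-1] + edges[1:])
        mask = hist > 0
        ref = -kT * np.log(hist[mask] / hist.sum())
        ref -= ref.min()
        got = np.interp(centers[mask], prof.bin_centers, prof.free_energy)
        assert np.abs(got - ref).max() < 1e-3

    def test_parabola_recovered(self):
        rms = acc.wham_oracle_rms(acc.parabola_coeffs(), seed=11,
                                  n_steps=500_000)
        assert rms < 0.15

    def test_duplicating_samples_leaves_profile_unchanged(self, rng):
        coeffs = acc.parabola_coeffs()
        wins = fe.generate_windows(n_windows=10, d0_start=30.0, spacing=2.0,
                                   replicates=1)
        wins = fe.sample_windows_1d(coeffs, wins, n_steps=100_000,
                                    stride=20, seed=3)
        doubled = [fe.UmbrellaWindow(w.index, w.d0, w.k, w.replicate,
                                     np.concatenate([w.series, w.series]))
                   for w in wins]
        lo = min(w.series.min() for w in wins)
        hi = max(w.series.max() for w in wins)
        p1 = fe.wham(wins, bin_range=(lo, hi))
        p2 = fe.wham(doubled, bin_range=(lo, hi))
        np.testing.assert_allclose(p1.free_energy, p2.free_energy,
                                   atol=1e-6)

    def test_disjoint_windows_raise_instead_of_extrapolating(self, rng):
        w1 = fe.UmbrellaWindow(0, 20.0, series=rng.normal(20, 0.3, 2000))
        w2 = fe.UmbrellaWindow(1, 40.0, series=rng.normal(40, 0.3, 2000))
        with pytest.raises(ValueError, match="overlap"):
            fe.wham([w1, w2])

    def test_bin_width_halving_consistent(self):
        coeffs = acc.parabola_coeffs()
        wins = fe.generate_windows(n_windows=12, d0_start=28.0, spacing=2.0,
                                   replicates=1)
        wins = fe.sample_windows_1d(coeffs, wins, n_steps=400_000,
                                    stride=40, seed=4)
        p_wide = fe.wham(wins, bin_width=1.0)
        p_fine = fe.wham(wins, bin_width=0.5)
        central = np.abs(p_wide.bin_centers - 40.0) <= 8.0
        got = np.interp(p_wide.bin_centers[central], p_fine.bin_centers,
                        p_fine.free_energy)
        rms = np.sqrt(np.mean((got - p_wide.free_energy[central]) ** 2))
        assert rms < 0.15


class TestSplitErrors:
    def test_identical_subseries_give_zero_sd(self):
        # constant samples: every random subdataset has the same
        # histogram, so the split SD must vanish identically
        win = fe.UmbrellaWindow(0, 25.0, series=np.full(150, 25.0))
        prof = fe.split_sample_errors([win], n_splits=3, seed=0,
                                      bin_width=2.0)
        assert prof.errors.max() < 1e-9

    def test_splits_are_seed_reproducible(self, rng):
        wins = fe.generate_windows(n_windows=6, d0_start=34.0, spacing=2.0,
                                   replicates=1)
        wins = fe.sample_windows_1d(acc.parabola_coeffs(), wins,
                                    n_steps=60_000, stride=20, seed=5)
        e1 = fe.split_sample_errors(wins, seed=7).errors
        e2 = fe.split_sample_errors(wins, seed=7).errors
        np.testing.assert_array_equal(e1, e2)

    def test_errors_shrink_with_sampling(self):
        coeffs = acc.parabola_coeffs()
        sds = []
        for n_steps in (40_000, 640_000):
            wins = fe.generate_windows(n_windows=10, d0_start=30.0,
                                       spacing=2.0, replicates=1)
            wins = fe.sample_windows_1d(coeffs, wins, n_steps=n_steps,
                                        stride=20, seed=6)
            sds.append(fe.split_sample_errors(wins, seed=1).errors.mean())
        # 16x the samples should cut the SD by roughly 4; demand > 2
        assert sds[0] / sds[1] > 2.0

    def test_too_few_samples_rejected(self):
        win = fe.UmbrellaWindow(0, 25.0, series=np.array([25.0, 25.1]))
        with pytest.raises(ValueError, match="too few"):
            fe.split_sample_errors([win], n_splits=3)


class TestStandardState:
    @staticmethod
    def _flat_profile(lo=5.0, hi=60.0):
        d = np.arange(lo, hi, 0.5)
        return fe.FreeEnergyProfile(d, np.zeros_like(d), np.zeros_like(d),
                                    300.0)

    def test_flat_profile_entropy_only_limit(self):
        prof = self._flat_profile()
        cutoff = 15.0
        dg = fe.standard_binding_dG(prof, bound_cutoff=cutoff)
        d = prof.bin_centers[prof.bin_centers <= cutoff]
        v_bound = np.trapezoid(4 * np.pi * d**2, d)
        expected = -kt(300.0) * np.log(v_bound / STANDARD_VOLUME)
        assert dg.dg0 == pytest.approx(expected, abs=1e-9)
        assert dg.components_sum() == pytest.approx(dg.dg0)

    def test_square_well_closed_form(self):
        kT = kt(300.0)
        d = np.arange(4.0, 80.0, 0.25)
        depth = 3.0
        W = np.where(d < 12.0, -depth, 0.0)
        prof = fe.FreeEnergyProfile(d, W - W.min(), np.zeros_like(d), 300.0)
        dg = fe.standard_binding_dG(prof, bound_cutoff=12.0)
        mask = d <= 12.0
        v_eff = np.trapezoid(4 * np.pi * d[mask] ** 2
                             * np.exp(depth / kT * (d[mask] < 12.0)), d[mask])
        expected = -depth - kT * np.log(
            np.trapezoid(4 * np.pi * d[mask] ** 2
                         * np.exp((W[mask] + depth) / -kT * -1), d[mask])
            / STANDARD_VOLUME)
        del v_eff
        # direct evaluation of the defining integral
        expected = -kT * np.log(np.trapezoid(
            4 * np.pi * d[mask] ** 2 * np.exp(-W[mask] / kT), d[mask])
            / STANDARD_VOLUME)
        assert dg.dg0 == pytest.approx(expected, abs=0.05)

    def test_deepening_well_shifts_dg_linearly(self):
        kT = kt(300.0)
        d = np.arange(4.0, 80.0, 0.25)
        delta = 1.5

        def dg_for(depth):
            W = np.where(d < 12.0, -depth, 0.0)
            prof = fe.FreeEnergyProfile(d, W - W.min(), np.zeros_like(d),
                                        300.0)
            return fe.standard_binding_dG(prof, bound_cutoff=12.0).dg0

        # deep-well limit: ΔG° drops by exactly the added depth
        assert dg_for(10.0 + delta) - dg_for(10.0) == pytest.approx(
            -delta, abs=0.01)
        del kT

    def test_missing_plateau_rejected(self):
        d = np.arange(5.0, 40.0, 0.5)
        W = 0.5 * d  # relentless slope
        prof = fe.FreeEnergyProfile(d, W - W.min(), np.zeros_like(d), 300.0)
        with pytest.raises(ValueError, match="plateau"):
            fe.standard_binding_dG(prof)

    def test_dissociation_constant_elementary_relation(self):
        kT = kt(300.0)
        dg = -12.6
        kd = fe.dissociation_constant(dg, 300.0)
        assert kd == pytest.approx(np.exp(dg / kT))
        # the elementary relation maps −12.6 kcal/mol to sub-nanomolar Kd
        assert kd < 1e-9
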