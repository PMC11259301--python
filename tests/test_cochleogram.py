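"""Cochleogram smoothing, fraction conversion, fragment merging and
resampling, including the count-conservation and smoothness invariants."""

from __future__ import annotations

import numpy as np
import pytest

from cochleoquant import (
    FragmentCoordinates,
    combine_fragments,
    compute_cochleogram,
    resample_relative,
    to_fraction,
)
from cochleoquant.cochleogram import ConfigurationError

L = 5700.0
SIGMA = 250.0


class TestComputeCochleogram:
    def test_no_cells_gives_zero_density(self):
        cg = compute_cochleogram({"IHC": []}, L=L)
        assert np.all(cg.densities["IHC"] == 0.0)
        assert cg.n_cells["IHC"] == 0

    def test_single_cell_interior_peak_value(self):
        """One interior cell: the density at the cell equals the unit-mass
        Gaussian peak 1/(σ√(2π)) since w ≈ 1 there."""
        cg = compute_cochleogram({"IHC": [2850.0]}, L=L, sigma=SIGMA)
        k = int(np.argmin(np.abs(cg.grid - 2850.0)))
        expected = 1.0 / (SIGMA * np.sqrt(2.0 * np.pi))
        assert cg.densities["IHC"][k] == pytest.approx(expected, rel=1e-3)

    def test_uniform_cells_flat_density(self):
        """673 equally spaced cells (the IHC expectation 11.8/100 μm × 5700 μm)
        give a density within 3% of 673/5700 everywhere, correction on."""
        n = 673
        s = (np.arange(n) + 0.5) * (L / n)
        cg = compute_cochleogram({"IHC": s}, L=L, sigma=SIGMA)
        assert np.all(np.abs(cg.densities["IHC"] - n / L) < 0.03 * n / L)

    def test_coordinate_outside_domain_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            compute_cochleogram({"IHC": [-5.0]}, L=L)
        with pytest.raises(ValueError, match="outside"):
            compute_cochleogram({"IHC": [L + 5.0]}, L=L)

    @pytest.mark.parametrize("seed", range(3))
    def test_count_conservation_with_correction(self, seed):
        rng = np.random.default_rng(seed)
        # basally-declining density via thinning, as transduction profiles produce
        u = rng.uniform(0, L, 1200)
        keep = rng.uniform(0, 1, u.size) < 1.0 / (1.0 + np.exp((u - 1700.0) / 400.0))
        coords = {
            "IHC": rng.uniform(0, L, 400),
            "OHC1": u[keep],
        }
        cg = compute_cochleogram(coords, L=L, sigma=SIGMA, boundary_correction=True)
        for t, s in coords.items():
            integral = np.trapezoid(cg.densities[t], cg.grid)
            assert integral == pytest.approx(len(s), rel=0.005)

    def test_uncorrected_density_understates_edges(self):
        rng = np.random.default_rng(0)
        coords = {"IHC": rng.uniform(0, L, 500)}
        on = compute_cochleogram(coords, L=L, boundary_correction=True)
        off = compute_cochleogram(coords, L=L, boundary_correction=False)
        # uniform density: uncorrected edge value ≈ ρ/2, corrected ≈ ρ
        assert off.densities["IHC"][0] < 0.6 * on.densities["IHC"][0]
        # deep interior (≥ 4σ from the ends): correction reduces to the global
        # mass factor, which stays within half a percent of 1
        interior = (on.grid > 4 * SIGMA) & (on.grid < L - 4 * SIGMA)
        ratio = on.densities["IHC"][interior] / off.densities["IHC"][interior]
        assert np.all(np.abs(ratio - ratio.mean()) < 1e-4)
        assert abs(ratio.mean() - 1.0) < 5e-3

    def test_permutation_invariance_exact(self):
        rng = np.random.default_rng(1)
        s = rng.uniform(0, L, 200)
        a = compute_cochleogram({"IHC": s}, L=L)
        b = compute_cochleogram({"IHC": rng.permutation(s)}, L=L)
        assert np.array_equal(a.densities["IHC"], b.densities["IHC"])

    def test_sigma_monotone_smoothing(self):
        """Larger σ never increases the maximum profile gradient."""
        rng = np.random.default_rng(3)
        coords = {"IHC": rng.uniform(0, L, 300)}
        grads = []
        for sigma in (100.0, 175.0, 250.0, 400.0):
            cg = compute_cochleogram(coords, L=L, sigma=sigma)
            f = to_fraction(cg).fractions["IHC"]
            grads.append(np.max(np.abs(np.diff(f) / np.diff(cg.grid))))
        assert np.all(np.diff(grads) <= 1e-12)


class TestToFraction:
    def test_reference_density_ratio_unity(self):
        """A density equal to the IHC reference (11.8/100 μm) is fraction 1."""
        cg = compute_cochleogram({"IHC": []}, L=L)
        cg.densities["IHC"][:] = 0.118
        prof = to_fraction(cg)
        assert np.allclose(prof.fractions["IHC"], 1.0)

    def test_zero_density_zero_fraction(self):
        prof = to_fraction(compute_cochleogram({"OHC2": []}, L=L))
        assert np.all(prof.fractions["OHC2"] == 0.0)

    def test_half_reference_is_half(self):
        cg = compute_cochleogram({"OHC1": []}, L=L)
        cg.densities["OHC1"][:] = 0.0685
        prof = to_fraction(cg)
        assert np.allclose(prof.fractions["OHC1"], 0.5)

    def test_missing_reference_names_type(self):
        cg = compute_cochleogram({"PC": []}, L=L)
        with pytest.raises(ConfigurationError, match="PC"):
            to_fraction(cg)

    def test_supporting_cells_with_explicit_reference(self):
        cg = compute_cochleogram({"PC": []}, L=L)
        cg.densities["PC"][:] = 0.13
        prof = to_fraction(cg, refs={"PC": 13.0})
        assert np.allclose(prof.fractions["PC"], 1.0)

    def test_over_unity_warns_but_not_clamped(self, caplog):
        cg = compute_cochleogram({"IHC": []}, L=L)
        cg.densities["IHC"][:] = 0.118 * 1.2
        with caplog.at_level("WARNING"):
            prof = to_fraction(cg)
        assert np.allclose(prof.fractions["IHC"], 1.2)
        assert any("1.05" in r.message for r in caplog.records)


class TestCombineFragments:
    def test_offset_arithmetic(self):
        frags = [
            FragmentCoordinates({"IHC": np.array([100.0])}, L=3000.0),
            FragmentCoordinates({"IHC": np.array([100.0])}, L=2700.0),
        ]
        # correction off so each kernel peaks exactly at its cell
        prof = combine_fragments(frags, boundary_correction=False)
        assert prof.L == pytest.approx(5700.0)
        # density peaks at the offset coordinates 100 and 3100
        lam = prof.densities["IHC"]
        first = prof.grid < 1500
        second = ~first
        assert prof.grid[first][np.argmax(lam[first])] == pytest.approx(100.0, abs=10.0)
        assert prof.grid[second][np.argmax(lam[second])] == pytest.approx(3100.0, abs=10.0)

    def test_single_fragment_identity(self):
        rng = np.random.default_rng(2)
        coords = {"IHC": rng.uniform(0, L, 150)}
        whole = to_fraction(compute_cochleogram(coords, L=L))
        frag = combine_fragments([FragmentCoordinates(coords, L=L)])
        assert np.allclose(whole.fractions["IHC"], frag.fractions["IHC"])

    def test_cut_reanalysis_matches_uncut(self):
        """Cutting coordinates at a known position and re-merging matches the
        uncut profile away from the cut ± 2σ."""
        rng = np.random.default_rng(7)
        coords = {"IHC": np.sort(rng.uniform(0, L, 600))}
        cut = 2500.0
        uncut = to_fraction(compute_cochleogram(coords, L=L, sigma=SIGMA))
        frags = [
            FragmentCoordinates({"IHC": coords["IHC"][coords["IHC"] < cut]}, L=cut),
            FragmentCoordinates({"IHC": coords["IHC"][coords["IHC"] >= cut] - cut}, L=L - cut),
        ]
        merged = combine_fragments(frags, sigma=SIGMA)
        away = np.abs(uncut.grid - cut) > 2 * SIGMA
        dev = np.abs(uncut.fractions["IHC"][away] - merged.fractions["IHC"][away])
        assert dev.max() < 0.05

    def test_empty_fragment_list_is_error(self):
        with pytest.raises(ValueError):
            combine_fragments([])


class TestResampleRelative:
    def _ramp(self):
        grid = np.arange(0.0, L + 1, 10.0)
        f = grid / L
        from cochleoquant.cochleogram import TransductionProfile

        return TransductionProfile(
            grid=grid, fractions={"IHC": f}, densities={"IHC": f * 0.118}
        )

    def test_constant_stays_constant(self):
        prof = self._ramp()
        prof.fractions["IHC"][:] = 0.4
        out = resample_relative(prof, 37)
        assert np.allclose(out.fractions["IHC"], 0.4)

    def test_identity_on_original_grid(self):
        prof = self._ramp()
        out = resample_relative(prof, len(prof.grid))
        assert np.allclose(out.fractions["IHC"], prof.fractions["IHC"], atol=1e-9)

    def test_linear_ramp_maps_to_relative_grid(self):
        out = resample_relative(self._ramp(), 101)
        assert np.allclose(out.fractions["IHC"], out.grid, atol=1e-6)

    def test_too_few_points_is_error(self):
        with pytest.raises(ValueError):
            resample_relative(self._ramp(), 1)
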