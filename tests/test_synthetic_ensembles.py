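import math

import numpy as np
import pytest

from crebind import (
    CREThresholds,
    Ensemble,
    HostWall,
    MTDParams,
    ToyTorsionModel,
    assemble_cre,
    assign_to_minima,
    brute_force_reference,
    embed,
    genetic_cross,
    measure_torsions,
    mtd_bias,
    numerical_frequencies,
    run_mtd,
    run_unbiased,
    toy_energy,
)
from crebind.constants import AMU_KG, AVOGADRO, SPEED_OF_LIGHT, rt


def double_well(n=1, barrier=1.0, tilt=0.0):
    """Per-torsion V = barrier*(1 - cos 2phi) + tilt*(1 - cos(phi - pi))."""
    if tilt:
        return ToyTorsionModel(
            n_torsions=n,
            amplitudes=((barrier, tilt),) * n,
            multiplicities=((2, 1),) * n,
            phases=((0.0, math.pi),) * n,
        )
    return ToyTorsionModel(
        n_torsions=n,
        amplitudes=((barrier,),) * n,
        multiplicities=((2,),) * n,
        phases=((0.0,),) * n,
    )


class TestToyEnergy:
    def test_single_torsion_values(self):
        m = double_well()
        assert toy_energy(m, [0.0]) == pytest.approx(0.0)
        assert toy_energy(m, [math.pi / 2]) == pytest.approx(2.0)

    def test_no_host_no_wall(self):
        m = double_well()
        assert toy_energy(m, [1.0]) == toy_energy(m, [1.0], position=(100.0, 0, 0))

    def test_wall_zero_on_boundary_and_inside(self):
        host = HostWall(semiaxes=(3.0, 3.0, 3.0), strength=50.0, exponent=4)
        m = ToyTorsionModel(
            n_torsions=1, amplitudes=((1.0,),), multiplicities=((2,),),
            phases=((0.0,),), host=host,
        )
        base = toy_energy(double_well(), [0.5])
        centroid = embed(double_well(), [0.5]).coords.mean(axis=0)
        on_surface = np.array([3.0, 0.0, 0.0]) - centroid
        assert toy_energy(m, [0.5], position=on_surface) == pytest.approx(base, abs=1e-9)
        outside = np.array([6.0, 0.0, 0.0]) - centroid
        assert toy_energy(m, [0.5], position=outside) > base + 1.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            toy_energy(double_well(), [0.0, 0.0])


class TestEmbed:
    def test_canonical_placement(self):
        s = embed(double_well(n=2), [1.0, -2.0])
        np.testing.assert_allclose(s.coords[0], 0.0, atol=1e-12)

    def test_torsion_roundtrip(self, rng):
        m = double_well(n=4)
        for _ in range(10):
            phi = rng.uniform(-math.pi, math.pi, size=4)
            got = measure_torsions(embed(m, phi))
            np.testing.assert_allclose(got, phi, atol=1e-8)

    def test_all_trans_is_extended(self, rng):
        m = double_well(n=3)
        trans = embed(m, [math.pi] * 3)
        e2e_trans = np.linalg.norm(trans.coords[-1] - trans.coords[0])
        for _ in range(20):
            s = embed(m, rng.uniform(-math.pi, math.pi, size=3))
            assert np.linalg.norm(s.coords[-1] - s.coords[0]) <= e2e_trans + 1e-9


class TestBruteForceReference:
    def test_symmetric_double_well(self):
        ref = brute_force_reference(double_well(), 72, 300.0)
        assert len(ref.populations) == 2
        np.testing.assert_allclose(ref.populations, [0.5, 0.5], atol=1e-12)
        np.testing.assert_allclose(
            np.sort(np.abs(ref.minima_torsions.ravel())), [0.0, math.pi], atol=0.05
        )

    def test_tilted_double_well_population_ratio(self):
        """Basin populations match the grid partition sums of the two wells."""
        m = double_well(barrier=1.0, tilt=0.15)
        T = 300.0
        ref = brute_force_reference(m, 144, T)
        assert len(ref.populations) == 2
        # independent two-basin partition sum on a fine grid, split at the
        # barrier tops (phi = +-pi/2 for the m=2 term dominating)
        phi = np.linspace(-math.pi, math.pi, 20001)
        v = 1.0 * (1 - np.cos(2 * phi)) + 0.15 * (1 - np.cos(phi - math.pi))
        w = np.exp(-v / rt(T))
        inner = np.abs(phi) < math.pi / 2
        p_inner = w[inner].sum() / w.sum()
        assert ref.populations[np.argmin(np.abs(ref.minima_torsions.ravel()))] == pytest.approx(
            p_inner, abs=0.01
        )

    def test_grid_refinement_converges(self):
        m = double_well(barrier=1.0, tilt=0.15)
        coarse = brute_force_reference(m, 36, 300.0)
        fine = brute_force_reference(m, 360, 300.0)
        np.testing.assert_allclose(coarse.populations, fine.populations, atol=0.01)

    def test_grid_limits(self):
        with pytest.raises(ValueError):
            brute_force_reference(double_well(), 10, 300.0)
        with pytest.raises(ValueError):
            brute_force_reference(double_well(n=9), 36, 300.0)


class TestMtdBias:
    def test_zero_distance_full_push(self):
        s = embed(double_well(), [0.0])
        assert mtd_bias(s, [s], 1.0, 0.8) == pytest.approx(1.0)

    def test_far_reference_vanishes(self):
        m = double_well(n=3)
        a = embed(m, [0.0, 0.0, 0.0])
        b = embed(m, [math.pi, -2.0, 2.0])
        assert mtd_bias(a, [b], 1.0, 5.0) < 1e-3

    def test_additivity(self):
        s = embed(double_well(), [0.0])
        assert mtd_bias(s, [s, s], 0.5, 0.8) == pytest.approx(1.0)

    def test_empty_references(self):
        s = embed(double_well(), [0.0])
        assert mtd_bias(s, [], 1.0, 0.8) == 0.0


class TestSampling:
    def test_seed_determinism(self):
        m = double_well(n=2, barrier=1.5)
        p = MTDParams(steps=300, seed=42)
        e1, e2 = run_mtd(m, p), run_mtd(m, p)
        assert len(e1) == len(e2)
        np.testing.assert_array_equal(e1.energies, e2.energies)
        np.testing.assert_allclose(e1[-1].coords, e2[-1].coords)

    def test_zero_push_equals_unbiased(self):
        m = double_well(n=2, barrier=1.5)
        biased_off = run_mtd(m, MTDParams(steps=400, k_push=0.0, seed=7))
        unbiased = run_unbiased(m, steps=400, seed=7)
        np.testing.assert_array_equal(biased_off.energies, unbiased.energies)

    def test_recorded_energies_exclude_bias(self):
        m = double_well(n=2, barrier=1.5)
        ens = run_mtd(m, MTDParams(steps=400, k_push=1.0, seed=3))
        assert ens.bias_energies.max() > 0  # bias was actually active
        for s in list(ens)[::25]:
            phi = measure_torsions(s)
            assert s.energy_total == pytest.approx(toy_energy(m, phi), abs=1e-8)

    def test_zero_steps_rejected(self):
        with pytest.raises(ValueError):
            MTDParams(steps=0)

    def test_unbiased_sampling_matches_boltzmann(self):
        """Long unbiased run on a single-well torsion reproduces the grid
        Boltzmann density within binning error."""
        m = ToyTorsionModel(
            n_torsions=1, amplitudes=((1.2,),), multiplicities=((1,),), phases=((0.0,),)
        )
        ens = run_unbiased(m, T=300.0, steps=15000, seed=11)
        steps = ens.step_indices
        dwell = np.diff(np.append(steps, ens.total_steps)).astype(float)
        phis = np.array([measure_torsions(s)[0] for s in ens])
        keep = steps > 1000
        hist, edges = np.histogram(
            phis[keep], bins=12, range=(-math.pi, math.pi), weights=dwell[keep]
        )
        hist = hist / hist.sum()
        centers = 0.5 * (edges[:-1] + edges[1:])
        v = 1.2 * (1 - np.cos(centers))
        expect = np.exp(-v / rt(300.0))
        expect /= expect.sum()
        assert np.abs(hist - expect).max() < 0.05

    def test_bias_enhances_exploration(self):
        """Paired over seeds, the biased walker discovers at least as many
        distinct minima as the unbiased one."""
        m = double_well(barrier=2.5, tilt=0.3)
        ref = brute_force_reference(m, 72, 300.0)
        gains = []
        for seed in range(8):
            biased = run_mtd(m, MTDParams(steps=500, k_push=0.5, alpha=1.0,
                                          deposition_interval=25, max_references=20, seed=seed))
            plain = run_unbiased(m, steps=500, seed=seed)
            nb = len(set(assign_to_minima(np.array([measure_torsions(s) for s in biased]), ref)))
            nu = len(set(assign_to_minima(np.array([measure_torsions(s) for s in plain]), ref)))
            gains.append(nb - nu)
        assert np.mean(gains) >= 0


class TestGeneticCross:
    def test_two_torsion_children(self):
        children = genetic_cross([1.0, 2.0], [3.0, 4.0])
        got = {tuple(c) for c in children}
        assert got == {(1.0, 4.0), (3.0, 2.0)}

    def test_identical_parents_no_children(self):
        assert genetic_cross([1.0, 2.0], [1.0, 2.0]) == []

    def test_child_count_bound(self, rng):
        for n in (2, 3, 5):
            a, b = rng.normal(size=n), rng.normal(size=n)
            assert len(genetic_cross(a, b)) <= 2**n - 2

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            genetic_cross([1.0], [1.0, 2.0])

    def test_children_outside_window_are_pruned(self):
        """Crossing children with high torsional strain fall outside the
        retention window and are dropped by the CRE machinery."""
        m = double_well(n=2, barrier=4.0, tilt=0.5)
        parents = [np.array([0.0, 0.0]), np.array([math.pi, math.pi])]
        children = genetic_cross(parents[0], parents[1])
        structures = [embed(m, p) for p in [*parents, *children]]
        # widen separation: shift child energies via the model itself
        ens = Ensemble(structures)
        cre = assemble_cre(ens, CREThresholds(window=0.8))
        energies = cre.representative_energies
        assert energies.max() - energies.min() <= 0.8


class TestNumericalFrequencies:
    def test_closed_form_single_rotor(self):
        """Heavy-frame chain: the torsional mode reduces to a point mass on
        a circle, omega = sqrt(V''/I) with I = m (b sin(theta))^2."""
        m = ToyTorsionModel(
            n_torsions=1, amplitudes=((2.0,),), multiplicities=((1,),), phases=((0.0,),),
            atom_masses=(1e6, 1e6, 1e6, 1.0),
        )
        freqs = numerical_frequencies(m, [0.0])
        k = 2.0  # V'' of 2(1-cos phi) at phi=0
        inertia = 1.0 * (m.bond_length * math.sin(math.radians(m.bond_angle_deg))) ** 2
        omega = math.sqrt(k * 4184.0 / AVOGADRO / (inertia * AMU_KG * 1e-20))
        expected = omega / (2 * math.pi * SPEED_OF_LIGHT * 100.0)
        assert freqs[0] == pytest.approx(expected, rel=1e-3)

    def test_maximum_flags_imaginary(self):
        m = double_well()
        with pytest.raises(ValueError, match="imaginary"):
            numerical_frequencies(m, [math.pi / 2])  # barrier top

    def test_step_size_convergence(self):
        m = double_well(n=2, barrier=1.5, tilt=0.2)
        f1 = numerical_frequencies(m, [0.0, 0.0], step=2e-3)
        f2 = numerical_frequencies(m, [0.0, 0.0], step=1e-3)
        np.testing.assert_allclose(f1, f2, rtol=1e-3)

    def test_all_real_at_minimum(self):
        m = double_well(n=3, barrier=1.5)
        freqs = numerical_frequencies(m, [0.0, 0.0, 0.0])
        assert len(freqs) == 3
        assert np.all(freqs >= 0)
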