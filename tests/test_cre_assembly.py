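import dataclasses

import numpy as np
import pytest

from crebind import (
    CREThresholds,
    Ensemble,
    Structure,
    assemble_cre,
    classify_pair,
    prune_window,
    staged_refine,
)

from conftest import make_structure


@pytest.fixture
def chiral(rng):
    """A chiral 6-atom structure; its mirror has identical rotational
    constants but cannot be superposed by a proper rotation."""
    return make_structure(rng, n_atoms=6, energy=-5.0)


def mirror_of(s, energy=None):
    return Structure(
        s.atom_symbols,
        s.coords * np.array([1.0, 1.0, -1.0]),
        s.energy_total if energy is None else energy,
    )


def with_energy(s, energy):
    return dataclasses.replace(s, energy_total=energy)


class TestClassifyPair:
    def test_identical_is_duplicate(self, chiral):
        assert classify_pair(chiral, chiral) == "duplicate"

    def test_mirror_image_is_rotamer(self, chiral):
        """Same energy, same rotational constants, large RMSD: the
        definition of a rotamer (an internal-rotation/symmetry image)."""
        assert classify_pair(chiral, mirror_of(chiral)) == "rotamer"

    def test_energy_gap_is_conformer(self, chiral):
        assert classify_pair(chiral, with_energy(chiral, chiral.energy_total + 1.0)) == "conformer"

    def test_same_energy_different_shape_is_conformer(self, rng, chiral):
        other = Structure(chiral.atom_symbols, rng.normal(scale=2.0, size=chiral.coords.shape), chiral.energy_total)
        assert classify_pair(chiral, other) == "conformer"


class TestAssembleCre:
    def test_three_copies_collapse(self, chiral):
        ens = Ensemble([chiral, chiral, chiral])
        cre = assemble_cre(ens)
        assert cre.n_conformers == 1
        assert cre.n_structures == 1
        assert len(cre.drop_log) == 2

    def test_constructed_four_frame_case(self, chiral):
        rotamer = mirror_of(chiral, energy=chiral.energy_total + 0.01)
        conformer_b = with_energy(mirror_of(chiral), chiral.energy_total + 2.0)
        # B's mirror relation is to A, not to itself; against A it fails the
        # energy criterion, so it opens a second group
        duplicate = dataclasses.replace(chiral)
        ens = Ensemble([chiral, rotamer, conformer_b, duplicate])
        cre = assemble_cre(ens)
        assert cre.n_conformers == 2
        assert len(cre.groups[0].rotamers) == 1
        assert cre.n_structures == 3

    def test_global_minimum_is_first_representative(self, rng):
        ens = Ensemble([make_structure(rng, energy=float(e)) for e in rng.normal(scale=2.0, size=12)])
        cre = assemble_cre(ens)
        assert cre.groups[0].representative.energy_total == pytest.approx(ens.energies.min())
        assert np.all(np.diff(cre.representative_energies) >= 0)

    def test_idempotence(self, rng):
        ens = Ensemble([make_structure(rng, energy=float(e)) for e in rng.normal(scale=2.0, size=10)])
        cre1 = assemble_cre(ens)
        cre2 = assemble_cre(cre1.flatten())
        np.testing.assert_allclose(
            cre2.representative_energies, cre1.representative_energies
        )
        assert cre2.n_structures == cre1.n_structures

    def test_count_conservation(self, rng):
        ens = Ensemble([make_structure(rng, energy=float(e)) for e in rng.normal(scale=4.0, size=15)])
        cre = assemble_cre(ens)
        assert cre.n_structures + len(cre.drop_log) == len(ens)

    def test_order_robustness(self, rng):
        structures = [make_structure(rng, energy=float(e)) for e in rng.normal(scale=4.0, size=12)]
        cre_a = assemble_cre(Ensemble(structures))
        shuffled = list(structures)
        rng.shuffle(shuffled)
        cre_b = assemble_cre(Ensemble(shuffled))
        np.testing.assert_allclose(
            np.sort(cre_a.representative_energies),
            np.sort(cre_b.representative_energies),
            atol=1e-12,
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            Ensemble([])


class TestPruneWindow:
    def test_six_kcal_window(self, rng):
        structures = [make_structure(rng, energy=e) for e in (0.0, 3.0, 7.0)]
        cre = assemble_cre(Ensemble(structures), apply_window=False)
        pruned = prune_window(cre, 6.0)
        assert pruned.n_conformers == 2

    def test_infinite_window_is_identity(self, rng):
        structures = [make_structure(rng, energy=e) for e in (0.0, 3.0, 7.0)]
        cre = assemble_cre(Ensemble(structures), apply_window=False)
        assert prune_window(cre, np.inf).n_conformers == 3

    def test_monotonicity(self, rng):
        structures = [make_structure(rng, energy=float(e)) for e in rng.uniform(0, 20, size=20)]
        cre = assemble_cre(Ensemble(structures), apply_window=False)
        counts = [prune_window(cre, w).n_structures for w in (20.0, 15.0, 10.0, 6.0, 2.0)]
        assert counts == sorted(counts, reverse=True)


class TestStagedRefine:
    def test_survivor_counts(self, rng):
        structures = [make_structure(rng, energy=e) for e in (0.0, 4.0, 8.0, 12.0, 20.0)]
        cre = staged_refine(Ensemble(structures), windows=(15.0, 10.0, 6.0))
        assert cre.stage_counts == [4, 3, 2]

    def test_single_structure(self, rng):
        cre = staged_refine(Ensemble([make_structure(rng)]), windows=(15.0, 10.0, 6.0))
        assert cre.stage_counts == [1, 1, 1]

    def test_non_decreasing_windows_rejected(self, rng):
        with pytest.raises(ValueError):
            staged_refine(Ensemble([make_structure(rng)]), windows=(6.0, 10.0))

    def test_equivalent_to_direct_assembly(self, rng):
        """With constant thresholds the staged result equals a one-shot
        assembly at the final window."""
        for _ in range(5):
            structures = [make_structure(rng, energy=float(e)) for e in rng.uniform(0, 18, size=15)]
            ens = Ensemble(structures)
            staged = staged_refine(ens, windows=(15.0, 10.0, 6.0))
            direct = assemble_cre(ens, CREThresholds(window=6.0))
            np.testing.assert_allclose(
                staged.representative_energies, direct.representative_energies
            )


def test_cre_serialization_roundtrip(tmp_path, rng):
    import json

    from crebind import read_multixyz

    structures = [make_structure(rng, energy=float(e)) for e in rng.normal(size=8)]
    cre = assemble_cre(Ensemble(structures))
    xyz = tmp_path / "cre.xyz"
    cre.save(xyz, energy_unit="kcal/mol")
    back = read_multixyz(xyz, energy_unit="kcal/mol")
    assert len(back) == cre.n_structures
    sidecar = json.loads((tmp_path / "cre.xyz.json").read_text())
    assert len(sidecar["groups"]) == cre.n_conformers
    assert sidecar["groups"][0]["representative_frame"] == 0
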