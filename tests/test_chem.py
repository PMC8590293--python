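"""Standardization, scaffolds, fingerprints and similarity scores."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

from deephop import chem


class TestCanonicalize:
    def test_equivalent_smiles_share_canonical_form(self):
        assert chem.canonicalize("OCC").smiles == chem.canonicalize("CCO").smiles

    def test_idempotent(self):
        first = chem.canonicalize("c1ccccc1").smiles
        assert chem.canonicalize(first).smiles == first

    @pytest.mark.parametrize("bad", ["C(C", "notasmiles", "C1CC", ""])
    def test_invalid_raises(self, bad):
        with pytest.raises(chem.InvalidMoleculeError):
            chem.canonicalize(bad)


class TestStandardize:
    @pytest.mark.parametrize("smi,expected", [
        ("CCO.[Na+].[Cl-]", "CCO"),        # salt strip keeps organic fragment
        ("[13CH4]", "C"),                   # isotope label cleared
        ("CC(=O)[O-]", "CC(=O)O"),          # anion neutralized
        ("CC[NH3+]", "CCN"),                # cation neutralized
    ])
    def test_normalization_rules(self, smi, expected):
        assert chem.standardize(chem.canonicalize(smi)).smiles == expected

    def test_strict_mode_rejects_disconnected(self):
        rec = chem.canonicalize("CCO.[Na+].[Cl-]")
        with pytest.raises(chem.InvalidMoleculeError):
            chem.standardize(rec, strip_salts=False)

    def test_all_inorganic_rejected(self):
        with pytest.raises(chem.InvalidMoleculeError):
            chem.standardize(chem.canonicalize("[Na+].[Cl-]"))

    def test_idempotent_on_library(self, library):
        for rec in library:
            assert chem.standardize(rec).smiles == rec.smiles


def _murcko_oracle(smiles: str) -> str:
    """Independent scaffold pruner: iteratively delete terminal non-ring
    atoms.  A multiply-bonded terminal atom survives only when its neighbor
    is a ring atom (exocyclic =O stays; a side-chain nitrile goes)."""
    mol = Chem.RWMol(Chem.MolFromSmiles(smiles))
    changed = True
    while changed:
        changed = False
        for atom in mol.GetAtoms():
            if atom.GetDegree() == 1 and not atom.IsInRing():
                bond = atom.GetBonds()[0]
                other = bond.GetOtherAtom(atom)
                if (bond.GetBondType() == Chem.BondType.SINGLE
                        or not other.IsInRing()):
                    mol.RemoveAtom(atom.GetIdx())
                    changed = True
                    break
    if not any(a.IsInRing() for a in mol.GetAtoms()):
        return ""
    return Chem.MolToSmiles(mol.GetMol())


class TestBmScaffold:
    def test_ring_only_molecule_is_its_own_scaffold(self):
        rec = chem.canonicalize("c1ccc(-c2ccccc2)cc1")
        assert chem.bm_scaffold(rec).smiles == rec.smiles

    def test_acyclic_gives_empty_scaffold(self):
        assert chem.bm_scaffold(chem.canonicalize("CCCC")).smiles == ""

    def test_matches_independent_pruning_oracle(self, library):
        for rec in library:
            assert chem.bm_scaffold(rec).smiles == _murcko_oracle(rec.smiles)

    def test_idempotent(self, library):
        for rec in library:
            scaf = chem.bm_scaffold(rec)
            assert chem.bm_scaffold(scaf).smiles == scaf.smiles


class TestFingerprints:
    def test_deterministic(self):
        a = chem.morgan_fp(chem.canonicalize("Cc1ccccc1O"))
        b = chem.morgan_fp(chem.canonicalize("Cc1ccccc1O"))
        assert a.bits == b.bits

    def test_benzene_vs_cyclohexane_no_shared_environments(self):
        """Aromatic and aliphatic ring carbons share no circular environment:
        each homogeneous ring has exactly 1 distinct atom environment per
        radius (0, 1, 2), disjoint between the two molecules, so the
        Tanimoto is 0 and each fingerprint has at most 3 on-bits."""
        benzene = chem.morgan_fp(chem.canonicalize("c1ccccc1"))
        cyclohexane = chem.morgan_fp(chem.canonicalize("C1CCCCC1"))
        assert chem.tanimoto(benzene, cyclohexane) == 0.0
        assert len(benzene.bits) <= 3 and len(cyclohexane.bits) <= 3

    def test_bit_range_enforced(self):
        with pytest.raises(ValueError):
            chem.BitFingerprint(bits=frozenset([10]), n_bits=8)


class TestTanimoto:
    @pytest.mark.parametrize("a,b,expected", [
        ({1, 2, 3}, {1, 2, 3}, 1.0),
        ({1, 2}, {3, 4}, 0.0),
        ({1, 2, 3}, {2, 3, 4}, 0.5),
        (set(), set(), 0.0),     # both-empty convention
    ])
    def test_known_values(self, a, b, expected):
        fa = chem.BitFingerprint(bits=frozenset(a), n_bits=64)
        fb = chem.BitFingerprint(bits=frozenset(b), n_bits=64)
        assert chem.tanimoto(fa, fb) == expected

    def test_mismatched_length_rejected(self):
        with pytest.raises(ValueError):
            chem.tanimoto(chem.BitFingerprint(frozenset(), 64),
                          chem.BitFingerprint(frozenset(), 128))

    @settings(max_examples=200, deadline=None)
    @given(st.sets(st.integers(0, 63)), st.sets(st.integers(0, 63)))
    def test_matches_set_arithmetic_and_is_symmetric(self, a, b):
        fa = chem.BitFingerprint(bits=frozenset(a), n_bits=64)
        fb = chem.BitFingerprint(bits=frozenset(b), n_bits=64)
        expected = len(a & b) / len(a | b) if (a | b) else 0.0
        assert chem.tanimoto(fa, fb) == expected
        assert chem.tanimoto(fa, fb) == chem.tanimoto(fb, fa)
        assert 0.0 <= chem.tanimoto(fa, fb) <= 1.0


class TestScaffoldSimilarity2D:
    def test_self_similarity_is_one_for_every_ring_molecule(self, library):
        for rec in library:
            if chem.bm_scaffold(rec).smiles:
                assert chem.scaffold_similarity_2d(rec, rec) == 1.0

    def test_two_acyclic_molecules_score_zero(self):
        x, y = chem.canonicalize("CCCC"), chem.canonicalize("CCO")
        assert chem.scaffold_similarity_2d(x, y) == 0.0

    def test_shared_scaffold_scores_one(self):
        toluene = chem.canonicalize("Cc1ccccc1")
        ethylbenzene = chem.canonicalize("CCc1ccccc1")
        assert chem.scaffold_similarity_2d(toluene, ethylbenzene) == 1.0


class TestEmbedConformers:
    def test_deterministic_for_fixed_seed(self):
        rec = chem.canonicalize("CCOc1ccccc1", mol_id="m")
        a = chem.embed_conformers(rec, n_conf=3, seed=7)
        b = chem.embed_conformers(rec, n_conf=3, seed=7)
        assert np.array_equal(a.conformer.coords, b.conformer.coords)

    def test_selected_conformer_has_minimum_energy(self):
        from rdkit.Chem import AllChem
        rec = chem.canonicalize("CCCC", mol_id="butane")
        out = chem.embed_conformers(rec, n_conf=20, seed=3)
        # recompute the full energy list independently
        mol = Chem.AddHs(Chem.MolFromSmiles(rec.smiles))
        params = AllChem.ETKDGv3()
        params.randomSeed = 3
        params.numThreads = 1
        AllChem.EmbedMultipleConfs(mol, numConfs=20, params=params)
        energies = [e for _, e in AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=500)]
        assert out.conformer.energy <= min(energies) + 1e-6

    def test_coordinate_count_matches_h_added_atom_count(self, library3d):
        for rec in library3d[:5]:
            molh = Chem.AddHs(Chem.MolFromSmiles(rec.smiles))
            assert rec.conformer.coords.shape == (molh.GetNumAtoms(), 3)

    def test_unembeddable_raises(self):
        with pytest.raises((chem.ConformerError, chem.InvalidMoleculeError)):
            chem.embed_conformers(chem.canonicalize("[H][H]"), n_conf=2)


def _rigid_transform(rec, rng):
    from scipy.spatial.transform import Rotation
    R = Rotation.from_euler("xyz", rng.uniform(-np.pi, np.pi, 3)).as_matrix()
    t = rng.uniform(-10, 10, 3)
    coords = rec.conformer.coords @ R.T + t
    return replace(rec, conformer=chem.Conformer3D(coords=coords,
                                                   energy=rec.conformer.energy))


class TestScScore:
    def test_self_similarity_is_one(self, library3d):
        for rec in library3d[:3]:
            assert chem.sc_score(rec, rec) == pytest.approx(1.0, abs=1e-3)

    def test_invariant_under_rigid_transform(self, library3d, rng):
        x, y = library3d[0], library3d[1]
        base = chem.sc_score(x, y)
        moved = chem.sc_score(x, _rigid_transform(y, rng))
        assert moved == pytest.approx(base, abs=1e-3)
        assert 0.0 <= base <= 1.0

    def test_symmetric_up_to_alignment_tolerance(self, library3d):
        x, y = library3d[2], library3d[3]
        assert chem.sc_score(x, y) == pytest.approx(chem.sc_score(y, x), abs=1e-2)

    def test_missing_conformer_raises(self, library):
        with pytest.raises(chem.ConformerError):
            chem.sc_score(library[0], library[1])

    def test_shape_component_matches_voxel_oracle(self):
        """Numerically integrate the product of the summed atom Gaussians on
        a voxel grid and compare with the analytic pairwise formula."""
        benzene = chem.embed_conformers(chem.canonicalize("c1ccccc1", "b"), n_conf=3)
        pyridine = chem.embed_conformers(chem.canonicalize("c1ccncc1", "p"), n_conf=3)
        mx = benzene.to_mol(with_h=True)
        my = pyridine.to_mol(with_h=True)
        chem._align(my, mx)
        analytic = chem.shape_tanimoto(mx, my)

        def density(mol, grid):
            pos, rad = chem._heavy_coords_radii(mol)
            alpha = np.pi * (3 * chem._GAUSS_P / (4 * np.pi * rad ** 3)) ** (2 / 3)
            d2 = ((grid[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
            return (chem._GAUSS_P * np.exp(-alpha[None, :] * d2)).sum(1)

        lo, hi, h = -6.0, 6.0, 0.25
        axis = np.arange(lo, hi, h)
        grid = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), -1).reshape(-1, 3)
        rx, ry = density(mx, grid), density(my, grid)
        vxy = (rx * ry).sum() * h ** 3
        vxx = (rx * rx).sum() * h ** 3
        vyy = (ry * ry).sum() * h ** 3
        voxel = vxy / (vxx + vyy - vxy)
        assert analytic == pytest.approx(voxel, abs=0.05)


def test_smi_roundtrip(tmp_path, library):
    path = tmp_path / "lib.smi"
    chem.write_smi(library, path)
    back = chem.read_smi(path)
    assert [(r.mol_id, r.smiles) for r in back] == \
        [(r.mol_id, r.smiles) for r in library]


def test_sdf_written_for_conformers(tmp_path, library3d):
    path = tmp_path / "confs.sdf"
    chem.write_sdf(library3d[:3], path)
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    assert sum(1 for m in supplier if m is not None) == 3
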