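"""Molecule standardization, scaffolds, fingerprints and 2D/3D similarity.

This module defines what a "scaffold hop" means structurally:

* 2D side — the Tanimoto similarity of Morgan fingerprints computed on the
  Bemis–Murcko scaffolds of the two molecules must be *low* (dissimilar
  frameworks).
* 3D side — the shape-and-color (SC) score of their lowest-energy conformers
  must be *high* (similar shape and pharmacophore after rigid overlay).

Scores above 0.6 indicate a fair structural match in 3D and values of the
2D scaffold similarity at or below 0.6 indicate a genuinely different
framework; these two thresholds define the hop criteria used downstream.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, replace

import numpy as np
from rdkit import Chem, RDConfig, RDLogger
from rdkit.Chem import AllChem, rdMolAlign
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")


class InvalidMoleculeError(ValueError):
    """Raised when a SMILES string cannot be parsed into a valid molecule."""


class ConformerError(RuntimeError):
    """Raised when 3D embedding fails or a conformer is required but absent."""


@dataclass(frozen=True)
class Conformer3D:
    """Coordinates (Å) for the hydrogen-added molecule, plus force-field energy."""
    coords: np.ndarray          # (n_atoms_with_H, 3)
    energy: float               # kcal/mol (MMFF94)

    def __post_init__(self):
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))


@dataclass(frozen=True)
class MoleculeRecord:
    """A molecule with a stable id, canonical SMILES and optional conformer.

    ``smiles`` always round-trips through canonicalization to itself.  The
    conformer coordinates are stored in the atom order of
    ``Chem.AddHs(Chem.MolFromSmiles(smiles))`` — heavy atoms first (in
    canonical-SMILES parse order), hydrogens appended.
    """
    mol_id: str
    smiles: str
    conformer: Conformer3D | None = None

    def to_mol(self, with_h: bool = False) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:  # pragma: no cover - smiles is canonical by contract
            raise InvalidMoleculeError(self.smiles)
        if with_h:
            mol = Chem.AddHs(mol)
        if self.conformer is not None:
            molh = Chem.AddHs(Chem.MolFromSmiles(self.smiles))
            n = molh.GetNumAtoms() if with_h else mol.GetNumAtoms()
            conf = Chem.Conformer(n)
            for i in range(n):
                x, y, z = self.conformer.coords[i]
                conf.SetAtomPosition(i, (float(x), float(y), float(z)))
            mol.AddConformer(conf, assignId=True)
        return mol


@dataclass(frozen=True)
class BitFingerprint:
    bits: frozenset[int]
    n_bits: int

    def __post_init__(self):
        object.__setattr__(self, "bits", frozenset(self.bits))
        if any(b < 0 or b >= self.n_bits for b in self.bits):
            raise ValueError("bit index outside [0, n_bits)")


@dataclass(frozen=True)
class SimilarityPair:
    """2D scaffold Tanimoto and 3D SC score for one molecule pair."""
    sim2d: float
    sim3d: float

    def __post_init__(self):
        if not (0.0 <= self.sim2d <= 1.0 and 0.0 <= self.sim3d <= 1.0):
            raise ValueError("similarities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def canonicalize(smiles: str, mol_id: str | None = None) -> MoleculeRecord:
    """Parse a SMILES string and return a record with the canonical form.

    Raises :class:`InvalidMoleculeError` for unparseable or valence-violating
    input; callers in the generation pipeline treat that as an invalid
    candidate rather than an error.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise InvalidMoleculeError(f"cannot parse SMILES: {smiles!r}")
    can = Chem.MolToSmiles(mol)
    return MoleculeRecord(mol_id=mol_id if mol_id is not None else can, smiles=can)


_ORGANIC_Z = {1, 5, 6, 7, 8, 9, 15, 16, 17, 35, 53}  # H B C N O F P S Cl Br I


def _is_organic(frag: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() == 6 for a in frag.GetAtoms())


def standardize(record: MoleculeRecord, strip_salts: bool = True) -> MoleculeRecord:
    """Normalize a molecule: desalt, clear isotopes, neutralize charges.

    With ``strip_salts=True`` multi-fragment inputs keep the largest organic
    fragment; with ``strip_salts=False`` (strict mode) any disconnected input
    is rejected.  Purely inorganic inputs are always rejected.
    """
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise InvalidMoleculeError(record.smiles)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        if not strip_salts:
            raise InvalidMoleculeError(
                f"disconnected fragments rejected in strict mode: {record.smiles}")
        organic = [f for f in frags if _is_organic(f)]
        if not organic:
            raise InvalidMoleculeError(f"no organic fragment in {record.smiles}")
        mol = max(organic, key=lambda f: f.GetNumHeavyAtoms())
    elif not _is_organic(mol):
        raise InvalidMoleculeError(f"inorganic molecule rejected: {record.smiles}")
    for atom in mol.GetAtoms():
        atom.SetIsotope(0)
    mol = _neutralize(mol)
    return MoleculeRecord(mol_id=record.mol_id, smiles=Chem.MolToSmiles(mol))


def _neutralize(mol: Chem.Mol) -> Chem.Mol:
    """Protonate anions / deprotonate cations where a neutral form exists.

    Standard uncharger pattern: atoms with a formal charge and no oppositely
    charged neighbor get their charge removed with the H count adjusted.
    """
    mol = Chem.RWMol(mol)
    pattern = Chem.MolFromSmarts("[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]")
    for (idx,) in mol.GetSubstructMatches(pattern):
        atom = mol.GetAtomWithIdx(idx)
        charge = atom.GetFormalCharge()
        h = atom.GetTotalNumHs()
        if charge > 0 and h >= charge:
            atom.SetNumExplicitHs(h - charge)
            atom.SetFormalCharge(0)
        elif charge < 0:
            atom.SetNumExplicitHs(h - charge)
            atom.SetFormalCharge(0)
        atom.UpdatePropertyCache()
    Chem.SanitizeMol(mol)
    return mol.GetMol()


# ---------------------------------------------------------------------------
# scaffolds & fingerprints
# ---------------------------------------------------------------------------

def bm_scaffold(record: MoleculeRecord) -> MoleculeRecord:
    """Bemis–Murcko scaffold: ring systems plus linkers, side chains pruned.

    Acyclic molecules yield the *empty* scaffold (empty SMILES string).
    """
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise InvalidMoleculeError(record.smiles)
    scaf = MurckoScaffold.GetScaffoldForMol(mol)
    smiles = Chem.MolToSmiles(scaf) if scaf is not None and scaf.GetNumAtoms() else ""
    return MoleculeRecord(mol_id=record.mol_id, smiles=smiles)


def morgan_fp(record: MoleculeRecord, radius: int = 2, n_bits: int = 2048) -> BitFingerprint:
    """Morgan (circular) fingerprint as a set of on-bit indices.

    The empty molecule (e.g. the scaffold of an acyclic compound) maps to the
    empty bit set.
    """
    if record.smiles == "":
        return BitFingerprint(bits=frozenset(), n_bits=n_bits)
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise InvalidMoleculeError(record.smiles)
    fp = AllChem.GetMorganFingerprintAsBitVect(mol, radius, nBits=n_bits)
    return BitFingerprint(bits=frozenset(fp.GetOnBits()), n_bits=n_bits)


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """|a ∩ b| / |a ∪ b|; 0.0 by convention when both sets are empty."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


def scaffold_similarity_2d(x: MoleculeRecord, y: MoleculeRecord,
                           radius: int = 2, n_bits: int = 2048) -> float:
    """Tanimoto over Morgan fingerprints of the Bemis–Murcko scaffolds.

    Two acyclic molecules (both scaffolds empty) score 0.0; such molecules
    are excluded from hop mining upstream since they have no framework to hop.
    """
    fx = morgan_fp(bm_scaffold(x), radius, n_bits)
    fy = morgan_fp(bm_scaffold(y), radius, n_bits)
    return tanimoto(fx, fy)


# ---------------------------------------------------------------------------
# conformers
# ---------------------------------------------------------------------------

def conformer_seed(mol_id: str) -> int:
    """Deterministic per-molecule embedding seed derived from the id."""
    return zlib.crc32(mol_id.encode()) & 0x7FFFFFFF


def embed_conformers(record: MoleculeRecord, n_conf: int = 100,
                     seed: int | None = None) -> MoleculeRecord:
    """Embed ``n_conf`` MMFF94-minimized conformers and keep the lowest-energy one.

    Embedding uses ETKDG with a fixed seed (derived from the molecule id when
    not given), so repeated calls produce identical coordinates.  Raises
    :class:`ConformerError` when no conformer can be embedded; callers drop
    the molecule from 3D scoring.
    """
    if seed is None:
        seed = conformer_seed(record.mol_id)
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise InvalidMoleculeError(record.smiles)
    if mol.GetNumHeavyAtoms() == 0:
        raise ConformerError(f"no heavy atoms: {record.smiles}")
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    params.numThreads = 1
    conf_ids = AllChem.EmbedMultipleConfs(molh, numConfs=n_conf, params=params)
    if len(conf_ids) == 0:
        raise ConformerError(f"embedding failed for {record.smiles}")
    energies = _minimize_all(molh)
    best = int(np.argmin(energies))
    coords = molh.GetConformer(conf_ids[best]).GetPositions()
    return replace(record, conformer=Conformer3D(coords=coords, energy=float(energies[best])))


def _minimize_all(molh: Chem.Mol) -> np.ndarray:
    """MMFF94-minimize every conformer; UFF fallback for atoms MMFF lacks."""
    if AllChem.MMFFHasAllMoleculeParams(molh):
        res = AllChem.MMFFOptimizeMoleculeConfs(molh, maxIters=500)
    else:
        res = AllChem.UFFOptimizeMoleculeConfs(molh, maxIters=500)
    energies = np.array([e for _, e in res], dtype=float)
    # unconverged minimizations still return an energy; that is acceptable for
    # picking the best of a sample
    return energies


# ---------------------------------------------------------------------------
# 3D shape + color (SC) score
# ---------------------------------------------------------------------------

# Grant–Pickup Gaussian-volume constants: each atom is a Gaussian
# p * exp(-alpha r^2) chosen so its integral matches a hard sphere of the
# atom's vdW radius.
_GAUSS_P = 2.7
_FEATURE_RADIUS = 1.5  # Å, pharmacophore feature Gaussians

_FEATURE_FAMILIES = ("Donor", "Acceptor", "Aromatic", "Hydrophobe",
                     "PosIonizable", "NegIonizable")

_FEAT_FACTORY = AllChem.BuildFeatureFactory(
    os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef"))


def _gaussian_overlap_volume(pos_a: np.ndarray, rad_a: np.ndarray,
                             pos_b: np.ndarray, rad_b: np.ndarray) -> float:
    """First-order Gaussian overlap volume between two atom (or feature) sets."""
    if len(pos_a) == 0 or len(pos_b) == 0:
        return 0.0
    alpha_a = np.pi * (3.0 * _GAUSS_P / (4.0 * np.pi * rad_a ** 3)) ** (2.0 / 3.0)
    alpha_b = np.pi * (3.0 * _GAUSS_P / (4.0 * np.pi * rad_b ** 3)) ** (2.0 / 3.0)
    d2 = ((pos_a[:, None, :] - pos_b[None, :, :]) ** 2).sum(axis=-1)
    asum = alpha_a[:, None] + alpha_b[None, :]
    kij = np.exp(-(alpha_a[:, None] * alpha_b[None, :] / asum) * d2)
    vij = _GAUSS_P * _GAUSS_P * kij * (np.pi / asum) ** 1.5
    return float(vij.sum())


def _heavy_coords_radii(mol: Chem.Mol) -> tuple[np.ndarray, np.ndarray]:
    pt = Chem.GetPeriodicTable()
    conf = mol.GetConformer()
    idx = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    pos = np.array([list(conf.GetAtomPosition(i)) for i in idx], dtype=float)
    rad = np.array([pt.GetRvdw(mol.GetAtomWithIdx(i).GetAtomicNum()) for i in idx])
    return pos, rad


def shape_tanimoto(mol_x: Chem.Mol, mol_y: Chem.Mol) -> float:
    """Gaussian-volume shape Tanimoto V_xy / (V_xx + V_yy − V_xy), heavy atoms."""
    px, rx = _heavy_coords_radii(mol_x)
    py, ry = _heavy_coords_radii(mol_y)
    vxx = _gaussian_overlap_volume(px, rx, px, rx)
    vyy = _gaussian_overlap_volume(py, ry, py, ry)
    vxy = _gaussian_overlap_volume(px, rx, py, ry)
    denom = vxx + vyy - vxy
    return float(np.clip(vxy / denom, 0.0, 1.0)) if denom > 0 else 0.0


def _feature_points(mol: Chem.Mol) -> dict[str, np.ndarray]:
    feats: dict[str, list] = {}
    for f in _FEAT_FACTORY.GetFeaturesForMol(mol):
        fam = f.GetFamily()
        if fam in _FEATURE_FAMILIES:
            feats.setdefault(fam, []).append(list(f.GetPos()))
    return {fam: np.array(v, dtype=float) for fam, v in feats.items()}


def color_tanimoto(mol_x: Chem.Mol, mol_y: Chem.Mol) -> float:
    """Pharmacophore-feature ("color") Gaussian Tanimoto.

    Feature points of the same family (donor, acceptor, aromatic, hydrophobe,
    ±ionizable) overlap as identical Gaussians; cross-family overlap is zero.
    If neither molecule has any feature there is nothing to mismatch and the
    score is 1.0; if exactly one has features the score is 0.0.
    """
    fx = _feature_points(mol_x)
    fy = _feature_points(mol_y)
    if not fx and not fy:
        return 1.0
    if not fx or not fy:
        return 0.0
    vxy = vxx = vyy = 0.0
    for fam in set(fx) | set(fy):
        px = fx.get(fam)
        py = fy.get(fam)
        if px is not None:
            vxx += _gaussian_overlap_volume(px, np.full(len(px), _FEATURE_RADIUS),
                                            px, np.full(len(px), _FEATURE_RADIUS))
        if py is not None:
            vyy += _gaussian_overlap_volume(py, np.full(len(py), _FEATURE_RADIUS),
                                            py, np.full(len(py), _FEATURE_RADIUS))
        if px is not None and py is not None:
            vxy += _gaussian_overlap_volume(px, np.full(len(px), _FEATURE_RADIUS),
                                            py, np.full(len(py), _FEATURE_RADIUS))
    denom = vxx + vyy - vxy
    return float(np.clip(vxy / denom, 0.0, 1.0)) if denom > 0 else 0.0


def _align(probe: Chem.Mol, ref: Chem.Mol) -> None:
    """Rigidly align `probe` onto `ref` in place (O3A; Crippen fallback)."""
    try:
        o3a = rdMolAlign.GetO3A(probe, ref)
        o3a.Align()
    except Exception:
        o3a = rdMolAlign.GetCrippenO3A(probe, ref)
        o3a.Align()


def sc_score(x: MoleculeRecord, y: MoleculeRecord) -> float:
    """Shape-and-color 3D similarity in [0, 1].

    ``y``'s conformer is rigidly aligned onto ``x``'s, then the score is the
    mean of the Gaussian shape Tanimoto and the pharmacophore color Tanimoto.
    Values above 0.6 indicate a fair 3D match, above 0.8 an excellent one.
    Symmetric up to the tolerance of the alignment optimizer.
    """
    if x.conformer is None or y.conformer is None:
        raise ConformerError("sc_score requires conformers on both records")
    mx = x.to_mol(with_h=True)
    my = y.to_mol(with_h=True)
    _align(my, mx)
    return 0.5 * shape_tanimoto(mx, my) + 0.5 * color_tanimoto(mx, my)


# ---------------------------------------------------------------------------
# simple I/O
# ---------------------------------------------------------------------------

def read_smi(path) -> list[MoleculeRecord]:
    """Read a .smi file, one "SMILES<TAB>id" record per line."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else smiles
            out.append(canonicalize(smiles, mol_id=mol_id))
    return out


def write_smi(records, path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.smiles}\t{r.mol_id}\n")


def write_sdf(records, path) -> None:
    """Write records carrying conformers to an SDF file."""
    writer = Chem.SDWriter(str(path))
    try:
        for r in records:
            if r.conformer is None:
                continue
            mol = r.to_mol(with_h=True)
            mol.SetProp("_Name", r.mol_id)
            mol.SetProp("energy_kcal_mol", f"{r.conformer.energy:.4f}")
            writer.write(mol)
    finally:
        writer.close()
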