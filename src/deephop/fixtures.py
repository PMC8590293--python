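"""Deterministic synthetic data: molecules, bioactivities, protein sequences.

The generator emulates the shape of a multi-target kinase bioactivity table
at desk scale: a combinatorial library of ring cores decorated with common
substituents (so Bemis–Murcko scaffolds are non-trivial and diverse),
per-target activities that are *linear in Morgan fingerprint bits* (so QSAR
recovery has a known ground truth), and planted cross-scaffold pairs with an
activity gain ≥ 1 pChEMBL unit that the pair miner should rediscover.
Protein targets get random amino-acid sequences.

Everything is a pure function of the :class:`FixtureSpec` (including its
seed): the same spec yields byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .chem import (ConformerError, MoleculeRecord, bm_scaffold, canonicalize,
                   embed_conformers, morgan_fp, scaffold_similarity_2d,
                   standardize)
from .pairs import BioactivityRecord
from .protein import AMINO_ACIDS, ProteinSequence

logger = logging.getLogger(__name__)

# ring cores with one or two substitution sites; {a}/{b} are replaced by
# substituent SMILES fragments (or removed for the unsubstituted molecule)
_CORES_MONO = [
    "c1ccc({a})cc1",            # benzene
    "c1ccnc({a})c1",            # pyridine
    "c1cncnc1{a}",              # pyrimidine
    "c1cc({a})[nH]n1",          # pyrazole
    "c1csc({a})c1",             # thiophene
    "C1CCC({a})CC1",            # cyclohexane
    "c1ccc2ccc({a})cc2c1",      # naphthalene
    "c1ccc(-c2ccc({a})cc2)cc1", # biphenyl
    "C1CCN({a})CC1",            # piperidine (N-substituted)
]
_CORES_DI = [
    "c1cc({a})ccc1{b}",
    "c1cc({a})cnc1{b}",
    "c1cc({a})sc1{b}",
    "C1CC({a})CCC1{b}",
]
_SUBSTITUENTS = ["C", "CC", "CCC", "C(C)C", "O", "OC", "N", "NC", "Cl", "F",
                 "Br", "C#N", "C(F)(F)F", "C(=O)O", "C(=O)OC", "CO", "CCO"]


@dataclass(frozen=True)
class FixtureSpec:
    n_molecules: int = 60
    n_targets: int = 3
    seed: int = 0
    n_signal_bits: int = 20     # fingerprint bits carrying the activity signal
    noise_sd: float = 0.1       # pChEMBL units
    planted_hops: int = 3       # cross-scaffold Δ≥1 pairs planted per target
    n_conf: int = 5             # conformer sample size per molecule


def _enumerate_candidates() -> list[str]:
    smiles: list[str] = []
    for core in _CORES_MONO:
        smiles.append(core.replace("({a})", "").replace("{a}", ""))
        for s in _SUBSTITUENTS:
            smiles.append(core.replace("{a}", s))
    for core in _CORES_DI:
        for sa in _SUBSTITUENTS:
            for sb in _SUBSTITUENTS:
                smiles.append(core.replace("{a}", sa).replace("{b}", sb))
    return smiles


def make_library(spec: FixtureSpec) -> list[MoleculeRecord]:
    """Enumerate a small drug-like library with ≥ 2 distinct BM scaffolds."""
    rng = np.random.default_rng(spec.seed)
    seen: set[str] = set()
    records: list[MoleculeRecord] = []
    for smi in _enumerate_candidates():
        try:
            rec = standardize(canonicalize(smi))
        except Exception:
            continue
        if rec.smiles in seen:
            continue
        seen.add(rec.smiles)
        records.append(rec)
    order = rng.permutation(len(records))
    chosen = [records[i] for i in order[:spec.n_molecules]]
    chosen = [MoleculeRecord(mol_id=f"M{i:04d}", smiles=r.smiles)
              for i, r in enumerate(chosen)]
    scaffolds = {bm_scaffold(r).smiles for r in chosen}
    if len(scaffolds) < 2:  # pragma: no cover - template set guarantees this
        raise RuntimeError("fixture library must span at least two scaffolds")
    return chosen


def attach_conformers(library: list[MoleculeRecord],
                      n_conf: int = 5) -> list[MoleculeRecord]:
    """Embed conformers for the whole library, dropping failures."""
    out = []
    for rec in library:
        try:
            out.append(embed_conformers(rec, n_conf=n_conf))
        except ConformerError as exc:
            logger.warning("dropping %s: %s", rec.mol_id, exc)
    return out


def make_bioactivity(spec: FixtureSpec, library: list[MoleculeRecord],
                     return_planted: bool = False):
    """Per-target activities linear in fingerprint bits, scaled into [4, 10].

    For each target Z: pChEMBL(m, Z) = affine(w_Z · fp(m)) + ε, ε ~ N(0, sd),
    where the affine map standardizes the raw scores to mean 7 and spread 1.5
    (a typical pChEMBL dynamic range for a kinase assay panel) before
    clipping to [4, 10].  Then ``planted_hops`` disjoint cross-scaffold pairs
    (scaffold Tanimoto ≤ 0.6) get activities overwritten to (5.0, 6.5) so a
    Δ = 1.5 hop exists regardless of noise.
    """
    rng = np.random.default_rng(spec.seed + 1)
    fps = [sorted(morgan_fp(r).bits) for r in library]
    all_bits = sorted({b for fp in fps for b in fp})
    X = np.zeros((len(library), len(all_bits)))
    col = {b: i for i, b in enumerate(all_bits)}
    for i, fp in enumerate(fps):
        for b in fp:
            X[i, col[b]] = 1.0
    scaffolds = [bm_scaffold(r).smiles for r in library]
    records: list[BioactivityRecord] = []
    planted: dict[str, list[tuple[str, str]]] = {}
    for t in range(spec.n_targets):
        target = f"KIN{t + 1}"
        sig = rng.choice(len(all_bits), size=min(spec.n_signal_bits, len(all_bits)),
                         replace=False)
        w = np.zeros(len(all_bits))
        w[sig] = rng.normal(0.0, 1.0, size=len(sig))
        raw = X @ w
        activity = 7.0 + 1.5 * (raw - raw.mean()) / (raw.std() + 1e-12)
        activity = activity + rng.normal(0.0, spec.noise_sd, size=len(library))
        activity = np.clip(activity, 4.0, 10.0)
        planted[target] = _plant_hops(spec, library, scaffolds, activity, rng)
        for rec, a in zip(library, activity):
            records.append(BioactivityRecord(rec.mol_id, target, float(a)))
    if return_planted:
        return records, planted
    return records


def _plant_hops(spec: FixtureSpec, library, scaffolds, activity,
                rng: np.random.Generator) -> list[tuple[str, str]]:
    """Overwrite activities for disjoint cross-scaffold (source, product) pairs."""
    planted: list[tuple[str, str]] = []
    used: set[int] = set()
    order = rng.permutation(len(library))
    for i in order:
        if len(planted) >= spec.planted_hops:
            break
        if i in used:
            continue
        for j in order:
            if j == i or j in used or scaffolds[i] == scaffolds[j]:
                continue
            if scaffold_similarity_2d(library[i], library[j]) <= 0.6:
                activity[i] = 5.0
                activity[j] = 6.5
                used.update((int(i), int(j)))
                planted.append((library[i].mol_id, library[j].mol_id))
                break
    return planted


def make_proteins(spec: FixtureSpec) -> list[ProteinSequence]:
    """One random 200–400 residue sequence per target, seeded."""
    rng = np.random.default_rng(spec.seed + 2)
    alphabet = sorted(AMINO_ACIDS)
    seqs = []
    for t in range(spec.n_targets):
        length = int(rng.integers(200, 401))
        residues = "".join(rng.choice(alphabet, size=length))
        seqs.append(ProteinSequence(seq_id=f"KIN{t + 1}", residues=residues))
    return seqs
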