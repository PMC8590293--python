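"""Mining scaffold-hopping training pairs from bioactivity tables.

A hop pair ((X, Y) | Z) for protein target Z is a directed pair of molecules
satisfying all three criteria:

* activity improvement: pChEMBL(Y, Z) − pChEMBL(X, Z) ≥ 1 (a tenfold gain),
* 2D dissimilarity: scaffold Tanimoto(X, Y) ≤ 0.6,
* 3D similarity: SC score(X, Y) ≥ 0.6.

To avoid redundant pairs, at most ``max_hops_per_source`` hops are kept per
source molecule (the largest activity gains win).  Test molecules are held
out *before* mining so no test structure ever appears in a training pair.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import (ConformerError, MoleculeRecord, SimilarityPair,
                   canonicalize, scaffold_similarity_2d, sc_score, standardize)

logger = logging.getLogger(__name__)

# molar multipliers for common activity units
_UNIT_FACTORS = {
    "M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12,
}


@dataclass(frozen=True)
class BioactivityRecord:
    """One (molecule, target) activity measurement on the pChEMBL scale."""
    mol_id: str
    target_id: str
    pchembl: float

    def __post_init__(self):
        if not math.isfinite(self.pchembl):
            raise ValueError("pChEMBL value must be finite")


@dataclass(frozen=True)
class HopThresholds:
    """The three hop-pair predicates, in one place."""
    min_delta: float = 1.0
    max_sim2d: float = 0.6
    min_sim3d: float = 0.6


@dataclass(frozen=True)
class HopPair:
    source: MoleculeRecord       # X, lower activity
    product: MoleculeRecord      # Y, higher activity
    target_id: str               # Z
    delta_activity: float        # pChEMBL(Y,Z) − pChEMBL(X,Z)
    sim: SimilarityPair


@dataclass
class DatasetSplit:
    train_pairs: list[HopPair]
    val_pairs: list[HopPair]
    test_molecules: dict[str, list[MoleculeRecord]] = field(default_factory=dict)


def to_pchembl(value: float, unit: str) -> float:
    """Convert a molar activity (IC50/Ki/Kd) to pChEMBL = −log10(mol/L)."""
    if value <= 0:
        raise ValueError(f"activity must be positive, got {value}")
    try:
        factor = _UNIT_FACTORS[unit]
    except KeyError:
        raise ValueError(f"unknown activity unit {unit!r}") from None
    return -math.log10(value * factor)


def aggregate_records(records: list[BioactivityRecord]) -> list[BioactivityRecord]:
    """Deduplicate (mol, target) measurements by median pChEMBL."""
    by_key: dict[tuple[str, str], list[float]] = {}
    for r in records:
        by_key.setdefault((r.mol_id, r.target_id), []).append(r.pchembl)
    return [BioactivityRecord(m, t, float(np.median(v)))
            for (m, t), v in sorted(by_key.items())]


def filter_targets(records: list[BioactivityRecord], min_n: int = 300,
                   max_n: int = 5000) -> list[str]:
    """Targets whose unique-molecule count lies in [min_n, max_n], inclusive."""
    counts: dict[str, set[str]] = {}
    for r in records:
        counts.setdefault(r.target_id, set()).add(r.mol_id)
    return sorted(t for t, mols in counts.items() if min_n <= len(mols) <= max_n)


class SimilarityCache:
    """Caches 2D and 3D similarities per unordered molecule pair.

    The SC score is symmetric up to alignment tolerance, so one value per
    unordered pair is computed, with the lexically smaller canonical SMILES
    used as the alignment reference for determinism.
    """

    def __init__(self):
        self._s2: dict[frozenset, float] = {}
        self._s3: dict[frozenset, float] = {}

    def sim2d(self, x: MoleculeRecord, y: MoleculeRecord) -> float:
        key = frozenset((x.smiles, y.smiles))
        if key not in self._s2:
            self._s2[key] = scaffold_similarity_2d(x, y)
        return self._s2[key]

    def sim3d(self, x: MoleculeRecord, y: MoleculeRecord) -> float:
        key = frozenset((x.smiles, y.smiles))
        if key not in self._s3:
            a, b = sorted((x, y), key=lambda m: m.smiles)
            self._s3[key] = sc_score(a, b)
        return self._s3[key]


def mine_pairs(records: list[BioactivityRecord],
               mols: dict[str, MoleculeRecord],
               target_id: str,
               thresholds: HopThresholds = HopThresholds(),
               similarity: SimilarityCache | None = None) -> list[HopPair]:
    """Enumerate all directed hop pairs for one target.

    The expensive 3D score is only computed for pairs that already pass the
    activity and 2D-dissimilarity predicates.  Molecules without a conformer
    are skipped with a warning (they cannot be scored in 3D).
    """
    similarity = similarity or SimilarityCache()
    activity = {r.mol_id: r.pchembl for r in records if r.target_id == target_id}
    usable = []
    for mol_id in sorted(activity):
        mol = mols.get(mol_id)
        if mol is None:
            continue
        if mol.conformer is None:
            logger.warning("skipping %s for target %s: no conformer", mol_id, target_id)
            continue
        usable.append(mol)
    pairs: list[HopPair] = []
    for x in usable:
        for y in usable:
            if x.mol_id == y.mol_id:
                continue
            delta = activity[y.mol_id] - activity[x.mol_id]
            if delta < thresholds.min_delta:
                continue
            s2 = similarity.sim2d(x, y)
            if s2 > thresholds.max_sim2d:
                continue
            try:
                s3 = similarity.sim3d(x, y)
            except ConformerError:
                continue
            if s3 < thresholds.min_sim3d:
                continue
            pairs.append(HopPair(source=x, product=y, target_id=target_id,
                                 delta_activity=delta,
                                 sim=SimilarityPair(sim2d=s2, sim3d=s3)))
    return pairs


def cap_hops(pairs: list[HopPair], max_per_source: int = 10) -> list[HopPair]:
    """Keep at most ``max_per_source`` hops per (source, target).

    Kept pairs are the largest activity deltas; exact ties are broken by the
    product's canonical SMILES in lexical order so the result is deterministic.
    """
    by_source: dict[tuple[str, str], list[HopPair]] = {}
    for p in pairs:
        by_source.setdefault((p.source.mol_id, p.target_id), []).append(p)
    kept: list[HopPair] = []
    for key in sorted(by_source):
        group = sorted(by_source[key],
                       key=lambda p: (-p.delta_activity, p.product.smiles))
        kept.extend(group[:max_per_source])
    return kept


def select_test_molecules(records: list[BioactivityRecord], target_id: str,
                          test_frac: float, rng: np.random.Generator) -> set[str]:
    mol_ids = sorted({r.mol_id for r in records if r.target_id == target_id})
    n_test = int(round(test_frac * len(mol_ids)))
    if len(mol_ids) < 10:
        logger.warning("target %s has %d molecules; test set may be empty",
                       target_id, len(mol_ids))
    chosen = rng.choice(len(mol_ids), size=n_test, replace=False) if n_test else []
    return {mol_ids[i] for i in chosen}


def split_dataset(records: list[BioactivityRecord],
                  mols: dict[str, MoleculeRecord],
                  test_frac: float = 0.1, val_frac: float = 0.1,
                  seed: int = 0,
                  thresholds: HopThresholds = HopThresholds(),
                  max_hops_per_source: int = 10,
                  similarity: SimilarityCache | None = None) -> DatasetSplit:
    """Full per-target pipeline: hold out test molecules, mine, cap, split.

    Per target: a random ``test_frac`` of molecules becomes the test set;
    pairs are mined only among the remaining molecules (so no leakage is
    possible by construction), capped per source, then split into train and
    validation pair sets at ratio (1−val_frac):val_frac.  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(seed)
    similarity = similarity or SimilarityCache()
    targets = sorted({r.target_id for r in records})
    split = DatasetSplit(train_pairs=[], val_pairs=[], test_molecules={})
    for target in targets:
        test_ids = select_test_molecules(records, target, test_frac, rng)
        split.test_molecules[target] = [mols[m] for m in sorted(test_ids) if m in mols]
        train_records = [r for r in records
                         if r.target_id == target and r.mol_id not in test_ids]
        pairs = cap_hops(mine_pairs(train_records, mols, target, thresholds,
                                    similarity), max_hops_per_source)
        # shuffle deterministically, then carve off the validation fraction
        order = rng.permutation(len(pairs))
        n_val = int(round(val_frac * len(pairs)))
        val_idx = set(order[:n_val].tolist())
        for i, p in enumerate(pairs):
            (split.val_pairs if i in val_idx else split.train_pairs).append(p)
    return split


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def load_bioactivity_table(path, strip_salts: bool = True
                           ) -> tuple[list[BioactivityRecord], dict[str, MoleculeRecord]]:
    """Load a bioactivity CSV into records plus standardized molecules.

    Expected columns: ``mol_id, smiles, target_id`` and either ``pchembl`` or
    ``activity_value, activity_unit``.  Molecules that fail standardization
    are dropped with a warning; duplicate measurements are aggregated by
    median.
    """
    df = pd.read_csv(path)
    needed = {"mol_id", "smiles", "target_id"}
    if not needed.issubset(df.columns):
        raise ValueError(f"table must have columns {sorted(needed)}")
    mols: dict[str, MoleculeRecord] = {}
    records: list[BioactivityRecord] = []
    for row in df.itertuples(index=False):
        mol_id = str(row.mol_id)
        if mol_id not in mols:
            try:
                mols[mol_id] = standardize(canonicalize(row.smiles, mol_id=mol_id),
                                           strip_salts=strip_salts)
            except Exception as exc:
                logger.warning("dropping %s: %s", mol_id, exc)
                mols[mol_id] = None  # sentinel: known bad
        if mols[mol_id] is None:
            continue
        if hasattr(row, "pchembl") and not pd.isna(row.pchembl):
            p = float(row.pchembl)
        else:
            p = to_pchembl(float(row.activity_value), str(row.activity_unit))
        records.append(BioactivityRecord(mol_id, str(row.target_id), p))
    mols = {k: v for k, v in mols.items() if v is not None}
    return aggregate_records(records), mols


def write_pairs_tsv(pairs: list[HopPair], path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.source.smiles}\t{p.product.smiles}\t{p.target_id}\t"
                     f"{p.delta_activity:.4f}\n")


def write_split_manifest(split: DatasetSplit, path) -> None:
    manifest = {
        "n_train": len(split.train_pairs),
        "n_val": len(split.val_pairs),
        "test_molecules": {t: [m.mol_id for m in ms]
                           for t, ms in split.test_molecules.items()},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
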