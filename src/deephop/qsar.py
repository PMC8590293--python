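"""Multi-task QSAR profiler: fingerprint MLP with one head per target.

A shared trunk maps the Morgan fingerprint to a hidden representation; each
protein target gets its own linear regression head on the pChEMBL scale.
Training minimizes mean squared error over *observed* (molecule, target)
labels only — missing labels are masked out, which is what makes multi-task
training on a sparse bioactivity matrix possible.

The cross-validation report (per-target R² / RMSE over molecule-disjoint
folds) is used to gate which targets are reliable enough for virtual
profiling: only targets with CV R² strictly above the cutoff are kept.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import r2_score

from .chem import MoleculeRecord, morgan_fp
from .nn import Adam, Dropout, Linear, Module, Tensor
from .pairs import BioactivityRecord

logger = logging.getLogger(__name__)


@dataclass
class QsarConfig:
    radius: int = 2
    n_bits: int = 2048
    hidden: tuple[int, ...] = (1024, 512)
    dropout: float = 0.2
    lr: float = 1e-3
    epochs: int = 150
    batch_size: int = 0          # 0 = full batch


@dataclass
class CvReport:
    r2: dict[str, float]
    rmse: dict[str, float]
    n_folds: int

    def mean_r2(self) -> float:
        return float(np.mean(list(self.r2.values())))

    def mean_rmse(self) -> float:
        return float(np.mean(list(self.rmse.values())))


class _MtdnnNet(Module):
    def __init__(self, n_bits: int, hidden: tuple[int, ...], n_targets: int,
                 dropout: float, rng: np.random.Generator):
        super().__init__()
        dims = [n_bits, *hidden]
        self.layers = [Linear(dims[i], dims[i + 1], rng) for i in range(len(hidden))]
        self.drops = [Dropout(dropout, rng) for _ in hidden]
        self.head = Linear(dims[-1], n_targets, rng)

    def __call__(self, x: Tensor) -> Tensor:
        for lin, drop in zip(self.layers, self.drops):
            x = drop(lin(x).relu())
        return self.head(x)


@dataclass
class QsarModel:
    net: _MtdnnNet
    target_ids: list[str]
    config: QsarConfig
    _fp_cache: dict[str, np.ndarray] = field(default_factory=dict)

    def _fingerprint(self, mol: MoleculeRecord) -> np.ndarray:
        if mol.smiles not in self._fp_cache:
            fp = morgan_fp(mol, self.config.radius, self.config.n_bits)
            x = np.zeros(self.config.n_bits, dtype=np.float32)
            x[list(fp.bits)] = 1.0
            self._fp_cache[mol.smiles] = x
        return self._fp_cache[mol.smiles]

    def predict(self, mol: MoleculeRecord, target_id: str) -> float:
        """Predicted pChEMBL of `mol` against `target_id`."""
        if target_id not in self.target_ids:
            raise KeyError(f"unknown target {target_id!r}")
        self.net.eval()
        x = Tensor(self._fingerprint(mol)[None, :])
        out = self.net(x).data[0, self.target_ids.index(target_id)]
        return float(out)

    def predict_matrix(self, mols: list[MoleculeRecord]) -> np.ndarray:
        """(n_mols, n_targets) prediction matrix in one forward pass."""
        self.net.eval()
        X = np.stack([self._fingerprint(m) for m in mols])
        return self.net(Tensor(X)).data

    def save(self, path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.net.state_dict())
        sidecar = {"target_ids": self.target_ids,
                   "config": {"radius": self.config.radius,
                              "n_bits": self.config.n_bits,
                              "hidden": list(self.config.hidden),
                              "dropout": self.config.dropout,
                              "lr": self.config.lr,
                              "epochs": self.config.epochs,
                              "batch_size": self.config.batch_size}}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "QsarModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg = QsarConfig(**{**sidecar["config"],
                            "hidden": tuple(sidecar["config"]["hidden"])})
        net = _MtdnnNet(cfg.n_bits, cfg.hidden, len(sidecar["target_ids"]),
                        cfg.dropout, np.random.default_rng(0))
        with np.load(path.with_suffix(".npz")) as data:
            net.load_state_dict({k: data[k] for k in data.files})
        return cls(net=net, target_ids=sidecar["target_ids"], config=cfg)


def _design(records: list[BioactivityRecord], mols: dict[str, MoleculeRecord],
            target_ids: list[str], config: QsarConfig
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Fingerprint matrix X plus label/mask matrices Y, M (n_mols × n_targets)."""
    tcol = {t: i for i, t in enumerate(target_ids)}
    mol_ids = sorted({r.mol_id for r in records if r.mol_id in mols})
    mrow = {m: i for i, m in enumerate(mol_ids)}
    X = np.zeros((len(mol_ids), config.n_bits), dtype=np.float32)
    for m, i in mrow.items():
        fp = morgan_fp(mols[m], config.radius, config.n_bits)
        X[i, list(fp.bits)] = 1.0
    Y = np.zeros((len(mol_ids), len(target_ids)), dtype=np.float32)
    M = np.zeros_like(Y)
    for r in records:
        if r.mol_id in mrow and r.target_id in tcol:
            Y[mrow[r.mol_id], tcol[r.target_id]] = r.pchembl
            M[mrow[r.mol_id], tcol[r.target_id]] = 1.0
    return X, Y, M, mol_ids


def masked_mse(pred: Tensor, y: np.ndarray, mask: np.ndarray) -> Tensor:
    """MSE over observed labels only; equals plain MSE when fully observed."""
    m = Tensor(mask)
    diff = (pred - Tensor(y)) * m
    return (diff * diff).sum() * (1.0 / max(float(mask.sum()), 1.0))


def train_mtdnn(records: list[BioactivityRecord],
                mols: dict[str, MoleculeRecord],
                config: QsarConfig | None = None,
                seed: int = 0,
                loss_history: list[float] | None = None) -> QsarModel:
    """Fit the multi-task network on all observed labels."""
    config = config or QsarConfig()
    target_ids = sorted({r.target_id for r in records})
    for t in target_ids:
        if not any(r.target_id == t for r in records):  # pragma: no cover
            raise ValueError(f"empty target {t}")
    if not target_ids:
        raise ValueError("no bioactivity records")
    X, Y, M, _ = _design(records, mols, target_ids, config)
    rng = np.random.default_rng(seed)
    net = _MtdnnNet(config.n_bits, config.hidden, len(target_ids),
                    config.dropout, rng)
    opt = Adam(net.parameters(), lr=config.lr)
    n = X.shape[0]
    bs = config.batch_size or n
    net.train()
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            opt.zero_grad()
            loss = masked_mse(net(Tensor(X[idx])), Y[idx], M[idx])
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        if loss_history is not None:
            loss_history.append(epoch_loss / n)
    return QsarModel(net=net, target_ids=target_ids, config=config)


def predict(model: QsarModel, mol: MoleculeRecord, target_id: str) -> float:
    return model.predict(mol, target_id)


def cross_validate(records: list[BioactivityRecord],
                   mols: dict[str, MoleculeRecord],
                   k_folds: int = 5, seed: int = 0,
                   config: QsarConfig | None = None) -> CvReport:
    """k-fold CV with folds split by molecule (never by measurement).

    Targets with fewer molecules than folds are excluded with a warning.
    """
    if k_folds < 2:
        raise ValueError("need at least 2 folds")
    config = config or QsarConfig()
    counts: dict[str, set] = {}
    for r in records:
        counts.setdefault(r.target_id, set()).add(r.mol_id)
    kept_targets = []
    for t, ms in sorted(counts.items()):
        if len(ms) < k_folds:
            logger.warning("target %s has %d molecules < %d folds; excluded",
                           t, len(ms), k_folds)
        else:
            kept_targets.append(t)
    records = [r for r in records if r.target_id in kept_targets]
    mol_ids = sorted({r.mol_id for r in records if r.mol_id in mols})
    rng = np.random.default_rng(seed)
    fold_of = {m: f for m, f in zip(mol_ids,
               rng.permutation(len(mol_ids)) % k_folds)}
    truth: dict[str, list[float]] = {t: [] for t in kept_targets}
    preds: dict[str, list[float]] = {t: [] for t in kept_targets}
    for fold in range(k_folds):
        train_recs = [r for r in records if fold_of.get(r.mol_id) != fold]
        test_recs = [r for r in records if fold_of.get(r.mol_id) == fold]
        model = train_mtdnn(train_recs, mols, config, seed=seed + fold)
        test_mols = sorted({r.mol_id for r in test_recs})
        pmat = model.predict_matrix([mols[m] for m in test_mols])
        row = {m: i for i, m in enumerate(test_mols)}
        tcol = {t: i for i, t in enumerate(model.target_ids)}
        for r in test_recs:
            truth[r.target_id].append(r.pchembl)
            preds[r.target_id].append(float(pmat[row[r.mol_id], tcol[r.target_id]]))
    r2 = {t: float(r2_score(truth[t], preds[t])) for t in kept_targets}
    rmse = {t: float(np.sqrt(np.mean((np.array(truth[t]) - np.array(preds[t])) ** 2)))
            for t in kept_targets}
    return CvReport(r2=r2, rmse=rmse, n_folds=k_folds)


def gate_targets(report: CvReport, r2_min: float = 0.70) -> list[str]:
    """Targets whose CV R² is strictly above the cutoff."""
    return sorted(t for t, v in report.r2.items() if v > r2_min)
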