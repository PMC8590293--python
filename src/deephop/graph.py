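"""3D spatial graph encoder: geometry-gated message passing plus GRU readout.

Per layer l, each atom i updates as

    h_i^(l+1) = Σ_{j ∈ N_i} ReLU( (Uᵀ (p_j − p_i) + b) ⊙ h_j^(l) )

where p are conformer coordinates (Å), U ∈ R^{3×d} and b ∈ R^d are trainable,
and ⊙ is elementwise multiplication.  The operator depends only on
displacement vectors, so it is exactly translation invariant — but it is
*not* rotation invariant: a rotated conformer produces different embeddings,
which is intended (the gate learns directional geometry).

After the last layer a GRU runs over atoms in canonical-SMILES order to
produce the final per-atom embeddings Ĥ(v).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .chem import ConformerError, MoleculeRecord
from .nn import GRUCell, Linear, Module, Tensor, segment_sum

_ELEMENTS = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P"]  # + other
_HYBRID = [Chem.HybridizationType.SP, Chem.HybridizationType.SP2,
           Chem.HybridizationType.SP3, Chem.HybridizationType.SP3D]  # + other
_MAX_DEGREE = 6
_MAX_H = 4

ATOM_FEATURE_DIM = (len(_ELEMENTS) + 1) + (_MAX_DEGREE + 1) + 1 + 1 + 1 \
    + (_MAX_H + 1) + (len(_HYBRID) + 1)


@dataclass
class MolecularGraph3D:
    """Heavy-atom molecular graph with conformer coordinates.

    ``features``: (n, d0) per-atom descriptors; ``coords``: (n, 3) Å;
    ``edges``: directed (src j, dst i) index arrays covering both bond
    directions, so neighborhoods N_i are symmetric.
    """
    features: np.ndarray
    coords: np.ndarray
    edge_src: np.ndarray
    edge_dst: np.ndarray

    @property
    def n_atoms(self) -> int:
        return self.features.shape[0]


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    v: list[float] = []
    sym = atom.GetSymbol()
    v += [1.0 if sym == e else 0.0 for e in _ELEMENTS]
    v.append(0.0 if sym in _ELEMENTS else 1.0)
    deg = min(atom.GetDegree(), _MAX_DEGREE)
    v += [1.0 if deg == d else 0.0 for d in range(_MAX_DEGREE + 1)]
    v.append(float(atom.GetFormalCharge()))
    v.append(1.0 if atom.GetIsAromatic() else 0.0)
    v.append(1.0 if atom.IsInRing() else 0.0)
    h = min(atom.GetTotalNumHs(), _MAX_H)
    v += [1.0 if h == n else 0.0 for n in range(_MAX_H + 1)]
    hyb = atom.GetHybridization()
    v += [1.0 if hyb == t else 0.0 for t in _HYBRID]
    v.append(0.0 if hyb in _HYBRID else 1.0)
    return np.array(v, dtype=np.float32)


def featurize_atoms(record: MoleculeRecord) -> MolecularGraph3D:
    """Build the heavy-atom 3D graph for a molecule with a conformer.

    Hydrogens stay implicit in the graph; their count enters the features.
    """
    if record.conformer is None:
        raise ConformerError(f"featurize_atoms needs a conformer: {record.mol_id}")
    mol = Chem.MolFromSmiles(record.smiles)
    n = mol.GetNumAtoms()
    feats = np.stack([_atom_features(a) for a in mol.GetAtoms()])
    # AddHs appends hydrogens after the heavy atoms, so the first n rows of
    # the stored (H-added) coordinates are the heavy atoms in parse order
    coords = np.asarray(record.conformer.coords[:n], dtype=np.float64)
    src, dst = [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        src += [j, i]
        dst += [i, j]
    return MolecularGraph3D(features=feats, coords=coords,
                            edge_src=np.array(src, dtype=np.int64),
                            edge_dst=np.array(dst, dtype=np.int64))


def spatial_message_pass(graph: MolecularGraph3D,
                         U_layers: list[np.ndarray],
                         b_layers: list[np.ndarray],
                         h0: np.ndarray | None = None) -> np.ndarray:
    """Pure-numpy evaluation of the message-passing stack.

    One (U, b) pair per layer; U has shape (3, d) and b shape (d,).  The sum
    over an empty neighborhood is the zero vector.  ``h0`` defaults to the
    graph's raw features (then d must equal the feature dimension).
    """
    h = np.asarray(graph.features if h0 is None else h0, dtype=np.float64)
    for U, b in zip(U_layers, b_layers):
        U = np.asarray(U, dtype=np.float64)
        b = np.asarray(b, dtype=np.float64)
        if U.shape != (3, h.shape[1]) or b.shape != (h.shape[1],):
            raise ValueError(f"parameter shape mismatch: U {U.shape}, b {b.shape}, "
                             f"d={h.shape[1]}")
        nxt = np.zeros_like(h)
        if len(graph.edge_src):
            disp = graph.coords[graph.edge_src] - graph.coords[graph.edge_dst]
            gate = np.maximum(disp @ U + b, 0.0)
            np.add.at(nxt, graph.edge_dst, gate * h[graph.edge_src])
        h = nxt
    return h


class SpatialGNN(Module):
    """Trainable conformer encoder: input projection, spatial layers, GRU readout."""

    def __init__(self, dim: int = 64, n_layers: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.dim = dim
        self.n_layers = n_layers
        self.proj = Linear(ATOM_FEATURE_DIM, dim, rng)
        self.U = [Tensor(rng.normal(0, 0.3, size=(3, dim)), requires_grad=True)
                  for _ in range(n_layers)]
        self.b = [Tensor(np.full(dim, 0.5), requires_grad=True)
                  for _ in range(n_layers)]
        for i, (u, bb) in enumerate(zip(self.U, self.b)):
            self._params[f"U.{i}"] = u
            self._params[f"b.{i}"] = bb
        self.gru = GRUCell(dim, dim, rng)

    def message_pass(self, graph: MolecularGraph3D) -> Tensor:
        h = self.proj(Tensor(graph.features)).relu()
        for U, b in zip(self.U, self.b):
            if len(graph.edge_src) == 0:
                h = h * 0.0
                continue
            disp = Tensor(graph.coords[graph.edge_src] - graph.coords[graph.edge_dst])
            gate = (disp @ U + b).relu()
            msg = gate * h.take(graph.edge_src)
            h = segment_sum(msg, graph.edge_dst, graph.n_atoms)
        return h

    def __call__(self, graph: MolecularGraph3D,
                 order: np.ndarray | None = None) -> Tensor:
        """Final atom embeddings Ĥ(v): message passing then GRU readout.

        ``order`` is the atom visiting order for the recurrence (canonical
        SMILES output order); outputs are returned in graph atom order.
        """
        h = self.message_pass(graph)
        return gru_readout(self.gru, h, order)


def gru_readout(cell: GRUCell, embeddings: Tensor,
                order: np.ndarray | None = None) -> Tensor:
    """Run a GRU over atoms in the given order; outputs keep graph order.

    The recurrence is order-sensitive by design (it is a sequence model over
    the canonical atom ordering).
    """
    n = embeddings.shape[0]
    order = np.arange(n) if order is None else np.asarray(order)
    d = cell.hidden
    h = Tensor(np.zeros((1, d), dtype=np.float32))
    outputs: list[Tensor] = [None] * n
    for idx in order:
        x = embeddings.take(np.array([idx]))
        h = cell(x, h)
        outputs[int(idx)] = h
    from .nn import concat
    return concat(outputs, axis=0)
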