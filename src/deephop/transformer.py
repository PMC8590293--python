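"""Multimodal SMILES-to-SMILES transformer for target-conditioned hopping.

The encoder consumes the source molecule twice over: its canonical SMILES
token sequence and the per-atom embeddings of its 3D conformer from the
spatial graph encoder.  The two are fused *at atomic level* — each atom
token's embedding is concatenated with its atom's graph vector (zeros for
non-atom tokens such as ring digits and branches) and linearly projected to
the model width.  Sinusoidal positional encodings are added, a standard
self-attention encoder produces the latent L ∈ R^{m×f}, the protein's
k-dimensional embedding H_p is broadcast along the sequence, concatenated to
width f+k and projected back to f to form the decoder memory.  The decoder
is a standard causally-masked transformer that emits the product SMILES.

Training is teacher-forced cross-entropy; generation is length-bounded beam
search (width 1 reduces exactly to greedy decoding).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from .chem import MoleculeRecord
from .graph import MolecularGraph3D, SpatialGNN, featurize_atoms
from .nn import (Adam, Dropout, Embedding, FeedForward, LayerNorm, Linear,
                 Module, MultiHeadAttention, Tensor, concat, log_softmax,
                 scaled_dot_attention, sinusoidal_positions)
from .pairs import DatasetSplit, HopPair
from .protein import ProteinEmbedding

# ---------------------------------------------------------------------------
# SMILES tokenization
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\[[^\]]+\]|Br|Cl|%\d{2}|[BCNOSPFI]|[bcnops]|[()=#+\-\\/:~@?*$.]|\d")

_ATOM_TOKEN_RE = re.compile(r"\[[^\]]+\]|Br|Cl|[BCNOSPFI]|[bcnops]")

PAD, BOS, EOS, UNK = "<pad>", "<s>", "</s>", "<unk>"


class TokenizationError(ValueError):
    pass


def tokenize_smiles(smiles: str) -> list[str]:
    """Split a SMILES string into chemically meaningful tokens.

    Bracket atoms and two-letter elements are single tokens.  The
    tokenization is lossless: ``"".join(tokens) == smiles``; any character
    outside the grammar raises :class:`TokenizationError`.
    """
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise TokenizationError(f"cannot tokenize {smiles!r}")
    return tokens


def detokenize(tokens: list[str]) -> str:
    return "".join(tokens)


def is_atom_token(token: str) -> bool:
    return bool(_ATOM_TOKEN_RE.fullmatch(token))


def align_atoms_to_tokens(tokens: list[str], smiles: str) -> list[int | None]:
    """Map each token position to its atom index in the parsed molecule.

    Requires canonical SMILES: RDKit records the atom output order when
    writing the canonical string, so the i-th atom token corresponds to the
    i-th entry of that order.  Non-atom tokens map to ``None``.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r}")
    out = Chem.MolToSmiles(mol)
    if out != smiles:
        raise ValueError("SMILES must be canonical for atom-token alignment")
    order = list(map(int, mol.GetProp("_smilesAtomOutputOrder")
                     .strip("[],").split(",")))
    atom_positions = [i for i, t in enumerate(tokens) if is_atom_token(t)]
    if len(atom_positions) != mol.GetNumAtoms():
        raise ValueError(
            f"atom-token count {len(atom_positions)} != atom count "
            f"{mol.GetNumAtoms()} for {smiles!r}")
    mapping: list[int | None] = [None] * len(tokens)
    for tok_pos, atom_idx in zip(atom_positions, order):
        mapping[tok_pos] = atom_idx
    return mapping


class Vocabulary:
    """Token ↔ index mapping with the four special tokens at fixed indices."""

    def __init__(self, tokens: list[str]):
        specials = [PAD, BOS, EOS, UNK]
        self.itos = specials + sorted(set(tokens) - set(specials))
        self.stoi = {t: i for i, t in enumerate(self.itos)}

    def __len__(self) -> int:
        return len(self.itos)

    def encode(self, tokens: list[str]) -> list[int]:
        return [self.stoi.get(t, self.stoi[UNK]) for t in tokens]

    def decode(self, ids: list[int]) -> list[str]:
        return [self.itos[i] for i in ids
                if self.itos[i] not in (PAD, BOS, EOS)]

    @classmethod
    def from_corpus(cls, smiles_iter) -> "Vocabulary":
        tokens: list[str] = []
        for smi in smiles_iter:
            tokens.extend(tokenize_smiles(smi))
        return cls(tokens)

    def to_json(self) -> str:
        return json.dumps(self.itos)

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        v = cls([])
        v.itos = json.loads(text)
        v.stoi = {t: i for i, t in enumerate(v.itos)}
        return v


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class HopTransformerConfig:
    f: int = 256                 # model width
    n_heads: int = 8
    n_encoder_layers: int = 4
    n_decoder_layers: int = 4
    ffn_hidden: int = 512
    graph_dim: int = 64
    graph_layers: int = 3
    protein_dim: int = 128       # k
    dropout: float = 0.1
    label_smoothing: float = 0.0
    max_len: int = 200


@dataclass
class GenerationResult:
    """Ranked beam-search candidates for one (source, target) query."""
    source_id: str
    target_id: str
    candidates: list[str]        # SMILES, sorted by descending log-probability
    log_probs: list[float]
    beam_width: int


class _EncoderLayer(Module):
    def __init__(self, cfg: HopTransformerConfig, rng):
        super().__init__()
        self.attn = MultiHeadAttention(cfg.f, cfg.n_heads, rng)
        self.ffn = FeedForward(cfg.f, cfg.ffn_hidden, rng, cfg.dropout)
        self.ln1 = LayerNorm(cfg.f)
        self.ln2 = LayerNorm(cfg.f)
        self.drop = Dropout(cfg.dropout, rng)

    def __call__(self, x: Tensor, mask) -> Tensor:
        x = self.ln1(x + self.drop(self.attn(x, x, x, mask)))
        return self.ln2(x + self.drop(self.ffn(x)))


class _DecoderLayer(Module):
    def __init__(self, cfg: HopTransformerConfig, rng):
        super().__init__()
        self.self_attn = MultiHeadAttention(cfg.f, cfg.n_heads, rng)
        self.cross_attn = MultiHeadAttention(cfg.f, cfg.n_heads, rng)
        self.ffn = FeedForward(cfg.f, cfg.ffn_hidden, rng, cfg.dropout)
        self.ln1 = LayerNorm(cfg.f)
        self.ln2 = LayerNorm(cfg.f)
        self.ln3 = LayerNorm(cfg.f)
        self.drop = Dropout(cfg.dropout, rng)

    def __call__(self, y: Tensor, memory: Tensor, self_mask, mem_mask) -> Tensor:
        y = self.ln1(y + self.drop(self.self_attn(y, y, y, self_mask)))
        y = self.ln2(y + self.drop(self.cross_attn(y, memory, memory, mem_mask)))
        return self.ln3(y + self.drop(self.ffn(y)))


class HopTransformer(Module):
    def __init__(self, vocab: Vocabulary, config: HopTransformerConfig | None = None,
                 seed: int = 0):
        super().__init__()
        cfg = config or HopTransformerConfig()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.vocab = vocab
        self.embed = Embedding(len(vocab), cfg.f, rng)
        self.fuse = Linear(cfg.f + cfg.graph_dim, cfg.f, rng)
        self.gnn = SpatialGNN(cfg.graph_dim, cfg.graph_layers, rng)
        self.enc_layers = [_EncoderLayer(cfg, rng) for _ in range(cfg.n_encoder_layers)]
        self.dec_layers = [_DecoderLayer(cfg, rng) for _ in range(cfg.n_decoder_layers)]
        self.cond = Linear(cfg.f + cfg.protein_dim, cfg.f, rng)
        self.out = Linear(cfg.f, len(vocab), rng)
        self._pos = sinusoidal_positions(cfg.max_len + 2, cfg.f)
        self._source_cache: dict[str, "_SourceFeatures"] = {}

    # -- source featurization -----------------------------------------------
    def _source_features(self, mol: MoleculeRecord) -> "_SourceFeatures":
        if mol.smiles not in self._source_cache:
            tokens = tokenize_smiles(mol.smiles)
            mapping = align_atoms_to_tokens(tokens, mol.smiles)
            graph = featurize_atoms(mol)
            # GRU visits atoms in the canonical SMILES output order
            order = np.array([a for a in mapping if a is not None], dtype=np.int64)
            self._source_cache[mol.smiles] = _SourceFeatures(
                ids=np.array(self.vocab.encode(tokens), dtype=np.int64),
                atom_map=mapping, graph=graph, order=order)
        return self._source_cache[mol.smiles]

    def _fused_batch(self, sources: list[MoleculeRecord]
                     ) -> tuple[Tensor, np.ndarray]:
        """Fuse token and graph embeddings for a padded batch of sources."""
        feats = [self._source_features(m) for m in sources]
        T = max(len(f.ids) for f in feats)
        ids = np.zeros((len(feats), T), dtype=np.int64)          # pad id 0
        pad = np.ones((len(feats), T), dtype=bool)
        rows = []
        for b, f in enumerate(feats):
            ids[b, :len(f.ids)] = f.ids
            pad[b, :len(f.ids)] = False
            atom_emb = self.gnn(f.graph, f.order)                 # (n_atoms, g)
            zero_row = Tensor(np.zeros((1, self.cfg.graph_dim), dtype=np.float32))
            table = concat([atom_emb, zero_row], axis=0)
            idx = np.array([f.graph.n_atoms if a is None else a
                            for a in f.atom_map]
                           + [f.graph.n_atoms] * (T - len(f.ids)), dtype=np.int64)
            rows.append(table.take(idx).reshape(1, T, self.cfg.graph_dim))
        graph_part = concat(rows, axis=0)                         # (B, T, g)
        tok = self.embed(ids)                                     # (B, T, f)
        fused = self.fuse(concat([tok, graph_part], axis=-1))
        fused = fused + Tensor(self._pos[None, :T, :])
        return fused, pad

    # -- spec operations ------------------------------------------------------
    def encode(self, fused: Tensor, src_pad: np.ndarray) -> Tensor:
        """Run the self-attention encoder stack: fused embeddings → L (B,m,f)."""
        mask = src_pad[:, None, None, :]
        x = fused
        for layer in self.enc_layers:
            x = layer(x, mask)
        return x

    def condition_on_protein(self, L: Tensor, hp: ProteinEmbedding) -> Tensor:
        """Broadcast H_p along the sequence, concat to width f+k, project to f."""
        if hp.k != self.cfg.protein_dim:
            raise ValueError(f"protein embedding dim {hp.k} != "
                             f"configured k={self.cfg.protein_dim}")
        b, m, _ = L.shape
        tiled = Tensor(np.broadcast_to(hp.H_p, (b, m, hp.k)).copy())
        return self.cond(concat([L, tiled], axis=-1))

    def encode_source(self, sources: list[MoleculeRecord],
                      hps: list[ProteinEmbedding]) -> tuple[Tensor, np.ndarray]:
        fused, pad = self._fused_batch(sources)
        L = self.encode(fused, pad)
        if len({hp.k for hp in hps}) > 1:
            raise ValueError("inconsistent protein embedding dimensions in batch")
        mem_rows = [self.condition_on_protein(
            _narrow_batch(L, b), hps[b]) for b in range(len(sources))]
        memory = concat(mem_rows, axis=0)
        return memory, pad

    def decode(self, memory: Tensor, mem_pad: np.ndarray,
               tgt_ids: np.ndarray, tgt_pad: np.ndarray) -> Tensor:
        """Teacher-forced decoder pass; returns logits (B, T, |vocab|)."""
        B, T = tgt_ids.shape
        y = self.embed(tgt_ids) + Tensor(self._pos[None, :T, :])
        causal = np.triu(np.ones((T, T), dtype=bool), k=1)
        self_mask = causal[None, None, :, :] | tgt_pad[:, None, None, :]
        mem_mask = mem_pad[:, None, None, :]
        for layer in self.dec_layers:
            y = layer(y, memory, self_mask, mem_mask)
        return self.out(y)

    def loss(self, logits: Tensor, gold: np.ndarray, gold_mask: np.ndarray) -> Tensor:
        """Token cross-entropy with optional label smoothing, mean per token."""
        logp = log_softmax(logits, axis=-1)
        V = logits.shape[-1]
        eps = self.cfg.label_smoothing
        onehot = np.zeros(logits.shape, dtype=np.float32)
        B, T = gold.shape
        onehot[np.arange(B)[:, None], np.arange(T)[None, :], gold] = 1.0
        if eps > 0.0:
            onehot = (1.0 - eps) * onehot + eps / V
        w = gold_mask.astype(np.float32)[:, :, None]
        nll = -(logp * Tensor(onehot * w)).sum()
        return nll * (1.0 / max(float(gold_mask.sum()), 1.0))


def _narrow_batch(x: Tensor, b: int) -> Tensor:
    """Select batch row b as a (1, T, f) tensor (differentiable)."""
    return x.take(np.array([b]), axis=0)


@dataclass
class _SourceFeatures:
    ids: np.ndarray
    atom_map: list
    graph: MolecularGraph3D
    order: np.ndarray


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainReport:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


def _encode_targets(model: HopTransformer, pairs: list[HopPair]
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Teacher-forcing tensors: decoder input ids/pad and gold ids/mask."""
    bos, eos = model.vocab.stoi[BOS], model.vocab.stoi[EOS]
    seqs = [model.vocab.encode(tokenize_smiles(p.product.smiles)) for p in pairs]
    T = max(len(s) for s in seqs) + 1
    dec_in = np.zeros((len(seqs), T), dtype=np.int64)
    dec_pad = np.ones((len(seqs), T), dtype=bool)
    gold = np.zeros((len(seqs), T), dtype=np.int64)
    gold_mask = np.zeros((len(seqs), T), dtype=bool)
    for b, s in enumerate(seqs):
        dec_in[b, 0] = bos
        dec_in[b, 1:len(s) + 1] = s
        dec_pad[b, :len(s) + 1] = False
        gold[b, :len(s)] = s
        gold[b, len(s)] = eos
        gold_mask[b, :len(s) + 1] = True
    return dec_in, dec_pad, gold, gold_mask


def _batch_loss(model: HopTransformer, pairs: list[HopPair],
                proteins: dict[str, ProteinEmbedding]) -> Tensor:
    sources = [p.source for p in pairs]
    hps = [proteins[p.target_id] for p in pairs]
    memory, src_pad = model.encode_source(sources, hps)
    dec_in, dec_pad, gold, gold_mask = _encode_targets(model, pairs)
    logits = model.decode(memory, src_pad, dec_in, dec_pad)
    return model.loss(logits, gold, gold_mask)


def train(split: DatasetSplit, proteins: dict[str, ProteinEmbedding],
          model: HopTransformer | None = None,
          config: HopTransformerConfig | None = None,
          epochs: int = 50, batch_size: int = 16, lr: float = 1e-3,
          seed: int = 0, checkpoint_dir=None,
          init_state: dict | None = None,
          report: TrainReport | None = None) -> HopTransformer:
    """Train (or fine-tune) the hop transformer on a pair split.

    A checkpoint is taken every epoch; the returned model carries the weights
    of the epoch with the lowest validation loss.  Fine-tuning is the same
    loop started from ``init_state`` (continued training on new pairs).
    """
    if not split.train_pairs:
        raise ValueError("empty training pair set")
    if model is None:
        vocab = Vocabulary.from_corpus(
            [p.source.smiles for p in split.train_pairs + split.val_pairs]
            + [p.product.smiles for p in split.train_pairs + split.val_pairs])
        model = HopTransformer(vocab, config, seed=seed)
    if init_state is not None:
        model.load_state_dict(init_state)
    rng = np.random.default_rng(seed + 17)
    opt = Adam(model.parameters(), lr=lr)
    report = report if report is not None else TrainReport()
    best_state, best_val = None, float("inf")
    pairs = split.train_pairs
    for epoch in range(epochs):
        model.train()
        order = rng.permutation(len(pairs))
        total = 0.0
        for start in range(0, len(pairs), batch_size):
            batch = [pairs[i] for i in order[start:start + batch_size]]
            opt.zero_grad()
            loss = _batch_loss(model, batch, proteins)
            loss.backward()
            opt.step()
            total += float(loss.data) * len(batch)
        report.train_loss.append(total / len(pairs))
        model.eval()
        if split.val_pairs:
            val = float(_batch_loss(model, split.val_pairs, proteins).data)
        else:
            val = report.train_loss[-1]
        report.val_loss.append(val)
        if val < best_val:
            best_val, best_state = val, model.state_dict()
            report.best_epoch = epoch
        if checkpoint_dir is not None:
            path = Path(checkpoint_dir) / f"epoch{epoch:03d}.npz"
            np.savez(path, **model.state_dict())
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def beam_generate(model: HopTransformer, source: MoleculeRecord,
                  hp: ProteinEmbedding, beam_width: int = 10,
                  max_len: int | None = None,
                  target_id: str = "") -> GenerationResult:
    """Length-bounded beam search; ``beam_width=1`` is exactly greedy.

    Candidates stop at the end token (or the length bound), are detokenized
    and returned ranked by total log-probability.  The pad/unk/bos tokens are
    masked out of the decode distribution, so they are never emitted.
    """
    model.eval()
    max_len = max_len or model.cfg.max_len
    memory, src_pad = model.encode_source([source], [hp])
    bos, eos = model.vocab.stoi[BOS], model.vocab.stoi[EOS]
    banned = [model.vocab.stoi[PAD], model.vocab.stoi[UNK], bos]
    beams: list[tuple[list[int], float]] = [([bos], 0.0)]
    finished: list[tuple[list[int], float]] = []
    mem_data = memory.data
    for _ in range(max_len):
        if not beams:
            break
        B = len(beams)
        T = len(beams[0][0])
        tgt = np.array([b[0] for b in beams], dtype=np.int64)
        tgt_pad = np.zeros((B, T), dtype=bool)
        mem = Tensor(np.repeat(mem_data, B, axis=0))
        pad = np.repeat(src_pad, B, axis=0)
        logits = model.decode(mem, pad, tgt, tgt_pad).data[:, -1, :]
        logits[:, banned] = -np.inf
        logp = logits - _logsumexp(logits)
        cand: list[tuple[list[int], float]] = []
        for b, (toks, score) in enumerate(beams):
            for v in np.argsort(-logp[b])[:beam_width]:
                cand.append((toks + [int(v)], score + float(logp[b, v])))
        cand.sort(key=lambda c: -c[1])
        beams = []
        for toks, score in cand[:beam_width]:
            (finished if toks[-1] == eos else beams).append((toks, score))
        if not beams or len(finished) >= beam_width:
            break
    finished.extend(beams)  # length-bound hits count as candidates too
    finished.sort(key=lambda c: -c[1])
    finished = finished[:beam_width]
    return GenerationResult(
        source_id=source.mol_id, target_id=target_id,
        candidates=[detokenize(model.vocab.decode(t)) for t, _ in finished],
        log_probs=[s for _, s in finished], beam_width=beam_width)


def _logsumexp(x: np.ndarray) -> np.ndarray:
    m = np.max(np.where(np.isfinite(x), x, -np.inf), axis=-1, keepdims=True)
    return m + np.log(np.exp(x - m).sum(axis=-1, keepdims=True))


def greedy_generate(model: HopTransformer, source: MoleculeRecord,
                    hp: ProteinEmbedding, max_len: int | None = None,
                    target_id: str = "") -> GenerationResult:
    return beam_generate(model, source, hp, beam_width=1, max_len=max_len,
                         target_id=target_id)


# ---------------------------------------------------------------------------
# checkpoint I/O
# ---------------------------------------------------------------------------

def save_model(model: HopTransformer, path) -> None:
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    cfg = model.cfg
    sidecar = {"vocab": model.vocab.itos,
               "config": {k: getattr(cfg, k) for k in cfg.__dataclass_fields__}}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_model(path) -> HopTransformer:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    vocab = Vocabulary([])
    vocab.itos = sidecar["vocab"]
    vocab.stoi = {t: i for i, t in enumerate(vocab.itos)}
    model = HopTransformer(vocab, HopTransformerConfig(**sidecar["config"]))
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    model.eval()
    return model
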