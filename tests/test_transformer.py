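"""Tokenizer, attention, fusion/conditioning contracts and beam search."""

import numpy as np
import pytest

from deephop import chem, protein, transformer
from deephop.nn import Tensor, scaled_dot_attention
from deephop.transformer import (BOS, EOS, PAD, UNK, HopTransformer,
                                 HopTransformerConfig, Vocabulary,
                                 align_atoms_to_tokens, beam_generate,
                                 detokenize, tokenize_smiles)

TINY_CFG = HopTransformerConfig(f=32, n_heads=2, n_encoder_layers=2,
                                n_decoder_layers=2, ffn_hidden=64,
                                graph_dim=8, graph_layers=1, protein_dim=16,
                                dropout=0.0, max_len=60)


class TestTokenizer:
    @pytest.mark.parametrize("smiles,expected", [
        ("CCO", ["C", "C", "O"]),
        ("c1ccccc1", ["c", "1", "c", "c", "c", "c", "c", "1"]),
        ("C[Si](Cl)Br", ["C", "[Si]", "(", "Cl", ")", "Br"]),
        ("CC(=O)Nc1ccc(O)cc1",
         ["C", "C", "(", "=", "O", ")", "N", "c", "1", "c", "c", "c",
          "(", "O", ")", "c", "c", "1"]),
    ])
    def test_examples(self, smiles, expected):
        assert tokenize_smiles(smiles) == expected

    def test_roundtrip_exact_on_library(self, library):
        for rec in library:
            assert detokenize(tokenize_smiles(rec.smiles)) == rec.smiles

    def test_character_outside_grammar_rejected(self):
        with pytest.raises(transformer.TokenizationError):
            tokenize_smiles("CxC")


class TestAtomTokenAlignment:
    def test_linear_molecule(self):
        assert align_atoms_to_tokens(["C", "C", "O"], "CCO") == [0, 1, 2]

    def test_ring_digits_map_to_none(self):
        mapping = align_atoms_to_tokens(tokenize_smiles("c1ccccc1"), "c1ccccc1")
        assert mapping.count(None) == 2          # the two ring-closure digits
        assert sorted(m for m in mapping if m is not None) == list(range(6))

    def test_atom_token_count_equals_heavy_atoms_across_library(self, library):
        from rdkit import Chem
        for rec in library:
            tokens = tokenize_smiles(rec.smiles)
            n_atom_tokens = sum(transformer.is_atom_token(t) for t in tokens)
            assert n_atom_tokens == Chem.MolFromSmiles(rec.smiles).GetNumAtoms()
            mapping = align_atoms_to_tokens(tokens, rec.smiles)
            assert sorted(m for m in mapping if m is not None) \
                == list(range(n_atom_tokens))

    def test_non_canonical_input_rejected(self):
        with pytest.raises(ValueError):
            align_atoms_to_tokens(["O", "C", "C"], "OCC")


class TestVocabulary:
    def test_specials_fixed_and_roundtrip(self):
        v = Vocabulary.from_corpus(["CCO", "c1ccccc1"])
        assert v.itos[:4] == [PAD, BOS, EOS, UNK]
        toks = tokenize_smiles("CCO")
        assert v.decode(v.encode(toks)) == toks

    def test_unknown_token_maps_to_unk(self):
        v = Vocabulary.from_corpus(["CCO"])
        assert v.encode(["Br"]) == [v.stoi[UNK]]


class TestScaledDotAttention:
    def test_single_element_identity(self):
        x = Tensor(np.array([[3.0]], dtype=np.float32))
        out = scaled_dot_attention(x, x, x, 1)
        assert out.data == pytest.approx(3.0)

    def test_orthogonal_query_gives_row_mean_of_values(self, rng):
        q = Tensor(np.zeros((1, 4), dtype=np.float32))
        k = Tensor(rng.normal(size=(5, 4)).astype(np.float32))
        v = Tensor(rng.normal(size=(5, 3)).astype(np.float32))
        out = scaled_dot_attention(q, k, v, 4).data
        assert np.allclose(out, v.data.mean(axis=0), atol=1e-6)

    def test_matches_independent_oracle_on_random_inputs(self, rng):
        """100 random instances vs a separately coded matmul/softmax/matmul."""
        for _ in range(100):
            tq, tk, dk, dv = rng.integers(1, 6, size=4)
            q = rng.normal(size=(tq, dk)).astype(np.float32)
            k = rng.normal(size=(tk, dk)).astype(np.float32)
            v = rng.normal(size=(tk, dv)).astype(np.float32)
            scores = q @ k.T / np.sqrt(dk)
            e = np.exp(scores - scores.max(axis=-1, keepdims=True))
            expected = (e / e.sum(axis=-1, keepdims=True)) @ v
            got = scaled_dot_attention(Tensor(q), Tensor(k), Tensor(v), int(dk)).data
            assert np.allclose(got, expected, atol=1e-6)


@pytest.fixture(scope="module")
def tiny_model(library3d):
    vocab = Vocabulary.from_corpus([m.smiles for m in library3d])
    return HopTransformer(vocab, TINY_CFG, seed=0).eval()


@pytest.fixture(scope="module")
def hp16():
    return protein.ProteinEmbedding(H_p=np.linspace(0, 1, 16, dtype=np.float32))


class TestEncoderContracts:
    def test_zero_layer_encoder_is_identity(self, library3d):
        cfg = HopTransformerConfig(**{**TINY_CFG.__dict__, "n_encoder_layers": 0})
        vocab = Vocabulary.from_corpus([m.smiles for m in library3d])
        model = HopTransformer(vocab, cfg, seed=0).eval()
        fused, pad = model._fused_batch([library3d[0]])
        L = model.encode(fused, pad)
        assert np.array_equal(L.data, fused.data)

    def test_eval_mode_bitwise_stable(self, tiny_model, library3d):
        fused1, pad = tiny_model._fused_batch([library3d[0]])
        fused2, _ = tiny_model._fused_batch([library3d[0]])
        out1 = tiny_model.encode(fused1, pad).data
        out2 = tiny_model.encode(fused2, pad).data
        assert np.array_equal(out1, out2)

    def test_sequence_length_preserved_through_fusion_and_encoding(
            self, tiny_model, library3d):
        mols = library3d[:3]
        fused, pad = tiny_model._fused_batch(mols)
        T = max(len(tokenize_smiles(m.smiles)) for m in mols)
        assert fused.shape == (3, T, TINY_CFG.f)
        assert tiny_model.encode(fused, pad).shape == (3, T, TINY_CFG.f)


class TestProteinConditioning:
    def test_width_contract(self, tiny_model, library3d, hp16):
        fused, pad = tiny_model._fused_batch([library3d[0]])
        L = tiny_model.encode(fused, pad)
        mem = tiny_model.condition_on_protein(L, hp16)
        assert mem.shape == L.shape             # projected back to f

    def test_zero_protein_reduces_to_projection_of_L(self, tiny_model,
                                                     library3d):
        fused, pad = tiny_model._fused_batch([library3d[0]])
        L = tiny_model.encode(fused, pad)
        zero = protein.ProteinEmbedding(H_p=np.zeros(16, dtype=np.float32))
        mem = tiny_model.condition_on_protein(L, zero)
        W_l = tiny_model.cond.W.data[:TINY_CFG.f]    # bias is zero-initialized
        assert np.allclose(mem.data, L.data @ W_l, atol=1e-5)

    def test_different_proteins_give_different_memories(self, tiny_model,
                                                        library3d, hp16):
        fused, pad = tiny_model._fused_batch([library3d[0]])
        L = tiny_model.encode(fused, pad)
        other = protein.ProteinEmbedding(
            H_p=np.linspace(1, 0, 16, dtype=np.float32))
        a = tiny_model.condition_on_protein(L, hp16).data
        b = tiny_model.condition_on_protein(L, other).data
        assert not np.allclose(a, b)

    def test_dimension_mismatch_fails_fast(self, tiny_model, library3d):
        fused, pad = tiny_model._fused_batch([library3d[0]])
        L = tiny_model.encode(fused, pad)
        bad = protein.ProteinEmbedding(H_p=np.zeros(7, dtype=np.float32))
        with pytest.raises(ValueError):
            tiny_model.condition_on_protein(L, bad)


class TestLoss:
    def test_perfect_one_hot_predictions_give_zero_loss(self, tiny_model):
        V = len(tiny_model.vocab)
        gold = np.array([[5, 6, 2]])
        logits = np.full((1, 3, V), -1e4, dtype=np.float32)
        for t, g in enumerate(gold[0]):
            logits[0, t, g] = 1e4
        loss = tiny_model.loss(Tensor(logits), gold, np.ones((1, 3), dtype=bool))
        assert float(loss.data) == pytest.approx(0.0, abs=1e-4)

    def test_uniform_predictions_give_log_vocab_per_token(self, tiny_model):
        V = len(tiny_model.vocab)
        gold = np.array([[5, 6, 2, 4]])
        logits = np.zeros((1, 4, V), dtype=np.float32)
        loss = tiny_model.loss(Tensor(logits), gold, np.ones((1, 4), dtype=bool))
        assert float(loss.data) == pytest.approx(np.log(V), rel=1e-4)

    def test_padding_positions_excluded(self, tiny_model):
        V = len(tiny_model.vocab)
        gold = np.array([[5, 6, 0, 0]])
        mask = np.array([[True, True, False, False]])
        logits = np.zeros((1, 4, V), dtype=np.float32)
        loss = tiny_model.loss(Tensor(logits), gold, mask)
        assert float(loss.data) == pytest.approx(np.log(V), rel=1e-4)


class TestCausalMask:
    def test_future_target_tokens_cannot_affect_earlier_logits(
            self, tiny_model, library3d, hp16):
        """Perturbing decoder input at position j leaves logits < j unchanged."""
        mem, pad = tiny_model.encode_source([library3d[0]], [hp16])
        dec_in = np.array([[1, 5, 6, 7, 8]])
        dec_pad = np.zeros((1, 5), dtype=bool)
        base = tiny_model.decode(mem, pad, dec_in, dec_pad).data
        perturbed_in = dec_in.copy()
        perturbed_in[0, 3] = 9
        got = tiny_model.decode(mem, pad, perturbed_in, dec_pad).data
        assert np.allclose(got[0, :3], base[0, :3], atol=1e-6)
        assert not np.allclose(got[0, 3:], base[0, 3:], atol=1e-6)


class _ToyModel:
    """Hand-set two-step distribution where greedy is suboptimal.

    Vocabulary: pad <s> </s> unk a b.  After <s>: P(a)=0.6, P(b)=0.4.
    After a: P(</s>)=0.5, P(a)=P(b)=0.25.  After b: P(</s>)=0.9,
    P(a)=P(b)=0.05.  Greedy takes a then </s> (P=0.30); the best full
    sequence is b </s> (P=0.36).
    """

    def __init__(self):
        self.vocab = Vocabulary(["a", "b"])
        self.cfg = HopTransformerConfig(max_len=4)
        self.steps = {
            BOS: {"a": 0.6, "b": 0.4},
            "a": {EOS: 0.5, "a": 0.25, "b": 0.25},
            "b": {EOS: 0.9, "a": 0.05, "b": 0.05},
        }

    def eval(self):
        return self

    def encode_source(self, sources, hps):
        return Tensor(np.zeros((1, 1, 1), dtype=np.float32)), \
            np.zeros((1, 1), dtype=bool)

    def decode(self, memory, mem_pad, tgt_ids, tgt_pad):
        B, T = tgt_ids.shape
        V = len(self.vocab)
        logits = np.full((B, T, V), -30.0, dtype=np.float32)
        for b in range(B):
            last = self.vocab.itos[tgt_ids[b, -1]]
            for tok, p in self.steps[last].items():
                logits[b, -1, self.vocab.stoi[tok]] = np.log(p)
        return Tensor(logits)

    def sequence_prob(self, tokens):
        p, prev = 1.0, BOS
        for t in tokens:
            p *= self.steps[prev].get(t, 0.0)
            prev = t
        return p * self.steps[prev].get(EOS, 0.0)


@pytest.fixture
def toy():
    return _ToyModel()


def _dummy_source():
    return chem.MoleculeRecord("src", "C")


class TestBeamSearch:
    def test_greedy_picks_locally_best_beam_finds_global_best(self, toy):
        hp = protein.ProteinEmbedding(H_p=np.zeros(1, dtype=np.float32))
        greedy = beam_generate(toy, _dummy_source(), hp, beam_width=1, max_len=3)
        assert greedy.candidates[0] == "a"
        wide = beam_generate(toy, _dummy_source(), hp, beam_width=2, max_len=3)
        assert wide.candidates[0] == "b"
        # exhaustive enumeration of every sequence of length <= 2
        seqs = [[t] for t in ("a", "b")] + \
            [[t1, t2] for t1 in ("a", "b") for t2 in ("a", "b")]
        best = max(seqs, key=toy.sequence_prob)
        assert "".join(best) == wide.candidates[0]
        assert wide.log_probs[0] == pytest.approx(
            np.log(toy.sequence_prob(best)), abs=1e-5)

    def test_beam_width_one_equals_independent_greedy(self, tiny_model,
                                                      library3d, hp16):
        src = library3d[0]
        res = beam_generate(tiny_model, src, hp16, beam_width=1, max_len=15)
        # independent greedy loop straight over the decoder
        mem, pad = tiny_model.encode_source([src], [hp16])
        bos, eos = tiny_model.vocab.stoi[BOS], tiny_model.vocab.stoi[EOS]
        banned = [tiny_model.vocab.stoi[PAD], tiny_model.vocab.stoi[UNK], bos]
        toks = [bos]
        for _ in range(15):
            tgt = np.array([toks])
            logits = tiny_model.decode(mem, pad, tgt,
                                       np.zeros_like(tgt, dtype=bool)).data[0, -1]
            logits[banned] = -np.inf
            toks.append(int(np.argmax(logits)))
            if toks[-1] == eos:
                break
        expected = detokenize(tiny_model.vocab.decode(toks))
        assert res.candidates[0] == expected

    def test_candidate_count_and_ordering_contract(self, tiny_model,
                                                   library3d, hp16):
        res = beam_generate(tiny_model, library3d[1], hp16, beam_width=10,
                            max_len=20)
        assert len(res.candidates) <= 10
        assert all(a >= b for a, b in zip(res.log_probs, res.log_probs[1:]))


def test_model_save_load_roundtrip(tmp_path, tiny_model, library3d, hp16):
    transformer.save_model(tiny_model, tmp_path / "model")
    back = transformer.load_model(tmp_path / "model")
    a = beam_generate(tiny_model, library3d[0], hp16, beam_width=2, max_len=10)
    b = beam_generate(back, library3d[0], hp16, beam_width=2, max_len=10)
    assert a.candidates == b.candidates
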