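# Methods

## Problem

Scaffold hopping replaces the core ring framework of an active molecule with
a different one while preserving its 3D shape and pharmacophore, and with it
the bioactivity against a given protein target. This package treats the task
as supervised molecule-to-molecule translation: given a seed molecule X and
a target protein Z, a conditional sequence model proposes "hopped" products
Y with a novel 2D framework, a similar 3D presentation, and improved
predicted potency.

## Hop-pair construction

A directed training pair ((X, Y) | Z) must satisfy three predicates:

* **activity gain**: pChEMBL(Y, Z) − pChEMBL(X, Z) ≥ 1, where pChEMBL is
  −log10 of the molar IC50/Ki/Kd (a ≥ tenfold potency improvement);
* **2D dissimilarity**: Tanimoto over Morgan fingerprints (radius 2,
  2048 bits) of the two Bemis–Murcko scaffolds ≤ 0.6;
* **3D similarity**: shape-and-color (SC) score of the lowest-energy
  conformers ≥ 0.6.

Duplicate (molecule, target) measurements are aggregated by median pChEMBL
(robust to assay outliers). Targets are kept when they carry 300–5000
unique molecules. Per target, 10% of molecules are held out as the test set
*before* mining, so no test structure can appear in a pair; mined pairs are
capped at 10 hops per source molecule — when more candidates exist, the
largest activity gains are kept, with exact ties broken by the product's
canonical SMILES so the result is deterministic. The remaining pairs split
9:1 into train and validation.

Pairs are mined directed only (X → Y); the reverse direction is a different
training signal (activity *loss*) and is not emitted.

## Similarity machinery

* **Standardization**: largest organic fragment kept (strict mode rejects
  any disconnected input), isotope labels cleared, charges neutralized where
  a neutral valence form exists.
* **Scaffolds**: Bemis–Murcko frameworks (ring systems plus linkers);
  acyclic molecules yield the empty scaffold, two empty scaffolds score
  Tanimoto 0 by convention and such molecules are excluded from mining —
  a molecule without a framework cannot hop.
* **Conformers**: ETKDG embedding of N conformers (100 by default; the
  tests and the acceptance run use 3–5 to stay within desk-scale budgets)
  with explicit hydrogens, MMFF94 minimization (UFF fallback where MMFF
  parameters are missing), lowest energy kept. The embedding seed derives
  from a CRC32 of the molecule id, so conformers are reproducible per
  molecule.
* **SC score** = (shape Tanimoto + color Tanimoto)/2 after rigidly aligning
  y onto x with O3A (Crippen fallback). The shape term is the analytic
  first-order Gaussian-volume overlap Tanimoto over heavy atoms
  (Grant–Pickup atom Gaussians, p = 2.7, widths matched to vdW radii). The
  color term is the same Gaussian overlap computed over pharmacophore
  feature points (donor, acceptor, aromatic, hydrophobe, ±ionizable;
  radius 1.5 Å), with cross-family overlap zero. If neither molecule has
  any feature the color term is 1.0 (nothing to mismatch); if exactly one
  has features it is 0.0. This keeps self-similarity at 1.0 and the score
  in [0, 1], invariant to rigid transforms up to the alignment optimizer's
  tolerance (≈1e-3 in practice, usually far better). The score is treated
  as symmetric and cached per unordered pair, with the lexically smaller
  canonical SMILES as the alignment reference.

## QSAR profiler

A multi-task feed-forward network on Morgan fingerprints: a shared trunk
with per-target linear regression heads, trained with mean squared error
summed only over observed (molecule, target) labels. Masking is what allows
one model across a sparse activity matrix; on a fully observed table the
masked loss is exactly plain MSE (tested). Defaults: 2048-bit input, hidden
layers (1024, 512), ReLU, dropout 0.2, Adam. At the few-hundred-molecule
scale used in the tests a single 128-unit hidden layer with dropout 0.1
generalizes better and trains in seconds, so the desk-scale runs use that
configuration. Profiler quality is reported as 5-fold cross-validation with
folds split by molecule; only targets with CV R² strictly above 0.70 are
considered reliable for virtual profiling.

## Conformer graph encoder

Each molecule is a heavy-atom graph with per-atom descriptors (element
one-hot over {C,N,O,S,F,Cl,Br,I,P,other}, degree one-hot, formal charge,
aromaticity, ring membership, total H count one-hot, hybridization one-hot;
30 dimensions) and 3D coordinates from the selected conformer. A linear
projection lifts the descriptors to the model width d, then each of 3
spatial message-passing layers updates

    h_i ← Σ_{j∈N_i} ReLU((Uᵀ(p_j − p_i) + b) ⊙ h_j)

with its own trainable U ∈ R^{3×d} and b ∈ R^d. The sum over an empty
neighborhood is the zero vector. Because only displacement vectors enter,
the operator is exactly translation invariant; it is deliberately *not*
rotation invariant — the gate learns directional geometry, and a regression
test asserts that rotations change the output. After the last layer a GRU
(hidden size d) runs over the atoms in canonical-SMILES order to produce
the final per-atom embeddings; sequence models are order-sensitive, which
is accepted and documented rather than hidden.

## Protein encoder

The conditioning vector H_p is produced by a pluggable backend. The default
is a hashed k-mer composition (k = 1..3, md5-hashed into 128 buckets,
L2-normalized): deterministic, offline, sensitive to point substitutions,
invariant to the sequence id. Any pretrained per-residue encoder (e.g. a
transformer protein language model) can be plugged in through an adapter
that mean-pools the residue matrix; the adapter reports its own dimension
and the conditioning layer fails fast on a mismatch.

## Transformer

Standard encoder–decoder with post-layer-norm residual blocks, multi-head
scaled dot-product attention (softmax(QKᵀ/√d_k)V) and ReLU position-wise
FFNs. The source molecule enters twice: token embeddings of its canonical
SMILES, and the graph encoder's per-atom vectors concatenated *at atomic
level* — each atom token gets its atom's vector (ring digits, branches and
bonds get zeros), identified through the canonical-SMILES atom output
order. A linear layer fuses the concatenation to the model width and
sinusoidal positional encodings are added (the architecture needs explicit
positions). The encoder output L (m × f) is conditioned on the protein by
broadcasting H_p along the sequence, concatenating to width f + k and
projecting back to f, so standard decoder cross-attention widths apply.
The decoder is causally masked; training is teacher-forced token
cross-entropy (optional label smoothing), Adam, one checkpoint per epoch
with the lowest-validation-loss checkpoint returned. Fine-tuning on a new
target is the same loop initialized from a saved checkpoint.

Generation is length-bounded beam search; width 1 reduces exactly to greedy
decoding (tested token-exact), pad/unk/start tokens are masked out of the
decode distribution, and candidates are ranked by total log-probability.

Defaults are 4+4 layers, 8 heads, f = 256; the test and acceptance runs use
a 2+2-layer, f = 64 model that memorizes a 30-pair corpus within 200 epochs
on one CPU core.

All neural components run on a small reverse-mode autodiff engine over
numpy arrays written for this package (`deephop.nn`); its gradients are
checked against finite differences and a hand-rolled GRU recurrence in the
test suite, and float32 with a fixed seed on a single thread makes training
bit-reproducible.

## Metrics

Validity (% of attempts parsing), uniqueness (% unique among valid),
novelty (% of valid absent from the training set), mean predicted activity
improvement, and hop success rates. A generation succeeds when it is valid,
satisfies the structural hop condition (scaffold Tanimoto ≤ 0.6 ∩ SC ≥ 0.6)
and does not lose predicted activity; the constrained variant requires a
gain ≥ 1. The denominator is *all* generation attempts — an invalid or
conformer-failing candidate counts as a failure — which makes
constraint success ≤ success ≤ validity a theorem rather than a tendency,
and matches aggregate reporting across targets (overall numbers are the
unweighted mean of per-target numbers). The source activity is the measured
value when available (test-set sources have one), otherwise the profiler's
prediction. "Internal diversity" (1 − mean pairwise Tanimoto) is exposed as
a clearly-labelled optional extra, not part of the headline suite.

## Synthetic data

The fixture generator emulates the *shape* of a multi-target kinase
bioactivity panel, not real SAR: a combinatorial library of 13 ring cores
(benzene, pyridine, pyrimidine, pyrazole, thiophene, cyclohexane,
naphthalene, biphenyl, piperidine, and disubstituted variants) decorated
with 17 common substituents, guaranteeing several distinct Bemis–Murcko
scaffolds; per-target activities linear in fingerprint bits (20 signal bits
per target, weights N(0,1)), standardized to mean 7 and spread 1.5 pChEMBL
units — a typical dynamic range for a kinase assay panel — plus Gaussian
noise, clipped to [4, 10]; and a configurable number of planted
cross-scaffold pairs whose activities are overwritten to (5.0, 6.5) so a
Δ = 1.5 hop exists per target regardless of noise. Planting guarantees the
activity and 2D predicates; whether a planted pair also clears the 3D gate
depends on the actual conformers, so tests assert rediscovery *up to* the
3D threshold. Protein targets get uniform random 200–400-residue
sequences. Everything is a pure function of the spec (sizes, noise,
seed).

Because activities are linear in fingerprint bits, QSAR recovery has a known
ground truth; because the library is tiny and the sequences random, passing
tests demonstrate correctness of the machinery, not performance on real
chemistry — no ChEMBL-scale claim follows from them.

## Numerical choices and degenerate inputs

* Tanimoto of two empty bit sets is 0 (and such pairs never reach mining).
* Tie-breaks in hop capping use canonical-SMILES lexical order.
* The uniform-prediction cross-entropy equals ln |vocab| per token and the
  perfect-prediction loss is 0 (closed forms used as test anchors).
* Conformer-embedding failures are warnings: the molecule is dropped from
  3D scoring (mining) or counted as a failed attempt (metrics), never a
  crash.
* Problem sizes in the test suite and acceptance run (30–500 molecules,
  2–3 targets, 3–5 conformers, 2-layer f=64 models, ≤300 training epochs)
  are chosen so the whole pipeline runs in minutes on one CPU core.

## Known limitations

* The SC score is one defensible member of the shape+color family; absolute
  values differ from other implementations (different Gaussian widths,
  feature definitions, weighting), though the [0, 1] scale and the
  0.6/0.8 fair/excellent interpretation carry over.
* The default protein backend carries composition information only; real
  transfer across kinases needs a pretrained language-model adapter.
* The graph encoder is order- and rotation-sensitive by construction.
* Generation quality at desk scale is limited by the tiny synthetic corpus;
  the paper-scale behaviour (tens of thousands of pairs, 40 targets) is out
  of reach on one CPU and is not claimed.
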