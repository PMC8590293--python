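"""Evaluation metrics for a scaffold-hop generation run.

Conventions:

* Validity — % of all generation attempts whose SMILES parses to a valid
  molecule.
* Uniqueness — unique canonical structures among the *valid* candidates, as
  a % of the valid count.
* Novelty — % of valid candidates whose canonical structure is absent from
  the training set.
* Improvement — mean predicted activity gain pBio(Y) − pBio(X) over valid
  candidates, in pChEMBL units; the source activity is the measured value
  when available, else the profiler's prediction.
* Success rate — % of all attempts that are valid, structurally a hop
  (scaffold Tanimoto ≤ 0.6 and SC score ≥ 0.6) and have a non-negative
  predicted gain; the *constraint* variant requires a gain ≥ 1.

Using all attempts as the success denominator (an invalid generation counts
as a failure) makes constraint success ≤ success ≤ validity hold on every
run.  Overall numbers are the unweighted mean of per-target numbers.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

from .chem import (ConformerError, InvalidMoleculeError, MoleculeRecord,
                   canonicalize, embed_conformers, morgan_fp,
                   scaffold_similarity_2d, sc_score, tanimoto)
from .pairs import HopThresholds
from .qsar import QsarModel

logger = logging.getLogger(__name__)


@dataclass
class GenerationAttempt:
    """One generated candidate for a (source, target) query."""
    source: MoleculeRecord
    candidate_smiles: str
    target_id: str
    source_pchembl: float | None = None   # measured activity of X when known


@dataclass
class EvalReport:
    validity: float
    uniqueness: float
    novelty: float
    improvement: float
    success_rate: float
    constraint_success_rate: float
    per_target: dict[str, dict[str, float]] = field(default_factory=dict)
    internal_diversity: float | None = None

    def __post_init__(self):
        for name in ("validity", "uniqueness", "novelty",
                     "success_rate", "constraint_success_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} must be a percentage, got {v}")
        if self.constraint_success_rate > self.success_rate + 1e-9:
            raise ValueError("constraint success cannot exceed success")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def _valid_canonical(smiles: str) -> str | None:
    try:
        return canonicalize(smiles).smiles
    except InvalidMoleculeError:
        return None


def validity(candidates: list[str]) -> float:
    """% of candidate SMILES that parse and sanitize."""
    if not candidates:
        raise ValueError("no candidates")
    ok = sum(_valid_canonical(c) is not None for c in candidates)
    return 100.0 * ok / len(candidates)


def uniqueness(candidates: list[str]) -> float:
    """Unique canonical structures ÷ valid candidates, as a percentage."""
    valid = [s for s in (_valid_canonical(c) for c in candidates) if s is not None]
    if not valid:
        warnings.warn("uniqueness undefined with no valid candidates; reporting 0")
        return 0.0
    return 100.0 * len(set(valid)) / len(valid)


def novelty(candidates: list[str], training_molecules: set[str]) -> float:
    """% of valid candidates not present in the (canonicalized) training set."""
    valid = [s for s in (_valid_canonical(c) for c in candidates) if s is not None]
    if not valid:
        return 0.0
    novel = sum(s not in training_molecules for s in valid)
    return 100.0 * novel / len(valid)


def _source_activity(attempt: GenerationAttempt, qsar: QsarModel) -> float:
    if attempt.source_pchembl is not None:
        return attempt.source_pchembl
    return qsar.predict(attempt.source, attempt.target_id)


def improvement(attempts: list[GenerationAttempt], qsar: QsarModel) -> float:
    """Mean predicted gain pBio(Y) − pBio(X) over valid candidates."""
    deltas = []
    for a in attempts:
        can = _valid_canonical(a.candidate_smiles)
        if can is None:
            continue
        y = canonicalize(can)
        deltas.append(qsar.predict(y, a.target_id) - _source_activity(a, qsar))
    if not deltas:
        return 0.0
    return float(sum(deltas) / len(deltas))


def success_rate(attempts: list[GenerationAttempt], qsar: QsarModel,
                 thresholds: HopThresholds = HopThresholds(),
                 constrained: bool = False, n_conf: int = 5,
                 sim3d_cache: dict | None = None) -> float:
    """% of attempts that are valid, structurally a hop, and improve activity.

    The gain cutoff is ≥ 0 (relaxed) or ≥ ``thresholds.min_delta``
    (constrained).  Candidates whose conformer embedding fails count as
    non-success.
    """
    if not attempts:
        raise ValueError("no attempts")
    sim3d_cache = sim3d_cache if sim3d_cache is not None else {}
    wins = 0
    for a in attempts:
        if _evaluate_attempt(a, qsar, thresholds, constrained, n_conf, sim3d_cache):
            wins += 1
    return 100.0 * wins / len(attempts)


def _evaluate_attempt(a: GenerationAttempt, qsar: QsarModel,
                      thresholds: HopThresholds, constrained: bool,
                      n_conf: int, sim3d_cache: dict) -> bool:
    can = _valid_canonical(a.candidate_smiles)
    if can is None:
        return False
    y = canonicalize(can, mol_id=can)
    if scaffold_similarity_2d(a.source, y) > thresholds.max_sim2d:
        return False
    key = (a.source.smiles, can)
    if key not in sim3d_cache:
        try:
            x3 = (a.source if a.source.conformer is not None
                  else embed_conformers(a.source, n_conf=n_conf))
            y3 = embed_conformers(y, n_conf=n_conf)
            sim3d_cache[key] = sc_score(x3, y3)
        except ConformerError as exc:
            logger.warning("conformer failure for %s: %s", can, exc)
            sim3d_cache[key] = None
    if sim3d_cache[key] is None or sim3d_cache[key] < thresholds.min_sim3d:
        return False
    delta = qsar.predict(y, a.target_id) - _source_activity(a, qsar)
    return delta >= (thresholds.min_delta if constrained else 0.0)


def internal_diversity(candidates: list[str]) -> float:
    """1 − mean pairwise Tanimoto over valid candidates (optional extra).

    Not part of the headline metric suite; exposed because a "diversity"
    number is often wanted alongside it.
    """
    valid = [s for s in (_valid_canonical(c) for c in candidates) if s is not None]
    if len(valid) < 2:
        return 0.0
    fps = [morgan_fp(canonicalize(s)) for s in valid]
    sims = [tanimoto(fps[i], fps[j])
            for i in range(len(fps)) for j in range(i + 1, len(fps))]
    return 1.0 - sum(sims) / len(sims)


def evaluate(attempts: list[GenerationAttempt], qsar: QsarModel,
             training_molecules: set[str],
             thresholds: HopThresholds = HopThresholds(),
             n_conf: int = 5, with_diversity: bool = False) -> EvalReport:
    """Full metric suite, per target and averaged (unweighted over targets)."""
    by_target: dict[str, list[GenerationAttempt]] = {}
    for a in attempts:
        by_target.setdefault(a.target_id, []).append(a)
    per_target: dict[str, dict[str, float]] = {}
    cache: dict = {}
    for t, atts in sorted(by_target.items()):
        cands = [a.candidate_smiles for a in atts]
        per_target[t] = {
            "validity": validity(cands),
            "uniqueness": uniqueness(cands),
            "novelty": novelty(cands, training_molecules),
            "improvement": improvement(atts, qsar),
            "success_rate": success_rate(atts, qsar, thresholds, False,
                                         n_conf, cache),
            "constraint_success_rate": success_rate(atts, qsar, thresholds,
                                                    True, n_conf, cache),
        }
    def avg(key):
        return float(sum(v[key] for v in per_target.values()) / len(per_target))
    report = EvalReport(
        validity=avg("validity"), uniqueness=avg("uniqueness"),
        novelty=avg("novelty"), improvement=avg("improvement"),
        success_rate=avg("success_rate"),
        constraint_success_rate=avg("constraint_success_rate"),
        per_target=per_target)
    if with_diversity:
        report.internal_diversity = internal_diversity(
            [a.candidate_smiles for a in attempts])
    return report
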