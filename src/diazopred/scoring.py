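"""Nearest-neighbor probability scoring for diazotroph association.

A query metabolite is scored by finding the most Tanimoto-similar labeled
reference metabolite and converting that similarity s and the neighbor's
class indicator I_NN into a probability:

    P(FIX=1 | s) = 0.5 + 0.5 * s * (2*I_NN - 1)

so s = 0 is complete ignorance (0.5) and s = 1 full confidence in the
neighbor's class.  The class decision threshold is a strict > 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Tuple

from .fingerprints import Fingerprint, tanimoto

DECISION_THRESHOLD = 0.5


@dataclass(frozen=True)
class SimilarityResult:
    """Nearest labeled neighbor of one query."""

    query_id: str
    nn_id: str
    similarity: float
    nn_class: int
    tie_count: int = 1
    conflict: bool = False  # maximal-similarity tie spans both classes


@dataclass(frozen=True)
class PredictionResult:
    query_id: str
    probability: float
    predicted_class: int
    similarity: float
    nn_id: str
    nn_class: int


def nearest_labeled_neighbor(
    query_id: str,
    query_fp: Fingerprint,
    references: Mapping[str, Tuple[Fingerprint, int]],
    exclude: Optional[Iterable[str]] = None,
) -> SimilarityResult:
    """Argmax-Tanimoto scan over the labeled reference fingerprints.

    ``exclude`` removes reference ids (holdout discipline: a query being
    evaluated must not see itself).  Ties at the maximal similarity are
    counted; among tied references the lexicographically smallest id is
    reported, and a tie spanning both classes sets ``conflict``.
    """
    excluded = set(exclude or ())
    best_sim = -1.0
    tied: list[str] = []
    for ref_id in references:
        if ref_id in excluded:
            continue
        sim = tanimoto(query_fp, references[ref_id][0])
        if sim > best_sim:
            best_sim = sim
            tied = [ref_id]
        elif sim == best_sim:
            tied.append(ref_id)
    if not tied:
        raise ValueError("reference set is empty after exclusions")
    tied.sort()
    classes = {references[t][1] for t in tied}
    return SimilarityResult(
        query_id=query_id,
        nn_id=tied[0],
        similarity=best_sim,
        nn_class=references[tied[0]][1],
        tie_count=len(tied),
        conflict=len(classes) > 1,
    )


def predict(sim: SimilarityResult) -> PredictionResult:
    """Convert a similarity result into a probability and class decision.

    A conflicting-class tie at the maximal similarity collapses to maximal
    uncertainty (probability exactly 0.5), which the strict threshold maps to
    class 0 — conservative toward a positive diazotrophy call.
    """
    if sim.conflict:
        probability = 0.5
    else:
        probability = 0.5 + 0.5 * sim.similarity * (2 * sim.nn_class - 1)
    predicted = 1 if probability > DECISION_THRESHOLD else 0
    return PredictionResult(
        query_id=sim.query_id,
        probability=probability,
        predicted_class=predicted,
        similarity=sim.similarity,
        nn_id=sim.nn_id,
        nn_class=sim.nn_class,
    )


def score_batch(
    queries: Mapping[str, Fingerprint],
    references: Mapping[str, Tuple[Fingerprint, int]],
    exclude_self: bool = False,
) -> list[PredictionResult]:
    """Score every query against the labeled references.

    Results are sorted by descending probability (ties by query id), forming
    a most-to-least-likely diazotroph-association ranking.  With
    ``exclude_self`` each query id is removed from its own reference scan.
    """
    if not references:
        raise ValueError("reference set is empty")
    results = []
    for query_id in queries:
        exclude = {query_id} if exclude_self else None
        sim = nearest_labeled_neighbor(query_id, queries[query_id], references, exclude)
        results.append(predict(sim))
    results.sort(key=lambda r: (-r.probability, r.query_id))
    return results
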