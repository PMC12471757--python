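"""Strain-level rollups and exclusivity summaries.

Scored metabolites are grouped by producing strain; a strain's evidence for
diazotrophy is the maximum probability over its metabolites, with the number
of unique structures as supporting context.  The exclusivity summary reports
how private metabolite structures are to a single genus or strain, which is
what makes structural similarity informative about the producer's lineage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from rdkit import Chem

from .data import Dataset
from .scoring import PredictionResult

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StrainRanking:
    strain_key: tuple
    max_probability: float
    metabolite_count: int
    top_metabolite_id: str


def _canonical_structure(record) -> str:
    """Canonical SMILES, falling back to the compound name, then the id."""
    mol = Chem.MolFromSmiles(record.smiles) if record.smiles else None
    if mol is not None:
        return Chem.MolToSmiles(mol)
    return record.compound_name or record.compound_id


def rank_strains(
    predictions: Sequence[PredictionResult], dataset: Dataset
) -> list[StrainRanking]:
    """Roll metabolite predictions up to producing strains.

    Per strain: the maximum probability, the metabolite attaining it, and the
    number of unique structures scored.  Sorted by descending max
    probability, then descending metabolite count, then strain key.
    """
    by_id = dataset.by_id()
    groups: dict[tuple, list] = {}
    for pred in predictions:
        record = by_id.get(pred.query_id)
        if record is None:
            log.warning("prediction for unknown compound %s ignored", pred.query_id)
            continue
        groups.setdefault(record.strain_key, []).append((pred, record))

    rankings = []
    for key, members in groups.items():
        best = max(members, key=lambda m: (m[0].probability, m[0].query_id))
        structures = {_canonical_structure(rec) for _, rec in members}
        rankings.append(
            StrainRanking(
                strain_key=key,
                max_probability=best[0].probability,
                metabolite_count=len(structures),
                top_metabolite_id=best[0].query_id,
            )
        )
    rankings.sort(
        key=lambda r: (-r.max_probability, -r.metabolite_count, r.strain_key)
    )
    return rankings


def exclusivity_summary(dataset: Dataset) -> dict:
    """Fractions of metabolites observed in exactly one genus / one strain.

    Metabolites are grouped by canonical structure (name or id when the
    structure does not parse); only records with a genus are considered.
    """
    genera: dict[str, set] = {}
    strains: dict[str, set] = {}
    for record in dataset:
        if not str(record.genus).strip():
            continue
        key = _canonical_structure(record)
        genera.setdefault(key, set()).add(record.strain_key[0])
        strains.setdefault(key, set()).add(record.strain_key)
    n = len(genera)
    if n == 0:
        return {"n_structures": 0, "genus_exclusive": float("nan"),
                "strain_exclusive": float("nan")}
    return {
        "n_structures": n,
        "genus_exclusive": sum(1 for g in genera.values() if len(g) == 1) / n,
        "strain_exclusive": sum(1 for s in strains.values() if len(s) == 1) / n,
    }
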