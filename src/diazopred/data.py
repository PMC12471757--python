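"""Metabolite and strain tables and the diazotrophy (FIX) labeling rules.

The central objects are :class:`MetaboliteRecord` (one metabolite from one
producing organism) and :class:`Dataset` (an ordered collection with
provenance).  Organism-level diazotrophy labels are derived from nitrogenase
marker proteins: a strain with any of NifH/NifD/NifK in its reported proteome
is diazotrophic (FIX=1); a strain with none of them is non-diazotrophic
(FIX=0) only if its proteome is large enough that the absence is informative,
otherwise it stays unlabeled.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

import pandas as pd

log = logging.getLogger(__name__)

#: Sentinel for a record or strain without a FIX label.
UNLABELED = None

#: Default column names for a metabolite CSV (role -> column).
DEFAULT_COLUMN_MAP = {
    "compound_id": "compound_id",
    "compound_name": "compound_name",
    "smiles": "smiles",
    "genus": "genus",
    "species": "species",
    "strain": "strain",
    "fix": "fix",
}


@dataclass
class MetaboliteRecord:
    """One metabolite entry: structure plus producing-organism metadata."""

    compound_id: str
    compound_name: str
    smiles: str
    genus: str = ""
    species: str = ""
    strain: str = ""
    fix_label: Optional[int] = UNLABELED  # 1, 0 or UNLABELED

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError(f"record {self.compound_id!r}: empty SMILES")
        if self.fix_label not in (0, 1, UNLABELED):
            raise ValueError(
                f"record {self.compound_id!r}: fix_label must be 0, 1 or UNLABELED"
            )

    @property
    def strain_key(self) -> tuple[str, str, str]:
        return strain_key(self.genus, self.species, self.strain)


@dataclass(frozen=True)
class StrainAnnotation:
    """Nif marker presence and proteome size for one strain."""

    genus: str
    species: str
    strain: str
    has_nifH: bool
    has_nifD: bool
    has_nifK: bool
    proteome_size: int

    def __post_init__(self) -> None:
        if self.proteome_size < 0:
            raise ValueError("proteome_size must be >= 0")

    @property
    def key(self) -> tuple[str, str, str]:
        return strain_key(self.genus, self.species, self.strain)


@dataclass
class Dataset:
    """An ordered collection of metabolite records with provenance metadata."""

    records: list[MetaboliteRecord] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MetaboliteRecord]:
        return iter(self.records)

    def labeled(self) -> list[MetaboliteRecord]:
        return [r for r in self.records if r.fix_label in (0, 1)]

    def unlabeled(self) -> list[MetaboliteRecord]:
        return [r for r in self.records if r.fix_label is UNLABELED]

    def by_id(self) -> dict[str, MetaboliteRecord]:
        return {r.compound_id: r for r in self.records}


def strain_key(genus: str, species: str, strain: str) -> tuple[str, str, str]:
    """Normalized (genus, species, strain) identity: trimmed and case-folded."""
    return (
        str(genus).strip().casefold(),
        str(species).strip().casefold(),
        str(strain).strip().casefold(),
    )


def _parse_fix(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return UNLABELED
    text = str(value).strip()
    if text == "" or text.lower() in ("na", "nan", "none"):
        return UNLABELED
    num = float(text)
    if num not in (0.0, 1.0):
        raise ValueError(f"FIX value must be 0, 1 or empty; got {value!r}")
    return int(num)


def read_metabolite_csv(
    path, column_map: Optional[Mapping[str, str]] = None
) -> Dataset:
    """Read a metabolite table (UTF-8 CSV with a header row).

    ``column_map`` maps roles (``compound_id``, ``compound_name``, ``smiles``,
    ``genus``, ``species``, ``strain``, ``fix``) to column names in the file.
    Rows whose FIX column is empty become UNLABELED.  Duplicate compound ids
    are a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)

    required = ["compound_id", "compound_name", "smiles"]
    for role in required:
        if cmap[role] not in frame.columns:
            raise KeyError(
                f"metabolite CSV {path} is missing mapped column "
                f"{cmap[role]!r} (role {role!r})"
            )

    records: list[MetaboliteRecord] = []
    seen: set[str] = set()
    for _, row in frame.iterrows():
        cid = row[cmap["compound_id"]].strip()
        if cid in seen:
            raise ValueError(f"duplicate compound_id {cid!r} in {path}")
        seen.add(cid)
        fix_col = cmap["fix"]
        fix = _parse_fix(row[fix_col]) if fix_col in frame.columns else UNLABELED
        records.append(
            MetaboliteRecord(
                compound_id=cid,
                compound_name=row.get(cmap["compound_name"], ""),
                smiles=row[cmap["smiles"]].strip(),
                genus=row.get(cmap["genus"], ""),
                species=row.get(cmap["species"], ""),
                strain=row.get(cmap["strain"], ""),
                fix_label=fix,
            )
        )
    return Dataset(records=records, provenance={"source": str(path), "rows": len(records)})


def read_strain_annotations_csv(path) -> list[StrainAnnotation]:
    """Read a strain annotation table (genus, species, strain, Nif flags, proteome size)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    truthy = {"1", "true", "yes", "t", "y"}
    out = []
    for _, row in frame.iterrows():
        out.append(
            StrainAnnotation(
                genus=row["genus"],
                species=row.get("species", ""),
                strain=row.get("strain", ""),
                has_nifH=row.get("has_nifH", "").strip().lower() in truthy,
                has_nifD=row.get("has_nifD", "").strip().lower() in truthy,
                has_nifK=row.get("has_nifK", "").strip().lower() in truthy,
                proteome_size=int(float(row.get("proteome_size", "0") or 0)),
            )
        )
    return out


def assign_fix_labels(
    annotations: Iterable[StrainAnnotation], min_proteome: int = 100
) -> dict[tuple[str, str, str], Optional[int]]:
    """Derive FIX labels from Nif marker presence and proteome size.

    Any Nif protein present -> 1.  No Nif proteins and a proteome strictly
    larger than ``min_proteome`` -> 0 (the absence is believed).  No Nif
    proteins and a proteome of at most ``min_proteome`` -> UNLABELED, since a
    shallow proteome cannot rule diazotrophy out.
    """
    labels: dict[tuple[str, str, str], Optional[int]] = {}
    for ann in annotations:
        if ann.has_nifH or ann.has_nifD or ann.has_nifK:
            label = 1
        elif ann.proteome_size > min_proteome:
            label = 0
        else:
            label = UNLABELED
        if ann.key in labels and labels[ann.key] != label:
            raise ValueError(
                f"conflicting duplicate annotations for strain {ann.key}"
            )
        labels[ann.key] = label
    return labels


def join_labels(
    dataset: Dataset, labels: Mapping[tuple[str, str, str], Optional[int]]
) -> Dataset:
    """Return a new Dataset with each record's FIX label set from its strain.

    Records whose strain is absent from the mapping become UNLABELED.
    """
    normalized = {strain_key(*k): v for k, v in labels.items()}
    records = [
        replace(rec, fix_label=normalized.get(rec.strain_key, UNLABELED))
        for rec in dataset.records
    ]
    provenance = dict(dataset.provenance)
    provenance["labeled"] = sum(1 for r in records if r.fix_label in (0, 1))
    return Dataset(records=records, provenance=provenance)


def write_predictions_csv(results, path, names: Optional[Mapping[str, str]] = None) -> None:
    """Write prediction results sorted by descending probability.

    Columns: compound_id, compound_name, nn_compound_id, similarity,
    probability, predicted_class.  ``names`` optionally maps compound ids to
    display names.  Probabilities are printed with six decimals (at least the
    three the output contract requires).
    """
    results = list(results)
    if not results:
        raise ValueError("no prediction results to write")
    names = dict(names or {})
    rows = sorted(results, key=lambda r: (-r.probability, r.query_id))
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "compound_id",
                "compound_name",
                "nn_compound_id",
                "similarity",
                "probability",
                "predicted_class",
            ]
        )
        for r in rows:
            writer.writerow(
                [
                    r.query_id,
                    names.get(r.query_id, getattr(r, "compound_name", "")),
                    r.nn_id,
                    f"{r.similarity:.6f}",
                    f"{r.probability:.6f}",
                    r.predicted_class,
                ]
            )


def read_sdf_structures(path, id_property: str = "compound_id") -> dict[str, str]:
    """Read an SDF file and return compound_id -> canonical SMILES.

    Molecules are matched to metabolite records by the named SDF property.
    Unparseable molecules and molecules missing the property are skipped with
    a log message.
    """
    from rdkit import Chem

    out: dict[str, str] = {}
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            log.warning("SDF %s: molecule %d failed to parse; skipped", path, i)
            continue
        if not mol.HasProp(id_property):
            log.warning("SDF %s: molecule %d lacks property %r; skipped", path, i, id_property)
            continue
        out[mol.GetProp(id_property)] = Chem.MolToSmiles(mol)
    return out


def write_run_report(path, payload: dict) -> None:
    """Write a JSON run report (config echo, counts, warnings)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
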