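"""Derive FIX labels from strain annotations and join them onto metabolites.

A strain with any nitrogenase marker protein (NifH/NifD/NifK) is labeled
diazotrophic.  A strain with none of them is labeled non-diazotrophic only if
its reported proteome exceeds 100 proteins; smaller proteomes stay unlabeled
because the absence of nif markers in a shallow proteome is uninformative.
"""

from diazopred import (
    StrainAnnotation,
    assign_fix_labels,
    join_labels,
)
from diazopred.data import Dataset, MetaboliteRecord

annotations = [
    StrainAnnotation("Nostoc", "sp.", "PCC-7120", True, True, True, 6100),
    StrainAnnotation("Microcystis", "aeruginosa", "NIES-843", False, False, False, 6300),
    StrainAnnotation("Schizothrix", "sp.", "IL-208", False, False, False, 40),
]
labels = assign_fix_labels(annotations)
for ann in annotations:
    value = labels[ann.key]
    print(f"{ann.genus:14s} {ann.strain:10s} proteome={ann.proteome_size:5d} "
          f"-> FIX={'unlabeled' if value is None else value}")

metabolites = Dataset(records=[
    MetaboliteRecord("M1", "anabaenopeptin-like", "O=C1C(CCCCN)NC(=O)CN1",
                     genus="Nostoc", species="sp.", strain="PCC-7120"),
    MetaboliteRecord("M2", "microcystin-like", "CC(=O)CC(Cl)C(=O)O",
                     genus="Microcystis", species="aeruginosa", strain="NIES-843"),
    MetaboliteRecord("M3", "uncharacterized", "O=C1CNC(=O)CN1",
                     genus="Schizothrix", species="sp.", strain="IL-208"),
])
joined = join_labels(metabolites, labels)
print()
for r in joined:
    print(f"{r.compound_id}: {r.compound_name:20s} "
          f"FIX={'unlabeled' if r.fix_label is None else r.fix_label}")
print("\nOnly labeled metabolites enter the reference set; unlabeled ones")
print("become queries to be ranked.")
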