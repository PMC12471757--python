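"""Rank candidate strains by their strongest diazotroph-associated metabolite.

Uses a labeled synthetic reference set to score a second, unlabeled batch,
rolls the per-metabolite probabilities up to producing strains, and prints
the top candidates (max probability, unique-metabolite count) together with
the structure-exclusivity summary.
"""

import dataclasses

from diazopred import (
    SimConfig,
    exclusivity_summary,
    fingerprint_dataset,
    generate_dataset,
    rank_strains,
    score_batch,
)
from diazopred.data import Dataset
from diazopred.fingerprints import FingerprintConfig

references = generate_dataset(SimConfig(n_pos=20, n_neg=20, seed=1))
unknowns = generate_dataset(SimConfig(n_pos=12, n_neg=12, seed=99))
# strip labels: these records play the role of uncharacterized strains
unknowns = Dataset(records=[
    dataclasses.replace(r, compound_id="U" + r.compound_id, fix_label=None)
    for r in unknowns
])

config = FingerprintConfig(n_bits=4096)
ref_fps, _ = fingerprint_dataset(references, config)
unk_fps, _ = fingerprint_dataset(unknowns, config)
labels = {r.compound_id: r.fix_label for r in references}

predictions = score_batch(unk_fps, {c: (fp, labels[c]) for c, fp in ref_fps.items()})
rankings = rank_strains(predictions, unknowns)

print(f"{'genus':14s} {'strain':10s} {'max P':>7s} {'count':>6s}")
for r in rankings[:8]:
    print(f"{r.strain_key[0]:14s} {r.strain_key[2]:10s} "
          f"{r.max_probability:7.3f} {r.metabolite_count:6d}")

summary = exclusivity_summary(unknowns)
print(f"\n{summary['n_structures']} unique structures; "
      f"{100 * summary['genus_exclusive']:.0f}% private to one genus, "
      f"{100 * summary['strain_exclusive']:.0f}% to one strain.")
print("Strains at the top are the best candidates for follow-up sequencing")
print("of nitrogen-fixation (nif) genes.")
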