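"""Score unknown metabolites against a labeled reference set.

Builds a tiny labeled reference set (two diazotroph-associated cyclic
peptides, two halogenated non-diazotroph metabolites), then scores three
query structures and prints the probability that each producer is
diazotrophic.  A probability above 0.5 predicts a diazotroph; 0.5 means the
structure carries no usable evidence.
"""

from diazopred import FingerprintConfig, fingerprint_dataset, score_batch
from diazopred.data import Dataset, MetaboliteRecord


def record(cid, smiles, fix=None):
    return MetaboliteRecord(compound_id=cid, compound_name=cid, smiles=smiles,
                            genus="Example", species="sp.", strain=cid,
                            fix_label=fix)


references = Dataset(records=[
    record("pep-A", "O=C1C(CCCCN)NC(=O)C(CC(C)C)NC(=O)C(CO)N1", fix=1),
    record("pep-B", "O=C1C(CO)NC(=O)CNC(=O)C(C)N1", fix=1),
    record("hal-A", "CC(=O)C(Cl)CC(Br)C(=O)C", fix=0),
    record("hal-B", "C(Cl)C(Cl)CC(=O)CC(O)C", fix=0),
])

queries = Dataset(records=[
    record("query-peptide", "O=C1C(CCCCN)NC(=O)C(C)NC(=O)C(CO)N1"),
    record("query-halide", "CC(=O)C(Cl)CC(Cl)C(=O)C"),
    record("query-alien", "c1ccc2ccccc2c1"),  # resembles neither class
])

config = FingerprintConfig()  # path fingerprint, depth 30, 262,144 bits
ref_fps, _ = fingerprint_dataset(references, config)
query_fps, _ = fingerprint_dataset(queries, config)
labels = {r.compound_id: r.fix_label for r in references}

results = score_batch(query_fps, {c: (fp, labels[c]) for c, fp in ref_fps.items()})

print(f"{'query':16s} {'nearest':10s} {'s':>6s} {'P(FIX=1)':>9s} {'class':>6s}")
for r in results:
    print(f"{r.query_id:16s} {r.nn_id:10s} {r.similarity:6.3f} "
          f"{r.probability:9.3f} {r.predicted_class:6d}")
print("\nP(FIX=1) = 0.5 + 0.5*s*(2*I_NN - 1): similarity to a labeled")
print("metabolite pulls the probability toward that neighbor's class.")
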