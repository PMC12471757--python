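"""Shared fixtures and independent oracles for the test suite.

The oracle functions here are deliberately written from first principles
(brute-force enumeration, explicit pair counting) and never call the package
code paths they are used to check.
"""

from __future__ import annotations

from itertools import combinations

import pytest
from rdkit import Chem

from diazopred import Dataset, MetaboliteRecord, SimConfig, generate_dataset
from diazopred.fingerprints import FingerprintConfig

# small configuration used throughout the tests: full depth, fewer bits
SMALL_FP = FingerprintConfig(fp_type="path", depth=30, n_bits=4096)

_BOND_CHAR = {1.0: "-", 2.0: "=", 3.0: "#", 1.5: ":"}


def oracle_enumerate_paths(smiles: str, depth: int) -> set:
    """Brute-force simple-path enumerator working directly on an RDKit mol.

    Independent of the package's graph representation and DFS: enumerates
    every ordered simple atom sequence of 0..depth bonds by breadth-first
    extension over explicit neighbor lists, encodes both directions and keeps
    the lexicographic minimum.
    """
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, smiles

    def token(atom):
        return atom.GetSymbol().lower() if atom.GetIsAromatic() else atom.GetSymbol()

    sequences = [[i] for i in range(mol.GetNumAtoms())]
    out = set()
    for length in range(depth + 1):
        next_sequences = []
        for seq in sequences:
            atoms = [token(mol.GetAtomWithIdx(i)) for i in seq]
            bonds = [
                _BOND_CHAR[
                    mol.GetBondBetweenAtoms(seq[i], seq[i + 1]).GetBondTypeAsDouble()
                ]
                for i in range(len(seq) - 1)
            ]
            forward = atoms[0] + "".join(b + a for b, a in zip(bonds, atoms[1:]))
            backward = atoms[-1] + "".join(
                b + a for b, a in zip(reversed(bonds), reversed(atoms[:-1]))
            )
            out.add(min(forward, backward))
            for nbr in mol.GetAtomWithIdx(seq[-1]).GetNeighbors():
                if nbr.GetIdx() not in seq:
                    next_sequences.append(seq + [nbr.GetIdx()])
        sequences = next_sequences
        if not sequences:
            break
    return out


def oracle_auc(y_true, scores) -> float:
    """Fraction of correctly ordered (positive, negative) pairs, ties at 0.5."""
    positives = [s for y, s in zip(y_true, scores) if y == 1]
    negatives = [s for y, s in zip(y_true, scores) if y == 0]
    assert positives and negatives
    total = 0.0
    for p in positives:
        for n in negatives:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(positives) * len(negatives))


def oracle_tanimoto(a: set, b: set) -> float:
    """Set-arithmetic Tanimoto on raw bit sets."""
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def make_dataset(rows) -> Dataset:
    """Dataset from (id, smiles, fix_label) or (id, smiles, fix, genus,
    species, strain) tuples."""
    records = []
    for row in rows:
        cid, smiles, fix = row[:3]
        genus, species, strain = (row[3:6] if len(row) > 3 else ("G", "sp", "S1"))
        records.append(
            MetaboliteRecord(
                compound_id=cid, compound_name=cid, smiles=smiles,
                genus=genus, species=species, strain=strain, fix_label=fix,
            )
        )
    return Dataset(records=records)


@pytest.fixture(scope="session")
def separable_dataset() -> Dataset:
    """30+30 perfectly separated chemotypes, no label noise (seed 1)."""
    return generate_dataset(
        SimConfig(n_pos=30, n_neg=30, separation=1.0, label_noise=0.0, seed=1)
    )


@pytest.fixture(scope="session")
def small_dataset() -> Dataset:
    """Small hand-built set: two near-identical pairs per class."""
    return make_dataset(
        [
            ("P1", "O=C1CNC(=O)CN1", 1),
            ("P2", "O=C1CNC(=O)C(C)N1", 1),
            ("H1", "ClCCCCCl", 0),
            ("H2", "ClCCCCBr", 0),
        ]
    )
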