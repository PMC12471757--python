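"""Synthetic metabolite datasets with controllable class structure.

Two chemotypes mirror the contrast observed between real diazotroph- and
non-diazotroph-associated cyanobacterial metabolites:

* class 1: homodetic cyclic peptides (high nitrogen, many amide bonds,
  macrocyclic), built from a small alphabet of proteinogenic-like side
  chains including two nitrogen-rich ones;
* class 0: halogenated polyketide-like chains with no nitrogen.

``separation`` controls how faithfully a record's structure matches its
class: the chemotype matching the class is drawn with probability
0.5 + separation/2, so separation = 1 gives structurally disjoint classes
and separation = 0 removes the structural signal entirely.  ``label_noise``
flips labels independently after the structures are drawn.  Everything is
reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .data import Dataset, MetaboliteRecord
from .fingerprints import parse_smiles

#: Side-chain fragments attached to the alpha carbon ("" = glycine).  Two are
#: nitrogen-rich (lysine- and arginine-like), mirroring the N-dense residues
#: common in diazotroph-associated cyclic peptides.
DEFAULT_RESIDUE_ALPHABET: tuple = (
    "",            # glycine
    "C",           # alanine
    "CC(C)C",      # leucine-like
    "CO",          # serine-like
    "C(C)O",       # threonine-like
    "Cc1ccccc1",   # phenylalanine-like
    "CCCCN",       # lysine-like
    "CCCNC(=N)N",  # arginine-like
)

_SCAFFOLD_UNITS = ("C", "CC(=O)", "C(O)", "C=C")
_HALOGENS = ("Cl", "Br")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset."""

    n_pos: int = 30
    n_neg: int = 30
    separation: float = 1.0
    label_noise: float = 0.0
    peptide_length_range: tuple = (3, 8)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.separation <= 1.0:
            raise ValueError("separation must be in [0, 1]")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must be in [0, 1]")
        lo, hi = self.peptide_length_range
        if lo < 2 or hi < lo:
            raise ValueError("peptide_length_range must be (lo, hi) with lo >= 2")
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("class sizes must be non-negative")


def gen_cyclic_peptide(
    n_residues: int,
    alphabet: Sequence[str] = DEFAULT_RESIDUE_ALPHABET,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """SMILES of a homodetic cyclic peptide with ``n_residues`` residues.

    The backbone repeats N-Calpha-C(=O) and is ring-closed, so the molecule
    carries exactly ``n_residues`` backbone amide bonds and at least one
    ring.  Side chains are drawn uniformly from ``alphabet``.
    """
    if n_residues < 2:
        raise ValueError("a cyclic peptide needs at least 2 residues")
    rng = rng or np.random.default_rng()
    for fragment in alphabet:
        if fragment and parse_smiles_safe(fragment) is None:
            raise ValueError(f"invalid side-chain fragment SMILES: {fragment!r}")
    side_chains = [alphabet[rng.integers(len(alphabet))] for _ in range(n_residues)]

    def alpha(fragment: str) -> str:
        return f"C({fragment})" if fragment else "C"

    # ring-closure label %10 cannot collide with single-digit ring bonds
    # inside side-chain fragments (e.g. an aromatic ring's "1")
    smiles = "O=C%10"
    for fragment in side_chains[:-1]:
        smiles += f"{alpha(fragment)}NC(=O)"
    smiles += f"{alpha(side_chains[-1])}N%10"
    parse_smiles(smiles)  # construction guarantees validity; fail loudly if not
    return smiles


def gen_halogenated_scaffold(
    n_units: int,
    halogen_rate: float = 0.5,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """SMILES of a linear polyketide-like chain with random halogenation.

    Units are drawn from methylene, ketone, hydroxyl and alkene fragments;
    each unit independently receives a Cl or Br substituent with probability
    ``halogen_rate``.  Contains no nitrogen.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    rng = rng or np.random.default_rng()
    parts = []
    for _ in range(n_units):
        unit = _SCAFFOLD_UNITS[rng.integers(len(_SCAFFOLD_UNITS))]
        if rng.random() < halogen_rate:
            halogen = _HALOGENS[rng.integers(len(_HALOGENS))]
            unit = f"C({halogen})" + unit[1:]
        parts.append(unit)
    smiles = "".join(parts)
    parse_smiles(smiles)
    return smiles


def parse_smiles_safe(smiles: str):
    """Parse a SMILES, returning None instead of raising on failure."""
    from .fingerprints import SmilesParseError

    try:
        return parse_smiles(smiles)
    except SmilesParseError:
        return None


def generate_dataset(config: SimConfig = SimConfig()) -> Dataset:
    """Generate a labeled synthetic metabolite dataset per ``config``.

    Records are grouped three-per-strain within each class so that
    strain-level rollups and exclusivity summaries are exercised.  The
    produced table has the same schema as a real metabolite CSV.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.peptide_length_range
    records: list[MetaboliteRecord] = []
    index = 0
    for true_class, count in ((1, config.n_pos), (0, config.n_neg)):
        for j in range(count):
            match = rng.random() < 0.5 + config.separation / 2
            chemotype = true_class if match else 1 - true_class
            if chemotype == 1:
                smiles = gen_cyclic_peptide(
                    int(rng.integers(lo, hi + 1)), rng=rng
                )
            else:
                smiles = gen_halogenated_scaffold(
                    int(rng.integers(4, 11)), halogen_rate=0.5, rng=rng
                )
            label = true_class
            if rng.random() < config.label_noise:
                label = 1 - label
            prefix = "Dzg" if true_class == 1 else "Nfx"
            strain_index = j // 3
            records.append(
                MetaboliteRecord(
                    compound_id=f"SYN{index:04d}",
                    compound_name=f"synthetic metabolite {index}",
                    smiles=smiles,
                    genus=f"{prefix}genus{strain_index}",
                    species="sp.",
                    strain=f"{prefix.upper()}-{strain_index:03d}",
                    fix_label=label,
                )
            )
            index += 1
    return Dataset(
        records=records,
        provenance={
            "generator": "diazopred.simulate",
            "config": config.__dict__.copy(),
        },
    )
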