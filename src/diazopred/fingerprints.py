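"""Hashed path-based binary fingerprints and Tanimoto similarity.

A molecule is represented by the set of linear atom/bond paths it contains,
up to a maximum path length in bonds (the *depth*).  Each unique path string
is hashed with 64-bit FNV-1a and folded modulo the bit length into a sparse
binary fingerprint.  Similarity between two fingerprints is the Tanimoto
coefficient on their set bits.

Defaults (depth 30, 262,144 bits) favor long paths so that large macrocyclic
peptides — the dominant chemotype among diazotroph-associated cyanobacterial
metabolites — are distinguished by their full ring-spanning paths.

Alternate backends: ``extended`` appends ring-closure tokens to the path set,
``graph`` ignores bond orders and aromaticity, ``maccs_like`` uses the fixed
166-key MACCS substructure set, and ``external`` accepts any caller-supplied
generator that yields a set of bit indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")  # parse failures are reported as exceptions

_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3
_U64 = 0xFFFFFFFFFFFFFFFF

_BOND_TOKEN = {1.0: "-", 2.0: "=", 3.0: "#", 1.5: ":"}
_HASHED_TYPES = ("path", "extended", "graph")
_FP_TYPES = _HASHED_TYPES + ("maccs_like", "external")


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a valid molecule."""

    def __init__(self, smiles: str, reason: str = "invalid SMILES"):
        self.smiles = smiles
        super().__init__(f"{reason}: {smiles!r}")


class PathLimitWarning(UserWarning):
    """Path enumeration stopped after reaching the unique-path cap."""


class EmptyFingerprintWarning(UserWarning):
    """Tanimoto was asked to compare two empty fingerprints."""


@dataclass(frozen=True)
class FingerprintConfig:
    """How a fingerprint is generated.

    ``depth`` is the maximum path length in bonds; ``n_bits`` the folded
    length (a power of two for the hashed backends); ``path_limit`` caps the
    number of unique paths enumerated per molecule before deterministic
    truncation.
    """

    fp_type: str = "path"
    depth: int = 30
    n_bits: int = 262_144
    path_limit: int = 1_048_576

    def __post_init__(self) -> None:
        if self.fp_type not in _FP_TYPES:
            raise ValueError(f"unknown fp_type {self.fp_type!r}; one of {_FP_TYPES}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.fp_type in _HASHED_TYPES and self.n_bits & (self.n_bits - 1):
            raise ValueError("n_bits must be a power of two for hashed fingerprints")
        if self.n_bits < 1 or self.path_limit < 1:
            raise ValueError("n_bits and path_limit must be positive")


@dataclass(frozen=True)
class Fingerprint:
    bits: frozenset
    config: FingerprintConfig

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", frozenset(self.bits))
        if self.bits and max(self.bits) >= self.config.n_bits:
            raise ValueError("bit index out of range for configured n_bits")


@dataclass
class MolecularGraph:
    """A sanitized molecular graph with canonical atom ranks.

    ``atoms`` holds (element symbol, formal charge, attached H count,
    aromatic flag) per atom; ``bonds`` holds (i, j, order) with order in
    {1, 2, 3, 1.5} (1.5 = aromatic); ``ring_count`` is the SSSR size.
    """

    atoms: list
    bonds: list
    ring_count: int
    canonical_rank: list = field(default_factory=list)
    mol: Optional[Chem.Mol] = field(default=None, repr=False, compare=False)

    @property
    def num_atoms(self) -> int:
        return len(self.atoms)


def fnv1a64(text: str) -> int:
    """64-bit FNV-1a hash of a UTF-8 string; stable across runs and platforms."""
    h = _FNV_OFFSET
    for byte in text.encode("utf-8"):
        h ^= byte
        h = (h * _FNV_PRIME) & _U64
    return h


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a sanitized, aromaticity-normalized graph.

    Kekulized and aromatic spellings of the same molecule yield identical
    graphs.  Raises :class:`SmilesParseError` for invalid input; batch
    callers should catch it, skip the record and log the failure.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError(smiles, "empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    atoms = [
        (a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs(), a.GetIsAromatic())
        for a in mol.GetAtoms()
    ]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
        for b in mol.GetBonds()
    ]
    ring_count = len(Chem.GetSSSR(mol))
    rank = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    return MolecularGraph(
        atoms=atoms, bonds=bonds, ring_count=int(ring_count),
        canonical_rank=rank, mol=mol,
    )


def _atom_token(graph: MolecularGraph, idx: int, use_aromatic: bool) -> str:
    symbol, _charge, _hs, aromatic = graph.atoms[idx]
    return symbol.lower() if (use_aromatic and aromatic) else symbol


def _encode(graph, atom_path, bond_orders, use_aromatic, use_bond_orders) -> str:
    atoms = [_atom_token(graph, i, use_aromatic) for i in atom_path]
    bonds = [
        _BOND_TOKEN[o] if use_bond_orders else "-" for o in bond_orders
    ]
    forward = atoms[0]
    for token, atom in zip(bonds, atoms[1:]):
        forward += token + atom
    backward = atoms[-1]
    for token, atom in zip(reversed(bonds), reversed(atoms[:-1])):
        backward += token + atom
    return min(forward, backward)


def enumerate_paths(
    graph: MolecularGraph,
    depth: int,
    path_limit: int = 1_048_576,
    *,
    use_aromatic: bool = True,
    use_bond_orders: bool = True,
) -> set:
    """All simple paths of 0..``depth`` bonds as canonical strings.

    A path is encoded as alternating atom tokens (element symbol, lowercase
    when aromatic) and bond tokens ('-', '=', '#', ':'); each undirected path
    contributes the lexicographic minimum of its two directions.  Enumeration
    follows canonical atom ranks so that truncation at ``path_limit`` unique
    strings is independent of SMILES atom input order; a
    :class:`PathLimitWarning` is issued on truncation.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    n = graph.num_atoms
    adjacency: dict[int, list] = {i: [] for i in range(n)}
    for a, b, order in graph.bonds:
        adjacency[a].append((b, order))
        adjacency[b].append((a, order))
    rank = graph.canonical_rank or list(range(n))
    for i in adjacency:
        adjacency[i].sort(key=lambda pair: rank[pair[0]])
    start_order = sorted(range(n), key=lambda i: rank[i])

    paths: set[str] = set()
    truncated = False

    def dfs(path: list, orders: list, visited: set) -> bool:
        nonlocal truncated
        paths.add(_encode(graph, path, orders, use_aromatic, use_bond_orders))
        if len(paths) > path_limit:
            truncated = True
            return False
        if len(orders) >= depth:
            return True
        for nbr, order in adjacency[path[-1]]:
            if nbr in visited:
                continue
            visited.add(nbr)
            ok = dfs(path + [nbr], orders + [order], visited)
            visited.discard(nbr)
            if not ok:
                return False
        return True

    for start in start_order:
        if not dfs([start], [], {start}):
            break
    if truncated:
        warnings.warn(
            f"path enumeration truncated at {path_limit} unique paths",
            PathLimitWarning,
        )
    return paths


def _ring_closure_tokens(graph: MolecularGraph) -> set:
    """Ring tokens for the 'extended' backend: one per SSSR ring, by size and
    aromaticity of its atoms."""
    if graph.mol is None:
        return set()
    tokens = set()
    for ring in graph.mol.GetRingInfo().AtomRings():
        aromatic = all(graph.atoms[i][3] for i in ring)
        tokens.add(f"ring{'~' if aromatic else ''}{len(ring)}")
    return tokens


def hash_paths_to_bits(paths: Iterable[str], n_bits: int,
                       config: Optional[FingerprintConfig] = None) -> Fingerprint:
    """Fold unique path strings into set bits: FNV-1a hash modulo ``n_bits``."""
    if n_bits & (n_bits - 1) or n_bits < 1:
        raise ValueError("n_bits must be a power of two")
    bits = frozenset(fnv1a64(p) % n_bits for p in set(paths))
    cfg = config or FingerprintConfig(n_bits=n_bits)
    return Fingerprint(bits=bits, config=cfg)


def compute_fingerprint(
    molecule,
    config: FingerprintConfig = FingerprintConfig(),
    external_generator: Optional[Callable[[str], Iterable[int]]] = None,
) -> Fingerprint:
    """Fingerprint a molecule (SMILES string or parsed graph) per ``config``."""
    if isinstance(molecule, str):
        graph = parse_smiles(molecule)
        smiles = molecule
    else:
        graph = molecule
        smiles = Chem.MolToSmiles(graph.mol) if graph.mol is not None else ""

    if config.fp_type == "external":
        if external_generator is None:
            raise ValueError("fp_type 'external' requires an external_generator")
        bits = frozenset(int(b) for b in external_generator(smiles))
        return Fingerprint(bits=bits, config=config)
    if config.fp_type == "maccs_like":
        from rdkit.Chem import MACCSkeys

        if graph.mol is None:
            raise SmilesParseError(smiles, "no parsed molecule for MACCS keys")
        keys = MACCSkeys.GenMACCSKeys(graph.mol)
        return Fingerprint(bits=frozenset(keys.GetOnBits()), config=config)

    use_orders = config.fp_type != "graph"
    paths = enumerate_paths(
        graph,
        config.depth,
        config.path_limit,
        use_aromatic=use_orders,
        use_bond_orders=use_orders,
    )
    if config.fp_type == "extended":
        paths = paths | _ring_closure_tokens(graph)
    return hash_paths_to_bits(paths, config.n_bits, config)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |A∩B| / |A∪B| of two fingerprints' set bits.

    Both-empty inputs return 0.0 with a warning: two structureless parses
    carry no evidence of identity.
    """
    if a.config != b.config:
        raise ValueError("cannot compare fingerprints with different configs")
    if not a.bits and not b.bits:
        warnings.warn("Tanimoto of two empty fingerprints; returning 0",
                      EmptyFingerprintWarning)
        return 0.0
    inter = len(a.bits & b.bits)
    union = len(a.bits | b.bits)
    return inter / union


def fingerprint_dataset(
    dataset,
    config: FingerprintConfig = FingerprintConfig(),
    external_generator: Optional[Callable[[str], Iterable[int]]] = None,
):
    """Fingerprint every record in a dataset.

    Returns ``(fingerprints, skipped)`` where ``fingerprints`` maps
    compound_id -> Fingerprint and ``skipped`` lists (compound_id, reason)
    for records whose SMILES failed to parse.  Per-record failures never
    abort the batch.
    """
    fingerprints: dict[str, Fingerprint] = {}
    skipped: list[tuple[str, str]] = []
    for record in dataset:
        try:
            fingerprints[record.compound_id] = compute_fingerprint(
                record.smiles, config, external_generator
            )
        except SmilesParseError as exc:
            skipped.append((record.compound_id, str(exc)))
    return fingerprints, skipped


def save_fingerprint_cache(fingerprints: Mapping[str, Fingerprint], path) -> None:
    """One line per compound: id, config digest, hex-encoded sorted bit indices."""
    with open(path, "w", encoding="utf-8") as fh:
        for cid in sorted(fingerprints):
            fp = fingerprints[cid]
            digest = _config_digest(fp.config)
            hexbits = ",".join(format(b, "x") for b in sorted(fp.bits))
            fh.write(f"{cid}\t{digest}\t{hexbits}\n")


def load_fingerprint_cache(path, config: FingerprintConfig) -> dict:
    """Load a cache written by :func:`save_fingerprint_cache`; the config
    digest must match."""
    expect = _config_digest(config)
    out: dict[str, Fingerprint] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            cid, digest, hexbits = line.rstrip("\n").split("\t")
            if digest != expect:
                raise ValueError(f"cache {path} was built with a different config")
            bits = frozenset(int(b, 16) for b in hexbits.split(",") if b)
            out[cid] = Fingerprint(bits=bits, config=config)
    return out


def _config_digest(config: FingerprintConfig) -> str:
    return format(
        fnv1a64(f"{config.fp_type}|{config.depth}|{config.n_bits}|{config.path_limit}"),
        "016x",
    )
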