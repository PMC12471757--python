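"""Chemical-space analysis: descriptors, clustering and MDS embedding.

Nine cheap structural descriptors summarize the chemistry that separates
diazotroph-associated metabolites (nitrogen-rich, amide- and carboxyl-heavy
macrocycles) from non-diazotroph-associated ones (often halogenated,
nitrogen-poor scaffolds): halogen/nitrogen/oxygen atom counts, ring count,
hetero-to-carbon and nitrogen-to-carbon ratios, amide and carboxyl group
counts, and double-bond equivalents.

On top of Tanimoto distances (d = 1 - s) the module provides agglomerative
clustering of the labeled metabolites with per-cluster FIX enrichment,
assignment of unknowns to the cluster of their nearest labeled neighbor, and
a classical (Torgerson) MDS embedding for visualization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .fingerprints import Fingerprint, MolecularGraph, parse_smiles, tanimoto

DESCRIPTOR_NAMES = (
    "n_halogen",
    "n_nitrogen",
    "n_oxygen",
    "n_rings",
    "hetero_to_carbon",
    "n_to_carbon",
    "n_amide",
    "n_carboxyl",
    "dbe",
)

_HALOGENS = {"F", "Cl", "Br", "I"}
_AMIDE = Chem.MolFromSmarts("[CX3](=[OX1])[#7]")
_CARBOXYL = Chem.MolFromSmarts("[CX3](=[OX1])[OX2H1]")


@dataclass(frozen=True)
class DescriptorVector:
    """The nine structural descriptors for one molecule.

    Ratios are NaN when the molecule has no carbon.  ``dbe`` is the degree of
    unsaturation (2C + 2 + N - H - X) / 2.
    """

    n_halogen: int
    n_nitrogen: int
    n_oxygen: int
    n_rings: int
    hetero_to_carbon: float
    n_to_carbon: float
    n_amide: int
    n_carboxyl: int
    dbe: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in DESCRIPTOR_NAMES],
                        dtype=float)


@dataclass(frozen=True)
class ClusterAssignment:
    compound_id: str
    cluster_id: int
    nearest_labeled_id: Optional[str] = None
    nearest_labeled_distance: Optional[float] = None


def compute_descriptors(molecule) -> DescriptorVector:
    """Compute the nine descriptors from a parsed graph or SMILES string."""
    graph = parse_smiles(molecule) if isinstance(molecule, str) else molecule
    mol = graph.mol
    if mol is None:
        raise ValueError("descriptor computation needs a parsed molecule")

    n_c = n_n = n_o = n_s = n_hal = n_h = 0
    for atom in mol.GetAtoms():
        symbol = atom.GetSymbol()
        n_h += atom.GetTotalNumHs()
        if symbol == "C":
            n_c += 1
        elif symbol == "N":
            n_n += 1
        elif symbol == "O":
            n_o += 1
        elif symbol == "S":
            n_s += 1
        elif symbol in _HALOGENS:
            n_hal += 1
        if symbol == "H":
            n_h += 1

    hetero_ratio = (n_n + n_o + n_s + n_hal) / n_c if n_c else float("nan")
    n_ratio = n_n / n_c if n_c else float("nan")
    dbe = (2 * n_c + 2 + n_n - n_h - n_hal) / 2
    return DescriptorVector(
        n_halogen=n_hal,
        n_nitrogen=n_n,
        n_oxygen=n_o,
        n_rings=graph.ring_count,
        hetero_to_carbon=hetero_ratio,
        n_to_carbon=n_ratio,
        n_amide=len(mol.GetSubstructMatches(_AMIDE)),
        n_carboxyl=len(mol.GetSubstructMatches(_CARBOXYL)),
        dbe=dbe,
    )


def descriptor_frame(vectors: Mapping[str, DescriptorVector]) -> pd.DataFrame:
    """Descriptor vectors as a DataFrame (rows = compound ids)."""
    return pd.DataFrame(
        {cid: vec.as_array() for cid, vec in vectors.items()},
        index=list(DESCRIPTOR_NAMES),
    ).T


def zscore_matrix(
    vectors: Mapping[str, DescriptorVector],
    groups: Mapping[str, str],
    ddof: int = 0,
    stat: str = "mean",
) -> pd.DataFrame:
    """Per-group aggregate z-scores of the descriptors.

    Each descriptor is standardized against the GLOBAL mean and SD over all
    molecules (population SD by default), then aggregated within each group
    by ``stat`` ('mean' for class-level views, 'median' for cluster-level
    views).  A zero-variance descriptor contributes 0 with a warning.
    """
    if not vectors:
        raise ValueError("no descriptor vectors")
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    frame = descriptor_frame(vectors)
    mu = frame.mean(axis=0, skipna=True)
    sigma = frame.std(axis=0, ddof=ddof, skipna=True)
    constant = sigma == 0
    if constant.any():
        warnings.warn(
            f"zero-variance descriptors reported as 0: "
            f"{list(sigma.index[constant])}"
        )
        sigma = sigma.replace(0, 1.0)
    z = (frame - mu) / sigma
    z[z.columns[constant]] = 0.0
    z["__group"] = [groups[cid] for cid in z.index]
    grouped = z.groupby("__group")
    out = grouped.mean() if stat == "mean" else grouped.median()
    out.index.name = "group"
    return out


def tanimoto_distance_matrix(
    fingerprints: Mapping[str, Fingerprint]
) -> pd.DataFrame:
    """Symmetric Tanimoto distance matrix, d = 1 - s, zero diagonal."""
    ids = sorted(fingerprints)
    if len(ids) < 2:
        raise ValueError("need at least two fingerprints")
    n = len(ids)
    matrix = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - tanimoto(fingerprints[ids[i]], fingerprints[ids[j]])
            matrix[i, j] = matrix[j, i] = d
    return pd.DataFrame(matrix, index=ids, columns=ids)


def hierarchical_clusters(
    distances: pd.DataFrame,
    labels: Optional[Mapping[str, int]] = None,
    n_clusters: int = 6,
    linkage: str = "average",
) -> tuple[dict, dict]:
    """Agglomerative clustering of the labeled metabolites.

    Returns ``(assignments, enrichment)``: compound_id -> cluster id in
    1..n_clusters (renumbered in order of first appearance along the sorted
    id axis, so the numbering is deterministic), and cluster id -> percent of
    FIX=1 members (empty when ``labels`` is None).
    """
    if linkage not in ("average", "complete", "single"):
        raise ValueError("linkage must be average, complete or single")
    ids = list(distances.index)
    if n_clusters > len(ids):
        raise ValueError("more clusters requested than items")
    if not np.allclose(distances.values, distances.values.T):
        raise ValueError("distance matrix must be symmetric")
    condensed = squareform(distances.values, checks=False)
    tree = scipy_linkage(condensed, method=linkage)
    raw = fcluster(tree, t=n_clusters, criterion="maxclust")

    relabel: dict[int, int] = {}
    assignments: dict[str, int] = {}
    for cid, cluster in zip(ids, raw):
        if cluster not in relabel:
            relabel[cluster] = len(relabel) + 1
        assignments[cid] = relabel[cluster]

    enrichment: dict[int, float] = {}
    if labels is not None:
        for cluster in sorted(set(assignments.values())):
            members = [cid for cid, c in assignments.items() if c == cluster]
            pos = sum(1 for cid in members if labels.get(cid) == 1)
            enrichment[cluster] = 100.0 * pos / len(members)
    return assignments, enrichment


def assign_unknowns_to_clusters(
    unknown_fps: Mapping[str, Fingerprint],
    labeled_fps: Mapping[str, Fingerprint],
    labeled_clusters: Mapping[str, int],
) -> tuple[dict, dict]:
    """Place each unknown in the cluster of its nearest labeled metabolite.

    Ties in distance are broken by the lexicographically smallest labeled id.
    Returns ``(assignments, distance_distributions)`` where the second maps
    cluster id -> list of nearest-labeled distances of the unknowns sorted
    into it (the intra-cluster novelty distribution).
    """
    if not labeled_fps:
        raise ValueError("empty labeled fingerprint set")
    assignments: dict[str, ClusterAssignment] = {}
    distributions: dict[int, list] = {c: [] for c in set(labeled_clusters.values())}
    labeled_ids = sorted(labeled_fps)
    for uid in sorted(unknown_fps):
        best_id, best_d = None, math.inf
        for lid in labeled_ids:
            d = 1.0 - tanimoto(unknown_fps[uid], labeled_fps[lid])
            if d < best_d:
                best_id, best_d = lid, d
        cluster = labeled_clusters[best_id]
        assignments[uid] = ClusterAssignment(
            compound_id=uid,
            cluster_id=cluster,
            nearest_labeled_id=best_id,
            nearest_labeled_distance=best_d,
        )
        distributions.setdefault(cluster, []).append(best_d)
    return assignments, distributions


def mds_embedding(distances: pd.DataFrame, dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared-distance matrix, takes the top ``dims``
    eigenpairs and scales eigenvectors by the square roots of their
    eigenvalues.  Negative eigenvalues among the kept components (the matrix
    is not exactly Euclidean) are truncated to zero with a warning.
    """
    values = distances.values
    if not np.allclose(values, values.T):
        raise ValueError("distance matrix must be symmetric")
    n = values.shape[0]
    centering = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * centering @ (values ** 2) @ centering
    eigenvalues, eigenvectors = np.linalg.eigh(gram)
    order = np.argsort(eigenvalues)[::-1][:dims]
    top = eigenvalues[order]
    if (top < -1e-9).any():
        warnings.warn("negative eigenvalues truncated in MDS embedding")
    top = np.clip(top, 0.0, None)
    coords = eigenvectors[:, order] * np.sqrt(top)
    return pd.DataFrame(
        coords, index=distances.index,
        columns=[f"dim{i + 1}" for i in range(dims)],
    )
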