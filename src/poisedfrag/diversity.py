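"""Shape-pharmacophore (USRCAT) descriptors, fingerprint clustering and
greedy diversity selection.

USRCAT is an alignment-free 3D descriptor: for a conformer, distances from
four reference points (molecular centroid; atom closest to the centroid;
atom farthest from the centroid; atom farthest from that atom - all chosen
over ALL heavy atoms) are collected for five atom subsets (all,
hydrophobic, aromatic, H-bond donor, H-bond acceptor), and the first three
moments of each distance distribution (mean, standard deviation and the
cube root of the third central moment, sign preserved) give 12 numbers per
subset, 60 in all.  Similarity between descriptors is the standard inverse
scaled-Manhattan kernel ``1 / (1 + mean |a_i - b_i|)``.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.ML.Cluster import Butina

from .chem import mol_from_smiles, morgan_fp

#: Pharmacophoric subsets, in descriptor block order after "all".
SUBSET_SMARTS = {
    "hydrophobic": "[c,s,Br,I,$([S;H0;v2]),$([CX4;!$(C[#7,#8,#9,Cl,Br,I])])]",
    "aromatic": "[a]",
    "donor": "[$([N;H1,H2,H3;!$(N[C,S]=[O,S,N])]),$([O;H1]),$([S;H1])]",
    "acceptor": "[$([O;X1,X2;!$(O=N)]),$([N;X1,X2;v3]),$([n;X2])]",
}
SUBSET_ORDER = ("hydrophobic", "aromatic", "donor", "acceptor")


class EmbeddingError(RuntimeError):
    """3D embedding failed for a molecule."""


def embed_conformer(smiles: str, seed: int, n_confs: int = 3):
    """Embed one low-energy conformer; deterministic for fixed (smiles, seed).

    Hydrogens are added before embedding; a small ETKDG ensemble is
    generated and the MMFF94 (fallback UFF) lowest-energy member kept.
    Returns ``(mol_with_hs, coords)`` with coordinates in Angstrom.
    """
    mol = Chem.AddHs(mol_from_smiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    params.numThreads = 1
    conf_ids = AllChem.EmbedMultipleConfs(mol, numConfs=max(1, n_confs), params=params)
    if len(conf_ids) == 0:
        raise EmbeddingError(f"embedding failed for {smiles!r}")
    energies = {}
    try:
        results = AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=200)
    except Exception:
        results = None
    if results is None or all(code != 0 and e == -1 for code, e in results):
        results = AllChem.UFFOptimizeMoleculeConfs(mol, maxIters=200)
    for cid, (code, energy) in zip(conf_ids, results):
        energies[cid] = energy if energy is not None else np.inf
    best = min(conf_ids, key=lambda cid: (energies[cid], cid))
    coords = mol.GetConformer(best).GetPositions()
    return mol, np.asarray(coords, dtype=float)


def _moments(dists: np.ndarray) -> np.ndarray:
    if dists.size == 0:
        return np.zeros(3)
    mean = dists.mean()
    centred = dists - mean
    std = np.sqrt(np.mean(centred**2))
    m3 = np.mean(centred**3)
    # cbrt amplifies float noise without bound as m3 -> 0; snap the
    # sub-noise regime to zero so rigid-motion invariance holds to ~1e-9
    if abs(m3) < 1e-9:
        m3 = 0.0
    skew = np.cbrt(m3)
    return np.array([mean, std, skew])


def usrcat_descriptor(coordinates, atom_subsets) -> np.ndarray:
    """60-number USRCAT vector from coordinates and subset index lists.

    ``atom_subsets`` are index arrays for the four pharmacophoric subsets in
    :data:`SUBSET_ORDER`; the all-atoms block is computed implicitly.
    Reference points are always derived from all atoms; an empty subset
    contributes 12 zeros.
    """
    coords = np.asarray(coordinates, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 3:
        raise ValueError("need >= 3 atoms for a USRCAT descriptor")
    if len(atom_subsets) != len(SUBSET_ORDER):
        raise ValueError(f"expected {len(SUBSET_ORDER)} atom subsets")
    centroid = coords.mean(axis=0)
    d_centroid = np.linalg.norm(coords - centroid, axis=1)
    closest = coords[int(np.argmin(d_centroid))]
    farthest = coords[int(np.argmax(d_centroid))]
    d_far = np.linalg.norm(coords - farthest, axis=1)
    far_from_far = coords[int(np.argmax(d_far))]
    refs = (centroid, closest, farthest, far_from_far)

    blocks = []
    subsets = [np.arange(coords.shape[0])] + [
        np.asarray(s, dtype=int) for s in atom_subsets
    ]
    for subset in subsets:
        pts = coords[subset] if subset.size else np.empty((0, 3))
        for ref in refs:
            if pts.shape[0] == 0:
                blocks.append(np.zeros(3))
            else:
                blocks.append(_moments(np.linalg.norm(pts - ref, axis=1)))
    values = np.concatenate(blocks)
    assert values.shape == (60,)
    return values


def pharmacophore_subsets(mol) -> list:
    """Heavy-atom index lists for the four pharmacophoric subsets."""
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    remap = {idx: i for i, idx in enumerate(heavy)}
    out = []
    for name in SUBSET_ORDER:
        patt = Chem.MolFromSmarts(SUBSET_SMARTS[name])
        matched = sorted(
            {m[0] for m in mol.GetSubstructMatches(patt)} & set(heavy)
        )
        out.append(np.array([remap[i] for i in matched], dtype=int))
    return out


def usrcat_from_smiles(smiles: str, seed: int, n_confs: int = 3) -> np.ndarray:
    """Embed a conformer and compute its USRCAT descriptor (heavy atoms)."""
    mol, coords = embed_conformer(smiles, seed, n_confs=n_confs)
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    return usrcat_descriptor(coords[heavy], pharmacophore_subsets(mol))


def usrcat_similarity(a, b) -> float:
    """Inverse scaled-Manhattan similarity in (0, 1]; 1 for identical."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != (60,) or b.shape != (60,):
        raise ValueError("USRCAT descriptors must have length 60")
    return float(1.0 / (1.0 + np.abs(a - b).sum() / 60.0))


class ClusterAssignment:
    """Butina cluster labels plus the centroid id of each cluster."""

    def __init__(self, assignment: dict, centroids: list):
        self.assignment = dict(assignment)
        self.centroids = list(centroids)

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def members(self, cluster_index: int) -> list:
        return sorted(k for k, v in self.assignment.items() if v == cluster_index)


def cluster_fingerprints(records, cutoff: float = 0.4) -> ClusterAssignment:
    """Leader-style (Butina) clustering on circular fingerprints.

    ``cutoff`` is a Tanimoto *distance*: molecules within ``cutoff`` of a
    cluster centroid join that cluster.  Input is sorted by id first so the
    result is order-independent.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff {cutoff} outside (0, 1)")
    recs = sorted(records, key=lambda r: r.id)
    fps = [morgan_fp(mol_from_smiles(r.smiles)) for r in recs]
    n = len(recs)
    dists = []
    from rdkit import DataStructs

    for i in range(1, n):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i])
        dists.extend(1.0 - s for s in sims)
    clusters = Butina.ClusterData(dists, n, cutoff, isDistData=True)
    assignment, centroids = {}, []
    for ci, members in enumerate(clusters):
        centroids.append(recs[members[0]].id)  # Butina lists the centroid first
        for m in members:
            assignment[recs[m].id] = ci
    return ClusterAssignment(assignment, centroids)


def greedy_max_min(ids, dist, k: int) -> list:
    """Greedy max-min pick on a precomputed distance matrix.

    Seed pick is the item with the highest summed distance to all others
    (ties to the lexicographically smallest id); each later pick maximizes
    the minimum distance to the already-selected set under the same tie rule.
    """
    ids = list(ids)
    dist = np.asarray(dist, dtype=float)
    n = len(ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    order = sorted(range(n), key=lambda i: ids[i])  # lexicographic tie-break
    sums = dist.sum(axis=1)
    best = max(sums[i] for i in order)
    seed_pick = next(i for i in order if sums[i] == best)
    selected = [seed_pick]
    remaining = [i for i in order if i != seed_pick]
    min_d = dist[seed_pick].copy()
    while len(selected) < k:
        best_val = max(min_d[i] for i in remaining)
        pick = next(i for i in remaining if min_d[i] == best_val)
        selected.append(pick)
        remaining.remove(pick)
        min_d = np.minimum(min_d, dist[pick])
    return [ids[i] for i in selected]


def select_diverse(
    candidates,
    k: int,
    metric: str = "fingerprint",
    seed: int = 0,
    n_confs: int = 3,
) -> list:
    """Pick ``k`` maximally spread candidates by greedy max-min selection.

    ``metric`` is ``fingerprint`` (1 - Morgan Tanimoto) or ``usrcat``
    (1 - shape-pharmacophore similarity on a seeded conformer).
    """
    recs = list(candidates)
    if k > len(recs):
        raise ValueError(f"k={k} exceeds candidate pool of {len(recs)}")
    ids = [r.id for r in recs]
    n = len(recs)
    if metric == "fingerprint":
        from rdkit import DataStructs

        fps = [morgan_fp(mol_from_smiles(r.smiles)) for r in recs]
        dist = np.zeros((n, n))
        for i in range(n):
            if i:
                sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i])
                dist[i, :i] = [1.0 - s for s in sims]
                dist[:i, i] = dist[i, :i]
    elif metric == "usrcat":
        descs = [usrcat_from_smiles(r.smiles, seed=seed, n_confs=n_confs) for r in recs]
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i):
                d = 1.0 - usrcat_similarity(descs[i], descs[j])
                dist[i, j] = dist[j, i] = d
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return greedy_max_min(ids, dist, k)
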