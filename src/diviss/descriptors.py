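"""Pharmacophore feature perception and 2D feature-pair descriptors.

Three descriptor spaces of decreasing fuzziness are provided, all built from
the same six-label atom typing (donor, acceptor, positive, negative,
hydrophobic, aromatic) and topological shortest-path distances:

SHED
    21 unordered feature-pair Shannon entropies (bits) of the distribution of
    topological distances between atoms carrying the two features.
FPD
    the 21 normalized distance histograms themselves (distances 1-10, longer
    paths pooled into the last bin), concatenated to a 210-vector.
PHRAG
    a bag of length-3 feature-sequence fragments read along shortest paths.

All three are functions of the molecular graph only, hence invariant under
atom renumbering / SMILES rewriting.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations, combinations_with_replacement

import numpy as np
from rdkit import Chem

FEATURES = ("donor", "acceptor", "positive", "negative", "hydrophobic", "aromatic")
_FEATURE_CODE = {"donor": "D", "acceptor": "A", "positive": "P",
                 "negative": "N", "hydrophobic": "H", "aromatic": "R"}
FEATURE_PAIRS = tuple(combinations_with_replacement(FEATURES, 2))  # 21 pairs
DISTANCE_CAP = 10  # topological distances beyond this pool into the last bin

SPACES = ("SHED", "FPD", "PHRAG")


@dataclass(frozen=True)
class DescriptorVector:
    """A molecular descriptor in one named space.

    ``values`` is a numpy vector for SHED/FPD and a Counter (fragment bag)
    for PHRAG.
    """

    space: str
    values: object

    def __post_init__(self):
        if self.space not in SPACES:
            raise ValueError(f"unknown descriptor space {self.space!r}")


def perceive_features(mol: Chem.Mol) -> list[frozenset[str]]:
    """Per-atom pharmacophore labels.

    Rules (an atom may carry several labels or none):
      donor        N or O bearing at least one hydrogen
      acceptor     N or O with an available lone pair (not positively charged)
      positive     formal charge > 0
      negative     formal charge < 0
      hydrophobic  carbon with no N/O neighbor
      aromatic     member of an aromatic ring
    """
    if mol is None:
        raise ValueError("cannot perceive features of an unparsed molecule")
    out: list[frozenset[str]] = []
    for atom in mol.GetAtoms():
        labels = set()
        sym = atom.GetSymbol()
        charge = atom.GetFormalCharge()
        if sym in ("N", "O"):
            if atom.GetTotalNumHs() >= 1:
                labels.add("donor")
            if charge <= 0:
                labels.add("acceptor")
        if charge > 0:
            labels.add("positive")
        elif charge < 0:
            labels.add("negative")
        if sym == "C" and not any(
            nb.GetSymbol() in ("N", "O") for nb in atom.GetNeighbors()
        ):
            labels.add("hydrophobic")
        if atom.GetIsAromatic():
            labels.add("aromatic")
        out.append(frozenset(labels))
    return out


def _pair_distances(mol: Chem.Mol, features: list[frozenset[str]]
                    ) -> dict[tuple[str, str], Counter]:
    """Capped topological distance multisets for every unordered feature pair.

    An unordered atom pair {a, b} contributes once to pair (f1, f2) if one
    atom carries f1 and the other f2 (in either orientation).
    """
    dmat = Chem.GetDistanceMatrix(mol)
    n = mol.GetNumAtoms()
    dists: dict[tuple[str, str], Counter] = {p: Counter() for p in FEATURE_PAIRS}
    for i, j in combinations(range(n), 2):
        d = int(min(dmat[i, j], DISTANCE_CAP))
        if d <= 0 or not np.isfinite(dmat[i, j]):
            continue  # disconnected fragments carry no pair signal
        fi, fj = features[i], features[j]
        for f1, f2 in FEATURE_PAIRS:
            if (f1 in fi and f2 in fj) or (f2 in fi and f1 in fj):
                dists[(f1, f2)][d] += 1
    return dists


def shed_descriptor(mol: Chem.Mol) -> DescriptorVector:
    """21 feature-pair Shannon entropies (bits); empty distributions give 0."""
    features = perceive_features(mol)
    dists = _pair_distances(mol, features)
    vec = np.zeros(len(FEATURE_PAIRS))
    for k, pair in enumerate(FEATURE_PAIRS):
        counts = np.array(list(dists[pair].values()), dtype=float)
        if counts.size == 0:
            continue
        p = counts / counts.sum()
        vec[k] = float(-(p * np.log2(p)).sum())
    return DescriptorVector("SHED", vec)


def fpd_descriptor(mol: Chem.Mol) -> DescriptorVector:
    """Concatenated normalized feature-pair distance histograms (21 x 10)."""
    features = perceive_features(mol)
    dists = _pair_distances(mol, features)
    vec = np.zeros(len(FEATURE_PAIRS) * DISTANCE_CAP)
    for k, pair in enumerate(FEATURE_PAIRS):
        total = sum(dists[pair].values())
        if total == 0:
            continue
        for d, c in dists[pair].items():
            vec[k * DISTANCE_CAP + (d - 1)] = c / total
    return DescriptorVector("FPD", vec)


def phrag_descriptor(mol: Chem.Mol) -> DescriptorVector:
    """Bag of length-3 feature-sequence fragments along shortest paths.

    Every atom triple (i, k, j) with k bonded to both i and j and d(i, j) = 2
    is a window of some shortest path; each atom is encoded by its sorted
    feature letters ('0' when featureless) and the fragment is read in its
    lexicographically smaller direction.
    """
    features = perceive_features(mol)
    codes = ["".join(sorted(_FEATURE_CODE[f] for f in fs)) or "0" for fs in features]
    dmat = Chem.GetDistanceMatrix(mol)
    bag: Counter = Counter()
    for atom in mol.GetAtoms():
        k = atom.GetIdx()
        nbrs = [nb.GetIdx() for nb in atom.GetNeighbors()]
        for i, j in combinations(nbrs, 2):
            if dmat[i, j] != 2:
                continue
            fwd = (codes[i], codes[k], codes[j])
            bag["|".join(min(fwd, fwd[::-1]))] += 1
    return DescriptorVector("PHRAG", bag)


_COMPUTE = {"SHED": shed_descriptor, "FPD": fpd_descriptor, "PHRAG": phrag_descriptor}


def compute_descriptor(mol_or_smiles, space: str) -> DescriptorVector:
    """Descriptor for one molecule in one space (SMILES or RDKit mol input)."""
    if space not in SPACES:
        raise ValueError(f"unknown descriptor space {space!r}")
    mol = mol_or_smiles
    if isinstance(mol_or_smiles, str):
        mol = Chem.MolFromSmiles(mol_or_smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES {mol_or_smiles!r}")
    return _COMPUTE[space](mol)


def compute_all_descriptors(mol_or_smiles) -> dict[str, DescriptorVector]:
    mol = mol_or_smiles
    if isinstance(mol_or_smiles, str):
        mol = Chem.MolFromSmiles(mol_or_smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES {mol_or_smiles!r}")
    return {s: _COMPUTE[s](mol) for s in SPACES}


def molecule_distance(a: DescriptorVector, b: DescriptorVector) -> float:
    """Distance between two descriptors of the same space.

    Euclidean for SHED/FPD; bag (multiset) Jaccard distance for PHRAG.
    Two empty PHRAG bags are at distance 0.
    """
    if a.space != b.space:
        raise ValueError(f"descriptor space mismatch: {a.space} vs {b.space}")
    if a.space in ("SHED", "FPD"):
        return float(np.linalg.norm(np.asarray(a.values) - np.asarray(b.values)))
    inter = sum((a.values & b.values).values())
    union = sum((a.values | b.values).values())
    return 0.0 if union == 0 else 1.0 - inter / union
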