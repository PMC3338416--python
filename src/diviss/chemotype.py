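"""Scaffold-based chemotype clustering, cytotoxicity enrichment scoring,
enrichment-guided expansion and a generic MaxMin diversity picker.

A chemotype is keyed by the canonical Bemis-Murcko framework (ring systems
plus linkers, side chains removed); acyclic molecules form singleton keys
from their own canonical SMILES.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold
from scipy.spatial.distance import squareform, pdist

from .descriptors import shed_descriptor
from .io import Compound, CompoundLibrary


def assign_chemotype(compound: Compound) -> str:
    """Canonical scaffold key of a compound."""
    mol = compound.mol()
    if mol is None:
        raise ValueError(f"{compound.id}: unparseable structure")
    if mol.GetRingInfo().NumRings() == 0:
        return Chem.MolToSmiles(mol)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return Chem.MolToSmiles(mol)
    return Chem.MolToSmiles(scaffold)


@dataclass
class ChemotypeCluster:
    scaffold_key: str
    member_ids: list[str] = field(default_factory=list)
    n_tested: int = 0
    n_selective: int = 0

    @property
    def enrichment(self) -> float | None:
        """Fraction of tested members that are tumor-selective; None when the
        cluster has no tested members."""
        if self.n_tested == 0:
            return None
        return self.n_selective / self.n_tested


def cluster_library(library: CompoundLibrary) -> dict[str, ChemotypeCluster]:
    """Partition a library by scaffold key (every compound in exactly one
    cluster, deterministic keys)."""
    clusters: dict[str, ChemotypeCluster] = {}
    for compound in library:
        key = assign_chemotype(compound)
        clusters.setdefault(key, ChemotypeCluster(key)).member_ids.append(compound.id)
    return clusters


def enrichment_score(cluster: ChemotypeCluster, selective_ids: set[str],
                     tested_ids: set[str]) -> float | None:
    """Score = |members ∩ selective| / |members ∩ tested| and update the
    cluster's counters; None (undefined) when no member was tested."""
    if not selective_ids <= tested_ids:
        raise ValueError("selective compounds must be a subset of tested compounds")
    members = set(cluster.member_ids)
    cluster.n_tested = len(members & tested_ids)
    cluster.n_selective = len(members & selective_ids)
    return cluster.enrichment


def score_clusters(clusters: dict[str, ChemotypeCluster], selective_ids,
                   tested_ids) -> dict[str, ChemotypeCluster]:
    selective_ids, tested_ids = set(selective_ids), set(tested_ids)
    for cluster in clusters.values():
        enrichment_score(cluster, selective_ids, tested_ids)
    return clusters


def select_expansion(clusters: dict[str, ChemotypeCluster], untested_ids,
                     hit_rate_threshold: float = 0.20) -> list[str]:
    """Untested members of clusters whose enrichment exceeds the threshold.

    The comparison is strict ('higher than 20% hit rate'); output is sorted
    by (enrichment desc, compound id).
    """
    if not 0.0 <= hit_rate_threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    untested = set(untested_ids)
    picks: list[tuple[float, str]] = []
    for cluster in clusters.values():
        e = cluster.enrichment
        if e is None or e <= hit_rate_threshold:
            continue
        picks.extend((e, cid) for cid in cluster.member_ids if cid in untested)
    picks.sort(key=lambda t: (-t[0], t[1]))
    return [cid for _, cid in picks]


def diversity_select(library: CompoundLibrary, k: int, seed: int | None = None
                     ) -> list[str]:
    """Greedy MaxMin diversity selection in SHED descriptor space.

    Starts from the compound with maximal summed distance to all others and
    iteratively adds the compound maximizing its minimum distance to the
    chosen set; ties break on compound id. Deterministic (the seed argument
    is accepted for interface symmetry with the stochastic stages)."""
    n = len(library)
    if not 0 <= k <= n:
        raise ValueError(f"k={k} out of range for a library of {n}")
    if k == 0:
        return []
    ids = library.ids()
    vectors = np.array([shed_descriptor(c.mol()).values for c in library])
    dist = squareform(pdist(vectors)) if n > 1 else np.zeros((1, 1))
    order = np.lexsort((ids, -dist.sum(axis=1)))  # ties on id
    chosen = [int(order[0])]
    remaining = set(range(n)) - set(chosen)
    min_dist = dist[chosen[0]].copy()
    while len(chosen) < k:
        best = min(remaining, key=lambda i: (-min_dist[i], ids[i]))
        chosen.append(best)
        remaining.discard(best)
        min_dist = np.minimum(min_dist, dist[best])
    return [ids[i] for i in chosen]
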