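"""Ligand-based virtual target profiling.

Each protein target is represented by the ensemble of its known ligands in
descriptor space (SHED, FPD, PHRAG). The affinity of a query compound for a
target is interpolated by inverse distance weighting (IDW) over the
reference ligands that fall inside the target's applicability domain — the
radius around the ensemble beyond which no prediction is made. A query is
profiled against every model in all three spaces and a target is reported
when at least one space predicts; the reported pAct is the maximum across
predicting spaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .descriptors import (SPACES, DescriptorVector, compute_all_descriptors,
                          molecule_distance)
from .io import ChemogenomicsDB, Compound, CompoundLibrary

#: Applicability radius used for a space when a target has a single reference
#: ligand (no intra-target nearest-neighbor distances to take a percentile
#: of). Scaled to the typical distance between one-substituent analogs of a
#: shared scaffold in each space.
DEFAULT_FALLBACK_RADIUS = {"SHED": 1.0, "FPD": 0.8, "PHRAG": 0.5}


@dataclass
class ProfilingConfig:
    min_ligands: int = 1
    radius_percentile: float = 95.0
    radius_floor: float = 1e-6
    fallback_radius: dict = dc_field(default_factory=lambda: dict(DEFAULT_FALLBACK_RADIUS))
    fixed_radius: dict | None = None  # per-space override, bypasses the percentile rule
    idw_power: float = 2.0
    pact_min: float = 6.0
    spaces: tuple = SPACES


@dataclass
class TargetModel:
    """Per-protein ligand ensemble: descriptors in every space, experimental
    pActs, and one applicability radius per space."""

    target_id: str
    ligand_ids: list[str]
    pacts: np.ndarray
    descriptors: dict[str, list[DescriptorVector]]
    radius: dict[str, float]

    @property
    def n_references(self) -> int:
        return len(self.ligand_ids)


@dataclass(frozen=True)
class PredictedInteraction:
    compound_id: str
    target_id: str
    pact: float
    n_neighbors: int
    space: str


def _applicability_radius(vectors: list[DescriptorVector], percentile: float,
                          floor: float, fallback: float) -> float:
    """Radius = percentile of intra-ensemble nearest-neighbor distances."""
    n = len(vectors)
    if n < 2:
        return max(fallback, floor)
    nn = []
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = molecule_distance(vectors[i], vectors[j])
    for i in range(n):
        nn.append(np.min(np.delete(dmat[i], i)))
    return max(float(np.percentile(nn, percentile)), floor)


def build_target_models(db: ChemogenomicsDB,
                        config: ProfilingConfig | None = None
                        ) -> dict[str, TargetModel]:
    """One model per target with at least ``min_ligands`` references.

    Targets with fewer ligands are excluded; they are simply absent from the
    returned mapping (compare with the DB's target list to recover them).
    """
    config = config or ProfilingConfig()
    if db.n_interactions == 0:
        raise ValueError("empty chemogenomics DB")
    # compute descriptors once per unique structure
    desc_cache: dict[str, dict[str, DescriptorVector]] = {}
    models: dict[str, TargetModel] = {}
    for target_id, grp in db.interactions.groupby("target_id", sort=True):
        if len(grp) < config.min_ligands:
            continue
        descriptors: dict[str, list[DescriptorVector]] = {s: [] for s in config.spaces}
        for smi in grp["smiles"]:
            if smi not in desc_cache:
                desc_cache[smi] = compute_all_descriptors(smi)
            for s in config.spaces:
                descriptors[s].append(desc_cache[smi][s])
        radius = {}
        for s in config.spaces:
            if config.fixed_radius and s in config.fixed_radius:
                radius[s] = max(config.fixed_radius[s], config.radius_floor)
            else:
                radius[s] = _applicability_radius(
                    descriptors[s], config.radius_percentile,
                    config.radius_floor, config.fallback_radius[s])
        models[str(target_id)] = TargetModel(
            target_id=str(target_id),
            ligand_ids=list(grp["ligand_id"]),
            pacts=grp["pact"].to_numpy(dtype=float),
            descriptors=descriptors,
            radius=radius,
        )
    return models


def predict_affinity(query: DescriptorVector, model: TargetModel,
                     space: str, power: float = 2.0
                     ) -> tuple[float, int] | None:
    """IDW-interpolated pAct from in-domain neighbors, or None when the query
    is outside the applicability domain.

    Zero-distance references short-circuit to the mean pAct of the exact
    matches. The prediction is a convex combination, hence bounded by the
    neighbors' pAct range.
    """
    refs = model.descriptors[space]
    dists = np.array([molecule_distance(query, r) for r in refs])
    in_domain = dists <= model.radius[space]
    if not in_domain.any():
        return None
    d = dists[in_domain]
    p = model.pacts[in_domain]
    exact = d == 0.0
    if exact.any():
        return float(p[exact].mean()), int(exact.sum())
    w = d ** (-power)
    return float(np.sum(w * p) / np.sum(w)), int(len(d))


def profile_compound(compound: Compound, models: dict[str, TargetModel],
                     config: ProfilingConfig | None = None
                     ) -> list[PredictedInteraction]:
    """Predict a compound against every target model in all spaces.

    A target is reported when at least one space predicts; the reported pAct
    is the maximum over predicting spaces (permissive consensus)."""
    config = config or ProfilingConfig()
    queries = compute_all_descriptors(compound.smiles)
    out: list[PredictedInteraction] = []
    for target_id in sorted(models):
        model = models[target_id]
        best: PredictedInteraction | None = None
        for space in config.spaces:
            pred = predict_affinity(queries[space], model, space, config.idw_power)
            if pred is None:
                continue
            pact, n_nb = pred
            if best is None or pact > best.pact:
                best = PredictedInteraction(compound.id, target_id, pact, n_nb, space)
        if best is not None:
            out.append(best)
    return out


def profile_library(compounds: CompoundLibrary, models: dict[str, TargetModel],
                    config: ProfilingConfig | None = None) -> pd.DataFrame:
    """Interaction table (compound_id, target_id, pact, n_neighbors, space)
    for a whole compound set."""
    rows = []
    for compound in compounds:
        for it in profile_compound(compound, models, config):
            rows.append({"compound_id": it.compound_id, "target_id": it.target_id,
                         "pact": it.pact, "n_neighbors": it.n_neighbors,
                         "space": it.space})
    return pd.DataFrame(rows, columns=["compound_id", "target_id", "pact",
                                       "n_neighbors", "space"])


def filter_potent(interactions: pd.DataFrame, pact_min: float = 6.0) -> pd.DataFrame:
    """Keep interactions predicted at 1 uM or better by default (pAct >= 6,
    inclusive)."""
    if interactions.empty:
        return interactions
    return interactions[interactions["pact"] >= pact_min].reset_index(drop=True)


@dataclass(frozen=True)
class ProfileSummary:
    n_compounds: int
    n_covered: int               # compounds with >= 1 raw prediction
    coverage_percent: int        # rounded to nearest integer
    n_interactions: int          # raw predictions
    n_filtered_interactions: int
    n_filtered_molecules: int
    n_filtered_targets: int
    mean_targets_per_molecule: int  # over the filtered set, nearest integer


def profile_summary(compound_ids, interactions: pd.DataFrame,
                    pact_min: float = 6.0) -> ProfileSummary:
    """Coverage statistics of a profiling run over a compound set."""
    ids = list(compound_ids)
    n = len(ids)
    if interactions.empty:
        return ProfileSummary(n, 0, 0, 0, 0, 0, 0, 0)
    covered = interactions["compound_id"].nunique()
    potent = filter_potent(interactions, pact_min)
    n_mol = potent["compound_id"].nunique()
    mean_targets = round(len(potent) / n_mol) if n_mol else 0
    return ProfileSummary(
        n_compounds=n,
        n_covered=int(covered),
        coverage_percent=round(100.0 * covered / n) if n else 0,
        n_interactions=len(interactions),
        n_filtered_interactions=len(potent),
        n_filtered_molecules=int(n_mol),
        n_filtered_targets=int(potent["target_id"].nunique()),
        mean_targets_per_molecule=int(mean_targets),
    )
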