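"""Ligand-based virtual target profiling of a query compound.

Builds per-target ligand-ensemble models (SHED/FPD/PHRAG pharmacophore-pair
descriptors, applicability radius per space) from a synthetic chemogenomics
database and predicts the multi-target affinity profile of a probe compound
by inverse-distance-weighted interpolation.
"""

from diviss.io import Compound
from diviss.profiling import (build_target_models, filter_potent,
                              profile_compound)
from diviss.simulate import CampaignConfig, generate_chemogenomics_db, generate_library

config = CampaignConfig(n_compounds=0, n_cancer_targets=5, n_normal_targets=3,
                        n_housekeeping_targets=3, seed=5)
_, truth = generate_library(config)
db = generate_chemogenomics_db(truth, config)
print(f"chemogenomics DB: {db.n_ligands} ligands, {db.n_targets} targets, "
      f"{db.n_interactions} interactions")

models = build_target_models(db)
first = truth.targets.iloc[0]
probe = Compound("probe", first["archetype_smiles"])
print(f"\nprobe = archetype of {first['target_id']} "
      f"(planted pAct {first['archetype_pact']:.2f}): {probe.smiles}")

predictions = profile_compound(probe, models)
for p in predictions:
    print(f"  {p.target_id}: predicted pAct {p.pact:.2f} "
          f"({p.n_neighbors} neighbors, {p.space} space)")
potent = [p for p in predictions if p.pact >= 6.0]
print(f"{len(potent)} predicted interaction(s) at 1 uM or better (pAct >= 6)")

# The probe sits at distance zero from its own target's ensemble, so the
# prediction averages the exact-match neighbors and lands on the planted
# archetype potency; targets whose ligand chemistry is unrelated leave the
# probe outside their applicability domain and contribute no prediction.
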