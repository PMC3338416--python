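import numpy as np
import pandas as pd
import pytest

from diviss.descriptors import DescriptorVector, compute_all_descriptors
from diviss.io import ChemogenomicsDB, Compound
from diviss.profiling import (ProfilingConfig, TargetModel,
                              build_target_models, filter_potent,
                              predict_affinity, profile_compound,
                              profile_library, profile_summary)
from diviss.simulate import CampaignConfig, generate_chemogenomics_db, generate_library


def db_from(rows):
    return ChemogenomicsDB(pd.DataFrame(
        rows, columns=["ligand_id", "smiles", "target_id", "pact"]))


def shed(vec21):
    v = np.zeros(21)
    v[:len(vec21)] = vec21
    return DescriptorVector("SHED", v)


def manual_model(ref_vectors, pacts, radius=10.0):
    return TargetModel(
        target_id="T", ligand_ids=[f"L{i}" for i in range(len(pacts))],
        pacts=np.asarray(pacts, dtype=float),
        descriptors={"SHED": ref_vectors},
        radius={"SHED": radius})


class TestBuildModels:
    def test_single_ligand_target(self):
        models = build_target_models(db_from([("L1", "CCO", "T1", 6.0)]))
        assert set(models) == {"T1"}
        assert models["T1"].n_references == 1
        assert models["T1"].radius["SHED"] > 0

    def test_all_references_and_pacts_stored(self):
        models = build_target_models(db_from([
            ("L1", "CCO", "T1", 5.0), ("L2", "CCN", "T1", 6.0),
            ("L3", "CCS", "T1", 7.0)]))
        assert sorted(models["T1"].pacts) == [5.0, 6.0, 7.0]

    def test_min_ligands_filter(self):
        models = build_target_models(
            db_from([("L1", "CCO", "T1", 6.0), ("L2", "CCN", "T2", 6.0),
                     ("L3", "CCS", "T2", 7.0)]),
            ProfilingConfig(min_ligands=2))
        assert set(models) == {"T2"}

    def test_empty_db_rejected(self):
        with pytest.raises((ValueError, KeyError)):
            build_target_models(db_from([]))


class TestPredictAffinity:
    def test_exact_match_returns_reference_pact(self):
        model = manual_model([shed([1.0, 2.0])], [7.2])
        pact, n = predict_affinity(shed([1.0, 2.0]), model, "SHED")
        assert pact == 7.2 and n == 1

    def test_hand_computed_idw(self):
        # neighbors at d=1 (pAct 6) and d=2 (pAct 9), power 2:
        # (6 + 9/4) / (1 + 1/4) = 6.6
        model = manual_model([shed([1.0]), shed([2.0])], [6.0, 9.0])
        query = shed([0.0])
        pact, n = predict_affinity(query, model, "SHED", power=2.0)
        assert pact == pytest.approx(6.6)
        assert n == 2

    def test_outside_domain_gives_no_prediction(self):
        model = manual_model([shed([5.0])], [7.0], radius=1.0)
        assert predict_affinity(shed([0.0]), model, "SHED") is None

    def test_boundedness(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            refs = [shed(rng.uniform(0, 3, size=4)) for _ in range(5)]
            pacts = rng.uniform(4, 9, size=5)
            model = manual_model(refs, pacts)
            out = predict_affinity(shed(rng.uniform(0, 3, size=4)), model, "SHED")
            assert out is not None
            assert pacts.min() - 1e-9 <= out[0] <= pacts.max() + 1e-9

    def test_brute_force_oracle_equivalence(self):
        """IDW prediction equals an independent naive recomputation."""
        rng = np.random.default_rng(2)
        for _ in range(30):
            refs = [shed(rng.uniform(0, 2, size=6)) for _ in range(8)]
            pacts = rng.uniform(4, 9, size=8)
            radius = rng.uniform(0.5, 4.0)
            model = manual_model(refs, pacts, radius=radius)
            q = shed(rng.uniform(0, 2, size=6))
            got = predict_affinity(q, model, "SHED", power=2.0)
            dists = np.array([np.linalg.norm(q.values - r.values) for r in refs])
            mask = dists <= radius
            if not mask.any():
                assert got is None
                continue
            if (dists[mask] == 0).any():
                expected = pacts[mask][dists[mask] == 0].mean()
            else:
                w = dists[mask] ** -2.0
                expected = np.sum(w * pacts[mask]) / np.sum(w)
            assert got[0] == pytest.approx(expected, abs=1e-9)

    def test_domain_monotonicity(self):
        """Shrinking the applicability radius never adds predictions."""
        rng = np.random.default_rng(3)
        refs = [shed(rng.uniform(0, 2, size=6)) for _ in range(6)]
        pacts = rng.uniform(4, 9, size=6)
        queries = [shed(rng.uniform(0, 2, size=6)) for _ in range(40)]
        counts = []
        for radius in (3.0, 2.0, 1.0, 0.5, 0.1):
            model = manual_model(refs, pacts, radius=radius)
            counts.append(sum(
                predict_affinity(q, model, "SHED") is not None for q in queries))
        assert counts == sorted(counts, reverse=True)


class TestProfileAndSummary:
    def test_empty_model_set_empty_profile(self):
        assert profile_compound(Compound("X", "CCO"), {}) == []

    def test_max_consensus_across_spaces(self):
        # query inside both targets' SHED domains; reported pact is the max
        # across spaces and per-target the best space wins
        db = db_from([("L1", "CCO", "T1", 6.5), ("L2", "CCO", "T2", 7.5)])
        models = build_target_models(db)
        preds = profile_compound(Compound("X", "CCO"), models)
        assert {p.target_id: p.pact for p in preds} == {"T1": 6.5, "T2": 7.5}

    def test_filter_potent_inclusive_edge(self):
        table = pd.DataFrame({"compound_id": ["a", "b", "c"],
                              "target_id": ["T1", "T1", "T1"],
                              "pact": [5.5, 6.0, 7.3]})
        kept = filter_potent(table)
        assert list(kept["pact"]) == [6.0, 7.3]

    def test_summary_reproduces_coverage_arithmetic(self):
        ids = [f"c{i}" for i in range(265)]
        rows = []
        # 139 molecules carry 818 potent interactions (123 x 6 + 16 x 5)
        k = 0
        for i in range(139):
            n_t = 6 if i < 123 else 5
            for t in range(n_t):
                rows.append({"compound_id": ids[i], "target_id": f"T{k}",
                             "pact": 7.0})
                k += 1
        # 34 further molecules are covered only below the potency filter
        for i in range(139, 173):
            rows.append({"compound_id": ids[i], "target_id": "Tweak",
                         "pact": 5.0})
        summary = profile_summary(ids, pd.DataFrame(rows))
        assert summary.n_covered == 173
        assert summary.coverage_percent == 65
        assert summary.n_filtered_interactions == 818
        assert summary.n_filtered_molecules == 139
        assert summary.mean_targets_per_molecule == 6

    def test_empty_interactions(self):
        summary = profile_summary(["a"], pd.DataFrame())
        assert summary.n_covered == 0 and summary.coverage_percent == 0


class TestPlantedRecovery:
    def test_archetype_probes_recover_their_targets(self, small_campaign):
        """Probes built from target archetypes are predicted for their own
        target within 0.5 of the planted archetype potency."""
        config, library, truth = small_campaign
        db = generate_chemogenomics_db(truth, config)
        models = build_target_models(db)
        errors = []
        for trow in truth.targets.itertuples(index=False):
            probe = Compound("probe", trow.archetype_smiles)
            preds = {p.target_id: p.pact
                     for p in profile_compound(probe, models)}
            assert trow.target_id in preds
            errors.append(abs(preds[trow.target_id] - trow.archetype_pact))
        assert np.median(errors) <= 0.5

    def test_every_cancer_target_has_an_in_domain_selective_compound(
            self, small_campaign):
        config, library, truth = small_campaign
        db = generate_chemogenomics_db(truth, config)
        models = build_target_models(db)
        selective = truth.compounds[truth.compounds["class"] == "tumor_selective"]
        for tid in truth.cancer_targets():
            own = selective[selective["target_id"] == tid]
            assert len(own) >= 1
            found = False
            for row in own.itertuples(index=False):
                queries = compute_all_descriptors(row.smiles)
                for space in ("SHED", "FPD", "PHRAG"):
                    if predict_affinity(queries[space], models[tid], space):
                        found = True
            assert found, f"no in-domain selective compound for {tid}"
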