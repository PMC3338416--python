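import numpy as np
import pandas as pd
import pytest

from diviss.doseresponse import curves_from_records, fit_curve
from diviss.screening import CONTROL_NEG, CONTROL_POS
from diviss.simulate import (CampaignConfig, generate_annotations,
                             generate_chemogenomics_db, generate_library,
                             simulate_dose_response, simulate_primary_screen)


class TestConfig:
    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            CampaignConfig(fraction_cytotoxic=1.5)
        with pytest.raises(ValueError):
            CampaignConfig(fraction_cytotoxic=0.01,
                           fraction_tumor_selective=0.4)

    def test_dilution_series_shape(self):
        c = CampaignConfig().concentrations()
        assert len(c) == 6
        assert c[0] == 50.0
        assert np.allclose(c[:-1] / c[1:], 3.0)


class TestGenerateLibrary:
    def test_empty_campaign(self):
        lib, truth = generate_library(CampaignConfig(n_compounds=0, seed=0))
        assert len(lib) == 0
        assert truth.compounds.empty

    def test_same_seed_identical_outputs(self):
        cfg = CampaignConfig(n_compounds=60, seed=5)
        lib1, truth1 = generate_library(cfg)
        lib2, truth2 = generate_library(CampaignConfig(n_compounds=60, seed=5))
        assert [c.smiles for c in lib1] == [c.smiles for c in lib2]
        pd.testing.assert_frame_equal(truth1.compounds, truth2.compounds)
        pd.testing.assert_frame_equal(truth1.targets, truth2.targets)

    def test_cytotoxic_fraction_holds_in_expectation(self):
        cfg = CampaignConfig(n_compounds=100, fraction_cytotoxic=0.13,
                             fraction_tumor_selective=0.0,
                             fraction_normal_selective=0.0,
                             n_cancer_targets=0, n_normal_targets=0, seed=9)
        _, truth = generate_library(cfg)
        n_toxic = int((truth.compounds["ic50_tumor_um"] <= 50.0).sum())
        sd = np.sqrt(100 * 0.13 * 0.87)
        assert abs(n_toxic - 13) <= 3 * sd

    def test_ground_truth_is_recomputable(self, small_campaign):
        """Planted IC50s follow IC50 = 10^(6-pAct)/weight exactly."""
        _, _, truth = small_campaign
        weights = truth.targets.set_index("target_id")
        active = truth.compounds[truth.compounds["target_id"] != ""]
        for row in active.itertuples(index=False):
            w_t = weights.loc[row.target_id, "tumor_weight"]
            assert row.ic50_tumor_um == pytest.approx(
                truth.recompute_ic50(row.pact, w_t), rel=1e-9)

    def test_all_structures_parse(self, small_campaign):
        _, library, _ = small_campaign
        assert all(c.mol() is not None for c in library)


class TestPrimaryScreen:
    def test_inactive_compound_reads_full_viability(self):
        cfg = CampaignConfig(n_compounds=40, fraction_cytotoxic=0.0,
                             fraction_tumor_selective=0.0,
                             fraction_normal_selective=0.0,
                             n_cancer_targets=0, n_normal_targets=0, seed=2)
        lib, truth = generate_library(cfg)
        plates = simulate_primary_screen(lib, truth, cfg)
        wells = plates[~plates["compound_id"].isin((CONTROL_POS, CONTROL_NEG))]
        span = cfg.pos_control_mean - cfg.neg_control_mean
        viability = 100 * (wells["raw_signal"] - cfg.neg_control_mean) / span
        # mean viability ~ 100% within 3 standard errors of the noise
        se = cfg.viability_noise_sd / np.sqrt(len(viability))
        assert abs(viability.mean() - 100.0) < 3 * se

    def test_potent_compound_expected_viability(self):
        """True tumor IC50 of 1 uM and slope 1 gives 100/(1+50) ~ 1.96% at
        the 50 uM screening concentration."""
        cfg = CampaignConfig(n_compounds=30, viability_noise_sd=0.0,
                             n_cancer_targets=2, n_normal_targets=1,
                             n_housekeeping_targets=1, seed=4)
        lib, truth = generate_library(cfg)
        probes = truth.compounds[
            (truth.compounds["class"] == "tumor_selective")
            & (truth.compounds["ic50_tumor_um"] == 1.0)]
        assert len(probes) >= 2
        plates = simulate_primary_screen(lib, truth, cfg)
        span = cfg.pos_control_mean - cfg.neg_control_mean
        for cid in probes["compound_id"]:
            wells = plates[plates["compound_id"] == cid]
            v = 100 * (wells["raw_signal"] - cfg.neg_control_mean) / span
            assert v.to_numpy() == pytest.approx([1.9608, 1.9608], abs=1e-3)

    def test_duplicates_identical_without_noise(self):
        cfg = CampaignConfig(n_compounds=20, viability_noise_sd=0.0,
                             n_cancer_targets=2, n_normal_targets=1,
                             n_housekeeping_targets=1, seed=1)
        lib, truth = generate_library(cfg)
        plates = simulate_primary_screen(lib, truth, cfg)
        wells = plates[~plates["compound_id"].isin((CONTROL_POS, CONTROL_NEG))]
        spread = wells.groupby("compound_id")["raw_signal"].agg(lambda s: s.max() - s.min())
        assert (spread == 0).all()


class TestDoseResponse:
    def _noise_free(self, seed=6):
        cfg = CampaignConfig(n_compounds=60, viability_noise_sd=0.0,
                             n_cancer_targets=3, n_normal_targets=2,
                             n_housekeeping_targets=2, seed=seed)
        lib, truth = generate_library(cfg)
        return cfg, lib, truth

    def test_unknown_cell_line_rejected(self):
        cfg, lib, truth = self._noise_free()
        with pytest.raises(ValueError):
            simulate_dose_response(lib.ids()[:2], truth, "HELA", cfg)

    def test_inactive_compound_flat_at_100(self):
        cfg, lib, truth = self._noise_free()
        inactive = truth.compounds.loc[truth.compounds["class"] == "inactive",
                                       "compound_id"].iloc[:3]
        records = simulate_dose_response(list(inactive), truth, "HCT116", cfg)
        assert (records["viability"] == 100.0).all()
        assert len(records) == 3 * 6 * 2

    def test_seeded_reproducibility(self):
        cfg = CampaignConfig(n_compounds=30, n_cancer_targets=3,
                             n_normal_targets=2, n_housekeeping_targets=2,
                             seed=8)
        lib, truth = generate_library(cfg)
        ids = lib.ids()[:5]
        a = simulate_dose_response(ids, truth, "MRC5", cfg)
        b = simulate_dose_response(ids, truth, "MRC5", cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_noise_free_refit_recovers_true_ic50(self):
        """Self-consistency: fitting noise-free simulated curves returns the
        planted IC50 to 0.1% for IC50 inside the tested range."""
        cfg, lib, truth = self._noise_free()
        active = truth.compounds[
            (truth.compounds["ic50_tumor_um"] > 0.21)
            & (truth.compounds["ic50_tumor_um"] < 50.0)]
        ids = list(active["compound_id"].iloc[:10])
        records = simulate_dose_response(ids, truth, "HCT116", cfg)
        planted = truth.compounds.set_index("compound_id")["ic50_tumor_um"]
        for curve in curves_from_records(records):
            result = fit_curve(curve)
            if result.censored:
                continue
            assert result.ic50 == pytest.approx(
                planted[curve.compound_id], rel=1e-3)


class TestChemogenomicsAndAnnotations:
    def test_single_target_db(self):
        cfg = CampaignConfig(n_compounds=0, n_cancer_targets=1,
                             n_normal_targets=0, n_housekeeping_targets=0,
                             db_ligands_per_target=5, seed=3)
        _, truth = generate_library(cfg)
        db = generate_chemogenomics_db(truth, cfg)
        assert db.n_targets == 1
        assert db.n_interactions == 5

    def test_archetype_is_its_own_nearest_neighbor(self, small_campaign):
        config, _, truth = small_campaign
        db = generate_chemogenomics_db(truth, config)
        for trow in truth.targets.itertuples(index=False):
            ligands = db.interactions[db.interactions["target_id"] == trow.target_id]
            assert trow.archetype_smiles in set(ligands["smiles"])

    def test_db_pacts_center_on_archetype_potency(self, small_campaign):
        config, _, truth = small_campaign
        db = generate_chemogenomics_db(truth, config)
        offsets = []
        for trow in truth.targets.itertuples(index=False):
            pacts = db.interactions.loc[
                db.interactions["target_id"] == trow.target_id, "pact"]
            offsets.append(pacts.mean() - trow.archetype_pact)
        # per-target means scatter around 0; the grand mean is tight
        assert abs(np.mean(offsets)) < 0.1

    def test_cancer_targets_receive_high_oncoscores(self, small_campaign):
        config, _, truth = small_campaign
        anns = generate_annotations(truth, config)
        cancer = [anns[t].oncoscore for t in truth.cancer_targets()]
        other = [a.oncoscore for t, a in anns.items()
                 if t not in truth.cancer_targets()]
        assert np.mean(cancer) > 0.7 > np.mean(other)

    def test_family_proportions_respected(self):
        cfg = CampaignConfig(n_compounds=0, seed=1,
                             family_proportions={"enzyme": 1.0})
        _, truth = generate_library(cfg)
        anns = generate_annotations(truth, cfg)
        assert all(a.family == "enzyme" for a in anns.values())

    def test_annotations_reproducible(self, small_campaign):
        config, _, truth = small_campaign
        a = generate_annotations(truth, config)
        b = generate_annotations(truth, config)
        assert a == b
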