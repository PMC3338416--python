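"""End-to-end orchestration of the differential screening pipeline.

Stages run in a fixed order — simulate, screen, fit, select, profile,
differential — each reading the files the previous stages wrote into the
run directory and appending an entry (parameters, input/output hashes,
headline counts) to a JSON manifest. Re-running an unchanged configuration
skips stages whose inputs, parameters and outputs all hash identically, so
a finished run is idempotent byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemotype as ct
from . import differential as da
from . import doseresponse as dr
from . import profiling as pf
from . import screening as sq
from . import simulate as sim
from .io import (read_affinity_db, read_annotations, read_pathways_gmt,
                 read_smiles_table, write_affinity_db, write_annotations,
                 write_pathways_gmt, write_smiles_table)

STAGES = ("simulate", "screen", "fit", "select", "profile", "differential")


@dataclass
class AnalysisParams:
    """Every decision threshold of the analysis, as named parameters."""

    viability_threshold: float = 20.0          # % viability at 50 uM, inclusive
    ratio_edges: tuple = dr.DEFAULT_RATIO_EDGES
    enrichment_threshold: float = 0.20         # strict, 'higher than 20% hit rate'
    pact_min: float = 6.0                      # inclusive, 1 uM or better
    oncoscore_cutoff: float = 0.7              # strict, 'above 0.7'
    drug_min_targets: int = 5                  # strict, 'more than 5'
    dose_response_cap: int | None = None       # round-1 dose-response budget
    diversity_n: int = 0                       # extra diversity picks in round 2


@dataclass
class PipelineConfig:
    outdir: str = "diviss_run"
    seed: int = 0
    stages: tuple = STAGES
    campaign: sim.CampaignConfig = field(default_factory=sim.CampaignConfig)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    profiling: pf.ProfilingConfig = field(default_factory=pf.ProfilingConfig)

    def __post_init__(self):
        self.campaign.seed = self.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    def canonical_hash(self) -> str:
        """Run identity: hash of the canonical config, independent of where
        the outputs land."""
        d = self.to_dict()
        d.pop("outdir", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()


def validate_config(path: str | Path) -> tuple[PipelineConfig | None, list[str]]:
    """Load and validate a YAML pipeline configuration.

    Returns (config, errors); config is None when any violation was found.
    Every violation names its field path; an empty file yields the full
    default configuration.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    errors: list[str] = []
    if not isinstance(raw, dict):
        return None, ["top level: expected a mapping"]
    known = {"outdir", "seed", "stages", "campaign", "analysis", "profiling"}
    for key in raw:
        if key not in known:
            errors.append(f"{key}: unknown field")

    def build(cls, section: str, overrides: dict):
        kwargs = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for k, v in (overrides or {}).items():
            if k not in fields:
                errors.append(f"{section}.{k}: unknown field")
            else:
                kwargs[k] = v
        try:
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            errors.append(f"{section}: {exc}")
            return cls()

    campaign = build(sim.CampaignConfig, "campaign", raw.get("campaign", {}))
    analysis = build(AnalysisParams, "analysis", raw.get("analysis", {}))
    profiling = build(pf.ProfilingConfig, "profiling", raw.get("profiling", {}))

    if not 0 <= analysis.viability_threshold <= 100:
        errors.append("analysis.viability_threshold: must lie in [0, 100]")
    if not 0 <= analysis.enrichment_threshold <= 1:
        errors.append("analysis.enrichment_threshold: must lie in [0, 1]")
    if analysis.pact_min < 0:
        errors.append("analysis.pact_min: must be >= 0")
    if not 0 <= analysis.oncoscore_cutoff <= 1:
        errors.append("analysis.oncoscore_cutoff: must lie in [0, 1]")
    edges = tuple(analysis.ratio_edges)
    if len(edges) != 4 or any(e <= 0 for e in edges) or list(edges) != sorted(edges):
        errors.append("analysis.ratio_edges: must be 4 increasing positive values")
    analysis.ratio_edges = edges
    stages = tuple(raw.get("stages", STAGES))
    for s in stages:
        if s not in STAGES:
            errors.append(f"stages: unknown stage {s!r}")
    if errors:
        return None, errors
    config = PipelineConfig(outdir=str(raw.get("outdir", "diviss_run")),
                            seed=int(raw.get("seed", 0)), stages=stages,
                            campaign=campaign, analysis=analysis,
                            profiling=profiling)
    return config, []


# ---------------------------------------------------------------------------

def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


class _Runner:
    """Stage executor with hashing-based caching and count conservation."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.previous = {}
        if self.manifest_path.exists():
            self.previous = json.loads(self.manifest_path.read_text()).get("stages", {})
        self.manifest = {"config_hash": config.canonical_hash(),
                         "seed": config.seed, "stages": {}}
        self.halted = False

    def path(self, name: str) -> Path:
        return self.out / name

    def _signature(self, params: dict, inputs: list[Path]) -> str:
        payload = {"params": params,
                   "inputs": {p.name: _hash_file(p) for p in inputs}}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()

    def run_stage(self, name: str, params: dict, inputs: list[str],
                  outputs: list[str], produce) -> None:
        if self.halted:
            return
        entry: dict = {"enabled": name in self.config.stages}
        if not entry["enabled"]:
            entry["skipped"] = "disabled in configuration"
            self.manifest["stages"][name] = entry
            return
        missing = [i for i in inputs if not self.path(i).exists()]
        if missing:
            producers = [s for s, e in self.manifest["stages"].items()
                         if e.get("skipped")]
            if producers:
                entry["skipped"] = (f"inputs {missing} unavailable "
                                    f"(upstream stage disabled)")
                self.manifest["stages"][name] = entry
                return
            raise FileNotFoundError(
                f"stage {name!r}: missing required inputs {missing}")
        in_paths = [self.path(i) for i in inputs]
        sig = self._signature(params, in_paths)
        prev = self.previous.get(name, {})
        out_paths = [self.path(o) for o in outputs]
        if (prev.get("signature") == sig and all(p.exists() for p in out_paths)
                and prev.get("outputs") == {p.name: _hash_file(p) for p in out_paths}):
            entry.update(prev)
            entry["cached"] = True
            self.manifest["stages"][name] = entry
            return
        counts = produce()
        entry.update({
            "signature": sig,
            "params": params,
            "inputs": {p.name: _hash_file(p) for p in in_paths},
            "outputs": {p.name: _hash_file(p) for p in out_paths},
            "counts": counts,
            "cached": False,
        })
        self.manifest["stages"][name] = entry

    def finalize(self) -> dict:
        # cache provenance stays in the returned manifest only, so a
        # re-executed unchanged run leaves every file byte-identical
        persisted = json.loads(json.dumps(self.manifest))
        for entry in persisted["stages"].values():
            entry.pop("cached", None)
        _write_json(persisted, self.manifest_path)
        return self.manifest


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order and return the run manifest."""
    runner = _Runner(config)
    camp = config.campaign
    ana = config.analysis

    # -- simulate ----------------------------------------------------------
    def do_simulate() -> dict:
        library, truth = sim.generate_library(camp)
        write_smiles_table(library, runner.path("library.tsv"))
        sim.write_ground_truth(truth, runner.path("truth_targets.tsv"),
                               runner.path("truth_compounds.tsv"))
        plates = sim.simulate_primary_screen(library, truth, camp)
        plates.to_csv(runner.path("plates.csv"), index=False)
        db = sim.generate_chemogenomics_db(truth, camp)
        write_affinity_db(db, runner.path("chemdb.tsv"))
        annotations = sim.generate_annotations(truth, camp)
        write_annotations(annotations, runner.path("annotations.tsv"))
        write_pathways_gmt(sim.generate_pathways(annotations, truth, camp),
                           runner.path("pathways.gmt"))
        return {"n_compounds": len(library),
                "n_targets": len(truth.targets),
                "n_db_interactions": db.n_interactions}

    runner.run_stage(
        "simulate", params=dataclasses.asdict(camp), inputs=[],
        outputs=["library.tsv", "truth_targets.tsv", "truth_compounds.tsv",
                 "plates.csv", "chemdb.tsv", "annotations.tsv", "pathways.gmt"],
        produce=do_simulate)

    # -- screen ------------------------------------------------------------
    def do_screen() -> dict:
        plates = pd.read_csv(runner.path("plates.csv"))
        stats = sq.plate_stats_from_frame(plates)
        viability = sq.normalize_plates(plates)
        viability.to_csv(runner.path("viability.tsv"), sep="\t", index=False)
        pairs, corr = sq.duplicate_concordance(viability)
        hits = sorted(sq.call_cytotoxic_hits(viability, ana.viability_threshold))
        runner.path("hits.txt").write_text("\n".join(hits) + ("\n" if hits else ""))
        zprimes = {pid: sq.zprime(s) for pid, s in stats.items()}
        qc = {"n_plates": len(stats),
              "mean_zprime": round(float(np.mean(list(zprimes.values()))), 4),
              "min_zprime": round(float(np.min(list(zprimes.values()))), 4),
              "mean_s_b": round(float(np.mean(
                  [sq.signal_to_background(s) for s in stats.values()])), 3),
              "duplicate_correlation": round(corr, 4)}
        _write_json(qc, runner.path("qc.json"))
        n_cmp = viability["compound_id"].nunique()
        return {"n_compounds": int(n_cmp), "n_hits": len(hits),
                "n_not_hit": int(n_cmp - len(hits)),
                "hit_rate_percent": round(100.0 * len(hits) / n_cmp, 1) if n_cmp else 0.0,
                **qc}

    runner.run_stage(
        "screen",
        params={"viability_threshold": ana.viability_threshold},
        inputs=["plates.csv"],
        outputs=["viability.tsv", "hits.txt", "qc.json"],
        produce=do_screen)

    # -- fit ---------------------------------------------------------------
    def do_fit() -> dict:
        hits = [h for h in runner.path("hits.txt").read_text().split() if h]
        library = read_smiles_table(runner.path("library.tsv"))
        truth = sim.read_ground_truth(runner.path("truth_targets.tsv"),
                                      runner.path("truth_compounds.tsv"))
        cap = ana.dose_response_cap
        if cap is not None and len(hits) > cap:
            round1 = ct.diversity_select(library.subset(hits), cap)
        else:
            round1 = list(hits)
        records = pd.concat([
            sim.simulate_dose_response(round1, truth, dr.TUMOR_LINE, camp),
            sim.simulate_dose_response(round1, truth, dr.NORMAL_LINE, camp),
        ], ignore_index=True)
        records.to_csv(runner.path("dose_response.csv"), index=False)
        fits = dr.fit_campaign(records, edges=tuple(ana.ratio_edges))
        fits.to_csv(runner.path("fits.tsv"), sep="\t", index=False)
        n_ts = int((fits["selectivity_class"] == "tumor_strong").sum())
        n_ns = int((fits["selectivity_class"] == "normal_strong").sum())
        return {"n_hits": len(hits), "n_dose_response": len(round1),
                "n_deferred": len(hits) - len(round1),
                "n_tumor_strong": n_ts, "n_normal_strong": n_ns,
                "n_data_points": int(sq.count_data_points(
                    0, 0, len(round1), camp.n_concentrations,
                    camp.n_replicates, 2))}

    runner.run_stage(
        "fit",
        params={"ratio_edges": list(ana.ratio_edges),
                "dose_response_cap": ana.dose_response_cap,
                "concentrations": list(camp.concentrations())},
        inputs=["hits.txt", "library.tsv", "truth_targets.tsv", "truth_compounds.tsv"],
        outputs=["dose_response.csv", "fits.tsv"],
        produce=do_fit)

    # -- select: chemotype enrichment and second dose-response round -------
    def do_select() -> dict:
        library = read_smiles_table(runner.path("library.tsv"))
        truth = sim.read_ground_truth(runner.path("truth_targets.tsv"),
                                      runner.path("truth_compounds.tsv"))
        fits = pd.read_csv(runner.path("fits.tsv"), sep="\t")
        tested = set(fits["compound_id"])
        selective = set(fits.loc[fits["selectivity_class"] == "tumor_strong",
                                 "compound_id"])
        clusters = ct.score_clusters(ct.cluster_library(library), selective, tested)
        rows = [{"scaffold_key": c.scaffold_key, "n_members": len(c.member_ids),
                 "n_tested": c.n_tested, "n_selective": c.n_selective,
                 "enrichment": np.nan if c.enrichment is None else round(c.enrichment, 4)}
                for c in sorted(clusters.values(), key=lambda c: c.scaffold_key)]
        pd.DataFrame(rows).to_csv(runner.path("chemotypes.tsv"), sep="\t", index=False)

        hits = [h for h in runner.path("hits.txt").read_text().split() if h]
        untested = [h for h in hits if h not in tested]
        expansion = ct.select_expansion(clusters, untested, ana.enrichment_threshold)
        if ana.diversity_n > 0:
            rest = [c for c in untested if c not in set(expansion)]
            if rest:
                expansion += ct.diversity_select(
                    library.subset(rest), min(ana.diversity_n, len(rest)))
        runner.path("expansion.txt").write_text(
            "\n".join(expansion) + ("\n" if expansion else ""))
        counts = {"n_clusters": len(clusters), "n_untested_hits": len(untested),
                  "n_expansion": len(expansion)}
        if expansion:  # second dose-response round on recovered compounds
            records = pd.concat([
                sim.simulate_dose_response(expansion, truth, dr.TUMOR_LINE, camp),
                sim.simulate_dose_response(expansion, truth, dr.NORMAL_LINE, camp),
            ], ignore_index=True)
            fits2 = dr.fit_campaign(records, edges=tuple(ana.ratio_edges))
            fits = pd.concat([fits, fits2], ignore_index=True)
            counts["n_tumor_strong_round2"] = int(
                (fits2["selectivity_class"] == "tumor_strong").sum())
        fits.to_csv(runner.path("fits_all.tsv"), sep="\t", index=False)
        counts["n_tested_total"] = int(fits["compound_id"].nunique())
        counts["n_tumor_strong_total"] = int(
            (fits["selectivity_class"] == "tumor_strong").sum())
        counts["n_normal_strong_total"] = int(
            (fits["selectivity_class"] == "normal_strong").sum())
        return counts

    runner.run_stage(
        "select",
        params={"enrichment_threshold": ana.enrichment_threshold,
                "diversity_n": ana.diversity_n},
        inputs=["library.tsv", "fits.tsv", "hits.txt",
                "truth_targets.tsv", "truth_compounds.tsv"],
        outputs=["chemotypes.tsv", "expansion.txt", "fits_all.tsv"],
        produce=do_select)

    # -- profile -----------------------------------------------------------
    def do_profile() -> dict:
        library = read_smiles_table(runner.path("library.tsv"))
        fits = pd.read_csv(runner.path("fits_all.tsv"), sep="\t")
        db = read_affinity_db(runner.path("chemdb.tsv"))
        models = pf.build_target_models(db, config.profiling)
        counts: dict = {"n_models": len(models)}
        for label, cls in (("tumor", "tumor_strong"), ("normal", "normal_strong")):
            ids = sorted(fits.loc[fits["selectivity_class"] == cls, "compound_id"])
            interactions = pf.profile_library(library.subset(ids), models,
                                              config.profiling)
            interactions.to_csv(runner.path(f"predictions_{label}.tsv"),
                                sep="\t", index=False)
            summary = pf.profile_summary(ids, interactions, ana.pact_min)
            counts[label] = dataclasses.asdict(summary)
        _write_json({k: counts[k] for k in ("tumor", "normal")},
                    runner.path("profile_summary.json"))
        return counts

    runner.run_stage(
        "profile",
        params={"pact_min": ana.pact_min,
                "profiling": dataclasses.asdict(config.profiling)},
        inputs=["library.tsv", "fits_all.tsv", "chemdb.tsv"],
        outputs=["predictions_tumor.tsv", "predictions_normal.tsv",
                 "profile_summary.json"],
        produce=do_profile)

    # -- differential ------------------------------------------------------
    def do_differential() -> dict:
        annotations = read_annotations(runner.path("annotations.tsv"))
        pred_t = pd.read_csv(runner.path("predictions_tumor.tsv"), sep="\t")
        pred_n = pd.read_csv(runner.path("predictions_normal.tsv"), sep="\t")
        t_set = set(pf.filter_potent(pred_t, ana.pact_min)["target_id"]) \
            if not pred_t.empty else set()
        n_set = set(pf.filter_potent(pred_n, ana.pact_min)["target_id"]) \
            if not pred_n.empty else set()
        venn = da.venn_partition(t_set, n_set)
        _write_json({"tumor_unique": sorted(venn.tumor_unique),
                     "shared": sorted(venn.shared),
                     "normal_unique": sorted(venn.normal_unique),
                     "sizes": {"tumor_unique": len(venn.tumor_unique),
                               "shared": len(venn.shared),
                               "normal_unique": len(venn.normal_unique)}},
                    runner.path("venn.json"))
        fam = da.family_composition(venn.tumor_unique, annotations)
        fam.to_csv(runner.path("family_composition.tsv"), sep="\t", index=False)
        ec = da.enzyme_class_composition(venn.tumor_unique, annotations)
        ec.to_csv(runner.path("enzyme_composition.tsv"), sep="\t", index=False)
        prioritized = da.high_score_subset(venn.tumor_unique, annotations,
                                           ana.oncoscore_cutoff)
        prioritized.to_csv(runner.path("prioritized_targets.tsv"),
                           sep="\t", index=False)
        drug_db = read_affinity_db(runner.path("chemdb.tsv"))
        drugs = da.rank_drugs(drug_db, venn.tumor_unique, ana.pact_min,
                              ana.drug_min_targets)
        da.drug_profile_frame(drugs).to_csv(runner.path("drug_profiles.tsv"),
                                            sep="\t", index=False)
        pathways = read_pathways_gmt(runner.path("pathways.gmt"))
        overlap, overlap_summary = da.pathway_overlap(
            pathways, prioritized["gene"] if not prioritized.empty else [])
        overlap.to_csv(runner.path("pathway_overlap.tsv"), sep="\t", index=False)
        return {"venn": {"tumor_unique": len(venn.tumor_unique),
                         "shared": len(venn.shared),
                         "normal_unique": len(venn.normal_unique)},
                "oncoscore_above_cutoff_percent": da.oncoscore_cumulative(
                    venn.tumor_unique, annotations, ana.oncoscore_cutoff),
                "n_prioritized": len(prioritized),
                "n_regulation_flagged": da.count_regulation_flagged(prioritized),
                "n_multi_target_drugs": len(drugs),
                "pathway_overlap": overlap_summary}

    runner.run_stage(
        "differential",
        params={"pact_min": ana.pact_min,
                "oncoscore_cutoff": ana.oncoscore_cutoff,
                "drug_min_targets": ana.drug_min_targets},
        inputs=["predictions_tumor.tsv", "predictions_normal.tsv",
                "annotations.tsv", "chemdb.tsv", "pathways.gmt"],
        outputs=["venn.json", "family_composition.tsv", "enzyme_composition.tsv",
                 "prioritized_targets.tsv", "drug_profiles.tsv",
                 "pathway_overlap.tsv"],
        produce=do_differential)

    return runner.finalize()


def evaluate_recovery(outdir: str | Path, truth: sim.GroundTruth | None = None
                      ) -> dict:
    """Compare a finished run's tumor-unique list with the campaign's planted
    cancer targets (validation harness; analysis stages never read truth)."""
    out = Path(outdir)
    if truth is None:
        truth = sim.read_ground_truth(out / "truth_targets.tsv",
                                      out / "truth_compounds.tsv")
    venn = json.loads((out / "venn.json").read_text())
    planted = truth.cancer_targets()
    recovered = planted & set(venn["tumor_unique"])
    return {"n_planted": len(planted), "n_recovered": len(recovered),
            "recovery_fraction": len(recovered) / len(planted) if planted else 0.0,
            "missed": sorted(planted - recovered)}
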