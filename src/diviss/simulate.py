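"""Synthetic differential-screening campaign generator.

Generates everything a DIVISS-style analysis consumes — a compound library,
single-point duplicate viability plates with controls, six-point duplicate
dose-response data on a tumor (HCT116) and a normal (MRC-5) cell line, a
ligand-target chemogenomics database with planted neighbor structure, and
target annotations — together with the exported ground truth, so that every
downstream stage can be tested for parameter recovery.

Model
-----
Structures come from a fixed scaffold x substituent grammar (chemically
valid by construction). Each synthetic protein target owns one scaffold and
an archetype potency; a compound active on a target carries a true potency
pAct and its cell-line toxicity follows

    IC50_line (uM) = 10^(6 - pAct) / w_line

where w_line in (0, 1] is the target's relevance weight for that cell line.
The selectivity ratio R = IC50(normal)/IC50(tumor) = w_tumor/w_normal is
therefore a property of the planted target, shared by its ligands, and the
ground truth is exactly recomputable from the planted potencies. Viability
is a logistic (Hill) law of concentration with both asymptotes fixed plus
Gaussian noise.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .doseresponse import NORMAL_LINE, TUMOR_LINE, logistic_viability
from .io import ChemogenomicsDB, Compound, CompoundLibrary, TargetAnnotation
from .screening import CONTROL_NEG, CONTROL_POS

CLASSES = ("inactive", "unselective_cytotoxic", "tumor_selective", "normal_selective")


@dataclass
class CampaignConfig:
    """Study conditions of a synthetic campaign.

    Defaults mirror a 50 uM single-point duplicate screen with six-point
    duplicate threefold dilution dose-response follow-up, control CVs of a
    resazurin assay (Z' in the 0.6-0.8 band, S/B ~ 10) and a ~14% cytotoxic
    rate with a ~1% selective tail on each side.
    """

    n_compounds: int = 2000
    fraction_cytotoxic: float = 0.14        # true tumor IC50 <= top concentration
    fraction_tumor_selective: float = 0.012
    fraction_normal_selective: float = 0.012
    n_cancer_targets: int = 20
    n_normal_targets: int = 8
    n_housekeeping_targets: int = 8
    top_concentration_um: float = 50.0
    dilution_factor: float = 3.0
    n_concentrations: int = 6
    n_replicates: int = 2
    pos_control_mean: float = 10000.0
    pos_control_cv: float = 0.05
    neg_control_mean: float = 1000.0
    neg_control_cv: float = 0.05
    n_control_wells: int = 16
    compounds_per_plate: int = 160
    viability_noise_sd: float = 5.0         # percentage points
    hill_slope: float = 1.0
    archetype_pact_mean: float = 7.0
    archetype_pact_sd: float = 0.3
    db_ligands_per_target: int = 8   # capped at the series family size
    series_bias: float = 0.75        # P(active compound uses its target's series)
    scaffold_collision_margin: float = 0.5
    #: substituent families tight enough in descriptor space to give sharp
    #: applicability domains; planted cancer- and normal-relevant targets
    #: draw their ligand series from these so their domains stay selective
    selective_series_families: tuple = ("alkyl", "inert")
    #: normal-relevant actives are strict congeners of their target's series
    normal_series_bias: float = 1.0
    regulation_flag_fraction: float = 0.25  # of cancer targets
    family_proportions: dict = field(default_factory=lambda: {
        "enzyme": 0.50, "GPCR": 0.22, "ion_channel": 0.10,
        "nuclear_receptor": 0.06, "transporter": 0.06, "other": 0.06})
    ec_proportions: dict = field(default_factory=lambda: {
        "transferase": 0.45, "hydrolase": 0.20, "oxidoreductase": 0.15,
        "lyase": 0.08, "isomerase": 0.06, "ligase": 0.06})
    seed: int = 0

    def __post_init__(self):
        for name in ("fraction_cytotoxic", "fraction_tumor_selective",
                     "fraction_normal_selective"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if (self.fraction_tumor_selective + self.fraction_normal_selective
                > self.fraction_cytotoxic):
            raise ValueError("selective fractions cannot exceed the cytotoxic fraction")
        if self.n_compounds < 0:
            raise ValueError("n_compounds must be >= 0")
        if self.dilution_factor <= 1:
            raise ValueError("dilution factor must be > 1")

    def concentrations(self) -> np.ndarray:
        """Strictly decreasing dilution series (uM)."""
        return self.top_concentration_um / self.dilution_factor ** np.arange(
            self.n_concentrations)

    def rng(self, stage: str) -> np.random.Generator:
        """Stage-scoped substream of the campaign seed."""
        stage_key = int.from_bytes(stage.encode(), "little") % (2 ** 31)
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage_key]))


def _load_grammar() -> tuple[pd.DataFrame, pd.DataFrame]:
    data = importlib.resources.files("diviss.data")
    with importlib.resources.as_file(data / "scaffolds.tsv") as p:
        scaffolds = pd.read_csv(p, sep="\t")
    with importlib.resources.as_file(data / "substituents.tsv") as p:
        substituents = pd.read_csv(p, sep="\t")
    if scaffolds.empty or substituents.empty:
        raise ValueError("empty structure grammar fixture")
    return scaffolds, substituents


@dataclass
class GroundTruth:
    """Planted facts of a campaign: per-target weights and archetypes and
    per-compound class, potency and true IC50s. Never read by analysis
    stages — test harness and validation only."""

    targets: pd.DataFrame    # target_id, scaffold_id, template, archetype_smiles,
    #                          archetype_pact, tumor_weight, normal_weight,
    #                          ratio, is_cancer_target, group
    compounds: pd.DataFrame  # compound_id, smiles, class, target_id, pact,
    #                          ic50_tumor_um, ic50_normal_um

    def true_ic50(self, compound_id: str, cell_line: str) -> float:
        row = self.compounds.set_index("compound_id").loc[compound_id]
        if cell_line == TUMOR_LINE:
            return float(row["ic50_tumor_um"])
        if cell_line == NORMAL_LINE:
            return float(row["ic50_normal_um"])
        raise ValueError(f"unknown cell line {cell_line!r}")

    def cancer_targets(self) -> set[str]:
        return set(self.targets.loc[self.targets["is_cancer_target"], "target_id"])

    def recompute_ic50(self, pact: float, weight: float) -> float:
        """Viability-model-consistent IC50 (uM) from a planted potency."""
        return np.inf if weight <= 0 else 10.0 ** (6.0 - pact) / weight


def _scaffold_components(scaffolds: pd.DataFrame, margin: float) -> list[list[int]]:
    """Connected components of the scaffold collision graph.

    Two scaffolds collide when, probed with a shared small substituent, any
    descriptor space puts them closer than ``margin`` — close enough that a
    ligand of one could fall inside an applicability domain built on the
    other. Components are kept within a single target group so planted
    cancer targets cannot be aliased by normal-relevant chemistry.
    """
    from .descriptors import SPACES, compute_all_descriptors, molecule_distance

    probes = ("[H]", "C")
    desc = [[compute_all_descriptors(t.replace("{R}", p)) for p in probes]
            for t in scaffolds["template"]]
    n = len(scaffolds)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            close = any(
                min(molecule_distance(desc[i][k][s], desc[j][k][s])
                    for k in range(len(probes))) < margin
                for s in SPACES)
            if close:
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return sorted(comps.values(), key=lambda c: (-len(c), c[0]))


def _make_targets(config: CampaignConfig, scaffolds: pd.DataFrame,
                  substituents: pd.DataFrame,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Target panel: each target owns a scaffold and a congeneric substituent
    family (its ligand series); tumor/normal relevance weights encode the
    planted selectivity ratio of its ligands."""
    quotas = {"cancer": config.n_cancer_targets,
              "normal": config.n_normal_targets,
              "housekeeping": config.n_housekeeping_targets}
    # deal collision components to groups, largest remaining quota first
    pools: dict[str, list[int]] = {g: [] for g in quotas}
    remaining = dict(quotas)
    for comp in _scaffold_components(scaffolds, config.scaffold_collision_margin):
        group = max(remaining, key=lambda g: remaining[g])
        pools[group].extend(comp)
        remaining[group] = max(remaining[group] - len(comp), 0)
    families = sorted(substituents["family"].unique())
    rows = []
    k = 0
    for group, quota in quotas.items():
        pool = pools[group] or list(range(len(scaffolds)))
        for t in range(quota):
            scf_idx = pool[t % len(pool)] if t < len(pool) else int(rng.choice(pool))
            if group == "cancer":
                ratio = float(10.0 ** rng.uniform(np.log10(8.0), np.log10(50.0)))
                w_t, w_n = 1.0, 1.0 / ratio
            elif group == "normal":
                ratio = float(10.0 ** rng.uniform(np.log10(0.02), np.log10(0.125)))
                w_t, w_n = ratio, 1.0
            else:
                ratio = float(10.0 ** rng.uniform(np.log10(0.6), np.log10(1.67)))
                w_t, w_n = 1.0, 1.0 / ratio
            template = scaffolds.iloc[scf_idx]["template"]
            pool_families = (list(config.selective_series_families)
                             if group in ("cancer", "normal") else families)
            family = pool_families[int(rng.integers(len(pool_families)))]
            # the archetype is the scaffold decorated with its series' lead
            # substituent, so it sits inside its own ligand ensemble
            lead = substituents.loc[substituents["family"] == family,
                                    "smiles"].iloc[0]
            rows.append({
                "target_id": f"TGT{k + 1:03d}",
                "group": group,
                "is_cancer_target": group == "cancer",
                "scaffold_id": scaffolds.iloc[scf_idx]["scaffold_id"],
                "template": template,
                "archetype_smiles": template.replace("{R}", lead),
                "series_family": family,
                "archetype_pact": float(rng.normal(config.archetype_pact_mean,
                                                   config.archetype_pact_sd)),
                "tumor_weight": w_t,
                "normal_weight": w_n,
                "ratio": ratio,
            })
            k += 1
    return pd.DataFrame(rows)


def generate_library(config: CampaignConfig
                     ) -> tuple[CompoundLibrary, GroundTruth]:
    """Compound library plus exported ground truth.

    Class fractions hold in expectation (per-compound Bernoulli draws), with
    one guaranteed bare-archetype probe per planted cancer and normal-
    relevant target so that every planted target is recoverable downstream.
    """
    scaffolds, substituents = _load_grammar()
    rng = config.rng("library")
    targets = _make_targets(config, scaffolds, substituents, rng)
    n = config.n_compounds
    if n == 0:
        return CompoundLibrary(), GroundTruth(targets, pd.DataFrame(
            columns=["compound_id", "smiles", "class", "target_id", "pact",
                     "ic50_tumor_um", "ic50_normal_um"]))

    p_ts = config.fraction_tumor_selective
    p_ns = config.fraction_normal_selective
    p_un = config.fraction_cytotoxic - p_ts - p_ns
    classes = rng.choice(
        ["tumor_selective", "normal_selective", "unselective_cytotoxic", "inactive"],
        size=n, p=[p_ts, p_ns, p_un, 1.0 - config.fraction_cytotoxic])

    # guarantee one probe slot per planted cancer / normal target
    probes: list[tuple[int, str]] = []  # (compound index, target_id)
    for group, cls in (("cancer", "tumor_selective"), ("normal", "normal_selective")):
        tids = list(targets.loc[targets["group"] == group, "target_id"])
        slots = list(np.flatnonzero(classes == cls))
        while len(slots) < len(tids):
            spare = np.flatnonzero(classes == "inactive")
            if spare.size == 0:
                spare = np.flatnonzero(classes == "unselective_cytotoxic")
            if spare.size == 0:
                raise ValueError(
                    "n_compounds too small to plant one selective probe "
                    "per cancer/normal target")
            extra = int(rng.choice(spare))
            classes[extra] = cls
            slots.append(extra)
        for tid, slot in zip(tids, sorted(slots)[:len(tids)]):
            probes.append((slot, tid))
    probe_target = dict(probes)

    by_group = {g: targets[targets["group"] == g].reset_index(drop=True)
                for g in ("cancer", "normal", "housekeeping")}
    sub_smiles = list(substituents["smiles"])
    by_family = {f: list(g["smiles"]) for f, g in substituents.groupby("family")}
    top = config.top_concentration_um

    lib = CompoundLibrary()
    rows = []
    for i in range(n):
        cid = f"CMP{i + 1:06d}"
        cls = classes[i]
        if cls == "inactive":
            template = scaffolds.iloc[int(rng.integers(len(scaffolds)))]["template"]
            smiles = template.replace("{R}", sub_smiles[int(rng.integers(len(sub_smiles)))])
            tid, pact, ic50_t, ic50_n = "", np.nan, np.inf, np.inf
        else:
            group = {"tumor_selective": "cancer", "normal_selective": "normal",
                     "unselective_cytotoxic": "housekeeping"}[cls]
            pool = by_group[group]
            if i in probe_target:
                trow = pool.set_index("target_id").loc[probe_target[i]]
                tid = probe_target[i]
                smiles = trow["archetype_smiles"]
                ic50_t = 1.0  # probes are potently cytotoxic by construction
            else:
                trow = pool.iloc[int(rng.integers(len(pool)))]
                tid = trow["target_id"]
                # actives resemble their target's known ligand series more
                # often than not (congeneric SAR)
                bias = (config.normal_series_bias if cls == "normal_selective"
                        else config.series_bias)
                if rng.random() < bias:
                    series = by_family[trow["series_family"]]
                    sub = series[int(rng.integers(len(series)))]
                else:
                    sub = sub_smiles[int(rng.integers(len(sub_smiles)))]
                smiles = trow["template"].replace("{R}", sub)
                lo, hi = (0.1, 10.0) if cls != "unselective_cytotoxic" else (0.1, 25.0)
                ic50_t = float(10.0 ** rng.uniform(np.log10(lo), np.log10(hi)))
            w_t, w_n = float(trow["tumor_weight"]), float(trow["normal_weight"])
            pact = 6.0 - np.log10(ic50_t * w_t)
            ic50_n = 10.0 ** (6.0 - pact) / w_n if w_n > 0 else np.inf
        lib.add(Compound(id=cid, smiles=smiles, source="synthetic"))
        rows.append({"compound_id": cid, "smiles": smiles, "class": cls,
                     "target_id": tid, "pact": pact,
                     "ic50_tumor_um": ic50_t, "ic50_normal_um": ic50_n})
    truth = GroundTruth(targets, pd.DataFrame(rows))
    # invariant: cytotoxic fraction counts compounds with tumor IC50 <= top
    assert (truth.compounds["ic50_tumor_um"] <= top).sum() == (classes != "inactive").sum()
    return lib, truth


def _true_viability(ic50_um: float, conc_um, slope: float) -> np.ndarray:
    if not np.isfinite(ic50_um):
        return np.full(np.shape(conc_um), 100.0)
    return logistic_viability(np.asarray(conc_um, dtype=float), ic50_um, slope)


def simulate_primary_screen(library: CompoundLibrary, truth: GroundTruth,
                            config: CampaignConfig) -> pd.DataFrame:
    """Raw-signal plate table of the 50 uM duplicate single-point screen on
    the tumor line, with positive/negative control wells per plate."""
    rng = config.rng("primary")
    ic50 = truth.compounds.set_index("compound_id")["ic50_tumor_um"]
    missing = [c.id for c in library if c.id not in ic50.index]
    if missing:
        raise ValueError(f"ground truth does not cover compounds: {missing[:5]}")
    conc = config.top_concentration_um
    span = config.pos_control_mean - config.neg_control_mean
    rows = []
    ids = library.ids()
    n_per_plate = config.compounds_per_plate
    for p_start in range(0, max(len(ids), 1), n_per_plate):
        plate_ids = ids[p_start:p_start + n_per_plate]
        if not plate_ids:
            break
        plate = f"P{p_start // n_per_plate + 1:03d}"
        well = 0
        for kind, mean, cv in ((CONTROL_POS, config.pos_control_mean, config.pos_control_cv),
                               (CONTROL_NEG, config.neg_control_mean, config.neg_control_cv)):
            for _ in range(config.n_control_wells):
                well += 1
                rows.append({"plate_id": plate, "well": f"W{well:03d}",
                             "compound_id": kind, "cell_line": TUMOR_LINE,
                             "concentration_um": 0.0, "replicate": 1,
                             "raw_signal": float(rng.normal(mean, cv * mean))})
        for cid in plate_ids:
            v_true = float(_true_viability(float(ic50[cid]), conc, config.hill_slope))
            for rep in range(1, config.n_replicates + 1):
                well += 1
                v = v_true + float(rng.normal(0.0, config.viability_noise_sd))
                raw = config.neg_control_mean + v / 100.0 * span
                rows.append({"plate_id": plate, "well": f"W{well:03d}",
                             "compound_id": cid, "cell_line": TUMOR_LINE,
                             "concentration_um": conc, "replicate": rep,
                             "raw_signal": raw})
    return pd.DataFrame(rows)


def simulate_dose_response(compound_ids, truth: GroundTruth, cell_line: str,
                           config: CampaignConfig) -> pd.DataFrame:
    """Viability table of the six-point duplicate dose-response screen for
    the given compounds on one cell line."""
    if cell_line not in (TUMOR_LINE, NORMAL_LINE):
        raise ValueError(f"unknown cell line {cell_line!r}")
    rng = config.rng(f"doseresponse:{cell_line}")
    conc = config.concentrations()
    col = "ic50_tumor_um" if cell_line == TUMOR_LINE else "ic50_normal_um"
    ic50 = truth.compounds.set_index("compound_id")[col]
    rows = []
    for cid in compound_ids:
        v_true = _true_viability(float(ic50[cid]), conc, config.hill_slope)
        for c, v in zip(conc, v_true):
            for rep in range(1, config.n_replicates + 1):
                noise = float(rng.normal(0.0, config.viability_noise_sd)) \
                    if config.viability_noise_sd > 0 else 0.0
                rows.append({"compound_id": cid, "cell_line": cell_line,
                             "concentration_um": float(c), "replicate": rep,
                             "viability": float(v) + noise})
    return pd.DataFrame(rows)


def generate_chemogenomics_db(truth: GroundTruth, config: CampaignConfig
                              ) -> ChemogenomicsDB:
    """Ligand-target affinity DB with planted neighbor structure.

    Each target's first ligand is its archetype itself (at the archetype
    potency, guaranteeing a zero-distance neighbor for archetype probes);
    the rest are single-substituent perturbations of the archetype scaffold
    with pActs scattered around the archetype potency.
    """
    _, substituents = _load_grammar()
    rng = config.rng("chemdb")
    by_family = {f: list(g["smiles"]) for f, g in substituents.groupby("family")}
    rows = []
    for trow in truth.targets.itertuples(index=False):
        rows.append({"ligand_id": f"{trow.target_id}_L000",
                     "smiles": trow.archetype_smiles,
                     "target_id": trow.target_id,
                     "pact": trow.archetype_pact, "source": "synthetic"})
        series = [s for s in by_family[trow.series_family]
                  if trow.template.replace("{R}", s) != trow.archetype_smiles]
        n_extra = min(max(config.db_ligands_per_target - 1, 0), len(series))
        picks = rng.choice(len(series), size=n_extra, replace=False)
        for j, s_idx in enumerate(sorted(int(i) for i in picks), start=1):
            rows.append({"ligand_id": f"{trow.target_id}_L{j:03d}",
                         "smiles": trow.template.replace("{R}", series[s_idx]),
                         "target_id": trow.target_id,
                         "pact": float(rng.normal(trow.archetype_pact,
                                                  config.archetype_pact_sd)),
                         "source": "synthetic"})
    return ChemogenomicsDB(pd.DataFrame(rows))


def generate_annotations(truth: GroundTruth, config: CampaignConfig
                         ) -> dict[str, TargetAnnotation]:
    """Target annotations: families/EC classes from configured proportions,
    Beta(8,2) OncoScores for planted cancer targets vs Beta(2,8) otherwise,
    regulation flags on a configured subset of the cancer targets."""
    rng = config.rng("annotations")
    fams, fam_p = zip(*sorted(config.family_proportions.items()))
    fam_p = np.array(fam_p) / np.sum(fam_p)
    ecs, ec_p = zip(*sorted(config.ec_proportions.items()))
    ec_p = np.array(ec_p) / np.sum(ec_p)
    out: dict[str, TargetAnnotation] = {}
    for trow in truth.targets.itertuples(index=False):
        family = str(rng.choice(fams, p=fam_p))
        ec = str(rng.choice(ecs, p=ec_p)) if family == "enzyme" else "none"
        if trow.is_cancer_target:
            score = float(rng.beta(8, 2))
            regulation = (str(rng.choice(["up", "down"]))
                          if rng.random() < config.regulation_flag_fraction else "none")
        else:
            score = float(rng.beta(2, 8))
            regulation = "none"
        out[trow.target_id] = TargetAnnotation(
            target_id=trow.target_id, gene=f"GENE{trow.target_id[3:]}",
            family=family, ec_class=ec, oncoscore=round(score, 3),
            regulation=regulation)
    return out


def generate_pathways(annotations: dict[str, TargetAnnotation],
                      truth: GroundTruth, config: CampaignConfig,
                      n_pathways: int = 12) -> list:
    """Synthetic gene-set panel: one core signaling pathway concentrating
    planted cancer-target genes plus random background pathways."""
    from .io import PathwaySet

    rng = config.rng("pathways")
    genes = sorted(a.gene for a in annotations.values())
    cancer_genes = sorted(annotations[t].gene for t in truth.cancer_targets()
                          if t in annotations)
    pathways = []
    core = set(cancer_genes[:7])
    core |= {genes[int(i)] for i in rng.choice(len(genes), size=3, replace=False)}
    pathways.append(PathwaySet(name="SIG_CORE_PROLIFERATION", genes=frozenset(core)))
    for k in range(1, n_pathways):
        size = int(rng.integers(4, 12))
        members = {genes[int(i)] for i in
                   rng.choice(len(genes), size=min(size, len(genes)), replace=False)}
        pathways.append(PathwaySet(name=f"PW{k:03d}", genes=frozenset(members)))
    return pathways


def pad_annotation_panel(reference: dict[str, TargetAnnotation], n_total: int,
                         seed: int = 0) -> dict[str, TargetAnnotation]:
    """Pad an annotation panel to ``n_total`` targets with synthetic
    low-OncoScore entries (scores <= 0.65, some missing), preserving the
    reference entries. The padding is synthetic stand-in data for target
    sets whose remaining members are not individually published."""
    rng = np.random.default_rng(seed)
    out = dict(reference)
    k = 0
    while len(out) < n_total:
        k += 1
        tid = f"SYN{k:03d}"
        if tid in out:
            continue
        score = None if rng.random() < 0.2 else round(float(rng.uniform(0.0, 0.65)), 3)
        family = str(rng.choice(["enzyme", "GPCR", "other"], p=[0.5, 0.3, 0.2]))
        out[tid] = TargetAnnotation(
            target_id=tid, gene=tid, family=family,
            ec_class="transferase" if family == "enzyme" else "none",
            oncoscore=score, regulation="none")
    return out


def write_ground_truth(truth: GroundTruth, targets_path, compounds_path) -> None:
    truth.targets.to_csv(targets_path, sep="\t", index=False)
    truth.compounds.to_csv(compounds_path, sep="\t", index=False)


def read_ground_truth(targets_path, compounds_path) -> GroundTruth:
    return GroundTruth(pd.read_csv(targets_path, sep="\t"),
                       pd.read_csv(compounds_path, sep="\t"))
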