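"""Differential target-set analytics.

Set algebra on the tumor- and normal-selective target profiles (Venn
partition), protein-family and enzyme-class composition, oncogene-probability
(OncoScore) prioritization, multi-target drug ranking against the
tumor-unique list, and pathway-membership counting.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import ChemogenomicsDB, PathwaySet, TargetAnnotation

PAFF_BINS = ((6.0, 7.0), (7.0, 8.0), (8.0, 9.0), (9.0, float("inf")))


@dataclass(frozen=True)
class VennPartition:
    """Disjoint decomposition of two predicted target sets."""

    tumor_unique: frozenset[str]
    shared: frozenset[str]
    normal_unique: frozenset[str]

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.tumor_unique), len(self.shared), len(self.normal_unique)


def venn_partition(tumor_targets, normal_targets) -> VennPartition:
    """tumor_unique = T \\ N, shared = T ∩ N, normal_unique = N \\ T."""
    t, n = frozenset(tumor_targets), frozenset(normal_targets)
    return VennPartition(tumor_unique=t - n, shared=t & n, normal_unique=n - t)


def _annotation_for(tid: str, annotations: dict[str, TargetAnnotation]
                    ) -> TargetAnnotation | None:
    return annotations.get(tid) or annotations.get(tid.upper())


def family_composition(target_set, annotations: dict[str, TargetAnnotation]
                       ) -> pd.DataFrame:
    """Counts and integer-rounded percentages per protein family.

    Targets without an annotation fall into family 'other' and are counted
    in the ``unannotated`` column.
    """
    targets = sorted(set(target_set))
    if not targets:
        return pd.DataFrame(columns=["family", "count", "percent", "unannotated"])
    rows: dict[str, dict] = {}
    for tid in targets:
        ann = _annotation_for(tid, annotations)
        family = ann.family if ann is not None else "other"
        rec = rows.setdefault(family, {"family": family, "count": 0, "unannotated": 0})
        rec["count"] += 1
        rec["unannotated"] += int(ann is None)
    df = pd.DataFrame(sorted(rows.values(), key=lambda r: (-r["count"], r["family"])))
    df["percent"] = (100.0 * df["count"] / len(targets)).round().astype(int)
    return df[["family", "count", "percent", "unannotated"]]


def enzyme_class_composition(target_set, annotations: dict[str, TargetAnnotation]
                             ) -> pd.DataFrame:
    """Composition across EC top classes of the enzymes in the set."""
    enzymes = [tid for tid in sorted(set(target_set))
               if (a := _annotation_for(tid, annotations)) is not None
               and a.family == "enzyme"]
    if not enzymes:
        return pd.DataFrame(columns=["ec_class", "count", "percent"])
    counts: dict[str, int] = {}
    for tid in enzymes:
        ec = _annotation_for(tid, annotations).ec_class
        counts[ec] = counts.get(ec, 0) + 1
    df = pd.DataFrame(sorted(({"ec_class": k, "count": v} for k, v in counts.items()),
                             key=lambda r: (-r["count"], r["ec_class"])))
    df["percent"] = (100.0 * df["count"] / len(enzymes)).round().astype(int)
    return df


def oncoscore_cumulative(target_set, annotations: dict[str, TargetAnnotation],
                         cutoff: float) -> float:
    """Percentage (1 dp) of set members with OncoScore strictly above the
    cutoff; members without a score stay in the denominator (NA category)."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    targets = sorted(set(target_set))
    if not targets:
        return 0.0
    above = sum(
        1 for tid in targets
        if (a := _annotation_for(tid, annotations)) is not None
        and a.oncoscore is not None and a.oncoscore > cutoff)
    return round(100.0 * above / len(targets), 1)


def high_score_subset(target_set, annotations: dict[str, TargetAnnotation],
                      cutoff: float = 0.7) -> pd.DataFrame:
    """Ranked table of set members with OncoScore strictly above the cutoff,
    sorted by score descending then protein name, carrying regulation flags."""
    rows = []
    for tid in sorted(set(target_set)):
        ann = _annotation_for(tid, annotations)
        if ann is None or ann.oncoscore is None or not ann.oncoscore > cutoff:
            continue
        rows.append({"target_id": ann.target_id, "gene": ann.gene,
                     "name": ann.name, "oncoscore": ann.oncoscore,
                     "regulation": ann.regulation})
    df = pd.DataFrame(rows, columns=["target_id", "gene", "name", "oncoscore",
                                     "regulation"])
    if df.empty:
        return df
    return df.sort_values(["oncoscore", "name", "gene"],
                          ascending=[False, True, True]).reset_index(drop=True)


def count_regulation_flagged(table: pd.DataFrame) -> int:
    """Rows known to be up- or down-regulated in the tumor tissue."""
    if table.empty:
        return 0
    return int(table["regulation"].isin(("up", "down")).sum())


@dataclass(frozen=True)
class DrugProfileRow:
    drug_id: str
    paffinities: tuple[tuple[str, float], ...]  # (target, experimental pAff >= cut)
    n_targets: int
    bin_counts: tuple[int, int, int, int]       # [6,7) [7,8) [8,9) [9,inf)


def _bin_index(paff: float) -> int | None:
    for k, (lo, hi) in enumerate(PAFF_BINS):
        if lo <= paff < hi:
            return k
    return None


def rank_drugs(drug_db: ChemogenomicsDB, tumor_unique, paff_min: float = 6.0,
               min_targets: int = 5) -> list[DrugProfileRow]:
    """Drugs hitting strictly more than ``min_targets`` tumor-unique targets
    with experimental pAffinity >= paff_min, sorted by target count
    descending then drug id. Each qualifying affinity is binned per log unit.
    """
    wanted = set(tumor_unique)
    rows: list[DrugProfileRow] = []
    hits = drug_db.interactions[
        drug_db.interactions["target_id"].isin(wanted)
        & (drug_db.interactions["pact"] >= paff_min)]
    for drug_id, grp in hits.groupby("ligand_id", sort=True):
        if len(grp) <= min_targets:
            continue
        pairs = tuple(sorted(zip(grp["target_id"], grp["pact"].astype(float))))
        bins = [0, 0, 0, 0]
        for _, paff in pairs:
            k = _bin_index(paff)
            if k is not None:
                bins[k] += 1
        rows.append(DrugProfileRow(str(drug_id), pairs, len(pairs), tuple(bins)))
    rows.sort(key=lambda r: (-r.n_targets, r.drug_id))
    return rows


def drug_profile_frame(rows: list[DrugProfileRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"drug_id": r.drug_id, "n_targets": r.n_targets,
          "bin_6_7": r.bin_counts[0], "bin_7_8": r.bin_counts[1],
          "bin_8_9": r.bin_counts[2], "bin_9_plus": r.bin_counts[3]}
         for r in rows],
        columns=["drug_id", "n_targets", "bin_6_7", "bin_7_8", "bin_8_9",
                 "bin_9_plus"])


def pathway_overlap(pathways: list[PathwaySet], gene_set
                    ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-pathway overlap with a gene set plus summary counts of pathways
    with >= 2 and >= 5 overlapping genes. Symbols are matched upper-case."""
    genes = {str(g).upper() for g in gene_set}
    rows = [{"pathway": p.name,
             "n_genes": len(p.genes),
             "overlap": len(p.genes & genes),
             "overlap_genes": ";".join(sorted(p.genes & genes))}
            for p in pathways]
    df = pd.DataFrame(rows, columns=["pathway", "n_genes", "overlap", "overlap_genes"])
    if not df.empty:
        df = df.sort_values(["overlap", "pathway"],
                            ascending=[False, True]).reset_index(drop=True)
    summary = {"n_pathways": len(df),
               "ge2": int((df["overlap"] >= 2).sum()) if not df.empty else 0,
               "ge5": int((df["overlap"] >= 5).sum()) if not df.empty else 0}
    return df, summary
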