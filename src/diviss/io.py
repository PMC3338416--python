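"""Domain types and readers/writers for every file the pipeline touches.

All structures are canonicalized at read time (RDKit canonical SMILES is the
identity of a compound throughout the package) and every potency is carried
internally as pAct = -log10(molar activity); unit conversions happen only at
I/O boundaries.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

FAMILIES = ("GPCR", "enzyme", "ion_channel", "nuclear_receptor", "transporter", "other")
EC_CLASSES = (
    "oxidoreductase",
    "transferase",
    "hydrolase",
    "lyase",
    "isomerase",
    "ligase",
    "none",
)
REGULATIONS = ("up", "down", "none", "missing")


class FormatError(ValueError):
    """Raised when an input file violates its documented schema."""


def canonical_smiles(smiles: str) -> str | None:
    """RDKit canonical SMILES, or None if the string does not parse to a
    molecule with at least one heavy atom."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumHeavyAtoms() < 1:
        return None
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class Compound:
    """An identified molecule with a parseable structure."""

    id: str
    smiles: str  # canonical form
    source: str = ""

    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


@dataclass
class ParseReport:
    """Bookkeeping for a reader: accepted + rejected == total input rows."""

    n_total: int = 0
    n_accepted: int = 0
    rejections: list[tuple[int, str]] = field(default_factory=list)  # (row, reason)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)


class CompoundLibrary:
    """Ordered, id-unique collection of compounds."""

    def __init__(self, compounds: list[Compound] | None = None,
                 report: ParseReport | None = None):
        self._compounds: list[Compound] = []
        self._by_id: dict[str, Compound] = {}
        self.report = report or ParseReport()
        for c in compounds or []:
            self.add(c)

    def add(self, compound: Compound) -> None:
        if not compound.id:
            raise ValueError("compound id must be non-empty")
        if compound.id in self._by_id:
            raise ValueError(f"duplicate compound id: {compound.id!r}")
        self._compounds.append(compound)
        self._by_id[compound.id] = compound

    def __len__(self) -> int:
        return len(self._compounds)

    def __iter__(self) -> Iterator[Compound]:
        return iter(self._compounds)

    def __contains__(self, cid: str) -> bool:
        return cid in self._by_id

    def __getitem__(self, cid: str) -> Compound:
        return self._by_id[cid]

    def ids(self) -> list[str]:
        return [c.id for c in self._compounds]

    def subset(self, ids) -> "CompoundLibrary":
        wanted = set(ids)
        return CompoundLibrary([c for c in self._compounds if c.id in wanted])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": [c.id for c in self._compounds],
             "smiles": [c.smiles for c in self._compounds],
             "source": [c.source for c in self._compounds]}
        )


class ChemogenomicsDB:
    """Ligand–target affinity interactions, unique per (ligand, target) pair.

    Duplicate pairs are aggregated by maximum pAct when the DB is built.
    """

    def __init__(self, interactions: pd.DataFrame, report: ParseReport | None = None):
        required = {"ligand_id", "smiles", "target_id", "pact"}
        missing = required - set(interactions.columns)
        if missing:
            raise FormatError(f"affinity table missing columns: {sorted(missing)}")
        df = interactions.copy()
        if "source" not in df.columns:
            df["source"] = ""
        df["pact"] = df["pact"].astype(float)
        if not np.isfinite(df["pact"]).all():
            raise ValueError("pAct values must be finite")
        # keep the most potent record per (ligand, target) pair
        df = (df.sort_values("pact", ascending=False)
                .drop_duplicates(["ligand_id", "target_id"], keep="first")
                .sort_index(kind="stable")
                .reset_index(drop=True))
        self.interactions = df[["ligand_id", "smiles", "target_id", "pact", "source"]]
        self.report = report or ParseReport()

    @property
    def n_ligands(self) -> int:
        return self.interactions["ligand_id"].nunique()

    @property
    def n_targets(self) -> int:
        return self.interactions["target_id"].nunique()

    @property
    def n_interactions(self) -> int:
        return len(self.interactions)

    def by_target(self) -> dict[str, pd.DataFrame]:
        return {t: g for t, g in self.interactions.groupby("target_id", sort=True)}


@dataclass(frozen=True)
class TargetAnnotation:
    target_id: str
    gene: str
    family: str = "other"
    ec_class: str = "none"
    oncoscore: float | None = None
    regulation: str = "missing"
    name: str = ""  # optional protein name, used only for report ordering

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.ec_class not in EC_CLASSES:
            raise ValueError(f"unknown EC class {self.ec_class!r}")
        if (self.ec_class == "none") != (self.family != "enzyme"):
            raise ValueError(
                f"{self.target_id}: ec_class must be 'none' iff family is not enzyme"
            )
        if self.regulation not in REGULATIONS:
            raise ValueError(f"unknown regulation flag {self.regulation!r}")
        if self.oncoscore is not None and not (0.0 <= self.oncoscore <= 1.0):
            raise ValueError("oncoscore must lie in [0, 1]")


@dataclass(frozen=True)
class PathwaySet:
    name: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"pathway {self.name!r} has no genes")


# ---------------------------------------------------------------------------
# readers

def read_smiles_table(path: str | Path) -> CompoundLibrary:
    """Read a TSV with columns ``id`` and ``smiles`` into a CompoundLibrary.

    Extra columns are concatenated into the compound's free ``source`` tag.
    Unparseable SMILES rows are dropped and recorded in ``library.report``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("id", "smiles"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    extra = [c for c in df.columns if c not in ("id", "smiles")]
    report = ParseReport(n_total=len(df))
    lib = CompoundLibrary(report=report)
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        can = canonical_smiles(d["smiles"])
        if can is None:
            report.rejections.append((row_no, f"unparseable SMILES {d['smiles']!r}"))
            continue
        source = ";".join(f"{c}={d[c]}" for c in extra if d[c]) if extra else ""
        lib.add(Compound(id=d["id"], smiles=can, source=source))
        report.n_accepted += 1
    return lib


def read_sdf(path: str | Path, id_prop: str = "_Name") -> CompoundLibrary:
    """Alternative compound input: SD file, ids from a named property."""
    report = ParseReport()
    lib = CompoundLibrary(report=report)
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        report.n_total += 1
        if mol is None or mol.GetNumHeavyAtoms() < 1:
            report.rejections.append((i, "unparseable record"))
            continue
        cid = mol.GetProp(id_prop) if mol.HasProp(id_prop) else f"SDF{i:06d}"
        lib.add(Compound(id=cid, smiles=Chem.MolToSmiles(mol), source="sdf"))
        report.n_accepted += 1
    return lib


def read_affinity_db(path: str | Path) -> ChemogenomicsDB:
    """Read a ligand–target affinity TSV (ligand_id, smiles, target_id, pact).

    Rows whose pact does not parse as a finite number are rejected and
    reported; duplicate (ligand, target) pairs keep the maximum pAct.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"ligand_id", "smiles", "target_id", "pact"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    if df.empty:
        raise FormatError(f"{path}: empty affinity table")
    report = ParseReport(n_total=len(df))
    pact = pd.to_numeric(df["pact"], errors="coerce")
    bad = ~np.isfinite(pact)
    for row_no in df.index[bad]:
        report.rejections.append((int(row_no) + 2, f"non-numeric pact {df.loc[row_no, 'pact']!r}"))
    kept = df.loc[~bad].copy()
    kept["pact"] = pact[~bad]
    report.n_accepted = len(kept)
    return ChemogenomicsDB(kept.reset_index(drop=True), report=report)


def read_annotations(path: str | Path) -> dict[str, TargetAnnotation]:
    """Read a target annotation TSV keyed by upper-cased target_id."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"target_id", "gene", "family", "ec_class", "oncoscore", "regulation"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    out: dict[str, TargetAnnotation] = {}
    for row in df.itertuples(index=False):
        tid = row.target_id.upper()
        score = float(row.oncoscore) if row.oncoscore not in ("", "NA") else None
        ann = TargetAnnotation(
            target_id=tid,
            gene=row.gene.upper(),
            family=row.family,
            ec_class=row.ec_class,
            oncoscore=score,
            regulation=row.regulation or "missing",
            name=getattr(row, "name", "") if hasattr(row, "name") else "",
        )
        out[tid] = ann
    return out


def read_pathways_gmt(path: str | Path) -> list[PathwaySet]:
    """Read gene sets from a standard GMT file (name, description, genes...).

    Lines with fewer than three fields are rejected; an exception naming the
    offending line numbers is raised only if nothing valid remains.
    """
    pathways: list[PathwaySet] = []
    rejected: list[int] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                rejected.append(line_no)
                continue
            name, _desc, *genes = fields
            genes = frozenset(g.upper() for g in genes if g)
            if not genes:
                rejected.append(line_no)
                continue
            pathways.append(PathwaySet(name=name, genes=genes))
    if rejected and not pathways:
        raise FormatError(f"{path}: no valid GMT lines (rejected lines {rejected})")
    return pathways


# ---------------------------------------------------------------------------
# writers (inverse of the readers; round-trip preserves records field-for-field)

def write_smiles_table(lib: CompoundLibrary, path: str | Path) -> None:
    lib.to_frame().to_csv(path, sep="\t", index=False)


def write_affinity_db(db: ChemogenomicsDB, path: str | Path) -> None:
    db.interactions.to_csv(path, sep="\t", index=False)


def write_annotations(annotations: dict[str, TargetAnnotation], path: str | Path) -> None:
    rows = [
        {
            "target_id": a.target_id,
            "gene": a.gene,
            "family": a.family,
            "ec_class": a.ec_class,
            "oncoscore": "" if a.oncoscore is None else f"{a.oncoscore:.3f}",
            "regulation": a.regulation,
            "name": a.name,
        }
        for a in annotations.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_pathways_gmt(pathways: list[PathwaySet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pathways:
            fh.write("\t".join([p.name, "na", *sorted(p.genes)]) + "\n")


def load_oncoscore_reference() -> dict[str, TargetAnnotation]:
    """The published reference panel of 42 high-oncogene-probability proteins
    (CGPrio OncoScores with colon-cancer regulation flags), shipped as package
    data and used for target prioritization examples and tests."""
    ref = importlib.resources.files("diviss.data") / "oncoscore_reference.tsv"
    with importlib.resources.as_file(ref) as p:
        return read_annotations(p)
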