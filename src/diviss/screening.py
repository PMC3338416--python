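"""Single-point screening analysis: viability normalization, plate quality
statistics (Z' factor, signal-to-background), hit calling and campaign
bookkeeping.

Tabular data conventions
------------------------
Plate tables are pandas DataFrames with columns ``plate_id, well, compound_id,
cell_line, concentration_um, replicate, raw_signal``; control wells use the
reserved compound ids ``CONTROL_POS`` (untreated cells, full signal) and
``CONTROL_NEG`` (background). Viability tables carry ``compound_id, cell_line,
concentration_um, replicate, viability``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CONTROL_POS = "CONTROL_POS"
CONTROL_NEG = "CONTROL_NEG"


class DegeneratePlateError(ValueError):
    """Positive and negative control means coincide; the plate is unusable."""


@dataclass(frozen=True)
class PlateStats:
    """Control-well summary of one plate."""

    plate_id: str
    pos_mean: float
    pos_sd: float
    neg_mean: float
    neg_sd: float

    def __post_init__(self):
        if self.pos_sd < 0 or self.neg_sd < 0:
            raise ValueError("control standard deviations must be >= 0")

    @classmethod
    def from_controls(cls, plate_id: str, pos_signals, neg_signals) -> "PlateStats":
        pos = np.asarray(pos_signals, dtype=float)
        neg = np.asarray(neg_signals, dtype=float)
        if pos.size == 0 or neg.size == 0:
            raise ValueError(f"plate {plate_id}: missing control wells")
        return cls(plate_id, float(pos.mean()), float(pos.std(ddof=1)) if pos.size > 1 else 0.0,
                   float(neg.mean()), float(neg.std(ddof=1)) if neg.size > 1 else 0.0)


def normalize_viability(raw_signal, plate: PlateStats):
    """Percent viability: 100 * (raw - neg_mean) / (pos_mean - neg_mean).

    Values are deliberately not clipped; <0 or >100 readings are preserved
    (they carry QC signal) and can be flagged downstream.
    """
    span = plate.pos_mean - plate.neg_mean
    if span == 0:
        raise DegeneratePlateError(f"plate {plate.plate_id}: pos and neg control means equal")
    if span < 0:
        raise DegeneratePlateError(
            f"plate {plate.plate_id}: positive control below background")
    raw = np.asarray(raw_signal, dtype=float)
    out = 100.0 * (raw - plate.neg_mean) / span
    return float(out) if np.isscalar(raw_signal) else out


def zprime(plate: PlateStats) -> float:
    """Z' = 1 - 3*(sd_pos + sd_neg)/|mean_pos - mean_neg| (Zhang et al. 1999)."""
    sep = abs(plate.pos_mean - plate.neg_mean)
    if sep == 0:
        raise DegeneratePlateError(f"plate {plate.plate_id}: control means equal")
    return 1.0 - 3.0 * (plate.pos_sd + plate.neg_sd) / sep


def signal_to_background(plate: PlateStats) -> float:
    if plate.neg_mean <= 0:
        raise ValueError(f"plate {plate.plate_id}: background mean must be > 0")
    return plate.pos_mean / plate.neg_mean


def plate_stats_from_frame(plates: pd.DataFrame) -> dict[str, PlateStats]:
    """PlateStats per plate_id, from the CONTROL_POS / CONTROL_NEG wells."""
    out: dict[str, PlateStats] = {}
    for pid, grp in plates.groupby("plate_id", sort=True):
        pos = grp.loc[grp["compound_id"] == CONTROL_POS, "raw_signal"]
        neg = grp.loc[grp["compound_id"] == CONTROL_NEG, "raw_signal"]
        out[str(pid)] = PlateStats.from_controls(str(pid), pos.to_numpy(), neg.to_numpy())
    return out


def normalize_plates(plates: pd.DataFrame) -> pd.DataFrame:
    """Normalize every compound well against its own plate's controls.

    Returns a viability table with an ``out_of_range`` flag for readings
    outside [0, 100].
    """
    stats = plate_stats_from_frame(plates)
    wells = plates[~plates["compound_id"].isin((CONTROL_POS, CONTROL_NEG))].copy()
    viability = np.empty(len(wells))
    for pid, idx in wells.groupby("plate_id", sort=False).groups.items():
        viability[wells.index.get_indexer(idx)] = normalize_viability(
            wells.loc[idx, "raw_signal"].to_numpy(), stats[str(pid)])
    wells["viability"] = viability
    wells["out_of_range"] = (viability < 0) | (viability > 100)
    return wells[["compound_id", "cell_line", "concentration_um",
                  "replicate", "viability", "out_of_range"]].reset_index(drop=True)


def call_cytotoxic_hits(records: pd.DataFrame, threshold: float = 20.0) -> set[str]:
    """Compounds whose replicate-averaged viability is <= threshold (inclusive).

    The default 20% cut marks the remarkably cytotoxic tail of a single-point
    screen at 50 uM.
    """
    means = records.groupby("compound_id")["viability"].mean()
    return set(means.index[means <= threshold])


def duplicate_concordance(records: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-compound (rep1, rep2) viability pairs and their Pearson correlation.

    Compounds without exactly the two expected replicates are excluded and
    counted in the returned table's attrs.
    """
    wide = records.pivot_table(index="compound_id", columns="replicate",
                               values="viability", aggfunc="mean")
    complete = wide.dropna()
    complete = complete[[c for c in (1, 2) if c in complete.columns]]
    if complete.shape[1] < 2:
        raise ValueError("records do not contain two replicates")
    pairs = complete.rename(columns={1: "rep1", 2: "rep2"}).reset_index()
    r = float(np.corrcoef(pairs["rep1"], pairs["rep2"])[0, 1])
    pairs.attrs["n_excluded"] = int(len(wide) - len(complete))
    return pairs, r


def count_data_points(n_single: int, n_single_reps: int, n_dr: int,
                      n_conc: int, n_dr_reps: int, n_cell_lines: int) -> int:
    """Total measurements of a campaign: single-point wells plus
    dose-response wells across concentrations, replicates and cell lines."""
    counts = (n_single, n_single_reps, n_dr, n_conc, n_dr_reps, n_cell_lines)
    if any(c < 0 for c in counts):
        raise ValueError("all counts must be >= 0")
    return n_single * n_single_reps + n_dr * n_conc * n_dr_reps * n_cell_lines
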