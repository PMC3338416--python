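"""Dose-response curve fitting, IC50 extraction with censoring, and the
differential selectivity ratio R = IC50(normal) / IC50(tumor).

The viability model is a two-parameter logistic with asymptotes fixed at
100% and 0% (six-point curves cannot support four free parameters):

    viability(c) = 100 / (1 + (c / IC50)^slope)

A compound whose mean viability never falls below 50% inside the tested
range is censored at the top concentration (reported as "> Cmax"); censored
tumor potency makes a compound non-toxic (NT) regardless of the normal line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

TUMOR_LINE = "HCT116"
NORMAL_LINE = "MRC5"

SELECTIVITY_CLASSES = ("tumor_strong", "tumor_moderate", "unselective",
                       "normal_moderate", "normal_strong", "NT")

SLOPE_BOUNDS = (0.3, 5.0)


@dataclass(frozen=True)
class DoseResponseCurve:
    """Viability measurements of one compound on one cell line.

    ``concentrations`` is the strictly decreasing dilution series (uM);
    ``viability`` has shape (n_concentrations, n_replicates), percent scale.
    """

    compound_id: str
    cell_line: str
    concentrations: tuple[float, ...]
    viability: tuple[tuple[float, ...], ...]

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        if len(c) < 4 or len(set(c)) < 4:
            raise ValueError("at least 4 distinct concentrations are required")
        if not (np.diff(c) < 0).all() or (c <= 0).any():
            raise ValueError("concentrations must be a strictly decreasing positive series")
        if len(self.viability) != len(c):
            raise ValueError("one viability row per concentration required")

    @property
    def cmax(self) -> float:
        return float(self.concentrations[0])

    def mean_viability(self) -> np.ndarray:
        return np.array([np.mean(v) for v in self.viability])


@dataclass(frozen=True)
class IC50Result:
    """Fitted potency with censoring.

    ``ic50`` is in uM and None when censored; censored results report the
    bound "> cmax".
    """

    compound_id: str
    cell_line: str
    ic50: float | None
    cmax: float
    hill_slope: float | None = None
    top: float = 100.0
    bottom: float = 0.0
    rmse: float = float("nan")
    converged: bool = True

    @property
    def censored(self) -> bool:
        return self.ic50 is None

    def __str__(self) -> str:
        if self.censored:
            return f">{self.cmax:g} uM"
        return f"{self.ic50:.3g} uM"


def logistic_viability(conc, ic50, slope, top=100.0, bottom=0.0):
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (conc / ic50) ** slope)


def fit_curve(curve: DoseResponseCurve) -> IC50Result:
    """Least-squares logistic fit; censored when viability never drops
    below 50% of control within the tested range."""
    mean_v = curve.mean_viability()
    if mean_v.min() > 50.0:
        return IC50Result(curve.compound_id, curve.cell_line, None, curve.cmax)
    conc, viab = [], []
    for c, reps in zip(curve.concentrations, curve.viability):
        for v in reps:  # replicates enter as separate points
            conc.append(c)
            viab.append(v)
    conc = np.array(conc)
    viab = np.array(viab)
    # initial IC50: concentration whose mean viability is nearest 50%
    c0 = curve.concentrations[int(np.argmin(np.abs(mean_v - 50.0)))]
    log_lo, log_hi = math.log10(curve.concentrations[-1]) - 3, math.log10(curve.cmax) + 3

    def model(c, log_ic50, slope):
        return logistic_viability(c, 10.0 ** log_ic50, slope)

    try:
        popt, _ = curve_fit(
            model, conc, viab,
            p0=[math.log10(c0), 1.0],
            bounds=([log_lo, SLOPE_BOUNDS[0]], [log_hi, SLOPE_BOUNDS[1]]),
            maxfev=10000,
        )
    except RuntimeError:
        return IC50Result(curve.compound_id, curve.cell_line, None, curve.cmax,
                          converged=False)
    ic50 = float(10.0 ** popt[0])
    slope = float(popt[1])
    rmse = float(np.sqrt(np.mean((model(conc, *popt) - viab) ** 2)))
    return IC50Result(curve.compound_id, curve.cell_line, ic50, curve.cmax,
                      hill_slope=slope, rmse=rmse)


def potency_to_plog(value_molar: float) -> float:
    """pAct / pIC50 / pGI50: -log10 of a molar concentration."""
    if value_molar <= 0:
        raise ValueError("concentration must be > 0")
    return -math.log10(value_molar)


def plog_to_potency(p: float) -> float:
    """Inverse of potency_to_plog (molar)."""
    return 10.0 ** (-p)


def micromolar_to_plog(value_um: float) -> float:
    return potency_to_plog(value_um * 1e-6)


@dataclass(frozen=True)
class SelectivityRecord:
    compound_id: str
    ic50_tumor: IC50Result
    ic50_normal: IC50Result
    ratio: float | None
    ratio_is_lower_bound: bool
    selectivity_class: str

    def __post_init__(self):
        if self.selectivity_class not in SELECTIVITY_CLASSES:
            raise ValueError(f"unknown class {self.selectivity_class!r}")


#: (normal_strong edge, normal_moderate edge, tumor_moderate edge, tumor_strong edge)
DEFAULT_RATIO_EDGES = (0.2, 0.5, 2.0, 5.0)


def classify_selectivity(ratio: float | None,
                         edges: tuple[float, float, float, float] = DEFAULT_RATIO_EDGES
                         ) -> str:
    """Bin a selectivity ratio; bins partition (0, inf).

    With the default edges: R >= 5 strongly tumor-selective (inclusive),
    2 <= R < 5 moderately; 0.5 < R < 2 unselective; 0.2 < R <= 0.5 and
    R <= 0.2 the mirrored normal-selective bins.
    """
    if ratio is None:
        return "NT"
    if ratio <= 0:
        raise ValueError("selectivity ratio must be > 0")
    ns, nm, tm, ts = edges
    if ratio >= ts:
        return "tumor_strong"
    if ratio >= tm:
        return "tumor_moderate"
    if ratio > nm:
        return "unselective"
    if ratio > ns:
        return "normal_moderate"
    return "normal_strong"


def selectivity_ratio(ic50_normal: IC50Result, ic50_tumor: IC50Result,
                      edges: tuple[float, float, float, float] = DEFAULT_RATIO_EDGES
                      ) -> SelectivityRecord:
    """Ratio R = IC50(normal) / IC50(tumor) with censoring rules.

    Censored tumor potency means non-toxic (NT), no ratio. A censored normal
    potency with finite tumor potency yields the lower bound Cmax/IC50_tumor;
    the class is assigned from that bound (conservative: the true ratio can
    only be larger).
    """
    cid = ic50_tumor.compound_id
    if ic50_tumor.censored:
        return SelectivityRecord(cid, ic50_tumor, ic50_normal, None, False, "NT")
    if ic50_normal.censored:
        bound = ic50_normal.cmax / ic50_tumor.ic50
        return SelectivityRecord(cid, ic50_tumor, ic50_normal, bound, True,
                                 classify_selectivity(bound, edges))
    r = ic50_normal.ic50 / ic50_tumor.ic50
    return SelectivityRecord(cid, ic50_tumor, ic50_normal, r, False,
                             classify_selectivity(r, edges))


def curves_from_records(records: pd.DataFrame) -> list[DoseResponseCurve]:
    """Group a viability table into per-(compound, cell line) curves."""
    curves = []
    for (cid, line), grp in records.groupby(["compound_id", "cell_line"], sort=True):
        wide = grp.pivot_table(index="concentration_um", columns="replicate",
                               values="viability", aggfunc="mean")
        wide = wide.sort_index(ascending=False)
        curves.append(DoseResponseCurve(
            compound_id=str(cid), cell_line=str(line),
            concentrations=tuple(float(c) for c in wide.index),
            viability=tuple(tuple(float(v) for v in row if not np.isnan(v))
                            for row in wide.to_numpy()),
        ))
    return curves


def fit_campaign(records: pd.DataFrame,
                 tumor_line: str = TUMOR_LINE,
                 normal_line: str = NORMAL_LINE,
                 edges: tuple[float, float, float, float] = DEFAULT_RATIO_EDGES
                 ) -> pd.DataFrame:
    """Fit both cell lines for every compound and classify selectivity.

    Returns one row per compound: IC50s (uM, NaN when censored), censor
    flags, ratio (possibly a lower bound) and selectivity class.
    """
    fits: dict[tuple[str, str], IC50Result] = {}
    for curve in curves_from_records(records):
        fits[(curve.compound_id, curve.cell_line)] = fit_curve(curve)
    rows = []
    for cid in sorted({k[0] for k in fits}):
        ft = fits.get((cid, tumor_line))
        fn = fits.get((cid, normal_line))
        if ft is None or fn is None:
            continue
        rec = selectivity_ratio(fn, ft, edges)
        rows.append({
            "compound_id": cid,
            "ic50_tumor_um": np.nan if ft.censored else ft.ic50,
            "tumor_censored": ft.censored,
            "ic50_normal_um": np.nan if fn.censored else fn.ic50,
            "normal_censored": fn.censored,
            "ratio": np.nan if rec.ratio is None else rec.ratio,
            "ratio_is_lower_bound": rec.ratio_is_lower_bound,
            "selectivity_class": rec.selectivity_class,
            "tumor_slope": np.nan if ft.hill_slope is None else ft.hill_slope,
            "tumor_rmse": ft.rmse,
            "normal_rmse": fn.rmse,
        })
    return pd.DataFrame(rows)
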