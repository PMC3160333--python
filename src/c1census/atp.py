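"""Luminescence-based quantification of cellular ATP content.

A luciferase assay reports luminescence proportional to ATP; a standard
curve (luminescence vs known ATP concentration) converts sample wells to
ATP concentration, then to mass per cell in zeptograms (10^-21 g) using the
ATP molar mass 507.18 g/mol, the assayed sample volume and the number of
cells in the well.

Experiments follow a T/N/P design: starved cells exposed to the test
compound (T), to nothing (N, negative control) and to pyruvate (P, positive
control confirming the cells are metabolically responsive).  A compound is
called stimulatory when the T vs N comparison is significant by a
pooled-variance Student's t-test on the triplicate means.  The default
alternative is one-sided (T > N): the scientific question is whether the
compound *increased* ATP, and with summary statistics rounded to integer
zeptograms a one-sided test is also the variant that reproduces the
reference significance pattern exactly.  A two-sided or Welch test is
available through the ``alternative`` / ``equal_var`` arguments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

ATP_MOLAR_MASS = 507.18  # g/mol
ZEPTO_PER_GRAM = 1e21

SAMPLE_LABELS = ("T", "N", "P")


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line through the ATP standards: lum = slope*conc + b."""

    slope: float       # luminescence units per nM ATP
    intercept: float   # luminescence units
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class PlateSet:
    """One plate: standard wells plus replicate sample wells.

    ``data`` columns: well, kind ("standard"|"sample"), label (T/N/P for
    samples, empty for standards), conc (nM, standards only), luminescence.
    """

    data: pd.DataFrame
    cells_in_well: float
    well_volume_l: float


@dataclass(frozen=True)
class AssayResult:
    """Per-compound summary mirroring a T/N/P assay table row group."""

    compound: str
    mean_T: float
    sd_T: float
    mean_N: float
    sd_N: float
    mean_P: float
    sd_P: float
    n_replicates: int
    fold_change_T_over_N: float
    significant: bool


def fit_standard_curve(concs, luminescence) -> StandardCurve:
    concs = np.asarray(concs, dtype=float)
    lum = np.asarray(luminescence, dtype=float)
    if len(concs) < 3:
        raise ValueError("standard curve needs at least 3 points")
    if np.any(np.diff(concs) <= 0):
        raise ValueError("standard concentrations must be strictly increasing")
    fit = stats.linregress(concs, lum)
    if fit.slope <= 0:
        raise ValueError("fitted standard-curve slope is not positive; "
                         "the plate is unusable")
    r2 = float(fit.rvalue ** 2) if np.isfinite(fit.rvalue) else 1.0
    return StandardCurve(float(fit.slope), float(fit.intercept), r2, len(concs))


def atp_per_cell(luminescence: float, curve: StandardCurve,
                 well_volume_l: float, cells_in_well: float) -> float:
    """Convert one sample well's luminescence to zeptograms ATP per cell."""
    if cells_in_well <= 0:
        raise ValueError("cells_in_well must be positive")
    if luminescence < curve.intercept:
        warnings.warn("luminescence below curve intercept; reporting 0 zg/cell",
                      stacklevel=2)
        return 0.0
    conc_nm = (luminescence - curve.intercept) / curve.slope
    moles = conc_nm * 1e-9 * well_volume_l
    grams = moles * ATP_MOLAR_MASS
    return grams * ZEPTO_PER_GRAM / cells_in_well


def fold_change(mean_t: float, mean_n: float) -> float:
    if mean_n <= 0:
        raise ValueError("fold change undefined for non-positive control mean")
    return mean_t / mean_n


def significance_from_summary(mean_t: float, sd_t: float, mean_n: float, sd_n: float,
                              n: int = 3, alpha: float = 0.01,
                              alternative: str = "greater",
                              equal_var: bool = True) -> bool:
    """Student's t-test (from summary statistics) for T vs N at level alpha."""
    if n < 2:
        raise ValueError("need n >= 2 replicates per group")
    if sd_t < 0 or sd_n < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd_t == 0 and sd_n == 0:
        if mean_t == mean_n:
            warnings.warn("both groups constant and equal; not significant",
                          stacklevel=2)
            return False
        return True  # zero within-group variance, distinct means
    res = stats.ttest_ind_from_stats(mean_t, sd_t, n, mean_n, sd_n, n,
                                     equal_var=equal_var, alternative=alternative)
    return bool(res.pvalue < alpha)


def analyze_plate(plate: PlateSet) -> pd.DataFrame:
    """Fit the plate's standard curve and summarise zg/cell per label."""
    std = plate.data[plate.data["kind"] == "standard"].sort_values("conc")
    curve = fit_standard_curve(std["conc"].to_numpy(), std["luminescence"].to_numpy())
    samples = plate.data[plate.data["kind"] == "sample"].copy()
    samples["zg_per_cell"] = [
        atp_per_cell(l, curve, plate.well_volume_l, plate.cells_in_well)
        for l in samples["luminescence"]
    ]
    grouped = samples.groupby("label")["zg_per_cell"]
    out = grouped.agg(["mean", "std", "count"]).reset_index()
    out.columns = ["label", "mean_zg_per_cell", "sd_zg_per_cell", "n"]
    return out


def build_assay_table(summaries: pd.DataFrame, n: int = 3, alpha: float = 0.01,
                      alternative: str = "greater") -> list[AssayResult]:
    """Assemble per-compound results from a (compound, sample, mean, sd) table."""
    results = []
    for compound, grp in summaries.groupby("compound", sort=False):
        by_label = {row["sample"]: row for _, row in grp.iterrows()}
        if "N" not in by_label:
            raise ValueError(f"compound {compound!r} is missing its N control")
        if "T" not in by_label:
            raise ValueError(f"compound {compound!r} is missing its T treatment")
        t, nrow = by_label["T"], by_label["N"]
        p = by_label.get("P")
        results.append(AssayResult(
            compound=compound,
            mean_T=float(t["mean"]), sd_T=float(t["sd"]),
            mean_N=float(nrow["mean"]), sd_N=float(nrow["sd"]),
            mean_P=float(p["mean"]) if p is not None else float("nan"),
            sd_P=float(p["sd"]) if p is not None else float("nan"),
            n_replicates=n,
            fold_change_T_over_N=fold_change(float(t["mean"]), float(nrow["mean"])),
            significant=significance_from_summary(
                float(t["mean"]), float(t["sd"]), float(nrow["mean"]),
                float(nrow["sd"]), n=n, alpha=alpha, alternative=alternative),
        ))
    return results


def assay_table_frame(results: list[AssayResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def _load_fixture(name: str) -> pd.DataFrame:
    with resources.files("c1census.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_alcohol_assay() -> pd.DataFrame:
    """Curated T/N/P summary for the alcohol panel (zg/cell, triplicate)."""
    return _load_fixture("atp_alcohols.tsv")


def load_c1_assay() -> pd.DataFrame:
    """Curated T/N/P summary for the C1/methylated-compound panel."""
    return _load_fixture("atp_c1_compounds.tsv")
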