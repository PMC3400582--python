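"""Survival estimation and lifespan-extension arithmetic.

Mean lifespan is the Kaplan-Meier restricted mean: the area under the
product-limit survival curve up to the largest observed time (the "mean
lifespan" of classic KM software output), which reduces to the arithmetic
mean of death times when nothing is censored.  From per-condition mean
lifespans the module derives, per gene inactivation:

* delta lifespan      — percent change vs the same-strain vector control;
* percent extension   — the long-lived mutant's lifespan gain over wild type
                        under the same RNAi treatment;
* delta extension     — percent change of that extension vs the vector
                        control, the screen's suppression readout.

Suppression classes use thresholds of 15%, 50% and 2/3 decrease in
extension, applied to unrounded values (printed tables round half away from
zero for display only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import restricted_mean_survival_time

from .types import SurvivalCohort

__all__ = [
    "KMCurve",
    "km_estimate",
    "restricted_mean_lifespan",
    "delta_lifespan",
    "percent_extension",
    "delta_extension",
    "build_lifespan_table",
    "classify_suppression",
    "cohort_mean_lifespans",
    "round_half_away",
]

TWO_THIRDS = 200.0 / 3.0


@dataclass
class KMCurve:
    times: np.ndarray        # event/censor times in ascending order
    survival: np.ndarray     # S(t) just after each time
    t_max: float
    n_events: int
    kmf: KaplanMeierFitter


def km_estimate(cohort: SurvivalCohort) -> KMCurve:
    """Product-limit survival estimate with tie and right-censor handling.

    Deaths tied at a scoring day are processed before censorings at the same
    time (the lifelines convention).  A cohort with no events at all cannot
    support a mean and raises.
    """
    if cohort.n_events == 0:
        raise ValueError("all animals censored: no events to estimate from")
    kmf = KaplanMeierFitter()
    kmf.fit(cohort.times, event_observed=cohort.status)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    return KMCurve(times=times, survival=surv, t_max=float(cohort.times.max()),
                   n_events=cohort.n_events, kmf=kmf)


def restricted_mean_lifespan(curve: KMCurve) -> float:
    """Area under S(t) on [0, t_max]; equals the mean death time uncensored."""
    return float(restricted_mean_survival_time(curve.kmf, t=curve.t_max))


def mean_lifespan(cohort: SurvivalCohort) -> float:
    """Convenience: KM restricted mean straight from a cohort."""
    return restricted_mean_lifespan(km_estimate(cohort))


def delta_lifespan(mean_rnai: float, mean_vector: float) -> float:
    """Percent change in mean lifespan vs the same-strain vector control."""
    if mean_rnai <= 0 or mean_vector <= 0:
        raise ValueError("mean lifespans must be > 0")
    return 100.0 * (mean_rnai - mean_vector) / mean_vector


def percent_extension(mean_mutant: float, mean_wildtype: float) -> float:
    """Lifespan extension of a long-lived mutant over wild type, same RNAi."""
    if mean_mutant <= 0 or mean_wildtype <= 0:
        raise ValueError("mean lifespans must be > 0")
    return 100.0 * (mean_mutant - mean_wildtype) / mean_wildtype


def delta_extension(ext_rnai: float, ext_vector: float) -> float:
    """Relative change in percent extension vs the vector control.

    This is the relative-change-in-extension form (not the day-gain form),
    which reproduces the screen's printed suppression percentages.
    """
    if ext_vector == 0:
        raise ValueError("control extension is zero: delta extension undefined")
    return 100.0 * (ext_rnai - ext_vector) / ext_vector


def round_half_away(x: float) -> int:
    """Round half away from zero, the convention of the printed tables."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def build_lifespan_table(means: pd.DataFrame, wildtype: str = "N2",
                         control_rnai: str = "vector") -> pd.DataFrame:
    """Derive extension/suppression columns from a strain x RNAi mean table.

    ``means`` has RNAi clones as the index (including ``control_rnai``) and
    strains as columns, wild type first.  Returns one row per non-control
    clone with columns ``delta_lifespan`` (wild type, %) and, per mutant
    strain, ``ext_<strain>`` and ``dext_<strain>`` (percent extension and
    delta extension, unrounded).
    """
    if control_rnai not in means.index:
        raise ValueError(f"missing {control_rnai!r} control row")
    if wildtype not in means.columns:
        raise ValueError(f"missing wild-type column {wildtype!r}")
    mutants = [c for c in means.columns if c != wildtype]
    ctrl = means.loc[control_rnai]
    ext_ctrl = {m: percent_extension(ctrl[m], ctrl[wildtype]) for m in mutants}

    rows = {}
    for rnai, row in means.drop(index=control_rnai).iterrows():
        rec = {"delta_lifespan": delta_lifespan(row[wildtype], ctrl[wildtype])}
        for m in mutants:
            ext = percent_extension(row[m], row[wildtype])
            rec[f"ext_{m}"] = ext
            rec[f"dext_{m}"] = delta_extension(ext, ext_ctrl[m])
        rows[rnai] = rec
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "rnai"
    return table


def classify_suppression(table: pd.DataFrame) -> dict:
    """Per-gene suppression classes and the screen's summary counts.

    A gene's class is its strongest suppression of extension across the
    long-lived mutants (unrounded delta-extension thresholds -15%, -50% and
    -2/3); classes are nested.  Wild-type effects are tallied from the
    unrounded delta-lifespan column: reductions of >= 15%, and the genes with
    reduction < 10% (increases qualify).
    """
    dext_cols = [c for c in table.columns if c.startswith("dext_")]
    if not dext_cols:
        raise ValueError("table has no delta-extension columns")
    strongest = table[dext_cols].min(axis=1)

    def klass(v: float) -> str:
        if v <= -TWO_THIRDS:
            return "ge_two_thirds"
        if v <= -50.0:
            return "ge_50"
        if v <= -15.0:
            return "ge_15"
        return "none"

    classes = strongest.map(klass)
    dlife = table["delta_lifespan"]
    counts = {
        "ge_two_thirds": int((strongest <= -TWO_THIRDS).sum()),
        "ge_50": int((strongest <= -50.0).sum()),
        "ge_15": int((strongest <= -15.0).sum()),
        "wt_reduction_ge_15": int((dlife <= -15.0).sum()),
        "wt_reduction_lt_10": int((dlife > -10.0).sum()),
    }
    return {"classes": classes, "counts": counts}


def cohort_mean_lifespans(cohorts: list[SurvivalCohort]) -> pd.DataFrame:
    """Strain x RNAi table of KM restricted-mean lifespans from raw cohorts."""
    rows: dict[str, dict[str, float]] = {}
    for c in cohorts:
        rows.setdefault(c.rnai_clone, {})[c.strain] = mean_lifespan(c)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "rnai"
    return table
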