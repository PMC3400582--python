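"""Hit calling and screen-level statistics.

A gene inactivation is called a hit against a reporter when its wells show a
fold decrease in reporter expression > 1.5x versus vector-treated controls
with a one-tailed t-test p <= 0.05 — deliberately without multiple-testing
correction, matching the screen's design.  The module also tabulates
gene x reporter hit matrices, reporter-specificity (Venn) partitions,
stress-tolerance survival comparisons, and ddCt qPCR fold changes against a
reference gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConditionSummary",
    "INFINITE_FOLD",
    "one_tailed_t_test",
    "fold_decrease",
    "build_hit_table",
    "count_hits_per_reporter",
    "pathway_overlap_sets",
    "stress_survival_compare",
    "qpcr_fold_change",
]

REPORTERS = ["hsp-4", "hsp-6", "sod-3", "gst-4"]

#: sentinel for suppressed conditions whose fluorescence does not differ from
#: background, precluding fold quantification
INFINITE_FOLD = ">>>"

FOLD_THRESHOLD = 1.5
P_THRESHOLD = 0.05


@dataclass
class ConditionSummary:
    reporter: str
    rnai_clone: str
    control_values: np.ndarray
    rnai_values: np.ndarray
    fold_decrease: float  # inf for the ">>>" case
    p_value: float
    is_hit: bool


def one_tailed_t_test(group_a, group_b, direction: str = "a>b",
                      pooled: bool = True) -> float:
    """One-sided two-sample t-test p-value.

    Pooled-variance Student's t by default (``pooled=False`` gives Welch).
    ``direction='a>b'`` tests the alternative mean(a) > mean(b).  Two groups
    with zero pooled variance and equal means return p = 0.5 (the symmetric
    null), rather than raising.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    if direction not in ("a>b", "b>a"):
        raise ValueError("direction must be 'a>b' or 'b>a'")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.5
        bigger_is_a = a.mean() > b.mean()
        return 0.0 if bigger_is_a == (direction == "a>b") else 1.0
    alternative = "greater" if direction == "a>b" else "less"
    res = stats.ttest_ind(a, b, equal_var=pooled, alternative=alternative)
    return float(res.pvalue)


def fold_decrease(control_values, rnai_values, reporter: str = "",
                  rnai_clone: str = "", pooled: bool = True) -> ConditionSummary:
    """Fold decrease vs vector control and the screen's hit call.

    fold = mean(control) / mean(rnai); p from a one-tailed t-test of
    control > rnai; hit iff fold > 1.5 (strict) and p <= 0.05.  A
    non-positive RNAi mean flags an unquantifiable (infinite) fold; the hit
    call then rests on the p criterion alone.
    """
    control = np.asarray(control_values, dtype=float)
    rnai = np.asarray(rnai_values, dtype=float)
    p = one_tailed_t_test(control, rnai, direction="a>b", pooled=pooled)
    if rnai.mean() <= 0:
        fold = math.inf
    else:
        fold = float(control.mean() / rnai.mean())
    is_hit = (fold > FOLD_THRESHOLD) and (p <= P_THRESHOLD)
    return ConditionSummary(reporter=reporter, rnai_clone=rnai_clone,
                            control_values=control, rnai_values=rnai,
                            fold_decrease=fold, p_value=p, is_hit=is_hit)


def build_hit_table(summaries: list[ConditionSummary],
                    reporters: list[str] | None = None) -> pd.DataFrame:
    """Gene x reporter matrix of fold values ('ns' where not a hit).

    Infinite folds render as the '>>>' sentinel.  Genes are ordered by their
    first-reporter fold ascending (presentation only).  Duplicate
    (gene, reporter) pairs raise.
    """
    reporters = reporters or REPORTERS
    seen = set()
    for s in summaries:
        key = (s.rnai_clone, s.reporter)
        if key in seen:
            raise ValueError(f"duplicate summary for {key}")
        seen.add(key)
    genes = list(dict.fromkeys(s.rnai_clone for s in summaries))
    table = pd.DataFrame("ns", index=pd.Index(genes, name="gene"),
                         columns=reporters, dtype=object)
    for s in summaries:
        if not s.is_hit:
            continue
        cell = INFINITE_FOLD if math.isinf(s.fold_decrease) else round(s.fold_decrease, 1)
        table.loc[s.rnai_clone, s.reporter] = cell
    if len(table) and len(reporters):
        first = table[reporters[0]].map(
            lambda v: math.inf if v in ("ns", INFINITE_FOLD) else float(v))
        table = table.loc[first.sort_values(kind="stable").index]
    return table


def _is_hit_cell(value) -> bool:
    return not (isinstance(value, str) and value == "ns")


def count_hits_per_reporter(table: pd.DataFrame) -> dict[str, int]:
    """Number of significant suppressor genes per reporter column."""
    return {col: int(table[col].map(_is_hit_cell).sum())
            for col in table.columns if col != "function"}


def pathway_overlap_sets(table: pd.DataFrame) -> dict:
    """Reporter-specificity partition of the hit table.

    Assigns each gene the set of reporters it regulates and returns the
    Venn-style intersection cardinalities: ``gene_sets`` (gene -> frozenset of
    reporters), ``intersection_counts`` (frozenset -> number of genes with
    exactly that reporter set), ``single_pathway`` / ``multi_pathway`` gene
    lists, and ``n_specific`` (genes hitting exactly one reporter).
    """
    reporter_cols = [c for c in table.columns if c != "function"]
    gene_sets: dict[str, frozenset] = {}
    for gene, row in table.iterrows():
        hits = frozenset(c for c in reporter_cols if _is_hit_cell(row[c]))
        if hits:
            gene_sets[gene] = hits
    counts: dict[frozenset, int] = {}
    for s in gene_sets.values():
        counts[s] = counts.get(s, 0) + 1
    single = sorted(g for g, s in gene_sets.items() if len(s) == 1)
    multi = sorted(g for g, s in gene_sets.items() if len(s) > 1)
    return {"gene_sets": gene_sets, "intersection_counts": counts,
            "single_pathway": single, "multi_pathway": multi,
            "n_specific": len(single)}


def stress_survival_compare(assay_survival, control_survival,
                            pooled: bool = True) -> dict:
    """Toxin-tolerance comparison on replicate survival proportions.

    One-tailed t-test of RNAi survival < control survival on >= 3 replicate
    proportions per arm; significant at p <= 0.05.  Means and SDs are
    reported for error-bar plotting.
    """
    assay = np.asarray(assay_survival, dtype=float)
    control = np.asarray(control_survival, dtype=float)
    if assay.size < 3 or control.size < 3:
        raise ValueError("need >= 3 replicates per arm")
    for arr in (assay, control):
        if ((arr < 0) | (arr > 1)).any():
            raise ValueError("survival proportions must lie in [0, 1]")
    p = one_tailed_t_test(assay, control, direction="b>a", pooled=pooled)
    return {"p_value": p, "significant": p <= P_THRESHOLD,
            "assay_mean": float(assay.mean()), "assay_sd": float(assay.std(ddof=1)),
            "control_mean": float(control.mean()),
            "control_sd": float(control.std(ddof=1))}


def qpcr_fold_change(target_cts, reference_cts,
                     control_target_cts, control_reference_cts) -> float:
    """Relative expression by the ddCt method against a reference gene.

    dCt = Ct_target - Ct_reference per sample; ddCt = mean dCt(treated) -
    mean dCt(control); fold = 2^(-ddCt).
    """
    groups = [np.asarray(g, dtype=float) for g in
              (target_cts, reference_cts, control_target_cts, control_reference_cts)]
    if groups[0].size != groups[1].size or groups[2].size != groups[3].size:
        raise ValueError("target and reference wells must pair up")
    if groups[1].size == 0 or groups[3].size == 0:
        raise ValueError("missing reference wells")
    if groups[0].size < 2 or groups[2].size < 2:
        raise ValueError("need >= 2 replicates per group")
    dct_treated = groups[0] - groups[1]
    dct_control = groups[2] - groups[3]
    ddct = dct_treated.mean() - dct_control.mean()
    return float(2.0 ** (-ddct))


def qpcr_fold_change_from_table(table: pd.DataFrame) -> float:
    """ddCt fold change from a tidy Ct table (group/target_ct/reference_ct)."""
    treated = table[table["group"] == "treated"]
    control = table[table["group"] == "control"]
    return qpcr_fold_change(treated["target_ct"], treated["reference_ct"],
                            control["target_ct"], control["reference_ct"])
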