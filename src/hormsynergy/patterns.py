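"""Venn partitioning, intersection refinement, and pattern codes.

The three DE gene lists (T3 vs vehicle, CORT vs vehicle, T3+CORT vs
vehicle) partition into the regions of a three-way Venn diagram:

    a  T3 only                      d  T3 and combined
    b  CORT only                    e  CORT and combined
    c  combined only                f  all three
    g  T3 and CORT but not combined (geometrically present; empty in
                                     data shaped like the study's)

Probes in the intersections d/e/f are refined by testing the combined
replicates against the single-hormone replicates: a combined response
that is significantly larger than the single-hormone response marks
enhancement, significantly smaller (or reversed) marks suppression.
The refined taxonomy is the pattern code:

    A1          T3-only response, abolished by CORT
    B1/B2       CORT-only response (induced/repressed), abolished by T3
    C1/C2       combined-only response (induced/repressed)
    D1/D2/D3    T3 response enhanced / reversed-or-suppressed /
                unaffected by CORT
    E1/E2       CORT response unaffected by T3 (induced/repressed)
    E3/E4       CORT response enhanced by T3
    E5/E6       CORT response suppressed by T3
    F1          responsive in all three arms

Probe-level assignments collapse to gene level: duplicate probes of one
gene are resolved by the probe with the largest |log2 FC| in its
section's defining arm, and unannotated probes are dropped with a count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de import welch_t
from .io import Design, ExpressionMatrix, ProbeAnnotation
from .thresholds import Thresholds

VENN_SECTIONS: tuple[str, ...] = ("a", "b", "c", "d", "e", "f", "g", "none")

PATTERN_CODES: tuple[str, ...] = (
    "A1", "B1", "B2", "C1", "C2", "D1", "D2", "D3",
    "E1", "E2", "E3", "E4", "E5", "E6", "F1", "none",
)

#: which hormone arm defines a section's effect size (probe collapsing)
DEFINING_TREATMENT: dict[str, str] = {
    "a": "T3",
    "b": "CORT",
    "c": "T3CORT",
    "d": "T3CORT",
    "e": "T3CORT",
    "f": "T3CORT",
    "g": "CORT",
    "none": "T3CORT",
}


def venn_partition(calls: pd.DataFrame) -> pd.Series:
    """Map each probe to its Venn section from the three DE calls.

    ``calls`` is the frame from :func:`hormsynergy.de.call_de` (columns
    T3 / CORT / T3CORT with values up / down / ns). Direction is ignored
    here; only membership in each DE list matters.
    """
    t3 = (calls["T3"] != "ns").to_numpy()
    cort = (calls["CORT"] != "ns").to_numpy()
    comb = (calls["T3CORT"] != "ns").to_numpy()
    section = np.select(
        [
            t3 & ~cort & ~comb,
            ~t3 & cort & ~comb,
            ~t3 & ~cort & comb,
            t3 & ~cort & comb,
            ~t3 & cort & comb,
            t3 & cort & comb,
            t3 & cort & ~comb,
        ],
        ["a", "b", "c", "d", "e", "f", "g"],
        default="none",
    )
    return pd.Series(section, index=calls.index, name="venn_section")


def _log2_group_stats(
    matrix: ExpressionMatrix, design: Design
) -> dict[str, tuple[np.ndarray, np.ndarray, int]]:
    out = {}
    for tr in ("T3", "CORT", "T3CORT"):
        vals = np.log2(matrix.signals[design.samples_for(tr)].to_numpy(dtype=float))
        out[tr] = (vals.mean(axis=1), vals.var(axis=1, ddof=1), vals.shape[1])
    return out


def assign_patterns(
    matrix: ExpressionMatrix,
    design: Design,
    stats_frame: pd.DataFrame,
    calls: pd.DataFrame,
    thresholds: Thresholds,
) -> pd.DataFrame:
    """Venn sections, refinement tests and pattern codes for all probes.

    Returns a frame indexed by probe id with columns ``venn_section``,
    ``pattern_code``, ``refine_p_vs_T3`` and ``refine_p_vs_CORT`` (NaN
    where the section needs no test). The refinement test is a
    two-sided Welch t on log2 signals, combined arm vs the single arm,
    at ``thresholds.alpha_refine``.
    """
    section = venn_partition(calls)
    g = _log2_group_stats(matrix, design)
    comb_mean, comb_var, comb_n = g["T3CORT"]

    refine_p = {}
    for single in ("T3", "CORT"):
        s_mean, s_var, s_n = g[single]
        _, _, p = welch_t(comb_mean, comb_var, comb_n, s_mean, s_var, s_n)
        refine_p[single] = p

    lfc_t3 = stats_frame["log2fc_T3"].to_numpy()
    lfc_cort = stats_frame["log2fc_CORT"].to_numpy()
    lfc_comb = stats_frame["log2fc_T3CORT"].to_numpy()
    dir_comb = np.where(lfc_comb > 0, "up", "down")
    dir_cort = calls["CORT"].to_numpy()

    codes = np.full(len(section), "none", dtype=object)
    p_t3_col = np.full(len(section), np.nan)
    p_cort_col = np.full(len(section), np.nan)
    sec = section.to_numpy()

    codes[sec == "a"] = "A1"
    mask_b = sec == "b"
    codes[mask_b] = np.where(dir_cort[mask_b] == "up", "B1", "B2")
    mask_c = sec == "c"
    codes[mask_c] = np.where(dir_comb[mask_c] == "up", "C1", "C2")
    codes[sec == "f"] = "F1"

    mask_d = sec == "d"
    if mask_d.any():
        p = refine_p["T3"][mask_d]
        p_t3_col[mask_d] = p
        sig = p < thresholds.alpha_refine
        same_sign = np.sign(lfc_comb[mask_d]) == np.sign(lfc_t3[mask_d])
        bigger = np.abs(lfc_comb[mask_d]) > np.abs(lfc_t3[mask_d])
        codes[mask_d] = np.select(
            [~sig, sig & same_sign & bigger],
            ["D3", "D1"],
            default="D2",
        )

    mask_e = sec == "e"
    if mask_e.any():
        p = refine_p["CORT"][mask_e]
        p_cort_col[mask_e] = p
        sig = p < thresholds.alpha_refine
        bigger = np.abs(lfc_comb[mask_e]) > np.abs(lfc_cort[mask_e])
        induced = dir_comb[mask_e] == "up"
        codes[mask_e] = np.select(
            [~sig & induced, ~sig & ~induced,
             sig & bigger & induced, sig & bigger & ~induced,
             sig & ~bigger & induced],
            ["E1", "E2", "E3", "E4", "E5"],
            default="E6",
        )

    # section f: both tests are reported for information, code stays F1
    mask_f = sec == "f"
    p_t3_col[mask_f] = refine_p["T3"][mask_f]
    p_cort_col[mask_f] = refine_p["CORT"][mask_f]

    return pd.DataFrame(
        {
            "venn_section": sec,
            "pattern_code": codes,
            "refine_p_vs_T3": p_t3_col,
            "refine_p_vs_CORT": p_cort_col,
        },
        index=section.index,
    )


def refine_intersection(
    matrix: ExpressionMatrix,
    design: Design,
    probe: str,
    stats_frame: pd.DataFrame,
    calls: pd.DataFrame,
    thresholds: Thresholds,
) -> pd.Series:
    """Pattern assignment for a single probe (row of :func:`assign_patterns`)."""
    full = assign_patterns(matrix, design, stats_frame, calls, thresholds)
    return full.loc[probe]


@dataclass
class CollapseResult:
    """Gene-level sets after probe collapsing.

    ``genes`` has one row per annotated gene with the winning probe and
    its section/code; ``sets`` maps each section and pattern-code label
    to its gene-symbol set; ``n_unannotated`` counts excluded probes.
    """

    genes: pd.DataFrame
    sets: dict[str, set[str]] = field(default_factory=dict)
    n_unannotated: int = 0
    n_conflicts: int = 0


def collapse_probes(
    assignments: pd.DataFrame,
    stats_frame: pd.DataFrame,
    annotation: ProbeAnnotation,
) -> CollapseResult:
    """Collapse probe-level assignments to one entry per gene symbol.

    A gene hit by several probes keeps the probe with the largest
    |log2 FC| in the defining arm of that probe's own section (ties
    break on probe id for determinism); probes with an empty symbol are
    excluded and counted.
    """
    symbol = annotation.symbol_of().reindex(assignments.index).fillna("")
    work = assignments.copy()
    work["gene_symbol"] = symbol.to_numpy()
    n_unannotated = int((work["gene_symbol"] == "").sum())
    work = work[work["gene_symbol"] != ""]

    defining = work["venn_section"].map(DEFINING_TREATMENT)
    eff = np.empty(len(work))
    for tr in ("T3", "CORT", "T3CORT"):
        m = (defining == tr).to_numpy()
        if m.any():
            eff[m] = np.abs(
                stats_frame[f"log2fc_{tr}"].reindex(work.index).to_numpy()[m]
            )
    work = work.assign(_effect=eff)
    work = work.sort_values(
        ["gene_symbol", "_effect"], ascending=[True, False], kind="stable"
    )
    # count genes whose probes disagree on section before deduplicating
    n_conflicts = int(
        work.groupby("gene_symbol")["venn_section"].nunique().gt(1).sum()
    )
    winners = work.loc[~work["gene_symbol"].duplicated(keep="first")].copy()
    winners = winners.rename_axis("probe_id").reset_index()
    winners = winners.drop(columns="_effect")

    sets: dict[str, set[str]] = {}
    for sec_label, grp in winners.groupby("venn_section"):
        if sec_label != "none":
            sets[str(sec_label)] = set(grp["gene_symbol"])
    for code_label, grp in winners.groupby("pattern_code"):
        if code_label != "none":
            sets[str(code_label)] = set(grp["gene_symbol"])
    return CollapseResult(
        genes=winners,
        sets=sets,
        n_unannotated=n_unannotated,
        n_conflicts=n_conflicts,
    )


def section_counts(assignments: pd.DataFrame) -> dict[str, int]:
    """Probe counts per Venn section (all eight values always present)."""
    counts = assignments["venn_section"].value_counts()
    return {s: int(counts.get(s, 0)) for s in VENN_SECTIONS}


def code_counts(assignments: pd.DataFrame) -> dict[str, int]:
    """Probe counts per pattern code."""
    counts = assignments["pattern_code"].value_counts()
    return {c: int(counts.get(c, 0)) for c in PATTERN_CODES}


def check_partition_identities(
    calls: pd.DataFrame, assignments: pd.DataFrame
) -> dict[str, bool]:
    """Verify the Venn partition identities.

    |T3 list| = a+d+f+g, |CORT list| = b+e+f+g,
    |combined list| = c+d+e+f, and e = (E1+E2)+(E3+E4)+(E5+E6);
    the g terms vanish on data shaped like the study's.
    """
    s = section_counts(assignments)
    c = code_counts(assignments)
    n_t3 = int((calls["T3"] != "ns").sum())
    n_cort = int((calls["CORT"] != "ns").sum())
    n_comb = int((calls["T3CORT"] != "ns").sum())
    return {
        "t3_list": n_t3 == s["a"] + s["d"] + s["f"] + s["g"],
        "cort_list": n_cort == s["b"] + s["e"] + s["f"] + s["g"],
        "combined_list": n_comb == s["c"] + s["d"] + s["e"] + s["f"],
        "section_e_codes": s["e"]
        == (c["E1"] + c["E2"]) + (c["E3"] + c["E4"]) + (c["E5"] + c["E6"]),
    }
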