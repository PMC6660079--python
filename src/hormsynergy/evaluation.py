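"""Recovery benchmarks: run the pipeline on planted data, score vs truth.

Each benchmark generates synthetic inputs under the documented study
conditions (triplicates, 0.15 log2 replicate noise, the default planted
effect sizes), runs the analysis exactly as a user would, and scores the
calls against the generator's truth labels. Problem sizes are chosen so
every estimate carries a few-per-mille binomial error while a full run
stays desk-scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .de import call_de, treatment_stats
from .mapping import classify_cohort, summarize_fractions
from .model import HormoneTreatmentModel
from .simulate import (
    DEFAULT_EFFECT_SIZES,
    ExpressionSimConfig,
    TrackSimConfig,
    simulate_expression,
    simulate_tracks,
)
from .synergy import call_synergy
from .thresholds import Thresholds


def _subseed(seed: int, i: int) -> int:
    return (seed * 1_009 + i) % (2**31 - 1)


def synergy_benchmark(
    n_probes: int = 10_000,
    n_seeds: int = 5,
    seed: int = 0,
    synergy_fraction: float = 0.05,
) -> dict:
    """Sensitivity and type-I behaviour of the synergy caller.

    Plants induced (greater-than-additive, +6 SD margins on inducing
    singles) and repressed (combined-only route, -6 margins) synergy
    probes among nulls; sensitivity is the fraction of planted probes
    called synergistic. The false-positive rate is the fraction of
    null probes passing the unrestricted greater-than-additive rule
    (margin + Welch at alpha 0.02), the binding statistical check.
    """
    th = Thresholds()
    n_planted = n_null = 0
    n_called = n_fp = 0
    welch_hits = margin_hits = 0
    for i in range(n_seeds):
        cfg = ExpressionSimConfig(
            n_probes=n_probes,
            class_fractions={
                "synergy_induced": synergy_fraction,
                "synergy_repressed": synergy_fraction,
            },
            rng_seed=_subseed(seed, i),
        )
        matrix, design, truth = simulate_expression(cfg)
        stats = treatment_stats(matrix, design)
        calls = call_de(stats, th)
        syn = call_synergy(calls, stats, th)
        planted = truth["synergy"].to_numpy()
        called = (syn["criterion"] != "none").to_numpy()
        n_planted += int(planted.sum())
        n_called += int((called & planted).sum())
        syn_open = call_synergy(
            calls, stats, th, restrict_to_intersections=False
        )
        null_mask = ~planted
        n_null += int(null_mask.sum())
        n_fp += int(
            (syn_open["criterion"].to_numpy() != "none")[null_mask].sum()
        )
        welch_hits += int((syn["welch_p"].to_numpy() < th.alpha_de)[planted].sum())
        diff = (
            stats["mean_T3CORT"].to_numpy() - syn["expectation"].to_numpy()
        )
        margin_hits += int(
            (np.abs(diff) >= syn["sd_margin"].to_numpy())[planted].sum()
        )
    se = float(np.sqrt(0.02 * 0.98 / n_null))
    return {
        "sensitivity": n_called / n_planted,
        "fpr_criterion2": n_fp / n_null,
        "fpr_bound": 0.02 + 3 * se,
        "welch_power": welch_hits / n_planted,
        "margin_rate": margin_hits / n_planted,
        "n_planted": n_planted,
        "n_null": n_null,
    }


def pattern_benchmark(
    n_probes: int = 6_000, n_seeds: int = 3, seed: int = 0
) -> dict:
    """Recovery of planted combined-only (section c) and E3 patterns."""
    n_c_planted = n_c_hit = n_e3_planted = n_e3_hit = 0
    for i in range(n_seeds):
        cfg = ExpressionSimConfig(
            n_probes=n_probes,
            class_fractions={"combined_only": 0.10, "cort_enhanced": 0.10},
            rng_seed=_subseed(seed, 100 + i),
        )
        matrix, design, truth = simulate_expression(cfg)
        res = HormoneTreatmentModel(matrix, design).fit()
        c_mask = (truth["planted_class"] == "combined_only").to_numpy()
        e3_mask = (truth["planted_class"] == "cort_enhanced").to_numpy()
        section = res.assignments["venn_section"].to_numpy()
        code = res.assignments["pattern_code"].to_numpy()
        n_c_planted += int(c_mask.sum())
        n_c_hit += int((section[c_mask] == "c").sum())
        n_e3_planted += int(e3_mask.sum())
        n_e3_hit += int((code[e3_mask] == "E3").sum())
    return {
        "section_c_recovery": n_c_hit / n_c_planted,
        "e3_recovery": n_e3_hit / n_e3_planted,
        "n_c_planted": n_c_planted,
        "n_e3_planted": n_e3_planted,
    }


#: planted composition mirroring the study's published Venn structure:
#: 9 T3 genes (3 a + 3 d + 3 f), 432 CORT (170 b + 259 e + 3 f),
#: 412 combined (147 c + 3 d + 259 e + 3 f), e split 226/10/23,
#: combined-only split 74 induced / 73 repressed
STUDY_SHAPED_COUNTS: dict[str, int] = {
    "t3_only": 3,
    "t3_combined": 3,
    "all_three": 3,
    "cort_only": 170,
    "cort_additive": 226,
    "cort_enhanced": 10,
    "cort_suppressed": 23,
    "combined_only": 74,
    "combined_only_repressed": 73,
}


def study_shaped_benchmark(seed: int = 0, n_probes: int = 20_000) -> dict:
    """End-to-end run on a matrix planted with the study-shaped counts.

    Returns planted and recovered headline counts (DE per arm, key
    sections, synergy by direction).
    """
    effect_sizes = dict(
        DEFAULT_EFFECT_SIZES, t3_combined=(1.0, 0.0, 0.0)
    )
    fractions = {k: v / n_probes for k, v in STUDY_SHAPED_COUNTS.items()}
    cfg = ExpressionSimConfig(
        n_probes=n_probes,
        class_fractions=fractions,
        effect_sizes=effect_sizes,
        rng_seed=_subseed(seed, 777),
    )
    matrix, design, truth = simulate_expression(cfg)
    res = HormoneTreatmentModel(matrix, design).fit()
    s = res.section_counts
    c = STUDY_SHAPED_COUNTS
    planted = {
        "de_T3": c["t3_only"] + c["t3_combined"] + c["all_three"],
        "de_CORT": c["cort_only"] + c["cort_additive"] + c["cort_enhanced"]
        + c["cort_suppressed"] + c["all_three"],
        "de_T3CORT": c["combined_only"] + c["combined_only_repressed"]
        + c["t3_combined"] + c["cort_additive"] + c["cort_enhanced"]
        + c["cort_suppressed"] + c["all_three"],
        "section_b": c["cort_only"],
        "section_c": c["combined_only"] + c["combined_only_repressed"],
        "section_e": c["cort_additive"] + c["cort_enhanced"] + c["cort_suppressed"],
        "synergy_induced": c["combined_only"] + c["cort_enhanced"],
        "synergy_repressed": c["combined_only_repressed"],
    }
    sy = res.synergy_counts
    recovered = {
        "de_T3": res.de_counts["T3"],
        "de_CORT": res.de_counts["CORT"],
        "de_T3CORT": res.de_counts["T3CORT"],
        "section_b": s["b"],
        "section_c": s["c"],
        "section_e": s["e"],
        "synergy_induced": sy["induced"],
        "synergy_repressed": sy["repressed"],
    }
    return {
        "planted": planted,
        "recovered": recovered,
        "identities_hold": all(res.partition_identities.values()),
    }


def track_benchmark(n_genes: int = 110, seed: int = 0) -> dict:
    """Planted-vs-measured co-localization fractions on synthetic tracks.

    The default planted fractions echo the published per-class
    percentages for the synergy cohort (e.g. ~21/15/16% for H3K27Ac).
    """
    cfg = TrackSimConfig(n_genes=n_genes, rng_seed=_subseed(seed, 555))
    loci, tracks, truth = simulate_tracks(cfg)
    classes = classify_cohort(loci, tracks, Thresholds())
    measured = summarize_fractions(classes)
    planted = summarize_fractions(truth)
    agreement = float((classes == truth.loc[classes.index]).all().all())
    return {
        "measured": measured,
        "planted": planted,
        "exact_agreement": agreement,
        "n_genes": n_genes,
    }
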