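"""Two-criterion synergy calling for combined hormone treatment.

A probe is synergistically regulated by T3 + CORT when either

1. neither hormone alone has an effect but the combined treatment is
   differentially expressed (FC and p cut-offs as for DE) — these are
   exactly the combined-only Venn probes; or
2. the combined signal departs from the additive expectation by at
   least one standard deviation (the SD computed from the summed
   single-treatment variances) on the synergistic side, and an
   unpaired Welch t-test of the combined signal against the additive
   expectation — with the expectation's variance taken as the sum of
   the variances of its component treatments — is significant.

The additive expectation has two modes. ``baseline_corrected``
(default) predicts mean_T3 + mean_CORT - mean_VEH, i.e. single-hormone
effects above baseline add; this makes synergistic repression (combined
signal below the expectation) detectable. ``literal_sum`` predicts
mean_T3 + mean_CORT, the raw sum of the single-treatment signals.

Induction means the combined mean exceeds the expectation; repression
means it falls below. Criterion-1 probes take their direction the same
way.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .de import VARIANCE_FLOOR
from .thresholds import Thresholds

AdditiveMode = Literal["baseline_corrected", "literal_sum"]


def additive_expectation(
    mean_t3,
    mean_cort,
    mean_veh,
    mode: AdditiveMode = "baseline_corrected",
):
    """Predicted combined-treatment signal if the two effects just add.

    ``baseline_corrected``: T3 + CORT - VEH (effects above baseline
    add). ``literal_sum``: T3 + CORT.
    """
    if mode == "baseline_corrected":
        return np.asarray(mean_t3) + np.asarray(mean_cort) - np.asarray(mean_veh)
    if mode == "literal_sum":
        return np.asarray(mean_t3) + np.asarray(mean_cort)
    raise ValueError(f"unknown additive mode {mode!r}")


def welch_sum_test(
    stats_frame: pd.DataFrame,
    mode: AdditiveMode = "baseline_corrected",
) -> pd.DataFrame:
    """Welch t-test of the combined signal against the additive expectation.

    The test statistic is

        t = (mean_comb - expectation) / sqrt(var_comb/n_c + var_T3/n_t
            + var_CORT/n_k [+ var_VEH/n_v under baseline correction])

    with Welch-Satterthwaite degrees of freedom over the same variance
    terms and a two-sided p-value. Works on the raw signal scale, where
    the additive prediction is stated.

    Returns a frame indexed like ``stats_frame`` with columns
    ``expectation``, ``sd_margin`` (sqrt of the summed single-treatment
    variances), ``welch_t``, ``welch_df``, ``welch_p``.
    """
    m = stats_frame
    expectation = additive_expectation(
        m["mean_T3"].to_numpy(), m["mean_CORT"].to_numpy(), m["mean_VEH"].to_numpy(), mode
    )
    terms = [
        (m["var_T3CORT"].to_numpy(), m["n_T3CORT"].to_numpy()),
        (m["var_T3"].to_numpy(), m["n_T3"].to_numpy()),
        (m["var_CORT"].to_numpy(), m["n_CORT"].to_numpy()),
    ]
    if mode == "baseline_corrected":
        terms.append((m["var_VEH"].to_numpy(), m["n_VEH"].to_numpy()))

    se2 = [np.maximum(v, 0.0) / n for v, n in terms]
    denom2 = np.sum(se2, axis=0)
    degenerate = denom2 <= 0
    denom2 = np.where(degenerate, VARIANCE_FLOOR, denom2)
    diff = m["mean_T3CORT"].to_numpy() - expectation
    t = diff / np.sqrt(denom2)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = denom2**2 / np.sum(
            [
                np.where(s > 0, s**2 / (n - 1), 0.0)
                for s, (_, n) in zip(se2, terms)
            ],
            axis=0,
        )
    min_n = np.min([n for _, n in terms], axis=0)
    df = np.where(np.isfinite(df) & (df > 0), df, min_n - 1)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate & (diff == 0), 1.0, np.clip(p, 0.0, 1.0))

    # the SD margin is always the summed single-treatment variances
    sd_margin = np.sqrt(
        np.maximum(m["var_T3"].to_numpy(), 0.0)
        + np.maximum(m["var_CORT"].to_numpy(), 0.0)
    )
    return pd.DataFrame(
        {
            "expectation": expectation,
            "sd_margin": sd_margin,
            "welch_t": t,
            "welch_df": df,
            "welch_p": p,
        },
        index=m.index,
    )


def call_synergy(
    calls: pd.DataFrame,
    stats_frame: pd.DataFrame,
    thresholds: Thresholds,
    mode: AdditiveMode = "baseline_corrected",
    require_margin: bool = True,
    require_welch: bool = True,
    restrict_to_intersections: bool = True,
) -> pd.DataFrame:
    """Synergy calls for every probe.

    Criterion 1 (``combined_only``) needs DE in the combined arm with
    both singles ns — exactly the combined-only Venn section.
    Criterion 2 (``greater_than_additive``) is evaluated on the Venn
    intersection probes (DE in the combined arm and in at least one
    single arm) and needs the combined mean to depart from the additive
    expectation by ``sd_multiplier`` x the SD margin on the synergistic
    side — away from baseline, i.e. above the expectation when the net
    single-hormone effect is induction and below it when it is
    repression, so mere blunting of a single-hormone response never
    counts — plus a significant variance-sum Welch test at
    ``alpha_de``. The margin and Welch sub-rules can each be relaxed;
    ``restrict_to_intersections=False`` scores criterion 2 on every
    probe regardless of DE membership.

    Returns a frame with ``direction`` (induced / repressed / none),
    ``criterion`` (combined_only / greater_than_additive / both /
    none) and the expectation / margin / Welch columns.
    """
    wt = welch_sum_test(stats_frame, mode)
    diff = stats_frame["mean_T3CORT"].to_numpy() - wt["expectation"].to_numpy()

    crit1 = (
        (calls["T3CORT"] != "ns")
        & (calls["T3"] == "ns")
        & (calls["CORT"] == "ns")
    ).to_numpy()

    margin_ok = np.abs(diff) >= thresholds.sd_multiplier * wt["sd_margin"].to_numpy()
    welch_ok = wt["welch_p"].to_numpy() < thresholds.alpha_de
    # departure must point away from baseline: with a net inducing
    # single-hormone expectation only combined-above-expectation is
    # synergy, with a net repressing expectation only combined-below
    net_single = wt["expectation"].to_numpy() - stats_frame["mean_VEH"].to_numpy()
    synergistic_side = ((diff > 0) & (net_single >= 0)) | (
        (diff < 0) & (net_single <= 0)
    )
    crit2 = synergistic_side
    if require_margin:
        crit2 = crit2 & margin_ok
    if require_welch:
        crit2 = crit2 & welch_ok
    if restrict_to_intersections:
        intersection = (
            (calls["T3CORT"] != "ns")
            & ((calls["T3"] != "ns") | (calls["CORT"] != "ns"))
        ).to_numpy()
        crit2 = crit2 & intersection

    criterion = np.select(
        [crit1 & crit2, crit1, crit2],
        ["both", "combined_only", "greater_than_additive"],
        default="none",
    )
    synergistic = criterion != "none"
    direction = np.select(
        [synergistic & (diff > 0), synergistic & (diff < 0)],
        ["induced", "repressed"],
        default="none",
    )
    # criterion-1-only probes with an exactly additive mean (diff == 0)
    # take direction from the combined DE call
    tie = synergistic & (diff == 0)
    if tie.any():
        comb_call = calls["T3CORT"].to_numpy()
        direction = np.where(
            tie, np.where(comb_call == "up", "induced", "repressed"), direction
        )

    out = wt.copy()
    out.insert(0, "criterion", criterion)
    out.insert(0, "direction", direction)
    return out


def ranked_synergy_table(
    synergy_frame: pd.DataFrame,
    stats_frame: pd.DataFrame,
    direction: Literal["induced", "repressed"],
    annotation_symbols: pd.Series | None = None,
    top_n: int | None = 20,
) -> pd.DataFrame:
    """Top synergistically induced/repressed probes by combined fold change.

    Induced probes sort by combined FC descending, repressed ascending,
    mirroring the study's top-gene tables.
    """
    sel = synergy_frame["direction"] == direction
    tab = pd.DataFrame(
        {
            "fc_T3": stats_frame.loc[sel, "fc_T3"],
            "fc_CORT": stats_frame.loc[sel, "fc_CORT"],
            "fc_T3CORT": stats_frame.loc[sel, "fc_T3CORT"],
            "criterion": synergy_frame.loc[sel, "criterion"],
            "welch_p": synergy_frame.loc[sel, "welch_p"],
        }
    )
    if annotation_symbols is not None:
        tab.insert(0, "gene_symbol", annotation_symbols.reindex(tab.index).fillna(""))
    tab = tab.sort_values("fc_T3CORT", ascending=(direction == "repressed"))
    return tab.head(top_n) if top_n else tab
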