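"""Per-probe treatment statistics and differential-expression calls.

For each probe the fold change of a hormone arm is the ratio of its
mean raw signal (n replicates) to the mean vehicle signal. A probe is
called up-regulated when FC >= 1.5 with p < 0.02, down-regulated when
FC <= 1/1.5 with p < 0.02 (symmetric on the log2 scale;
log2(1.5) = 0.58496), and not significant otherwise.

The per-probe test defaults to a two-sided Welch two-sample t-test on
log2-transformed floored signals — ratio effects are additive and
roughly homoscedastic on that scale — and can be switched to Student's
pooled-variance t or to the raw signal scale. No multiple-testing
correction is applied to the calls; a Benjamini-Hochberg column is
emitted for information only.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .io import Design, ExpressionMatrix, HORMONE_TREATMENTS, TREATMENTS
from .thresholds import Thresholds

VARIANCE_FLOOR = 1e-12

TestScale = Literal["log2", "raw"]


def welch_t(
    mean_a: np.ndarray,
    var_a: np.ndarray,
    n_a: int,
    mean_b: np.ndarray,
    var_b: np.ndarray,
    n_b: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-sided Welch t-test from summary statistics.

    Degenerate probes (both group variances zero) get p = 1 when the
    means agree; otherwise the variance floor keeps the statistic
    finite and the call obvious.
    """
    mean_a = np.asarray(mean_a, dtype=float)
    mean_b = np.asarray(mean_b, dtype=float)
    var_a = np.maximum(np.asarray(var_a, dtype=float), 0.0)
    var_b = np.maximum(np.asarray(var_b, dtype=float), 0.0)
    se2_a = var_a / n_a
    se2_b = var_b / n_b
    denom2 = se2_a + se2_b
    degenerate = denom2 <= 0
    denom2 = np.where(degenerate, VARIANCE_FLOOR, denom2)
    t = (mean_a - mean_b) / np.sqrt(denom2)
    # Welch-Satterthwaite; degenerate probes get the minimal df
    with np.errstate(divide="ignore", invalid="ignore"):
        df = denom2**2 / (
            np.where(se2_a > 0, se2_a**2 / (n_a - 1), 0.0)
            + np.where(se2_b > 0, se2_b**2 / (n_b - 1), 0.0)
        )
    df = np.where(np.isfinite(df) & (df > 0), df, min(n_a, n_b) - 1)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate & (mean_a == mean_b), 1.0, np.clip(p, 0.0, 1.0))
    return t, df, p


def student_t(
    mean_a: np.ndarray,
    var_a: np.ndarray,
    n_a: int,
    mean_b: np.ndarray,
    var_b: np.ndarray,
    n_b: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-sided pooled-variance (Student) t-test."""
    mean_a = np.asarray(mean_a, dtype=float)
    mean_b = np.asarray(mean_b, dtype=float)
    pooled = ((n_a - 1) * np.asarray(var_a) + (n_b - 1) * np.asarray(var_b)) / (
        n_a + n_b - 2
    )
    denom2 = pooled * (1.0 / n_a + 1.0 / n_b)
    degenerate = denom2 <= 0
    denom2 = np.where(degenerate, VARIANCE_FLOOR, denom2)
    t = (mean_a - mean_b) / np.sqrt(denom2)
    df = np.full_like(t, float(n_a + n_b - 2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate & (mean_a == mean_b), 1.0, np.clip(p, 0.0, 1.0))
    return t, df, p


def treatment_stats(
    matrix: ExpressionMatrix,
    design: Design,
    test: Literal["welch", "student"] = "welch",
    test_scale: TestScale = "log2",
) -> pd.DataFrame:
    """Per-probe means, variances and hormone-vs-vehicle tests.

    Returns a frame indexed by probe id with, per treatment, columns
    ``mean_<T>``, ``var_<T>`` (unbiased, n-1 denominator) and ``n_<T>``
    of the raw floored signals, and per hormone arm ``fc_<T>``
    (mean ratio over vehicle), ``log2fc_<T>``, ``p_<T>`` and a
    Benjamini-Hochberg ``padj_<T>`` column emitted for information only.
    """
    sig = matrix.signals
    out = pd.DataFrame(index=sig.index)
    group_raw: dict[str, np.ndarray] = {}
    for tr in TREATMENTS:
        cols = design.samples_for(tr)
        if len(cols) < 2:
            raise ValueError(f"treatment {tr} has n < 2; variance undefined")
        vals = sig[cols].to_numpy(dtype=float)
        group_raw[tr] = vals
        out[f"mean_{tr}"] = vals.mean(axis=1)
        out[f"var_{tr}"] = vals.var(axis=1, ddof=1)
        out[f"n_{tr}"] = vals.shape[1]

    try:
        test_fn = {"welch": welch_t, "student": student_t}[test]
    except KeyError:
        raise ValueError(f"unknown test {test!r}") from None
    if test_scale not in ("log2", "raw"):
        raise ValueError(f"unknown test_scale {test_scale!r}")

    veh_raw = group_raw["VEH"]
    veh_test = np.log2(veh_raw) if test_scale == "log2" else veh_raw
    veh_mean = veh_test.mean(axis=1)
    veh_var = veh_test.var(axis=1, ddof=1)
    n_veh = veh_test.shape[1]

    for tr in HORMONE_TREATMENTS:
        fc = out[f"mean_{tr}"] / out["mean_VEH"]
        out[f"fc_{tr}"] = fc
        out[f"log2fc_{tr}"] = np.log2(fc)
        trt_raw = group_raw[tr]
        trt_test = np.log2(trt_raw) if test_scale == "log2" else trt_raw
        _, _, p = test_fn(
            trt_test.mean(axis=1),
            trt_test.var(axis=1, ddof=1),
            trt_test.shape[1],
            veh_mean,
            veh_var,
            n_veh,
        )
        out[f"p_{tr}"] = p
        out[f"padj_{tr}"] = bh_adjust(p)
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out


def call_de(stats_frame: pd.DataFrame, thresholds: Thresholds) -> pd.DataFrame:
    """Direction calls (up / down / ns) per hormone arm.

    up: FC >= cutoff and p < alpha; down: FC <= 1/cutoff and p < alpha.
    """
    calls = pd.DataFrame(index=stats_frame.index)
    for tr in HORMONE_TREATMENTS:
        fc = stats_frame[f"fc_{tr}"].to_numpy()
        p = stats_frame[f"p_{tr}"].to_numpy()
        sig = p < thresholds.alpha_de
        up = sig & (fc >= thresholds.fc_cutoff)
        down = sig & (fc <= 1.0 / thresholds.fc_cutoff)
        calls[tr] = np.select([up, down], ["up", "down"], default="ns")
    return calls
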