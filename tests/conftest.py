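import numpy as np
import pandas as pd
import pytest

from hormsynergy import Thresholds
from hormsynergy.io import Design, ExpressionMatrix
from hormsynergy.simulate import (
    DEFAULT_EFFECT_SIZES,
    ExpressionSimConfig,
    TrackSimConfig,
    simulate_expression,
    simulate_tracks,
)


@pytest.fixture(scope="session")
def thresholds() -> Thresholds:
    return Thresholds()


@pytest.fixture(scope="session")
def sim_expression():
    """Moderate planted matrix shared by read-only tests."""
    cfg = ExpressionSimConfig(n_probes=2_000, rng_seed=101)
    return simulate_expression(cfg)


@pytest.fixture(scope="session")
def sim_tracks():
    cfg = TrackSimConfig(n_genes=80, rng_seed=202)
    return simulate_tracks(cfg)


@pytest.fixture()
def tiny_matrix_design():
    """Hand-written 2-probe, 12-sample dataset with exact group means.

    probe_hi: T3 replicates (300, 330, 270) vs VEH (100, 110, 90),
    so fc_T3 = 300 / 100 = 3. probe_flat: identical everywhere.
    """
    rows = {
        "probe_hi": {
            "VEH": [100.0, 110.0, 90.0],
            "T3": [300.0, 330.0, 270.0],
            "CORT": [150.0, 160.0, 140.0],
            "T3CORT": [600.0, 620.0, 580.0],
        },
        "probe_flat": {
            "VEH": [50.0] * 3,
            "T3": [50.0] * 3,
            "CORT": [50.0] * 3,
            "T3CORT": [50.0] * 3,
        },
    }
    sample_ids, design_rows, cols = [], [], {}
    for tr in ("VEH", "T3", "CORT", "T3CORT"):
        for rep in range(1, 4):
            sid = f"{tr}_{rep}"
            sample_ids.append(sid)
            design_rows.append(
                {"sample_id": sid, "treatment": tr, "replicate": rep}
            )
            cols[sid] = [rows[p][tr][rep - 1] for p in rows]
    signals = pd.DataFrame(cols, index=pd.Index(list(rows), name="probe_id"))
    matrix = ExpressionMatrix.floored(signals)
    design = Design.from_frame(pd.DataFrame(design_rows))
    return matrix, design


def make_stats_row(
    mean_veh, mean_t3, mean_cort, mean_comb,
    var_veh=0.0, var_t3=0.0, var_cort=0.0, var_comb=0.0, n=3,
    probe_id="p0",
) -> pd.DataFrame:
    """Single-probe summary-statistics frame for direct synergy calls."""
    row = {
        "mean_VEH": mean_veh, "var_VEH": var_veh, "n_VEH": n,
        "mean_T3": mean_t3, "var_T3": var_t3, "n_T3": n,
        "mean_CORT": mean_cort, "var_CORT": var_cort, "n_CORT": n,
        "mean_T3CORT": mean_comb, "var_T3CORT": var_comb, "n_T3CORT": n,
    }
    for tr, m in (("T3", mean_t3), ("CORT", mean_cort), ("T3CORT", mean_comb)):
        fc = m / mean_veh
        row[f"fc_{tr}"] = fc
        row[f"log2fc_{tr}"] = np.log2(fc)
        row[f"p_{tr}"] = np.nan
    return pd.DataFrame([row], index=pd.Index([probe_id], name="probe_id"))


def make_calls(t3, cort, comb, probe_id="p0") -> pd.DataFrame:
    return pd.DataFrame(
        {"T3": [t3], "CORT": [cort], "T3CORT": [comb]},
        index=pd.Index([probe_id], name="probe_id"),
    )
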