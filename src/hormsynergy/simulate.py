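"""Synthetic inputs with planted truth for every pipeline stage.

Expression matrices follow a log-normal model: each probe draws a
baseline log2 level, each treatment arm adds a class-specific log2
effect (vehicle = baseline; combined = baseline + T3 effect + CORT
effect + a planted departure from additivity), and replicates add
i.i.d. Gaussian log2 noise before exponentiation to the signal scale.
This matches a ratio-based fold-change analysis and keeps signals
positive. Synergy classes state their departure in units of the
expected raw-scale SD margin (sqrt of the summed single-treatment
variances), the same quantity the synergy caller thresholds on.

Genomic fixtures place genes on disjoint slots wide enough that one
gene's peaks can never fall in another gene's search window, then
plant receptor and mark peaks at controlled edge-to-edge gaps: planted
proximal pairs sit at least 2 bp below the proximity threshold and
planted decoys at least 2 bp above it, so no coordinate convention can
flip a truth label.

Both generators are deterministic under their seed and emit the same
TSV/BED formats the pipeline consumes, plus truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import Design, ExpressionMatrix
from .mapping import MARK_GROUPS, validate_loci, validate_track

LN2 = float(np.log(2.0))

#: planted log2 effects per expression class: (T3, CORT, departure from
#: additivity). Synergy classes carry departure in SD-margin units.
DEFAULT_EFFECT_SIZES: dict[str, tuple[float, float, float]] = {
    "null": (0.0, 0.0, 0.0),
    "t3_only": (1.0, 0.0, -1.0),          # section a: combined response abolished
    "cort_only": (0.0, 1.0, -1.0),        # section b: T3 abolishes CORT response
    "combined_only": (0.0, 0.0, 1.5),     # section c, induced (criterion-1 synergy)
    "combined_only_repressed": (0.0, 0.0, -1.5),
    "cort_additive": (0.0, 1.2, 0.0),     # section e, E1
    "cort_enhanced": (0.0, 1.0, 1.0),     # section e, E3
    "cort_suppressed": (0.0, 1.5, -0.6),  # section e, E5
    "all_three": (1.0, 1.0, 0.0),         # section f
    # criterion-2 synergy: induced singles with a greater-than-additive
    # combined response (margin units); synergistic repression with
    # repressing singles cannot reach 6 margins below the additive
    # expectation without crossing zero signal, so the repressed class
    # uses sub-threshold singles (combined-only route), matching the
    # composition real data shows
    "synergy_induced": (0.7, 0.7, 6.0),
    "synergy_repressed": (0.0, 0.0, -6.0),
}

#: classes whose departure is counted in raw-scale SD margins
MARGIN_CLASSES: frozenset[str] = frozenset({"synergy_induced", "synergy_repressed"})

#: class fractions loosely echoing the study's CORT-rich, T3-poor Venn
DEFAULT_CLASS_FRACTIONS: dict[str, float] = {
    "t3_only": 0.0005,
    "cort_only": 0.02,
    "combined_only": 0.008,
    "combined_only_repressed": 0.008,
    "cort_additive": 0.025,
    "cort_enhanced": 0.002,
    "cort_suppressed": 0.002,
    "all_three": 0.0005,
    "synergy_induced": 0.002,
    "synergy_repressed": 0.002,
}


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Parameters of the planted expression simulation.

    Defaults mirror the study conditions: triplicate arms, log2
    replicate noise of 0.15 (typical bead-array technical + biological
    scatter on normalized signals), baselines centred at 2^7 = 128
    signal units with 1.5 log2 units of between-probe spread.
    """

    n_probes: int = 10_000
    n_reps: int = 3
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    replicate_noise_sd: float = 0.15
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    effect_sizes: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES)
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if self.replicate_noise_sd <= 0:
            raise ValueError("replicate noise sd must be positive")
        total = sum(self.class_fractions.values())
        if total > 1.0 + 1e-9:
            raise ValueError(f"class fractions sum to {total} > 1")
        unknown = set(self.class_fractions) - set(self.effect_sizes)
        if unknown:
            raise ValueError(f"classes without effect sizes: {sorted(unknown)}")


def _expected_raw_sd(log2_mean: np.ndarray, noise_sd: float) -> np.ndarray:
    """Delta-method SD of a log-normal signal with given log2 mean/sd."""
    return 2.0**log2_mean * LN2 * noise_sd


def simulate_expression(
    config: ExpressionSimConfig,
) -> tuple[ExpressionMatrix, Design, pd.DataFrame]:
    """Generate a planted expression matrix, its design, and truth labels.

    Truth labels carry the planted class, the planted log2 effects per
    arm, the expected Venn section, and whether the probe is planted as
    synergistic (and in which direction).
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_probes

    # assign classes by fixed counts (deterministic composition)
    labels = np.array(["null"] * n, dtype=object)
    cursor = 0
    for cls, frac in config.class_fractions.items():
        k = int(round(frac * n))
        labels[cursor : cursor + k] = cls
        cursor += k
    rng.shuffle(labels)

    eff = np.array(
        [config.effect_sizes[c] for c in labels], dtype=float
    )  # columns: t3, cort, departure
    t3_eff, cort_eff, departure = eff.T
    is_margin = np.isin(labels, list(MARGIN_CLASSES))

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
    mu_veh = baseline
    mu_t3 = baseline + t3_eff
    mu_cort = baseline + cort_eff
    mu_comb = baseline + t3_eff + cort_eff + np.where(is_margin, 0.0, departure)

    if is_margin.any():
        sd_t3 = _expected_raw_sd(mu_t3[is_margin], config.replicate_noise_sd)
        sd_cort = _expected_raw_sd(mu_cort[is_margin], config.replicate_noise_sd)
        margin = np.sqrt(sd_t3**2 + sd_cort**2)
        expectation = (
            2.0 ** mu_t3[is_margin]
            + 2.0 ** mu_cort[is_margin]
            - 2.0 ** mu_veh[is_margin]
        )
        target = expectation + departure[is_margin] * margin
        floor = 2.0 ** (baseline[is_margin] - 6.0)  # keep signals positive
        mu_comb[is_margin] = np.log2(np.maximum(target, floor))

    sample_ids: list[str] = []
    design_rows = []
    blocks = []
    for tr, mu in (
        ("VEH", mu_veh),
        ("T3", mu_t3),
        ("CORT", mu_cort),
        ("T3CORT", mu_comb),
    ):
        for rep in range(1, config.n_reps + 1):
            sid = f"{tr}_{rep}"
            sample_ids.append(sid)
            design_rows.append({"sample_id": sid, "treatment": tr, "replicate": rep})
            blocks.append(
                2.0 ** (mu + rng.normal(0.0, config.replicate_noise_sd, n))
            )
    probe_ids = [f"probe_{i:05d}" for i in range(n)]
    signals = pd.DataFrame(
        np.column_stack(blocks), index=pd.Index(probe_ids, name="probe_id"),
        columns=sample_ids,
    )
    matrix = ExpressionMatrix.floored(signals)
    design = Design.from_frame(pd.DataFrame(design_rows))

    planted_comb_total = mu_comb - baseline
    de_threshold = np.log2(1.5)
    de_t3 = np.abs(t3_eff) > de_threshold
    de_cort = np.abs(cort_eff) > de_threshold
    de_comb = np.abs(planted_comb_total) > de_threshold
    section = np.select(
        [
            de_t3 & ~de_cort & ~de_comb,
            ~de_t3 & de_cort & ~de_comb,
            ~de_t3 & ~de_cort & de_comb,
            de_t3 & ~de_cort & de_comb,
            ~de_t3 & de_cort & de_comb,
            de_t3 & de_cort & de_comb,
            de_t3 & de_cort & ~de_comb,
        ],
        ["a", "b", "c", "d", "e", "f", "g"],
        default="none",
    )
    # cort_enhanced counts: its +1 log2 departure puts the combined
    # mean many SD margins above the additive expectation
    synergy_flag = np.isin(
        labels,
        [
            "combined_only",
            "combined_only_repressed",
            "cort_enhanced",
            "synergy_induced",
            "synergy_repressed",
        ],
    )
    synergy_direction = np.select(
        [
            np.isin(labels, ["combined_only", "cort_enhanced", "synergy_induced"]),
            np.isin(labels, ["combined_only_repressed", "synergy_repressed"]),
        ],
        ["induced", "repressed"],
        default="none",
    )
    truth = pd.DataFrame(
        {
            "planted_class": labels,
            "planted_t3_log2": t3_eff,
            "planted_cort_log2": cort_eff,
            "planted_departure": departure,
            "planted_comb_log2": planted_comb_total,
            "expected_section": section,
            "synergy": synergy_flag,
            "synergy_direction": synergy_direction,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return matrix, design, truth


@dataclass(frozen=True)
class TrackSimConfig:
    """Parameters of the planted genomic-track simulation.

    ``planted_fractions`` maps each mark group to the fraction of genes
    planted as GR_only / TR_only / both; the remainder are planted as
    none (a receptor peak whose nearest mark is safely beyond the
    proximity threshold). ``margin_bp`` keeps every planted gap at
    least that far from the threshold on the correct side.
    """

    n_genes: int = 100
    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"chrS1": 60_000_000, "chrS2": 60_000_000}
    )
    gene_length_range: tuple[int, int] = (5_000, 40_000)
    peak_width_range: tuple[int, int] = (200, 600)
    planted_fractions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "H3K27Ac": {"GR_only": 0.21, "TR_only": 0.15, "both": 0.16},
            "MED": {"GR_only": 0.18, "TR_only": 0.17, "both": 0.12},
            "POL2": {"GR_only": 0.11, "TR_only": 0.08, "both": 0.09},
        }
    )
    flank_bp: int = 50_000
    proximity_bp: int = 1_000
    margin_bp: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.gene_length_range[0] >= self.gene_length_range[1]:
            raise ValueError("gene_length_range must be (low, high)")
        if self.peak_width_range[0] >= self.peak_width_range[1]:
            raise ValueError("peak_width_range must be (low, high)")
        for group, fracs in self.planted_fractions.items():
            bad = set(fracs) - {"GR_only", "TR_only", "both"}
            if bad:
                raise ValueError(f"unknown planted classes {sorted(bad)}")
            if sum(fracs.values()) > 1.0 + 1e-9:
                raise ValueError(f"planted fractions for {group} exceed 1")


def simulate_tracks(
    config: TrackSimConfig,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], pd.DataFrame]:
    """Generate gene loci, peak tracks, and per-gene truth classes.

    Genes occupy disjoint slots of width gene length + 2 x flank +
    guard so windows never overlap; each planted receptor peak sits
    inside its gene's window with its mark partner at a controlled gap.

    Returns (loci frame, {track name -> track frame}, truth frame
    indexed by gene symbol with one column per mark group).
    """
    rng = np.random.default_rng(config.rng_seed)
    glo, ghi = config.gene_length_range
    whi = config.peak_width_range[1]
    # widest footprint of one mark group's planted elements: two
    # receptors with proximal marks, or one decoy receptor with a
    # distal mark
    group_span = max(
        3 * whi + 2 * config.proximity_bp + 2 * config.margin_bp,
        2 * whi + config.proximity_bp + config.margin_bp + 2_000,
    )
    # anchors of different mark groups far enough apart that a receptor
    # planted for one group is never proximal to another group's marks
    group_spacing = group_span + config.proximity_bp + config.margin_bp + 100
    if config.flank_bp < group_spacing + group_span:
        raise ValueError(
            f"flank_bp must be >= {group_spacing + group_span} so planted "
            "receptor peaks stay inside the gene window"
        )
    guard = 2 * (config.proximity_bp + whi + 100)
    slot = ghi + 2 * config.flank_bp + guard

    capacity = sum(size // slot for size in config.chrom_sizes.values())
    if capacity < config.n_genes:
        raise ValueError(
            f"chromosomes fit only {capacity} gene slots of {slot} bp; "
            f"need {config.n_genes}"
        )

    slots: list[tuple[str, int]] = []
    for chrom, size in config.chrom_sizes.items():
        for k in range(size // slot):
            slots.append((chrom, k * slot))
    chosen = [slots[i] for i in rng.choice(len(slots), config.n_genes, replace=False)]

    loci_rows = []
    for i, (chrom, slot_start) in enumerate(chosen):
        length = int(rng.integers(glo, ghi))
        start = slot_start + config.flank_bp + guard // 2
        strand = "+" if rng.random() < 0.5 else "-"
        loci_rows.append(
            {
                "gene_symbol": f"gene_{i:04d}",
                "chrom": chrom,
                "start": start,
                "end": start + length,
                "strand": strand,
            }
        )
    loci = validate_loci(pd.DataFrame(loci_rows))

    # per mark group, assign classes by count then shuffle
    truth_cols: dict[str, np.ndarray] = {}
    for group in MARK_GROUPS:
        fracs = config.planted_fractions.get(group, {})
        classes = np.array(["none"] * config.n_genes, dtype=object)
        cursor = 0
        for cls in ("GR_only", "TR_only", "both"):
            k = int(round(fracs.get(cls, 0.0) * config.n_genes))
            classes[cursor : cursor + k] = cls
            cursor += k
        rng.shuffle(classes)
        truth_cols[group] = classes

    wlo, whi = config.peak_width_range
    tracks: dict[str, list[dict]] = {
        name: [] for name in ("GR", "TR", "H3K27Ac", "MED1", "MED12", "POL2")
    }

    def _peak(chrom: str, start: int) -> dict:
        width = int(rng.integers(wlo, whi))
        return {"chrom": chrom, "start": start, "end": start + width}

    def _mark_name(group: str) -> str:
        if group == "MED":
            return "MED1" if rng.random() < 0.5 else "MED12"
        return group

    for gi, row in loci.iterrows():
        chrom = row["chrom"]
        body_mid = int((row["start"] + row["end"]) // 2)
        # each mark group gets its own receptor anchor, spread out so
        # pairs planted for one group stay > proximity away from the
        # marks of other groups
        for gidx, group in enumerate(MARK_GROUPS):
            cls = truth_cols[group][gi]
            anchor = body_mid + (gidx - 1) * group_spacing
            receptors = {
                "GR_only": ["GR"],
                "TR_only": ["TR"],
                "both": ["GR", "TR"],
                "none": [],
            }[cls]
            offset = 0
            for rec in receptors:
                rec_peak = _peak(chrom, anchor + offset)
                tracks[rec].append(rec_peak)
                gap = int(
                    rng.integers(0, config.proximity_bp - config.margin_bp + 1)
                )
                tracks[_mark_name(group)].append(_peak(chrom, rec_peak["end"] + gap))
                offset += whi + config.proximity_bp + 2 * config.margin_bp
            if cls == "none":
                # decoy: receptor peak present but its nearest mark sits
                # beyond the threshold; keeps "none" non-trivial
                rec_peak = _peak(chrom, anchor)
                tracks["GR" if rng.random() < 0.5 else "TR"].append(rec_peak)
                gap = config.proximity_bp + config.margin_bp + int(
                    rng.integers(0, 2_000)
                )
                tracks[_mark_name(group)].append(_peak(chrom, rec_peak["end"] + gap))

    track_frames = {
        name: validate_track(pd.DataFrame(rows, columns=["chrom", "start", "end"]))
        if rows
        else pd.DataFrame(columns=["chrom", "start", "end"])
        for name, rows in tracks.items()
    }
    truth = pd.DataFrame(
        truth_cols, index=pd.Index(loci["gene_symbol"], name="gene_symbol")
    )
    return loci, track_frames, truth
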