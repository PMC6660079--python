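"""Receptor-peak / enhancer-mark proximity around regulated genes.

Each gene defines a search window: the gene body plus a flank (default
50 kb) on each side, clamped at the chromosome origin. A receptor
(GR or TR) ChIP peak counts for a gene when it overlaps the window at
least partially AND lies within a proximity threshold (default 1 kb,
edge to edge) of some enhancer-mark peak — H3K27Ac for open chromatin,
MED1/MED12 (merged) for Mediator looping, or RNA Pol2 for transcribed
enhancers; the mark peak itself need not fall inside the window. Per
mark group a gene is classed ``none``, ``GR_only``, ``TR_only`` or
``both``.

All coordinates are BED convention: 0-based, half-open. Book-ended
intervals have gap 0. Tracks are plain (chrom, start, end) frames;
the proximity search is a sorted sweep (binary search on starts plus a
running maximum of ends), which tests verify against a brute-force
all-pairs oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .thresholds import Thresholds

RECEPTORS: tuple[str, ...] = ("GR", "TR")
MARK_GROUPS: tuple[str, ...] = ("H3K27Ac", "MED", "POL2")
#: raw track names feeding each mark group
MARK_GROUP_TRACKS: dict[str, tuple[str, ...]] = {
    "H3K27Ac": ("H3K27Ac",),
    "MED": ("MED1", "MED12"),
    "POL2": ("POL2",),
}
COLOC_CLASSES: tuple[str, ...] = ("none", "GR_only", "TR_only", "both")

_TRACK_COLS = ["chrom", "start", "end"]
_LOCUS_COLS = ["gene_symbol", "chrom", "start", "end", "strand"]


def validate_track(track: pd.DataFrame) -> pd.DataFrame:
    """Sort a (chrom, start, end) frame and check interval invariants."""
    missing = set(_TRACK_COLS) - set(track.columns)
    if missing:
        raise ValueError(f"track lacks columns {sorted(missing)}")
    t = track[list(track.columns)].copy()
    t["start"] = t["start"].astype(np.int64)
    t["end"] = t["end"].astype(np.int64)
    if (t["start"] < 0).any():
        raise ValueError("negative interval start")
    if (t["start"] >= t["end"]).any():
        raise ValueError("intervals must satisfy start < end")
    return t.sort_values(["chrom", "start", "end"], kind="stable").reset_index(
        drop=True
    )


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3+ (extra columns ignored) into a sorted track frame."""
    t = pd.read_csv(
        path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
        names=_TRACK_COLS, dtype={"chrom": str},
    )
    return validate_track(t)


def write_bed(track: pd.DataFrame, path: str | Path) -> None:
    track[_TRACK_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_gene_loci(path: str | Path) -> pd.DataFrame:
    """Gene loci from BED6 (name = symbol) or a headered TSV.

    Returns a frame with gene_symbol, chrom, start, end, strand plus
    derived tss/tts columns (tss = start on +, end on -).
    """
    with open(path, "rt", encoding="utf-8") as fh:
        first = fh.readline()
    if "gene_symbol" in first:
        loci = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    else:
        loci = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "gene_symbol", "score", "strand"],
            dtype={"chrom": str},
        ).drop(columns="score")
    return validate_loci(loci)


def validate_loci(loci: pd.DataFrame) -> pd.DataFrame:
    missing = set(_LOCUS_COLS) - set(loci.columns)
    if missing:
        raise ValueError(f"gene loci lack columns {sorted(missing)}")
    out = loci[_LOCUS_COLS].copy()
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    if (out["start"] >= out["end"]).any():
        raise ValueError("gene intervals must satisfy start < end")
    if out["gene_symbol"].duplicated().any():
        raise ValueError("duplicate gene symbols in loci")
    bad = ~out["strand"].isin(["+", "-", "."])
    if bad.any():
        raise ValueError("strand must be one of + - .")
    minus = out["strand"] == "-"
    out["tss"] = np.where(minus, out["end"], out["start"])
    out["tts"] = np.where(minus, out["start"], out["end"])
    return out.reset_index(drop=True)


def write_gene_loci(loci: pd.DataFrame, path: str | Path) -> None:
    loci[_LOCUS_COLS].to_csv(path, sep="\t", index=False)


def gene_window(
    start: int, end: int, flank_bp: int
) -> tuple[int, int]:
    """Search window [max(0, start - flank), end + flank) around a gene body.

    Both ends get the same flank, so the window is strand-independent.
    """
    return max(0, int(start) - int(flank_bp)), int(end) + int(flank_bp)


def interval_gap(
    a: tuple[str, int, int], b: tuple[str, int, int]
) -> float:
    """Edge-to-edge gap between two half-open intervals.

    inf on different chromosomes; 0 when overlapping or book-ended;
    otherwise the distance between the nearest ends
    (gap([100,200), [1100,1300)) = 900).
    """
    chrom_a, start_a, end_a = a
    chrom_b, start_b, end_b = b
    if chrom_a != chrom_b:
        return math.inf
    return float(max(0, max(start_a, start_b) - min(end_a, end_b)))


class _MarkIndex:
    """Per-chromosome sorted index for minimum-gap queries.

    Holds starts sorted ascending alongside a running maximum of ends,
    so a query interval resolves overlap, nearest-left and
    nearest-right candidates with two binary searches.
    """

    def __init__(self, track: pd.DataFrame):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, grp in track.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy(np.int64)
            ends = grp["end"].to_numpy(np.int64)
            order = np.argsort(starts, kind="stable")
            starts = starts[order]
            ends_cummax = np.maximum.accumulate(ends[order])
            self._by_chrom[str(chrom)] = (starts, ends_cummax)

    def min_gap(self, chrom: str, start: int, end: int) -> float:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return math.inf
        starts, ends_cummax = entry
        best = math.inf
        # marks beginning at/after the query end: nearest is the first
        j = int(np.searchsorted(starts, end, side="left"))
        if j < len(starts):
            best = float(starts[j] - end)
        # marks beginning before the query end: overlap or left gap
        if j > 0:
            left_end = int(ends_cummax[j - 1])
            best = min(best, float(max(0, start - left_end)))
        return best

    def min_gaps(self, chrom: str, starts_q: np.ndarray, ends_q: np.ndarray) -> np.ndarray:
        entry = self._by_chrom.get(chrom)
        out = np.full(len(starts_q), math.inf)
        if entry is None or len(starts_q) == 0:
            return out
        starts, ends_cummax = entry
        j = np.searchsorted(starts, ends_q, side="left")
        has_right = j < len(starts)
        out[has_right] = starts[np.minimum(j, len(starts) - 1)][has_right] - ends_q[has_right]
        has_left = j > 0
        left_end = ends_cummax[np.maximum(j, 1) - 1]
        left_gap = np.maximum(0, starts_q - left_end).astype(float)
        out[has_left] = np.minimum(out[has_left], left_gap[has_left])
        return out


def _overlapping_peaks(
    track: pd.DataFrame, chrom: str, wstart: int, wend: int
) -> pd.DataFrame:
    sel = (track["chrom"] == chrom) & (track["start"] < wend) & (track["end"] > wstart)
    return track.loc[sel]


def classify_gene(
    locus: Mapping,
    receptor_tracks: Mapping[str, pd.DataFrame],
    mark_track: pd.DataFrame,
    thresholds: Thresholds,
    _mark_index: _MarkIndex | None = None,
) -> str:
    """Co-localization class of one gene for one enhancer mark.

    A receptor counts when at least one of its peaks overlaps the gene
    window and sits within ``proximity_bp`` of some mark peak
    (anywhere on the chromosome).
    """
    chrom = str(locus["chrom"])
    wstart, wend = gene_window(locus["start"], locus["end"], thresholds.flank_bp)
    idx = _mark_index if _mark_index is not None else _MarkIndex(mark_track)
    proximal: dict[str, bool] = {}
    for rec in RECEPTORS:
        track = receptor_tracks.get(rec)
        hit = False
        if track is not None and len(track):
            peaks = _overlapping_peaks(track, chrom, wstart, wend)
            if len(peaks):
                gaps = idx.min_gaps(
                    chrom,
                    peaks["start"].to_numpy(np.int64),
                    peaks["end"].to_numpy(np.int64),
                )
                hit = bool((gaps <= thresholds.proximity_bp).any())
        proximal[rec] = hit
    if proximal["GR"] and proximal["TR"]:
        return "both"
    if proximal["GR"]:
        return "GR_only"
    if proximal["TR"]:
        return "TR_only"
    return "none"


def merge_mark_groups(
    tracks: Mapping[str, pd.DataFrame]
) -> dict[str, pd.DataFrame]:
    """Collapse raw mark tracks into the three mark groups (MED1 u MED12)."""
    groups: dict[str, pd.DataFrame] = {}
    for group, members in MARK_GROUP_TRACKS.items():
        parts = [tracks[m] for m in members if m in tracks and len(tracks[m])]
        if parts:
            groups[group] = validate_track(pd.concat(parts, ignore_index=True))
        else:
            groups[group] = pd.DataFrame(columns=_TRACK_COLS)
    return groups


def classify_cohort(
    loci: pd.DataFrame,
    tracks: Mapping[str, pd.DataFrame],
    thresholds: Thresholds,
) -> pd.DataFrame:
    """Per-gene co-localization class for every mark group.

    ``tracks`` maps raw names (GR, TR, H3K27Ac, MED1, MED12, POL2) to
    track frames; missing tracks are treated as empty. Returns a frame
    indexed by gene symbol with one column per mark group.
    """
    receptor_tracks = {r: tracks.get(r, pd.DataFrame(columns=_TRACK_COLS)) for r in RECEPTORS}
    groups = merge_mark_groups(tracks)
    out = {}
    for group in MARK_GROUPS:
        idx = _MarkIndex(groups[group]) if len(groups[group]) else _MarkIndex(
            pd.DataFrame(columns=_TRACK_COLS)
        )
        col = [
            classify_gene(row, receptor_tracks, groups[group], thresholds, _mark_index=idx)
            for row in loci.to_dict("records")
        ]
        out[group] = col
    return pd.DataFrame(out, index=pd.Index(loci["gene_symbol"], name="gene_symbol"))


def summarize_fractions(classes: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Percentages of genes per co-localization class, per mark group.

    ``pct_any`` is the fraction with at least one proximal receptor
    peak (class != none); percentages are 100 x count / total, rounded
    to 2 decimal places as in standard reporting.
    """
    if classes.empty:
        raise ValueError("empty class table")
    total = len(classes)
    out: dict[str, dict[str, float]] = {}
    for group in classes.columns:
        col = classes[group]
        counts = {c: int((col == c).sum()) for c in COLOC_CLASSES}
        out[group] = {
            "n_genes": total,
            "n_any": total - counts["none"],
            "pct_any": round(100.0 * (total - counts["none"]) / total, 2),
            "pct_GR_only": round(100.0 * counts["GR_only"] / total, 2),
            "pct_TR_only": round(100.0 * counts["TR_only"] / total, 2),
            "pct_both": round(100.0 * counts["both"] / total, 2),
        }
    return out


def sample_control_genes(
    universe: pd.DataFrame,
    exclude: Iterable[str],
    n: int,
    rng_seed: int,
) -> pd.DataFrame:
    """Uniform, seed-reproducible sample of non-regulated genes.

    Draws ``n`` loci without replacement from ``universe`` minus the
    excluded symbols. The candidate list is sorted by symbol before
    sampling, so the draw depends only on the seed and the candidate
    set, not on input row order.
    """
    excluded = set(exclude)
    pool = universe[~universe["gene_symbol"].isin(excluded)]
    pool = pool.sort_values("gene_symbol", kind="stable").reset_index(drop=True)
    if len(pool) < n:
        raise ValueError(
            f"universe has only {len(pool)} non-excluded genes; need {n}"
        )
    rng = np.random.default_rng(rng_seed)
    take = rng.choice(len(pool), size=n, replace=False)
    return pool.iloc[np.sort(take)].reset_index(drop=True)
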