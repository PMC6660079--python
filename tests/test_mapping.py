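import math

import numpy as np
import pandas as pd
import pytest

from hormsynergy import Thresholds
from hormsynergy.mapping import (
    classify_cohort,
    classify_gene,
    gene_window,
    interval_gap,
    read_bed,
    read_gene_loci,
    sample_control_genes,
    summarize_fractions,
    validate_loci,
    validate_track,
    write_bed,
    write_gene_loci,
)
from hormsynergy.simulate import TrackSimConfig, simulate_tracks


def brute_force_class(locus, receptor_tracks, mark_track, thresholds) -> str:
    """All-pairs oracle for classify_gene (no sorting, no indexing)."""
    wstart, wend = gene_window(locus["start"], locus["end"], thresholds.flank_bp)
    proximal = {}
    for rec in ("GR", "TR"):
        track = receptor_tracks.get(rec)
        hit = False
        if track is not None:
            for _, peak in track.iterrows():
                if peak["chrom"] != locus["chrom"]:
                    continue
                if not (peak["start"] < wend and peak["end"] > wstart):
                    continue
                for _, mark in mark_track.iterrows():
                    gap = interval_gap(
                        (peak["chrom"], peak["start"], peak["end"]),
                        (mark["chrom"], mark["start"], mark["end"]),
                    )
                    if gap <= thresholds.proximity_bp:
                        hit = True
                        break
                if hit:
                    break
        proximal[rec] = hit
    if proximal["GR"] and proximal["TR"]:
        return "both"
    if proximal["GR"]:
        return "GR_only"
    if proximal["TR"]:
        return "TR_only"
    return "none"


class TestGeneWindow:
    def test_plain_arithmetic(self):
        assert gene_window(100_000, 120_000, 50_000) == (50_000, 170_000)

    def test_clamped_at_origin(self):
        assert gene_window(10_000, 20_000, 50_000) == (0, 70_000)

    def test_zero_flank_identity(self):
        assert gene_window(500, 900, 0) == (500, 900)


class TestIntervalGap:
    def test_overlap_is_zero(self):
        assert interval_gap(("chr1", 100, 200), ("chr1", 150, 250)) == 0

    def test_disjoint_gap(self):
        assert interval_gap(("chr1", 100, 200), ("chr1", 1100, 1300)) == 900

    def test_book_ended_is_zero(self):
        assert interval_gap(("chr1", 100, 200), ("chr1", 200, 300)) == 0

    def test_cross_chromosome_infinite(self):
        assert interval_gap(("chr1", 100, 200), ("chr2", 100, 200)) == math.inf

    def test_symmetry_and_per_base_distance(self):
        """Gap equals the brute-force distance between closest occupied
        bases minus one (half-open convention), and is symmetric."""
        rng = np.random.default_rng(3)
        for _ in range(200):
            s1, s2 = rng.integers(0, 500, 2)
            a = ("c", int(s1), int(s1 + rng.integers(1, 50)))
            b = ("c", int(s2), int(s2 + rng.integers(1, 50)))
            gap = interval_gap(a, b)
            assert gap == interval_gap(b, a)
            bases_a = set(range(a[1], a[2]))
            bases_b = set(range(b[1], b[2]))
            min_dist = min(abs(x - y) for x in bases_a for y in bases_b)
            assert gap == max(0, min_dist - 1) if min_dist else gap == 0


def random_fixture(rng, n_genes=4, n_peaks=40):
    chroms = ["cA", "cB"]
    loci = validate_loci(
        pd.DataFrame(
            {
                "gene_symbol": [f"g{i}" for i in range(n_genes)],
                "chrom": rng.choice(chroms, n_genes),
                "start": (starts := rng.integers(0, 400_000, n_genes)),
                "end": starts + rng.integers(1_000, 60_000, n_genes),
                "strand": rng.choice(["+", "-"], n_genes),
            }
        )
    )

    def track(n):
        s = rng.integers(0, 500_000, n)
        return validate_track(
            pd.DataFrame(
                {
                    "chrom": rng.choice(chroms, n),
                    "start": s,
                    "end": s + rng.integers(50, 2_000, n),
                }
            )
        )

    return loci, {"GR": track(n_peaks), "TR": track(n_peaks)}, track(n_peaks)


class TestClassifyGene:
    def test_empty_receptor_tracks(self, thresholds):
        locus = {"chrom": "c1", "start": 1000, "end": 5000}
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        mark = validate_track(
            pd.DataFrame({"chrom": ["c1"], "start": [2000], "end": [2500]})
        )
        assert classify_gene(locus, {"GR": empty, "TR": empty}, mark, thresholds) == "none"

    def test_gr_only_at_900_bp(self, thresholds):
        locus = {"chrom": "c1", "start": 100_000, "end": 130_000}
        gr = validate_track(
            pd.DataFrame({"chrom": ["c1"], "start": [110_000], "end": [110_500]})
        )
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        mark = validate_track(
            pd.DataFrame({"chrom": ["c1"], "start": [111_400], "end": [111_800]})
        )
        cls = classify_gene(locus, {"GR": gr, "TR": empty}, mark, thresholds)
        assert cls == "GR_only"

    def test_both_when_each_receptor_proximal(self, thresholds):
        locus = {"chrom": "c1", "start": 100_000, "end": 130_000}
        gr = validate_track(
            pd.DataFrame({"chrom": ["c1"], "start": [110_000], "end": [110_500]})
        )
        tr = validate_track(
            pd.DataFrame({"chrom": ["c1"], "start": [120_000], "end": [120_300]})
        )
        mark = validate_track(
            pd.DataFrame(
                {"chrom": ["c1", "c1"], "start": [111_000, 120_900], "end": [111_300, 121_100]}
            )
        )
        receptor_tracks = {"GR": gr, "TR": tr}
        cls = classify_gene(locus, receptor_tracks, mark, thresholds)
        assert cls == "both"
        assert cls == brute_force_class(locus, receptor_tracks, mark, thresholds)

    def test_receptor_outside_window_ignored(self, thresholds):
        locus = {"chrom": "c1", "start": 300_000, "end": 310_000}
        gr = validate_track(
            pd.DataFrame({"chrom": ["c1"], "start": [100_000], "end": [100_400]})
        )
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        mark = validate_track(
            pd.DataFrame({"chrom": ["c1"], "start": [100_500], "end": [100_900]})
        )
        assert classify_gene(locus, {"GR": gr, "TR": empty}, mark, thresholds) == "none"

    def test_sweep_equals_brute_force_on_random_fixtures(self, thresholds):
        """Indexed proximity join matches the all-pairs oracle exactly."""
        rng = np.random.default_rng(11)
        for _ in range(40):
            loci, receptors, mark = random_fixture(rng)
            for locus in loci.to_dict("records"):
                assert classify_gene(
                    locus, receptors, mark, thresholds
                ) == brute_force_class(locus, receptors, mark, thresholds)

    def test_monotone_in_proximity_and_flank(self):
        """Growing proximity_bp or flank_bp never demotes a gene's class."""
        rank = {"none": 0, "GR_only": 1, "TR_only": 1, "both": 2}
        rng = np.random.default_rng(23)
        loci, receptors, mark = random_fixture(rng, n_genes=6, n_peaks=60)
        for small, big in [
            (Thresholds(proximity_bp=500), Thresholds(proximity_bp=5_000)),
            (Thresholds(flank_bp=5_000), Thresholds(flank_bp=80_000)),
        ]:
            for locus in loci.to_dict("records"):
                lo = classify_gene(locus, receptors, mark, small)
                hi = classify_gene(locus, receptors, mark, big)
                assert rank[hi] >= rank[lo]


class TestSummarizeFractions:
    def test_reported_percentage_arithmetic(self):
        """57 proximal genes out of 110 report as 51.82%."""
        classes = pd.DataFrame(
            {"H3K27Ac": ["GR_only"] * 23 + ["TR_only"] * 16 + ["both"] * 18 + ["none"] * 53}
        )
        out = summarize_fractions(classes)["H3K27Ac"]
        assert out["n_any"] == 57
        assert out["pct_any"] == pytest.approx(51.82)
        assert out["pct_GR_only"] == pytest.approx(20.91, abs=0.01)

    def test_zero_and_empty(self):
        out = summarize_fractions(pd.DataFrame({"MED": ["none"] * 40}))
        assert out["MED"]["pct_any"] == 0.0
        with pytest.raises(ValueError):
            summarize_fractions(pd.DataFrame(columns=["MED"]))

    def test_planted_cohort_fraction_recovered(self, sim_tracks, thresholds):
        loci, tracks, truth = sim_tracks
        classes = classify_cohort(loci, tracks, thresholds)
        for group in classes.columns:
            planted = float((truth[group] != "none").mean() * 100)
            assert summarize_fractions(classes)[group]["pct_any"] == pytest.approx(
                planted
            )


class TestSampleControlGenes:
    def _universe(self):
        return validate_loci(
            pd.DataFrame(
                {
                    "gene_symbol": [f"g{i}" for i in range(60)],
                    "chrom": "c1",
                    "start": np.arange(60) * 10_000,
                    "end": np.arange(60) * 10_000 + 5_000,
                    "strand": "+",
                }
            )
        )

    def test_seeded_reproducibility(self):
        u = self._universe()
        a = sample_control_genes(u, set(), 20, rng_seed=9)
        b = sample_control_genes(u, set(), 20, rng_seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_excluded_genes_never_sampled(self):
        u = self._universe()
        exclude = {f"g{i}" for i in range(0, 60, 2)}
        out = sample_control_genes(u, exclude, 25, rng_seed=1)
        assert not (set(out["gene_symbol"]) & exclude)

    def test_exhaustive_complement(self):
        u = self._universe()
        exclude = {f"g{i}" for i in range(50)}
        out = sample_control_genes(u, exclude, 10, rng_seed=4)
        assert set(out["gene_symbol"]) == {f"g{i}" for i in range(50, 60)}

    def test_insufficient_universe_rejected(self):
        with pytest.raises(ValueError, match="need"):
            sample_control_genes(self._universe(), set(), 100, rng_seed=0)


def test_bed_and_loci_round_trip(tmp_path, sim_tracks):
    loci, tracks, _ = sim_tracks
    write_bed(tracks["GR"], tmp_path / "gr.bed")
    back = read_bed(tmp_path / "gr.bed")
    pd.testing.assert_frame_equal(back, tracks["GR"][["chrom", "start", "end"]])
    write_gene_loci(loci, tmp_path / "loci.tsv")
    back_loci = read_gene_loci(tmp_path / "loci.tsv")
    pd.testing.assert_frame_equal(back_loci, loci)
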