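"""Bin construction, fork inference and strand labels."""

import numpy as np
import pandas as pd
import pytest

from apomut import binning, refio
from apomut.binning import (
    LEFTWARD,
    RIGHTWARD,
    GenomeAnnotation,
    infer_fork_map,
    make_expr_bins,
    make_rt_bins,
    replicative_class,
)

from conftest import random_genome


def _unit_tcn_genome(n_segments, seg_len=10):
    """One TCN per segment: repeats of 'TCAAAAAAAA' (no G, so no minus-strand TCN)."""
    seq = "TCA" + "A" * (seg_len - 3)
    g = refio.GenomeContext({"chr1": seq * n_segments})
    starts = np.arange(n_segments) * seg_len
    return g, starts


class TestRtBins:
    def test_exact_divisibility(self):
        g, starts = _unit_tcn_genome(700)
        profile = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 10,
                                "value": np.arange(700, 0, -1, dtype=float)})
        scheme = make_rt_bins(profile, g)
        assert scheme.n_motif_per_bin.tolist() == [100] * 7
        # bin 1 holds the earliest (highest-value) segments
        assert (scheme.segments.sort_values("value", ascending=False)["bin"].iloc[:100] == 1).all()

    def test_one_segment_per_bin(self):
        g, starts = _unit_tcn_genome(7, seg_len=50)
        # pad each segment to 5 TCN motifs
        seq = ("TCA" * 5 + "A" * 35)
        g = refio.GenomeContext({"chr1": seq * 7})
        profile = pd.DataFrame({"chrom": "chr1", "start": np.arange(7) * 50,
                                "end": np.arange(1, 8) * 50, "value": np.arange(7, 0, -1, dtype=float)})
        scheme = make_rt_bins(profile, g)
        assert sorted(scheme.segments["bin"]) == [1, 2, 3, 4, 5, 6, 7]

    def test_greedy_balance_property(self):
        """Per-bin TCN spread never exceeds the largest single-segment count."""
        rng = np.random.default_rng(41)
        g = random_genome(rng, 200_000)
        starts = np.arange(0, 200_000, 1000)
        profile = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 1000,
                                "value": rng.normal(size=len(starts))})
        scheme = make_rt_bins(profile, g)
        seg_tcn = scheme.segments["n_tcn"].to_numpy()
        per_bin = scheme.n_motif_per_bin
        assert per_bin.sum() == seg_tcn.sum()
        assert per_bin.max() - per_bin.min() <= seg_tcn.max()

    def test_constant_signal_rejected(self):
        g, starts = _unit_tcn_genome(10)
        profile = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 10, "value": 1.0})
        with pytest.raises(ValueError, match="degenerate"):
            make_rt_bins(profile, g)


class TestExprBins:
    def test_monotone_assignment(self):
        expr = pd.Series([1.0, 2, 3, 4, 5, 6, 7])
        scheme = make_expr_bins(expr)
        assert scheme.gene_bins.tolist() == [1, 2, 3, 4, 5, 6, 7]

    def test_zeros_floored_to_bin_one(self):
        expr = pd.Series([0.0, 0.0, 1, 2, 3, 4, 5, 6, 7])
        scheme = make_expr_bins(expr)
        assert (scheme.gene_bins.iloc[:2] == 1).all()

    def test_all_equal_degenerate(self):
        scheme = make_expr_bins(pd.Series([2.0] * 10))
        assert scheme.degenerate

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            make_expr_bins(pd.Series([0.0] * 10))

    def test_quantile_occupancy(self):
        rng = np.random.default_rng(43)
        expr = pd.Series(rng.lognormal(0, 1, size=7000))
        scheme = make_expr_bins(expr)
        counts = scheme.gene_bins.value_counts()
        assert counts.min() >= 998 and counts.max() <= 1002


class TestForkMap:
    def _profile(self, values):
        starts = np.arange(len(values)) * 1000
        return pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 1000,
                             "value": values})

    def test_linear_decreasing_all_rightward(self):
        fm = infer_fork_map(self._profile(np.linspace(100, 0, 50)), window_bp=10_000)
        assert (fm["direction"] == RIGHTWARD).all()

    def test_mirror_all_leftward(self):
        fm = infer_fork_map(self._profile(np.linspace(0, 100, 50)), window_bp=10_000)
        assert (fm["direction"] == LEFTWARD).all()

    def test_triangular_wave_alternates(self):
        x = np.arange(100)
        values = np.abs((x % 40) - 20).astype(float)  # peaks at 0 (mod 40), valleys at 20
        fm = infer_fork_map(self._profile(values), window_bp=6_000)
        d = fm["direction"].to_numpy()
        assert (d[5:15] == RIGHTWARD).all()     # falling flank: early on the left
        assert (d[25:35] == LEFTWARD).all()     # rising flank
        # extrema are low-derivative: undetermined under the default threshold
        assert d[20] == 0 or d[60] == 0 or d[40] == 0

    def test_strand_convention(self):
        assert replicative_class(np.array([True]), np.array([RIGHTWARD]))[0] == 1   # lagging
        assert replicative_class(np.array([True]), np.array([LEFTWARD]))[0] == -1   # leading
        assert replicative_class(np.array([False]), np.array([RIGHTWARD]))[0] == -1
        assert replicative_class(np.array([False]), np.array([0]))[0] == 0


class TestTranscriptionLabels:
    @pytest.fixture()
    def ann(self):
        g = refio.GenomeContext({"chr1": "TCA" * 200})  # 600 bp
        profile = pd.DataFrame({"chrom": "chr1", "start": [0, 200, 400],
                                "end": [200, 400, 600], "value": [3.0, 2.0, 1.0]})
        rt = binning.make_rt_bins(profile, g, n_bins=3)
        genes = pd.DataFrame({
            "gene_id": ["gp", "gm", "ga", "gb"],
            "chrom": "chr1",
            "start": [10, 110, 300, 320],
            "end": [60, 160, 350, 370],
            "strand": ["+", "-", "+", "-"],
        })
        return GenomeAnnotation(g, rt, None, genes)

    def _label(self, ann, pos, ref="C", alt="T"):
        df = pd.DataFrame({"sample": ["s"], "chrom": ["chr1"], "pos": [pos],
                           "ref": [ref], "alt": [alt]})
        df, _ = refio.annotate_mutations(df, ann.genome)
        from apomut import signature
        return binning.label_mutations(signature.classify_catalog(df), ann).iloc[0]

    def test_c_in_plus_gene_is_sense(self, ann):
        assert self._label(ann, 31)["tx_class"] == "sense"

    def test_c_in_minus_gene_is_antisense(self, ann):
        assert self._label(ann, 130)["tx_class"] == "antisense"

    def test_outside_genes_intergenic(self, ann):
        assert self._label(ann, 499)["tx_class"] == "intergenic"

    def test_overlapping_genes_ambiguous(self, ann):
        assert self._label(ann, 331)["tx_class"] == "ambiguous"


class TestExpressionFilter:
    def test_boundary_600(self):
        labeled = pd.DataFrame({
            "sample": ["a"] * 599 + ["b"] * 600,
            "gene_idx": [0] * 599 + [0] * 600,
        })
        kept = binning.filter_expression_samples(labeled)
        assert kept == ["b"]

    def test_sample_without_genic_mutations_excluded(self):
        labeled = pd.DataFrame({"sample": ["a"] * 10, "gene_idx": [-1] * 10})
        assert binning.filter_expression_samples(labeled) == []
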