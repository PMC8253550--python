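"""Strand ratios, the curvature shuffle test, and group comparisons."""

import numpy as np
import pandas as pd
import pytest

from apomut import asymmetry, binning
from apomut.asymmetry import (
    curvature_shuffle_test,
    gene_codirection,
    group_ratio_comparison,
    mean_ratio,
    quadratic_coefficient,
    replication_strand_profile,
)
from apomut.synthetic_data import SimulationConfig, generate_reference, simulate_catalog
from apomut.pipeline import RunConfig, build_annotation, prepare_catalog


def _profile_from_counts(lag, lead, m_lag, m_lead):
    df = pd.DataFrame({
        "bin": np.arange(1, len(lag) + 1),
        "n_lagging": lag, "n_leading": lead,
        "m_lagging": m_lag, "m_leading": m_lead,
    })
    df["ratio"] = (df["n_lagging"] / df["m_lagging"]) / (df["n_leading"] / df["m_leading"])
    return df


class TestRatios:
    def test_arithmetic(self):
        df = _profile_from_counts([30], [20], [1000], [1000])
        assert df["ratio"].iloc[0] == pytest.approx(1.5)

    def test_label_swap_inverts(self):
        df = _profile_from_counts([30, 10], [20, 20], [1000, 500], [1000, 500])
        swapped = _profile_from_counts([20, 20], [30, 10], [1000, 500], [1000, 500])
        assert np.allclose(swapped["ratio"], 1 / df["ratio"])

    def test_flat_bias_round_trip(self):
        """A uniform 1.5x lagging bias is recovered by the estimator."""
        cfg = SimulationConfig(seed=29, genome_length=2_000_000, n_genes=100,
                               n_samples=1, n_mutations=20_000, n_clusters=0,
                               rt_gradient=0.0, background_rt_gradient=0.0,
                               sense_bias_amplitude=0.0,
                               lagging_bias_amplitude=0.5, lagging_bias_width=100.0)
        ref = generate_reference(cfg)
        catalog, _ = simulate_catalog(cfg, ref)
        catalog = prepare_catalog(catalog, ref.genome)
        ann = build_annotation(ref.genome, ref.profile, ref.genes, RunConfig())
        labeled = binning.label_mutations(catalog, ann)
        prof = replication_strand_profile(labeled, ann, "apobec")
        assert 1.35 < mean_ratio(prof) < 1.65

    def test_strand_balance_converges_to_one(self):
        """With no bias the mean ratio sits within 3 binomial SE of 1."""
        rng = np.random.default_rng(53)
        m = np.full(7, 10_000)
        n = np.full(7, 14_000)  # ~1e5 mutations total
        lag = rng.binomial(n, 0.5)
        df = _profile_from_counts(lag, n - lag, m, m)
        se = 2 / np.sqrt(n.sum())  # SE of log-ratio, roughly
        assert abs(np.log(mean_ratio(df))) < 3 * se * np.sqrt(7)


class TestCurvature:
    def test_concave_profile_negative_coefficient(self):
        assert quadratic_coefficient(np.array([1.0, 1.3, 1.5, 1.3, 1.1, 1.0, 0.9])) < 0

    def test_log_inversion_negates_log_curvature(self):
        ratios = np.array([1.0, 1.3, 1.5, 1.3, 1.1, 1.0, 0.9])
        a = quadratic_coefficient(np.log(ratios))
        b = quadratic_coefficient(np.log(1 / ratios))
        assert a == pytest.approx(-b, rel=1e-10)

    def test_detects_injected_concavity(self):
        shape = 1 + 0.5 * np.exp(-((np.arange(1, 8) - 3) ** 2) / 4)
        n = np.full(7, 3000)
        rng = np.random.default_rng(59)
        p = shape / (shape + 1)
        lag = rng.binomial(n, p)
        prof = _profile_from_counts(lag, n - lag, np.full(7, 50_000), np.full(7, 50_000))
        res = curvature_shuffle_test(prof, n_shuffles=2000, seed=1)
        assert res.observed < 0
        assert res.p_gaussian < 1e-3
        assert 0 < res.p_empirical <= 1

    def test_null_is_unremarkable(self):
        rng = np.random.default_rng(61)
        n = np.full(7, 3000)
        lag = rng.binomial(n, 0.5)
        prof = _profile_from_counts(lag, n - lag, np.full(7, 50_000), np.full(7, 50_000))
        res = curvature_shuffle_test(prof, n_shuffles=2000, seed=2)
        assert res.p_empirical > 0.001

    def test_zero_exposure_rejected(self):
        prof = _profile_from_counts([5] * 7, [5] * 7, [0] * 7, [100] * 7)
        with pytest.raises(ValueError):
            curvature_shuffle_test(prof, n_shuffles=10, seed=0)


class TestGroupComparison:
    def test_identical_groups_not_significant(self):
        r = [1.1, 1.2, 1.3, 1.4]
        out = group_ratio_comparison(r, r)
        assert out["p"] > 0.99

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(67)
        a = 1.35 + 0.05 * rng.normal(size=30)
        b = 1.00 + 0.05 * rng.normal(size=30)
        out = group_ratio_comparison(a, b)
        assert out["p"] < 0.01 and out["mean_a"] > out["mean_b"]

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            group_ratio_comparison([1.0], [1.0, 1.1])


class TestCodirection:
    def test_gene_direction_definition(self, small_annotation):
        codir = gene_codirection(small_annotation)
        genes = small_annotation.genes
        for i in np.flatnonzero(codir != 0)[:20]:
            mid = (genes.loc[i, "start"] + genes.loc[i, "end"]) // 2
            fork = small_annotation.fork[genes.loc[i, "chrom"]][mid]
            expect = 1 if ((genes.loc[i, "strand"] == "+") == (fork == binning.RIGHTWARD)) else -1
            assert codir[i] == expect

    def test_no_effect_is_nonsignificant(self, small_labeled, small_annotation, small_ref):
        schemes = {s: binning.make_expr_bins(small_ref.expression[s])
                   for s in small_labeled["sample"].unique()}
        table, p = asymmetry.codirection_contrast(small_labeled, small_annotation, schemes)
        assert len(table) >= 3
        assert p > 0.01  # generator injects no co-direction effect
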