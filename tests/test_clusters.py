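"""Cluster detection, the negative-binomial p-value and its Monte-Carlo oracle."""

import numpy as np
import pandas as pd
import pytest

from apomut.clusters import (
    cluster_grid,
    cluster_pvalue,
    cluster_pvalue_mc,
    detect_clusters,
)
from apomut import binning
from apomut.pipeline import RunConfig, build_annotation, prepare_catalog
from apomut.synthetic_data import SimulationConfig, generate_reference, simulate_catalog


def _frame(positions, apobec=None, sample="s1", chrom="chr1"):
    n = len(positions)
    if apobec is None:
        apobec = [True] * n
    return pd.DataFrame({
        "sample": sample, "chrom": chrom, "pos": positions,
        "is_apobec": apobec, "context_ok": [True] * n,
    })


class TestDetect:
    def test_gap_rule_splits_runs(self):
        df = _frame([100, 5000, 30000])
        out = detect_clusters(df, n_total=3, genome_size=10**9, p_cutoff=1.0)
        assert len(out) == 1
        assert out.loc[0, "k"] == 2 and out.loc[0, "span"] == 4900

    def test_chained_gaps_form_one_candidate(self):
        df = _frame([1, 9000, 18000])
        out = detect_clusters(df, n_total=3, genome_size=10**9, p_cutoff=1.0)
        assert len(out) == 1 and out.loc[0, "k"] == 3

    def test_empty_sample(self):
        out = detect_clusters(_frame([]), n_total=1, genome_size=10**6, p_cutoff=1.0)
        assert len(out) == 0

    def test_p_cutoff_filters(self):
        # span 10 kb at pi=1e-5 has p ~ 0.095, far above the cutoff
        df = _frame([100, 10100])
        out = detect_clusters(df, n_total=30_000, genome_size=3 * 10**9, p_cutoff=1e-4)
        assert len(out) == 0

    @pytest.mark.parametrize(
        "apobec,expected",
        [([True, True, True], "APOBEC"),
         ([False, False, False], "NON_APOBEC"),
         ([True, True, False], "MIXED")],
    )
    def test_strict_classification(self, apobec, expected):
        df = _frame([100, 150, 200], apobec=apobec)
        out = detect_clusters(df, n_total=3, genome_size=10**9, p_cutoff=1.0)
        assert out.loc[0, "klass"] == expected


class TestPvalue:
    def test_adjacent_pair_closed_form(self):
        # two mutations on adjacent bases: p equals the per-base hit rate
        assert cluster_pvalue(2, 1, 30, 3_000_000) == pytest.approx(1e-5, rel=1e-9)

    def test_ten_kb_pair_value(self):
        # 1 - (1-pi)^10000 at pi = 1e-5
        p = cluster_pvalue(2, 10_000, 30_000, 3 * 10**9)
        assert p == pytest.approx(1 - (1 - 1e-5) ** 10_000, rel=1e-9)
        assert 0.09 < p < 0.10

    def test_monotone_in_span_and_k(self):
        ps = [cluster_pvalue(2, s, 100, 10**6) for s in (10, 100, 1000, 10_000)]
        assert ps == sorted(ps)
        pk = [cluster_pvalue(k, 2000, 100, 10**6) for k in (2, 3, 4, 5)]
        assert pk == sorted(pk, reverse=True)

    def test_denser_than_genome_rejected(self):
        with pytest.raises(ValueError):
            cluster_pvalue(2, 10, 100, 50)

    @pytest.mark.parametrize("k,span", [(2, 1000), (3, 3000)])
    def test_monte_carlo_oracle_quick(self, k, span):
        p = cluster_pvalue(k, span, 100, 10**6)
        est, se = cluster_pvalue_mc(k, span, 100, 10**6, n_reps=40_000, seed=5)
        assert abs(est - p) < 3 * se


@pytest.fixture(scope="module")
def sparse():
    # sparse catalog: mean gap >> 10 kb, so the 10 kb / 1e-4 constants behave
    cfg = SimulationConfig(seed=71, genome_length=8_000_000, n_genes=600,
                           n_samples=2, n_mutations=250, n_clusters=8,
                           apobec_fraction_range=(0.5, 0.6))
    ref = generate_reference(cfg)
    catalog, _ = simulate_catalog(cfg, ref)
    catalog = prepare_catalog(catalog, ref.genome)
    ann = build_annotation(ref.genome, ref.profile, ref.genes, RunConfig())
    return cfg, ref, ann, binning.label_mutations(catalog, ann)


class TestRoundTrip:

    def test_injected_clusters_recovered_and_audited(self, sparse):
        cfg, ref, ann, labeled = sparse
        found_any = False
        for sid, sub in labeled.groupby("sample"):
            sub = sub.reset_index(drop=True)
            out = detect_clusters(sub, n_total=len(sub), genome_size=ref.genome.total_length)
            if len(out):
                found_any = True
            pos_by_chrom = {c: s["pos"].to_numpy() for c, s in sub.groupby("chrom")}
            for _, cl in out.iterrows():
                members = pos_by_chrom[cl["chrom"]]
                members = members[(members >= cl["start"]) & (members < cl["end"])]
                assert len(members) == cl["k"]
                assert (np.diff(np.sort(members)) <= 10_000).all()
                assert cl["p"] <= 1e-4
        assert found_any

    def test_grid_counts_conserved(self, sparse):
        cfg, ref, ann, labeled = sparse
        sid = labeled["sample"].iloc[0]
        sub = labeled[labeled["sample"] == sid].reset_index(drop=True)
        out = detect_clusters(sub, n_total=len(sub), genome_size=ref.genome.total_length)
        scheme = binning.make_expr_bins(ref.expression[sid])
        grid = cluster_grid(out, ann, scheme)
        assert grid["count"].sum() == len(out)
        assert (grid["bp"] >= 0).all()

    def test_no_clusters_zero_grid(self, sparse):
        cfg, ref, ann, _ = sparse
        sid = ref.expression.columns[0]
        scheme = binning.make_expr_bins(ref.expression[sid])
        empty = pd.DataFrame(columns=["sample", "chrom", "start", "end", "k", "span", "p", "klass"])
        grid = cluster_grid(empty, ann, scheme)
        assert grid["count"].sum() == 0
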