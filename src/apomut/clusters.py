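"""Kataegis-like mutation cluster detection and classification.

A candidate cluster is a maximal run of >= 2 same-chromosome mutations with
neighbor gaps <= 10 kb.  Its p-value is the probability, under uniform random
placement of the sample's n mutations over the covered genome, that k
mutations span <= d bases: the k-1 inter-mutation distances are geometric
with per-base hit probability pi = n / G, so their sum follows a negative
binomial and p = P(NB(k-1, pi) <= d - (k-1)).  Candidates with p <= 1e-4 are
clusters.  A cluster is APOBEC only if every member carries the APOBEC
signature, non-APOBEC only if none does; mixed clusters are excluded from
both tallies.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .binning import BinScheme, GenomeAnnotation

log = logging.getLogger(__name__)


def cluster_pvalue(k: int, span: int, n_total: int, genome_size: int) -> float:
    """Random-placement p-value of k mutations spanning ``span`` bases.

    ``span`` is pos_last - pos_first; two adjacent bases have span 1 and
    p = pi exactly.
    """
    if k < 2 or span < 0 or n_total < k:
        raise ValueError("need k >= 2, span >= 0, n_total >= k")
    pi = n_total / genome_size
    if pi >= 1:
        raise ValueError("catalog denser than genome")
    if span < k - 1:
        return 0.0  # k distinct ordered positions cannot span fewer than k-1 bases
    return float(stats.nbinom.cdf(span - (k - 1), k - 1, pi))


def cluster_pvalue_mc(k: int, span: int, n_total: int, genome_size: int,
                      n_reps: int = 100_000, seed: int | None = None,
                      batch: int = 200_000):
    """Monte-Carlo oracle for ``cluster_pvalue``.

    Places ``n_total`` uniform integer positions on [0, G) per replicate and
    measures how often k consecutive order statistics span <= ``span``.
    Returns (estimate, standard_error).
    """
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    per = max(1, batch // n_total)
    while done < n_reps:
        m = min(per, n_reps - done)
        x = rng.integers(0, genome_size, size=(m, n_total))
        x.sort(axis=1)
        hits += int(np.sum(x[:, k - 1] - x[:, 0] <= span))
        done += m
    p = hits / n_reps
    se = float(np.sqrt(max(p * (1 - p), 1.0 / n_reps) / n_reps))
    return p, se


def detect_clusters(sample_df: pd.DataFrame, n_total: int, genome_size: int,
                    max_gap: int = 10_000, p_cutoff: float = 1e-4) -> pd.DataFrame:
    """Cluster table for one sample's catalog (candidates with p <= cutoff).

    ``n_total`` is the sample's genome-wide SBS count used for the null;
    ``genome_size`` the covered (non-N) genome length.
    """
    df = sample_df.sort_values(["chrom", "pos"], kind="stable")
    rows = []
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        apo = sub["is_apobec"].to_numpy() & sub["context_ok"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > max_gap)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks + 1, [len(pos)]))
        for s, e in zip(starts, ends):
            k = e - s
            if k < 2:
                continue
            span = int(pos[e - 1] - pos[s])
            p = cluster_pvalue(k, span, n_total, genome_size)
            if p > p_cutoff:
                continue
            n_apo = int(apo[s:e].sum())
            klass = "APOBEC" if n_apo == k else ("NON_APOBEC" if n_apo == 0 else "MIXED")
            rows.append({"chrom": chrom, "start": int(pos[s]), "end": int(pos[e - 1]) + 1,
                         "k": k, "span": span, "p": p, "klass": klass})
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "k", "span", "p", "klass"])
    if "sample" in sample_df.columns and len(sample_df):
        out.insert(0, "sample", sample_df["sample"].iloc[0])
    return out


def cluster_grid(clusters: pd.DataFrame, ann: GenomeAnnotation,
                 expr_bins: BinScheme) -> pd.DataFrame:
    """Cluster counts and bp-normalized densities over the (r, t) grid.

    Each cluster is assigned to the cell containing its midpoint; clusters
    outside genic territory go to the separate t=0 "intergenic" stratum.
    """
    nb = ann.n_bins
    gene_bin = expr_bins.gene_bins.to_numpy()
    counts = np.zeros((nb + 1, nb + 1), dtype=np.int64)  # [r, t]; t=0 intergenic, r=0 uncovered
    for _, c in clusters.iterrows():
        mid = (c["start"] + c["end"]) // 2
        r = ann.rt[c["chrom"]][mid]
        gi = ann.gene[c["chrom"]][mid]
        t = gene_bin[gi] if gi >= 0 else 0
        counts[r, t] += 1
    gene_rt_bp = ann.memo("gene_rt_bp", ann.gene_rt_bp)
    bp = np.zeros((nb + 1, nb + 1), dtype=np.int64)
    for t in range(1, nb + 1):
        bp[1:, t] = gene_rt_bp[gene_bin == t].sum(axis=0)
    # intergenic bp per timing bin = covered bin bp minus genic bp
    bp[1:, 0] = ann.rt_bins.bp_per_bin - gene_rt_bp.sum(axis=0)
    rows = []
    for r in range(1, nb + 1):
        for t in range(0, nb + 1):
            rows.append({"r": r, "t": t, "count": int(counts[r, t]), "bp": int(bp[r, t]),
                         "density": counts[r, t] / bp[r, t] if bp[r, t] > 0 else np.nan})
    return pd.DataFrame(rows)
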