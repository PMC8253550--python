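"""Replicative and transcriptional strand asymmetry statistics.

Ratios are densities (mutations per motif site) on one strand class over the
other — lagging/leading along replication-timing bins, sense/antisense along
expression bins — computed per sample and averaged across samples, never
pooled.  The mid-timing peak of the lagging/leading profile is tested with a
per-bin strand-shuffle null on the quadratic coefficient of a parabola
fitted to the seven per-bin ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .binning import BinScheme, GenomeAnnotation, LEFTWARD, RIGHTWARD
from .density import _is_nonc_site, slope_over_bins

log = logging.getLogger(__name__)


def _mutation_subset(labeled: pd.DataFrame, which: str) -> pd.DataFrame:
    """'apobec': signature SBS; 'non_tcn_c': SBS at non-TCN cytosines (control)."""
    sub = labeled[labeled["context_ok"]]
    if which == "apobec":
        return sub[sub["is_apobec"]]
    if which == "non_tcn_c":
        return sub[_is_nonc_site(sub["pyr_context"].to_numpy())]
    raise ValueError(which)


def replication_strand_profile(labeled: pd.DataFrame, ann: GenomeAnnotation,
                               which: str = "apobec") -> pd.DataFrame:
    """Per-timing-bin lagging/leading density ratio for one sample."""
    motif = "TCN" if which == "apobec" else "non_tcn_c"
    exp = ann.memo(("rep_exp", motif), lambda: ann.rep_strand_exposures(motif))
    sub = _mutation_subset(labeled, which)
    sub = sub[sub["rt_bin"] > 0]
    nb = ann.n_bins
    lag = np.bincount(sub.loc[sub["rep_class"] == "lagging", "rt_bin"], minlength=nb + 1)[1:]
    lead = np.bincount(sub.loc[sub["rep_class"] == "leading", "rt_bin"], minlength=nb + 1)[1:]
    df = pd.DataFrame({"bin": np.arange(1, nb + 1), "n_lagging": lag, "n_leading": lead,
                       "m_lagging": exp["lagging"].to_numpy(), "m_leading": exp["leading"].to_numpy()})
    df["ratio"] = _density_ratio(df, "n_lagging", "m_lagging", "n_leading", "m_leading")
    return df


def transcription_strand_profile(labeled: pd.DataFrame, ann: GenomeAnnotation,
                                 expr_bins: BinScheme, which: str = "apobec") -> pd.DataFrame:
    """Per-expression-bin sense/antisense density ratio for one sample."""
    motif = "TCN" if which == "apobec" else "non_tcn_c"
    gexp = ann.memo(("gene_strand", motif), lambda: ann.gene_strand_exposures(motif))
    gene_bin = expr_bins.gene_bins.to_numpy()
    nb = expr_bins.n_bins
    m_sense = np.bincount(gene_bin, weights=gexp["sense"], minlength=nb + 1)[1:]
    m_anti = np.bincount(gene_bin, weights=gexp["antisense"], minlength=nb + 1)[1:]
    sub = _mutation_subset(labeled, which)
    sub = sub[sub["gene_idx"] >= 0]
    t = gene_bin[sub["gene_idx"].to_numpy()] if len(sub) else np.array([], dtype=int)
    sense = np.bincount(t[(sub["tx_class"] == "sense").to_numpy()], minlength=nb + 1)[1:]
    anti = np.bincount(t[(sub["tx_class"] == "antisense").to_numpy()], minlength=nb + 1)[1:]
    df = pd.DataFrame({"bin": np.arange(1, nb + 1), "n_sense": sense, "n_antisense": anti,
                       "m_sense": m_sense, "m_antisense": m_anti})
    df["ratio"] = _density_ratio(df, "n_sense", "m_sense", "n_antisense", "m_antisense")
    return df


def _density_ratio(df, na, ma, nb_, mb):
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (df[na] / df[ma]) / (df[nb_] / df[mb])
    return np.where((df[na] > 0) & (df[nb_] > 0) & (df[ma] > 0) & (df[mb] > 0), r, np.nan)


def mean_ratio(profile: pd.DataFrame) -> float:
    """Sample-level mean of the per-bin ratios over defined bins (NaN if none)."""
    r = profile["ratio"].to_numpy(dtype=float)
    return float(np.nanmean(r)) if np.isfinite(r).any() else float("nan")


# ---------------------------------------------------------------------------
# curvature shuffle test


@dataclass
class CurvatureTest:
    observed: float
    null_mean: float
    null_sd: float
    n_shuffles: int
    n_valid: int
    p_gaussian: float        # two-sided on the z-score
    p_gaussian_concave: float  # one-sided, lower tail (mid-bin peak)
    p_empirical: float       # (1 + #{null <= obs}) / (n_valid + 1)


def quadratic_coefficient(values: np.ndarray) -> float:
    """Coefficient of x^2 in the OLS parabola of values against bin index."""
    x = np.arange(1, len(values) + 1, dtype=float)
    return float(np.polyfit(x, np.asarray(values, dtype=float), 2)[0])


def curvature_shuffle_test(profile: pd.DataFrame, n_shuffles: int = 10_000,
                           seed: int | None = None) -> CurvatureTest:
    """Strand-shuffle significance of the curvature of a lagging/leading profile.

    Each mutation keeps its timing bin; within a bin, strand labels are
    resampled with probability proportional to the strand motif exposures,
    preserving every bin's total count.  The null distribution of the
    quadratic coefficient gives a Gaussian-tail p (the observed effect sizes
    can fall far beyond any empirical rank) plus the empirical rank itself.
    """
    nb = len(profile)
    n = (profile["n_lagging"] + profile["n_leading"]).to_numpy()
    m_lag = profile["m_lagging"].to_numpy(dtype=float)
    m_lead = profile["m_leading"].to_numpy(dtype=float)
    if ((m_lag <= 0) | (m_lead <= 0) | (n <= 0)).any():
        raise ValueError("each bin needs mutations and exposure on both strands")
    obs = quadratic_coefficient(profile["ratio"].to_numpy())
    p_strand = m_lag / (m_lag + m_lead)
    rng = np.random.default_rng(seed)
    lag_s = rng.binomial(n[None, :].repeat(n_shuffles, axis=0), p_strand[None, :])
    lead_s = n[None, :] - lag_s
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = (lag_s / m_lag) / (lead_s / m_lead)
    valid = np.isfinite(ratios).all(axis=1)
    ratios = ratios[valid]
    if len(ratios) < 2:
        raise ValueError("degenerate null: too few valid shuffles")
    # quadratic coefficient for all shuffles at once via the hat-row of x^2
    x = np.arange(1, nb + 1, dtype=float)
    X = np.column_stack([x**2, x, np.ones(nb)])
    h = np.linalg.pinv(X)[0]
    null = ratios @ h
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    if sd < 1e-15:
        raise ValueError("degenerate null standard deviation")
    z = (obs - mu) / sd
    return CurvatureTest(
        observed=obs, null_mean=mu, null_sd=sd, n_shuffles=n_shuffles, n_valid=len(null),
        p_gaussian=float(2 * stats.norm.sf(abs(z))),
        p_gaussian_concave=float(stats.norm.cdf(z)),
        p_empirical=float((1 + np.sum(null <= obs)) / (len(null) + 1)),
    )


# ---------------------------------------------------------------------------
# group comparisons


def group_ratio_comparison(ratios_a, ratios_b):
    """Mean per-sample ratios of two groups and two-sided Mann-Whitney p."""
    a = np.asarray([r for r in ratios_a if np.isfinite(r)], dtype=float)
    b = np.asarray([r for r in ratios_b if np.isfinite(r)], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 samples")
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {"mean_a": float(a.mean()), "mean_b": float(b.mean()),
            "n_a": len(a), "n_b": len(b), "U": float(stat), "p": float(p)}


def gene_codirection(ann: GenomeAnnotation) -> np.ndarray:
    """+1 where transcription runs with the fork, -1 against, 0 undetermined.

    Fork direction is taken at the gene midpoint.
    """
    genes = ann.genes
    out = np.zeros(len(genes), dtype=np.int8)
    for i, g in genes.iterrows():
        mid = (g["start"] + g["end"]) // 2
        fork = ann.fork[g["chrom"]][mid]
        if fork == 0:
            continue
        tx = RIGHTWARD if g["strand"] == "+" else LEFTWARD
        out[i] = 1 if tx == fork else -1
    return out


def codirection_contrast(catalog: pd.DataFrame, ann: GenomeAnnotation,
                         expr_bins_by_sample: dict[str, BinScheme]):
    """RD-vs-expression slopes for co- vs anti-directional genes, per sample.

    Returns a per-sample slope table and a two-sided Wilcoxon signed-rank p
    across samples on the slope differences.
    """
    codir = gene_codirection(ann)
    g_tcn = ann.memo(("gene_rt", "TCN"), lambda: ann.gene_rt_exposures("TCN")).sum(axis=1)
    g_onc = ann.memo(("gene_rt", "non_tcn_c"), lambda: ann.gene_rt_exposures("non_tcn_c")).sum(axis=1)
    rows = []
    for sid, sub in catalog.groupby("sample", sort=True):
        if sid not in expr_bins_by_sample:
            continue
        scheme = expr_bins_by_sample[sid]
        gene_bin = scheme.gene_bins.to_numpy()
        nb = scheme.n_bins
        sub = sub[sub["context_ok"] & (sub["gene_idx"] >= 0)]
        gi = sub["gene_idx"].to_numpy()
        slopes = {}
        for name, grp in (("co", 1), ("anti", -1)):
            sel_gene = codir == grp
            m_tcn = np.bincount(gene_bin[sel_gene], weights=g_tcn[sel_gene], minlength=nb + 1)[1:]
            m_onc = np.bincount(gene_bin[sel_gene], weights=g_onc[sel_gene], minlength=nb + 1)[1:]
            in_grp = sel_gene[gi]
            t = gene_bin[gi[in_grp]]
            apo = np.bincount(t[sub["is_apobec"].to_numpy()[in_grp]], minlength=nb + 1)[1:]
            onc = np.bincount(t[_is_nonc_site(sub["pyr_context"].to_numpy()[in_grp])], minlength=nb + 1)[1:]
            with np.errstate(divide="ignore", invalid="ignore"):
                rd = np.where((m_tcn > 0) & (m_onc > 0), apo / m_tcn - onc / m_onc, np.nan)
            try:
                slopes[name], _, _ = slope_over_bins(rd)
            except ValueError:
                slopes[name] = np.nan
        rows.append({"sample": sid, "slope_co": slopes["co"], "slope_anti": slopes["anti"]})
    table = pd.DataFrame(rows)
    both = table.dropna()
    if len(both) < 3:
        raise ValueError("need >= 3 samples with both gene groups defined")
    diff = (both["slope_co"] - both["slope_anti"]).to_numpy()
    if np.allclose(diff, 0):
        p = 1.0
    else:
        _, p = stats.wilcoxon(diff, alternative="two-sided")
    return table, float(p)
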