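"""Motif-normalized mutation densities and their trends.

Core quantities, per sample and per bin b:

* D_APOBEC(b) = N_APOBEC(b) / N_TCN(b) — APOBEC-signature SBS per TCN site;
* D_NCN(b)    — SBS at non-TCN cytosine sites per such site (the background
  control; C→A events at TCN sites enter neither numerator nor denominator);
* RD(b)       = D_APOBEC(b) − D_NCN(b), the relative density;
* NRD(r,t)    = RD(r,t) / Σ RD over the 7×7 (timing × expression) grid,
  which removes the sample's overall mutation load.

Trends are ordinary least-squares slopes against the bin index (bin 1 =
earliest replication / bin 7 = highest expression).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .binning import BinScheme, GenomeAnnotation
from .refio import PYR_TRIMERS, code_to_trimer, trimer_code, _revcomp_code

log = logging.getLogger(__name__)

_TCN = {"TCA", "TCC", "TCG", "TCT"}


def _is_nonc_site(ctx: np.ndarray) -> np.ndarray:
    return np.array([bool(c) and c[1] == "C" and c not in _TCN for c in ctx])


def slope_over_bins(values, bins=None):
    """OLS slope of per-bin values against bin index; returns (k, se, p)."""
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    if bins is None:
        bins = np.arange(1, len(values) + 1)
    bins = np.asarray(bins, dtype=float)[ok]
    values = values[ok]
    if len(values) < 3:
        raise ValueError("need >= 3 bins with defined values")
    res = stats.linregress(bins, values)
    return float(res.slope), float(res.stderr), float(res.pvalue)


def _density_frame(n_apo, n_tcn, n_onc, n_onc_sites, bins):
    with np.errstate(divide="ignore", invalid="ignore"):
        d_apo = np.where(n_tcn > 0, n_apo / n_tcn, np.nan)
        d_ncn = np.where(n_onc_sites > 0, n_onc / n_onc_sites, np.nan)
    if (np.asarray(n_tcn) == 0).any():
        raise ValueError("bin with zero TCN sites: density undefined")
    return pd.DataFrame(
        {
            "bin": bins,
            "n_apobec": n_apo,
            "n_tcn": n_tcn,
            "n_other_c": n_onc,
            "n_nonc_sites": n_onc_sites,
            "d_apobec": d_apo,
            "d_ncn": d_ncn,
            "rd": d_apo - d_ncn,
        }
    )


def bin_densities_rt(labeled: pd.DataFrame, ann: GenomeAnnotation) -> pd.DataFrame:
    """Per-timing-bin densities for one sample's labeled catalog."""
    nb = ann.n_bins
    sub = labeled[labeled["context_ok"] & (labeled["rt_bin"] > 0)]
    n_apo = np.bincount(sub.loc[sub["is_apobec"], "rt_bin"], minlength=nb + 1)[1:]
    onc = sub[_is_nonc_site(sub["pyr_context"].to_numpy())] if len(sub) else sub
    n_onc = np.bincount(onc["rt_bin"], minlength=nb + 1)[1:] if len(onc) else np.zeros(nb, dtype=int)
    n_tcn = ann.rt_bins.n_motif_per_bin
    n_sites = ann.memo(("rt_exp", "non_tcn_c"), lambda: ann.rt_exposures("non_tcn_c"))
    return _density_frame(n_apo, n_tcn, n_onc, n_sites, np.arange(1, nb + 1))


def bin_densities_expr(labeled: pd.DataFrame, ann: GenomeAnnotation, expr_bins: BinScheme) -> pd.DataFrame:
    """Per-expression-bin densities over genic territory for one sample."""
    nb = expr_bins.n_bins
    gene_bin = expr_bins.gene_bins.to_numpy()  # gene_idx -> bin
    sub = labeled[labeled["context_ok"] & (labeled["gene_idx"] >= 0)]
    t = gene_bin[sub["gene_idx"].to_numpy()] if len(sub) else np.array([], dtype=int)
    n_apo = np.bincount(t[sub["is_apobec"].to_numpy()], minlength=nb + 1)[1:] if len(sub) else np.zeros(nb, int)
    onc_mask = _is_nonc_site(sub["pyr_context"].to_numpy()) if len(sub) else np.array([], dtype=bool)
    n_onc = np.bincount(t[onc_mask], minlength=nb + 1)[1:] if len(sub) else np.zeros(nb, int)
    g_tcn = ann.memo(("gene_rt", "TCN"), lambda: ann.gene_rt_exposures("TCN")).sum(axis=1)
    g_onc = ann.memo(("gene_rt", "non_tcn_c"), lambda: ann.gene_rt_exposures("non_tcn_c")).sum(axis=1)
    n_tcn = np.bincount(gene_bin, weights=g_tcn, minlength=nb + 1)[1:].astype(np.int64)
    n_sites = np.bincount(gene_bin, weights=g_onc, minlength=nb + 1)[1:].astype(np.int64)
    return _density_frame(n_apo, n_tcn, n_onc, n_sites, np.arange(1, nb + 1))


def per_context_slope_panel(labeled: pd.DataFrame, ann: GenomeAnnotation) -> pd.DataFrame:
    """Density slope over timing bins for each of the 32 pyrimidine contexts."""
    nb = ann.n_bins

    def context_exposures():
        # pyr-trimer index per position (plus strand central C/T as-is,
        # central G/A via reverse complement), one bincount pass per chrom
        lut = np.full(64, -1, dtype=np.int64)
        for i, t in enumerate(PYR_TRIMERS):
            lut[trimer_code(t)] = i
            lut[_revcomp_code(trimer_code(t))] = i
        out = np.zeros((nb + 1) * 32, dtype=np.int64)
        for chrom in ann.genome.chrom_names:
            codes = ann.genome.trimer_codes(chrom)
            valid = codes >= 0
            idx = lut[np.where(valid, codes, 0)]
            sel = valid & (idx >= 0)
            key = ann.rt[chrom][sel].astype(np.int64) * 32 + idx[sel]
            out += np.bincount(key, minlength=len(out))
        return out.reshape(nb + 1, 32)[1:]

    exp = ann.memo("context_exposures", context_exposures)
    sub = labeled[labeled["context_ok"] & (labeled["rt_bin"] > 0)]
    ctx_idx = pd.Categorical(sub["pyr_context"], categories=PYR_TRIMERS).codes
    counts = np.zeros((nb + 1, 32), dtype=np.int64)
    np.add.at(counts, (sub["rt_bin"].to_numpy(), ctx_idx), 1)
    counts = counts[1:]
    rows = []
    for i, t in enumerate(PYR_TRIMERS):
        if (exp[:, i] == 0).any():
            rows.append({"context": t, "is_tcn": t in _TCN, "slope": np.nan, "se": np.nan,
                         "p": np.nan, "defined": False})
            continue
        dens = counts[:, i] / exp[:, i]
        k, se, p = slope_over_bins(dens)
        rows.append({"context": t, "is_tcn": t in _TCN, "slope": k, "se": se, "p": p, "defined": True})
    return pd.DataFrame(rows)


def slopes_vs_enrichment(slopes: pd.Series, enrichment: pd.Series):
    """Cohort trend: OLS of per-sample RD slope on APOBEC enrichment."""
    joined = pd.concat([slopes.rename("k"), enrichment.rename("e")], axis=1).dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 samples")
    res = stats.linregress(joined["e"], joined["k"])
    return float(res.slope), float(res.stderr), float(res.pvalue)


def gene_intergenic_ratio(labeled: pd.DataFrame, ann: GenomeAnnotation):
    """Genic/intergenic APOBEC mutation count ratio and TCN-density ratio."""
    sub = labeled[labeled["is_apobec"] & labeled["context_ok"]]
    n_genic = int((sub["gene_idx"] >= 0).sum())
    n_inter = int((sub["gene_idx"] == -1).sum())
    if n_inter == 0:
        return float("nan"), float("nan")
    terr = ann.memo(("territory", "TCN"), lambda: ann.territory_exposures("TCN"))
    count_ratio = n_genic / n_inter
    density_ratio = (n_genic / terr["genic"]) / (n_inter / terr["intergenic"])
    return count_ratio, density_ratio


@dataclass
class NRDGrid:
    """Normalized relative APOBEC density on the (timing r × expression t) grid."""

    sample_id: str
    rd: np.ndarray       # (n_bins, n_bins), rows r = timing, cols t = expression
    nrd: np.ndarray
    sum_rd: float
    n_bins: int = 7


def build_nrd_grid(labeled: pd.DataFrame, ann: GenomeAnnotation, expr_bins: BinScheme,
                   sample_id: str = "", exclude_clustered: np.ndarray | None = None) -> NRDGrid:
    """RD per (timing, expression) cell over genic territory, normalized to sum 1."""
    nb = ann.n_bins
    gene_bin = expr_bins.gene_bins.to_numpy()
    g_tcn = ann.memo(("gene_rt", "TCN"), lambda: ann.gene_rt_exposures("TCN"))
    g_onc = ann.memo(("gene_rt", "non_tcn_c"), lambda: ann.gene_rt_exposures("non_tcn_c"))
    tcn = np.zeros((nb, nb))
    onc_sites = np.zeros((nb, nb))
    for t in range(1, nb + 1):
        sel = gene_bin == t
        tcn[:, t - 1] = g_tcn[sel].sum(axis=0)
        onc_sites[:, t - 1] = g_onc[sel].sum(axis=0)
    if (tcn == 0).any() or (onc_sites == 0).any():
        raise ValueError("grid cell with zero motif sites: grid invalid")
    sub = labeled[labeled["context_ok"] & (labeled["gene_idx"] >= 0) & (labeled["rt_bin"] > 0)]
    if exclude_clustered is not None:
        sub = sub[~exclude_clustered[sub.index]]
    r = sub["rt_bin"].to_numpy() - 1
    t = gene_bin[sub["gene_idx"].to_numpy()] - 1
    apo = np.zeros((nb, nb))
    onc = np.zeros((nb, nb))
    np.add.at(apo, (r[sub["is_apobec"].to_numpy()], t[sub["is_apobec"].to_numpy()]), 1)
    onc_mask = _is_nonc_site(sub["pyr_context"].to_numpy()) if len(sub) else np.array([], bool)
    np.add.at(onc, (r[onc_mask], t[onc_mask]), 1)
    rd = apo / tcn - onc / onc_sites
    s = float(rd.sum())
    if abs(s) < 1e-12:
        raise ValueError("non-normalizable sample: sum of RD over grid ~ 0")
    return NRDGrid(sample_id, rd=rd, nrd=rd / s, sum_rd=s, n_bins=nb)
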