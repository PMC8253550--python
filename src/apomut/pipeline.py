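"""End-to-end cohort analysis: from reference + catalog to the report bundle.

The stages mirror the analysis narrative: signature classification and
sample selection, timing/expression binning and strand labels, density
tables and slopes, strand-asymmetry statistics with the curvature shuffle
test, cluster calling, and the per-sample NRD regression with variance
decomposition.  Every stage works from the same `GenomeAnnotation`, so all
motif exposures are computed once per cohort.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import asymmetry, binning, clusters, density, model, refio, signature

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds and knobs of the full pipeline."""

    enrichment_threshold: float = 2.0
    enrichment_very_high: float = 2.5
    enrichment_very_low: float = 1.5
    min_in_gene_mutations: int = 600
    cluster_max_gap: int = 10_000
    cluster_p_cutoff: float = 1e-4
    n_bins: int = 7
    n_shuffles: int = 10_000
    alpha: float = 0.05
    fork_window_bp: int = 100_000
    fork_derivative_threshold: float | None = None
    seed: int = 0

    def to_dict(self):
        return dataclasses.asdict(self)


@dataclass
class CohortResults:
    config: RunConfig
    selection: pd.DataFrame
    rt_densities: dict[str, pd.DataFrame] = field(default_factory=dict)
    expr_densities: dict[str, pd.DataFrame] = field(default_factory=dict)
    rt_slopes: pd.DataFrame | None = None
    expr_slopes: pd.DataFrame | None = None
    slope_trends: dict = field(default_factory=dict)
    context_panel: pd.DataFrame | None = None
    replication_ratios: pd.DataFrame | None = None
    transcription_ratios: pd.DataFrame | None = None
    replication_comparison: dict | None = None
    transcription_comparison: dict | None = None
    curvature: asymmetry.CurvatureTest | None = None
    mean_lagging_profile: pd.DataFrame | None = None
    codirection: dict | None = None
    gene_intergenic: pd.DataFrame | None = None
    cluster_table: pd.DataFrame | None = None
    cluster_grid: pd.DataFrame | None = None
    model_fits: pd.DataFrame | None = None
    model_fits_noclust: pd.DataFrame | None = None
    cohort_model: dict | None = None
    cohort_model_noclust: dict | None = None
    counters: dict = field(default_factory=dict)
    annotation: binning.GenomeAnnotation | None = field(default=None, repr=False)
    expr_schemes: dict[str, binning.BinScheme] = field(default_factory=dict, repr=False)


def prepare_catalog(catalog: pd.DataFrame, genome: refio.GenomeContext) -> pd.DataFrame:
    """Annotate and classify a raw (sample, chrom, pos, ref, alt) catalog."""
    if "pyr_context" not in catalog.columns:
        catalog, _ = refio.annotate_mutations(catalog, genome)
    if "category" not in catalog.columns:
        catalog = signature.classify_catalog(catalog)
    return catalog


def build_annotation(genome, profile, genes, cfg: RunConfig):
    rt_bins = binning.make_rt_bins(profile, genome, n_bins=cfg.n_bins)
    fork_map = binning.infer_fork_map(profile, window_bp=cfg.fork_window_bp,
                                      derivative_threshold=cfg.fork_derivative_threshold)
    return binning.GenomeAnnotation(genome, rt_bins, fork_map, genes)


def _clustered_mask(sample_df: pd.DataFrame, cluster_table: pd.DataFrame) -> np.ndarray:
    mask = np.zeros(len(sample_df), dtype=bool)
    if cluster_table is None or not len(cluster_table):
        return mask
    for chrom, cl in cluster_table.groupby("chrom", sort=False):
        sel = sample_df["chrom"] == chrom
        pos = sample_df.loc[sel, "pos"].to_numpy()
        hit = np.zeros(len(pos), dtype=bool)
        for _, c in cl.iterrows():
            hit |= (pos >= c["start"]) & (pos < c["end"])
        mask[np.flatnonzero(sel.to_numpy())] = hit
    return mask


def analyze_cohort(genome, profile, genes, expression: pd.DataFrame,
                   catalog: pd.DataFrame, cfg: RunConfig | None = None) -> CohortResults:
    """Run the full analysis; ``expression`` columns are sample ids."""
    cfg = cfg or RunConfig()
    catalog = prepare_catalog(catalog, genome)
    summaries = signature.sample_summaries(catalog, genome)
    selection = signature.select_samples(summaries, cfg.enrichment_threshold,
                                         cfg.enrichment_very_high, cfg.enrichment_very_low)
    res = CohortResults(config=cfg, selection=selection)

    ann = build_annotation(genome, profile, genes, cfg)
    labeled = binning.label_mutations(catalog, ann)
    expr_ok = set(binning.filter_expression_samples(labeled, cfg.min_in_gene_mutations))
    res.counters["n_samples"] = labeled["sample"].nunique()
    res.counters["n_expression_samples"] = len(expr_ok)

    enrichment = selection.set_index("sample")["enrichment"]
    enriched = set(selection.loc[selection["apobec_enriched"], "sample"])
    genome_size = genome.total_length

    expr_schemes: dict[str, binning.BinScheme] = {}
    rt_slope_rows, expr_slope_rows, gi_rows = [], [], []
    rep_rows, tx_rows = [], []
    pooled_lag = pooled_lead = None
    fits, fits_nc = [], []
    cluster_frames, grid_counts = [], None
    panel = None

    for sid, sub in labeled.groupby("sample", sort=True):
        sub = sub.reset_index(drop=True)
        # timing axis densities
        dt = density.bin_densities_rt(sub, ann)
        res.rt_densities[sid] = dt
        k, se, p = density.slope_over_bins(dt["rd"])
        rt_slope_rows.append({"sample": sid, "slope": k, "se": se, "p": p})
        # clusters
        ct = clusters.detect_clusters(sub, n_total=len(sub), genome_size=genome_size,
                                      max_gap=cfg.cluster_max_gap, p_cutoff=cfg.cluster_p_cutoff)
        cluster_frames.append(ct)
        # gene/intergenic
        cr, dr = density.gene_intergenic_ratio(sub, ann)
        gi_rows.append({"sample": sid, "count_ratio": cr, "density_ratio": dr,
                        "enrichment": enrichment.get(sid, np.nan)})
        # replication strand ratios
        which = "apobec" if sid in enriched else "non_tcn_c"
        prof_apo = asymmetry.replication_strand_profile(sub, ann, "apobec")
        prof_ctl = asymmetry.replication_strand_profile(sub, ann, "non_tcn_c")
        rep_rows.append({"sample": sid, "enriched": sid in enriched,
                         "ratio_apobec": asymmetry.mean_ratio(prof_apo),
                         "ratio_control": asymmetry.mean_ratio(prof_ctl)})
        if sid in enriched:
            if pooled_lag is None:
                pooled_lag = np.zeros(cfg.n_bins, dtype=np.int64)
                pooled_lead = np.zeros(cfg.n_bins, dtype=np.int64)
            pooled_lag += prof_apo["n_lagging"].to_numpy()
            pooled_lead += prof_apo["n_leading"].to_numpy()
        if panel is None:
            panel = density.per_context_slope_panel(sub, ann)
        # expression axis
        if sid in expr_ok and sid in expression.columns:
            scheme = binning.make_expr_bins(expression[sid], n_bins=cfg.n_bins)
            if scheme.degenerate:
                log.warning("sample %s: degenerate expression bins, excluded", sid)
            else:
                expr_schemes[sid] = scheme
                de = density.bin_densities_expr(sub, ann, scheme)
                res.expr_densities[sid] = de
                ke, see, pe = density.slope_over_bins(de["rd"])
                expr_slope_rows.append({"sample": sid, "slope": ke, "se": see, "p": pe})
                tx_apo = asymmetry.transcription_strand_profile(sub, ann, scheme, "apobec")
                tx_ctl = asymmetry.transcription_strand_profile(sub, ann, scheme, "non_tcn_c")
                tx_rows.append({"sample": sid, "enriched": sid in enriched,
                                "ratio_apobec": asymmetry.mean_ratio(tx_apo),
                                "ratio_control": asymmetry.mean_ratio(tx_ctl)})
                # NRD model, with and without clustered mutations
                try:
                    grid = density.build_nrd_grid(sub, ann, scheme, sample_id=sid)
                    fits.append(model.fit_nrd_model(grid))
                    mask = _clustered_mask(sub, ct)
                    grid_nc = density.build_nrd_grid(sub, ann, scheme, sample_id=sid,
                                                     exclude_clustered=mask)
                    fits_nc.append(model.fit_nrd_model(grid_nc))
                except ValueError as err:
                    log.warning("sample %s: model skipped (%s)", sid, err)

    res.rt_slopes = pd.DataFrame(rt_slope_rows)
    res.expr_slopes = pd.DataFrame(expr_slope_rows)
    res.context_panel = panel
    res.gene_intergenic = pd.DataFrame(gi_rows)
    res.replication_ratios = pd.DataFrame(rep_rows)
    res.transcription_ratios = pd.DataFrame(tx_rows)

    # cohort slope-vs-enrichment trends
    for name, tab in (("timing", res.rt_slopes), ("expression", res.expr_slopes)):
        if len(tab) >= 3:
            sl = tab.set_index("sample")["slope"]
            kt, set_, pt = density.slopes_vs_enrichment(sl, enrichment)
            res.slope_trends[name] = {"k": kt, "se": set_, "p": pt, "n": int(len(sl))}

    # strand comparisons: enriched APOBEC ratios vs low-sample control ratios
    rr = res.replication_ratios
    if rr is not None and len(rr):
        try:
            res.replication_comparison = asymmetry.group_ratio_comparison(
                rr.loc[rr["enriched"], "ratio_apobec"], rr.loc[~rr["enriched"], "ratio_control"])
        except ValueError as err:
            log.warning("replication group comparison skipped (%s)", err)
    tr = res.transcription_ratios
    if tr is not None and len(tr):
        try:
            res.transcription_comparison = asymmetry.group_ratio_comparison(
                tr.loc[tr["enriched"], "ratio_apobec"], tr.loc[~tr["enriched"], "ratio_control"])
        except ValueError as err:
            log.warning("transcription group comparison skipped (%s)", err)

    # pooled lagging/leading profile over enriched samples + curvature test
    if pooled_lag is not None:
        exp = ann.memo(("rep_exp", "TCN"), lambda: ann.rep_strand_exposures("TCN"))
        pooled = pd.DataFrame({"bin": np.arange(1, cfg.n_bins + 1),
                               "n_lagging": pooled_lag, "n_leading": pooled_lead,
                               "m_lagging": exp["lagging"], "m_leading": exp["leading"]})
        pooled["ratio"] = (pooled["n_lagging"] / pooled["m_lagging"]) / (
            pooled["n_leading"] / pooled["m_leading"])
        res.mean_lagging_profile = pooled
        try:
            res.curvature = asymmetry.curvature_shuffle_test(pooled, cfg.n_shuffles, seed=cfg.seed)
        except ValueError as err:
            log.warning("curvature test skipped (%s)", err)

    # co-direction of replication and transcription
    if expr_schemes:
        try:
            table, p = asymmetry.codirection_contrast(labeled, ann, expr_schemes)
            res.codirection = {"table": table, "wilcoxon_p": p}
        except ValueError as err:
            log.warning("codirection contrast skipped (%s)", err)

    # clusters
    res.cluster_table = pd.concat(cluster_frames, ignore_index=True) if cluster_frames else None
    if res.cluster_table is not None and len(res.cluster_table) and expr_schemes:
        grids = []
        for sid, cl in res.cluster_table.groupby("sample", sort=True):
            if sid in expr_schemes:
                g = clusters.cluster_grid(cl[cl["klass"] == "APOBEC"], ann, expr_schemes[sid])
                grids.append(g.set_index(["r", "t"])[["count", "bp"]])
        if grids:
            total = sum(g["count"] for g in grids).to_frame("count")
            total["bp"] = grids[0]["bp"]
            total["density"] = total["count"] / total["bp"].replace(0, np.nan)
            res.cluster_grid = total.reset_index()

    res.annotation = ann
    res.expr_schemes = expr_schemes

    # NRD model cohort summaries
    if fits:
        res.model_fits = model.fits_table(fits)
        res.cohort_model = model.cohort_summary(res.model_fits, selection, cfg.alpha)
    if fits_nc:
        res.model_fits_noclust = model.fits_table(fits_nc)
        res.cohort_model_noclust = model.cohort_summary(res.model_fits_noclust, selection, cfg.alpha)
    return res
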