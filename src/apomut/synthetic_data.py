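"""Synthetic genomes and SBS catalogs with known ground truth.

The generator emulates the effect structure the pipeline estimates: APOBEC
mutations at TCN sites whose rate rises toward early replication and high
expression, with a lagging-strand bias peaking at a chosen timing bin and a
sense-strand bias growing with expression; background mutations at non-TCN
cytosines and thymines with a late-timing gradient; and strand-coordinated
clusters injected within 10 kb windows.  Fork and sense conventions are the
binning module's own (shared constants), so round-trip tests exercise the
estimators rather than the convention.

All randomness flows from one root seed via numpy SeedSequence spawning;
outputs are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import binning
from .refio import GenomeContext, motif_luts, write_fasta

log = logging.getLogger(__name__)

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort (defaults = default scale)."""

    seed: int = 0
    # reference
    genome_length: int = 20_000_000
    gc: float = 0.41
    chrom_name: str = "chr1"
    segment_bp: int = 1_000
    timing_period: float = 2_000_000.0
    timing_amplitude: float = 30.0
    timing_offset: float = 50.0
    n_genes: int = 2_000
    gene_len_median: int = 3_000
    gene_len_sigma: float = 0.5
    gene_len_min: int = 500
    gene_len_max: int = 15_000
    gene_early_assoc: float = 1.0     # gene-placement weight exp(assoc * timing z-score)
    expr_log_sigma: float = 1.5
    expr_sample_sigma: float = 0.5
    expr_zero_frac: float = 0.10
    # cohort
    n_samples: int = 30
    n_mutations: int = 40_000         # per sample, APOBEC + background
    apobec_fraction_range: tuple[float, float] = (0.05, 0.90)
    # effects
    rt_gradient: float = 0.12         # APOBEC weight 1 + g*(4 - r)
    lagging_bias_amplitude: float = 0.5
    lagging_bias_peak_bin: int = 3
    lagging_bias_width: float = 1.5   # bins (gaussian)
    sense_bias_amplitude: float = 0.5  # sense weight 1 + a*(t-1)/6
    background_rt_gradient: float = 0.08  # background weight 1 + g*(r - 4)
    background_t_fraction: float = 0.5    # background fraction at T sites
    apobec_ct_fraction: float = 2.0 / 3.0
    # clusters (kataegis-like: tight strand-coordinated runs)
    n_clusters: int = 30              # per sample
    cluster_k_min: int = 4
    cluster_extra_poisson: float = 2.0  # cluster size k = k_min + Poisson(lambda)
    cluster_span: int = 300
    cluster_rt_bias: float = 0.25
    cluster_expr_bias: float = 0.5
    n_bins: int = 7


@dataclass
class Reference:
    genome: GenomeContext
    profile: pd.DataFrame            # bedGraph-style timing segments
    genes: pd.DataFrame              # gene_id, chrom, start, end, strand
    expression: pd.DataFrame         # genes x samples TPM-like matrix
    fork_truth: pd.DataFrame         # analytic fork direction per segment
    annotation: binning.GenomeAnnotation = field(repr=False, default=None)


def _timing_value(x: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    return cfg.timing_offset + cfg.timing_amplitude * np.cos(2 * np.pi * x / cfg.timing_period)


def generate_reference(cfg: SimulationConfig) -> Reference:
    """Genome, timing profile, genes with expression, and truth fork map."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_g, rng_genes, rng_expr = (np.random.default_rng(s) for s in ss.spawn(3))
    p = np.array([(1 - cfg.gc) / 2, cfg.gc / 2, cfg.gc / 2, (1 - cfg.gc) / 2])
    seq_codes = rng_g.choice(4, size=cfg.genome_length, p=p)
    seq = "".join(_BASES[c] for c in seq_codes) if cfg.genome_length < 10_000 else None
    if seq is None:
        seq = np.frombuffer(b"ACGT", dtype=np.uint8)[seq_codes].tobytes().decode()
    genome = GenomeContext({cfg.chrom_name: seq})

    starts = np.arange(0, cfg.genome_length, cfg.segment_bp)
    ends = np.minimum(starts + cfg.segment_bp, cfg.genome_length)
    mids = (starts + ends) / 2.0
    values = _timing_value(mids, cfg)
    profile = pd.DataFrame({"chrom": cfg.chrom_name, "start": starts, "end": ends, "value": values})

    # analytic fork truth: timing derivative < 0 (early -> late rightward)
    deriv = -cfg.timing_amplitude * (2 * np.pi / cfg.timing_period) * np.sin(2 * np.pi * mids / cfg.timing_period)
    thr = 0.02 * np.abs(deriv).max()
    direction = np.zeros(len(mids), dtype=np.int8)
    direction[deriv <= -thr] = binning.RIGHTWARD
    direction[deriv >= thr] = binning.LEFTWARD
    fork_truth = profile.assign(slope=deriv, direction=direction)

    genes = _place_genes(cfg, values, starts, rng_genes)
    expression = _simulate_expression(cfg, len(genes), rng_expr)
    return Reference(genome, profile, genes, expression, fork_truth)


def _place_genes(cfg: SimulationConfig, seg_values, seg_starts, rng) -> pd.DataFrame:
    if cfg.n_genes == 0:
        return pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "strand"])
    z = (seg_values - seg_values.mean()) / max(seg_values.std(), 1e-12)
    w = np.exp(cfg.gene_early_assoc * z)
    w /= w.sum()
    lengths = np.clip(
        rng.lognormal(np.log(cfg.gene_len_median), cfg.gene_len_sigma, size=cfg.n_genes),
        cfg.gene_len_min, cfg.gene_len_max,
    ).astype(int)
    occupied_starts: list[int] = []
    occupied_ends: list[int] = []
    placed = []
    max_tries = 50 * cfg.n_genes
    tries = 0
    order = np.argsort(-lengths)  # longest first packs better
    for gi in order:
        L = int(lengths[gi])
        while True:
            tries += 1
            if tries > max_tries:
                raise ValueError("infeasible gene packing: too many placement failures")
            seg = rng.choice(len(seg_starts), p=w)
            start = int(seg_starts[seg] + rng.integers(0, cfg.segment_bp))
            end = start + L
            if end > cfg.genome_length:
                continue
            i = np.searchsorted(occupied_starts, start)
            if (i > 0 and occupied_ends[i - 1] > start) or (i < len(occupied_starts) and occupied_starts[i] < end):
                continue
            occupied_starts.insert(i, start)
            occupied_ends.insert(i, end)
            placed.append((gi, start, end))
            break
    placed.sort(key=lambda r: r[1])
    strands = rng.choice(["+", "-"], size=len(placed))
    return pd.DataFrame(
        {
            "gene_id": [f"g{int(i):05d}" for i, _, _ in placed],
            "chrom": cfg.chrom_name,
            "start": [s for _, s, _ in placed],
            "end": [e for _, _, e in placed],
            "strand": strands,
        }
    )


def _simulate_expression(cfg: SimulationConfig, n_genes: int, rng) -> pd.DataFrame:
    base = rng.normal(1.0, cfg.expr_log_sigma, size=n_genes)
    cols = {}
    for s in range(cfg.n_samples):
        v = np.exp(base + rng.normal(0, cfg.expr_sample_sigma, size=n_genes))
        zero = rng.random(n_genes) < cfg.expr_zero_frac
        v[zero] = 0.0
        cols[f"s{s:03d}"] = v
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# catalog simulation


class _SiteTable:
    """Static per-site attributes for one motif family on both strands."""

    def __init__(self, pos, pyr_plus, rt, fork, gene_idx, ref_base):
        self.pos = pos
        self.pyr_plus = pyr_plus
        self.rt = rt
        self.fork = fork
        self.gene_idx = gene_idx
        self.ref_base = ref_base


def _collect_sites(ref: Reference, cfg: SimulationConfig, motif_class: str, ann) -> _SiteTable:
    chrom = cfg.chrom_name
    codes = ref.genome.trimer_codes(chrom)
    plut, mlut = motif_luts(motif_class)
    valid = codes >= 0
    plus = valid & plut[np.where(valid, codes, 0)]
    minus = valid & mlut[np.where(valid, codes, 0)]
    pos = np.concatenate([np.flatnonzero(plus), np.flatnonzero(minus)])
    pyr_plus = np.concatenate([np.ones(plus.sum(), bool), np.zeros(minus.sum(), bool)])
    order = np.argsort(pos, kind="stable")
    pos, pyr_plus = pos[order], pyr_plus[order]
    enc = ref.genome.encoded(chrom)
    return _SiteTable(
        pos=pos,
        pyr_plus=pyr_plus,
        rt=ann.rt[chrom][pos],
        fork=ann.fork[chrom][pos],
        gene_idx=ann.gene[chrom][pos],
        ref_base=np.array(list(_BASES))[enc[pos]],
    )


def _truth_annotation(ref: Reference, cfg: SimulationConfig) -> binning.GenomeAnnotation:
    """Annotation built from the generator's own bins and analytic forks."""
    if ref.annotation is None:
        rt_bins = binning.make_rt_bins(ref.profile, ref.genome, n_bins=cfg.n_bins)
        ref.annotation = binning.GenomeAnnotation(ref.genome, rt_bins, ref.fork_truth, ref.genes)
    return ref.annotation


def _lagging_weight(r: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    return 1 + cfg.lagging_bias_amplitude * np.exp(
        -((r - cfg.lagging_bias_peak_bin) ** 2) / (2 * cfg.lagging_bias_width**2)
    )


def _gumbel_topk(rng, weights: np.ndarray, k: int) -> np.ndarray:
    """k distinct indices sampled with probability proportional to weights."""
    if k <= 0:
        return np.empty(0, dtype=np.int64)
    if k > np.count_nonzero(weights > 0):
        raise ValueError("demanded mutation count exceeds available sites")
    keys = np.log(np.where(weights > 0, weights, 1e-300)) + rng.gumbel(size=len(weights))
    keys[weights <= 0] = -np.inf
    return np.argpartition(keys, -k)[-k:]


def _alt_for_pyr(rng, ref_base: np.ndarray, pyr_plus: np.ndarray, pyr_alts, probs) -> np.ndarray:
    """Draw pyrimidine-strand alts and express them on the plus strand."""
    alts_p = rng.choice(pyr_alts, size=len(ref_base), p=probs)
    return np.where(pyr_plus, alts_p, [_COMP[a] for a in alts_p])


def simulate_catalog(cfg: SimulationConfig, ref: Reference):
    """Draw the cohort's mutation catalogs; returns (catalog, ground_truth).

    The catalog has 0-based positions plus truth columns (process,
    truth_strand_class); ground_truth echoes the config and realized
    per-sample counts.
    """
    ann = _truth_annotation(ref, cfg)
    ss = np.random.SeedSequence(cfg.seed).spawn(4)[3]
    sample_seeds = ss.spawn(cfg.n_samples)
    apo_sites = _collect_sites(ref, cfg, "TCN", ann)
    bgc_sites = _collect_sites(ref, cfg, "non_tcn_c", ann)
    bgt_sites = _collect_sites(ref, cfg, "NTN", ann)
    lag_site = binning.replicative_class(apo_sites.pyr_plus, apo_sites.fork) == 1
    gene_strand_plus = (ref.genes["strand"] == "+").to_numpy()
    genic = apo_sites.gene_idx >= 0
    sense_site = np.zeros(len(apo_sites.pos), bool)
    sense_site[genic] = gene_strand_plus[apo_sites.gene_idx[genic]] == apo_sites.pyr_plus[genic]

    lo, hi = cfg.apobec_fraction_range
    fracs = np.linspace(lo, hi, cfg.n_samples) if cfg.n_samples > 1 else np.array([(lo + hi) / 2])
    frames = []
    truth_samples = {}
    for si, (sid, seed) in enumerate(zip(ref.expression.columns, sample_seeds)):
        rng = np.random.default_rng(seed)
        if len(ref.genes):
            expr_scheme = binning.make_expr_bins(ref.expression[sid], n_bins=cfg.n_bins)
            gene_bin = expr_scheme.gene_bins.to_numpy()
        else:
            gene_bin = np.zeros(1, dtype=np.int8)  # unused: no genic sites exist
        n_apo = int(round(cfg.n_mutations * fracs[si]))
        n_bg = cfg.n_mutations - n_apo

        # APOBEC weights: timing gradient x lagging bias x sense bias
        r = apo_sites.rt.astype(float)
        w = np.where(r > 0, 1 + cfg.rt_gradient * (4 - r), 1.0)
        w = np.where(lag_site, w * np.where(r > 0, _lagging_weight(r, cfg), 1.0), w)
        t_site = np.where(genic, gene_bin[np.where(genic, apo_sites.gene_idx, 0)], 0)
        w = np.where(sense_site & (t_site > 0), w * (1 + cfg.sense_bias_amplitude * (t_site - 1) / 6), w)
        idx = _gumbel_topk(rng, w, n_apo)
        frames.append(_emit(rng, cfg, apo_sites, idx, sid, "apobec",
                            ["T", "G"], [cfg.apobec_ct_fraction, 1 - cfg.apobec_ct_fraction]))

        # background: late-timing-enriched, strand-neutral
        n_bg_t = int(round(n_bg * cfg.background_t_fraction))
        for sites, n_draw, alts in ((bgc_sites, n_bg - n_bg_t, None), (bgt_sites, n_bg_t, None)):
            rb = sites.rt.astype(float)
            wb = np.where(rb > 0, 1 + cfg.background_rt_gradient * (rb - 4), 1.0)
            idxb = _gumbel_topk(rng, wb, n_draw)
            pyr = "C" if sites is bgc_sites else "T"
            alt_set = [b for b in _BASES if b != pyr]
            frames.append(_emit(rng, cfg, sites, idxb, sid, "background",
                                alt_set, [1 / 3] * 3))

        # strand-coordinated clusters at TCN sites
        if cfg.n_clusters > 0:
            frames.append(_emit_clusters(rng, cfg, apo_sites, t_site, sid))
        truth_samples[sid] = {"apobec_fraction": float(fracs[si]), "n_apobec": n_apo,
                              "n_background": n_bg, "n_clusters": cfg.n_clusters}

    catalog = pd.concat(frames, ignore_index=True)
    # a site drawn twice by different processes would duplicate a position
    catalog = catalog.drop_duplicates(subset=["sample", "chrom", "pos"], keep="first")
    catalog = catalog.sort_values(["sample", "chrom", "pos"], kind="stable").reset_index(drop=True)
    truth = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in dataclasses.asdict(cfg).items()},
        "samples": truth_samples,
        "conventions": {"rightward_fork_plus_pyrimidine": "lagging"},
    }
    return catalog, truth


def _emit(rng, cfg, sites: _SiteTable, idx, sid, process, pyr_alts, probs) -> pd.DataFrame:
    idx = np.sort(idx)
    alts = _alt_for_pyr(rng, sites.ref_base[idx], sites.pyr_plus[idx], pyr_alts, probs)
    lagging = binning.replicative_class(sites.pyr_plus[idx], sites.fork[idx])
    return pd.DataFrame(
        {
            "sample": sid,
            "chrom": cfg.chrom_name,
            "pos": sites.pos[idx],
            "ref": sites.ref_base[idx],
            "alt": alts,
            "process": process,
            "truth_strand_class": np.select([lagging == 1, lagging == -1],
                                            ["lagging", "leading"], "undetermined"),
        }
    )


def _emit_clusters(rng, cfg, apo_sites: _SiteTable, t_site, sid) -> pd.DataFrame:
    r = apo_sites.rt.astype(float)
    w = np.where(r > 0, 1 + cfg.cluster_rt_bias * (4 - r), 1.0)
    w = np.where(t_site > 0, w * (1 + cfg.cluster_expr_bias * (t_site - 1) / 6), w)
    anchors = _gumbel_topk(rng, w, cfg.n_clusters)
    pos = apo_sites.pos
    chosen = []
    for a in anchors:
        k = cfg.cluster_k_min + rng.poisson(cfg.cluster_extra_poisson)
        strand = apo_sites.pyr_plus[a]
        hi = np.searchsorted(pos, pos[a] + cfg.cluster_span, side="right")
        cand = np.arange(a, hi)
        cand = cand[apo_sites.pyr_plus[cand] == strand]
        if len(cand) < 2:
            continue
        take = rng.choice(cand, size=min(k, len(cand)), replace=False)
        take = np.unique(np.concatenate(([a], take)))
        chosen.append(take)
    if not chosen:
        return pd.DataFrame(columns=["sample", "chrom", "pos", "ref", "alt", "process", "truth_strand_class"])
    idx = np.unique(np.concatenate(chosen))
    out = _emit(rng, cfg, apo_sites, idx, sid, "cluster",
                ["T", "G"], [cfg.apobec_ct_fraction, 1 - cfg.apobec_ct_fraction])
    return out


# ---------------------------------------------------------------------------
# writers


def write_reference(ref: Reference, outdir: str) -> dict:
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "fasta": os.path.join(outdir, "genome.fa"),
        "timing": os.path.join(outdir, "timing.bedgraph"),
        "genes": os.path.join(outdir, "genes.bed"),
        "expression": os.path.join(outdir, "expression.tsv"),
    }
    write_fasta(ref.genome, paths["fasta"])
    ref.profile.to_csv(paths["timing"], sep="\t", header=False, index=False,
                       float_format="%.6f")
    bed = ref.genes.assign(score=0)[["chrom", "start", "end", "gene_id", "score", "strand"]]
    bed.to_csv(paths["genes"], sep="\t", header=False, index=False)
    expr = ref.expression.copy()
    expr.insert(0, "gene_id", ref.genes["gene_id"].to_numpy())
    expr.to_csv(paths["expression"], sep="\t", index=False, float_format="%.6f")
    return paths


def write_catalog(catalog: pd.DataFrame, truth: dict, outdir: str) -> dict:
    os.makedirs(outdir, exist_ok=True)
    paths = {"mutations": os.path.join(outdir, "mutations.tsv"),
             "truth": os.path.join(outdir, "ground_truth.json")}
    out = catalog[["sample", "chrom", "pos", "ref", "alt"]].copy()
    out["pos"] = out["pos"] + 1  # MAF dialect is 1-based
    out.to_csv(paths["mutations"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
    return paths
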