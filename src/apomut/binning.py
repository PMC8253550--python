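"""Genome partitions and strand assignment.

Three partitions drive every downstream statistic:

* seven replication-timing bins with approximately equal TCN content,
  built by sorting timing segments from early (high signal) to late and
  cutting the cumulative TCN count at k/7 of the total;
* seven per-sample gene-expression bins (value septiles of log expression,
  zero-expression genes floored into bin 1);
* a fork-direction map inferred from the local derivative of the timing
  signal, from which each motif/mutation gets a lagging/leading label.

Strand convention (mirrored exactly by the simulator): in a region where the
fork moves rightward (timing decreasing with coordinate), a central
pyrimidine on the plus strand is on the LAGGING-strand template.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .refio import GenomeContext, count_motifs, motif_luts

log = logging.getLogger(__name__)

RIGHTWARD, LEFTWARD, UNDETERMINED = 1, -1, 0


def replicative_class(pyr_on_plus, fork_dir):
    """Lagging/leading label; vectorized over numpy inputs.

    Returns +1 lagging, -1 leading, 0 undetermined.
    """
    sign = np.where(pyr_on_plus, 1, -1)
    return np.asarray(fork_dir) * sign


@dataclass
class BinScheme:
    """A 7-way partition along one axis (replication timing or expression)."""

    axis: str
    n_bins: int
    segments: pd.DataFrame | None = None     # timing axis: chrom,start,end,value,bin
    gene_bins: pd.Series | None = None       # expression axis: gene_id -> bin
    n_motif_per_bin: np.ndarray | None = None
    bp_per_bin: np.ndarray | None = None
    degenerate: bool = False


def _bin_counts(cum: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    edges = np.concatenate(([0], cum[cuts], [cum[-1]]))
    return np.diff(edges)


def _repair_cuts(cum: np.ndarray, cuts: np.ndarray, max_rounds: int = 200) -> np.ndarray:
    """Nudge cut boundaries by one segment while that shrinks the count spread."""
    cuts = cuts.copy()
    n = len(cum)
    for _ in range(max_rounds):
        counts = _bin_counts(cum, cuts)
        spread = counts.max() - counts.min()
        best = None
        for i in range(len(cuts)):
            lo = cuts[i - 1] + 1 if i > 0 else 0
            hi = cuts[i + 1] - 1 if i + 1 < len(cuts) else n - 2
            for cand in (cuts[i] - 1, cuts[i] + 1):
                if not lo <= cand <= hi:
                    continue
                trial = cuts.copy()
                trial[i] = cand
                c = _bin_counts(cum, trial)
                s = c.max() - c.min()
                if s < spread and (best is None or s < best[0]):
                    best = (s, trial)
        if best is None:
            return cuts
        cuts = best[1]
    return cuts


def make_rt_bins(profile: pd.DataFrame, genome: GenomeContext, n_bins: int = 7) -> BinScheme:
    """Partition timing segments into ``n_bins`` groups of ~equal TCN content.

    Segments are ordered by timing value descending (bin 1 = earliest); each
    cut is placed at the segment boundary whose cumulative TCN count is
    nearest k/7 of the total, so per-bin counts differ by at most one
    segment's worth.
    """
    if profile["value"].nunique() < n_bins:
        raise ValueError("degenerate axis: too few distinct timing values")
    seg = profile.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    tcn = count_motifs(genome, seg, "TCN", per_interval=True)
    order = np.lexsort((np.arange(len(seg)), -seg["value"].to_numpy()))
    cum = np.cumsum(tcn[order])
    total = int(cum[-1])
    if total == 0:
        raise ValueError("no TCN motifs in covered territory")
    targets = total * np.arange(1, n_bins) / n_bins
    # boundary after segment j means cum[j] motifs on the early side; round
    # each boundary to the nearest achievable cumulative count
    cuts = np.empty(n_bins - 1, dtype=np.int64)
    for i, target in enumerate(targets):
        j = int(np.searchsorted(cum, target))
        if j > 0 and (j >= len(cum) or target - cum[j - 1] <= cum[j] - target):
            j -= 1
        cuts[i] = j
    for i in range(1, n_bins - 1):  # keep cuts strictly increasing
        cuts[i] = max(cuts[i], cuts[i - 1] + 1)
    cuts = _repair_cuts(cum, cuts)
    bins_sorted = 1 + np.searchsorted(cuts, np.arange(len(seg)), side="left").astype(np.int8)
    bins = np.empty(len(seg), dtype=np.int8)
    bins[order] = bins_sorted
    seg = seg.assign(bin=bins, n_tcn=tcn)
    n_per = np.zeros(n_bins, dtype=np.int64)
    bp_per = np.zeros(n_bins, dtype=np.int64)
    np.add.at(n_per, bins - 1, tcn)
    np.add.at(bp_per, bins - 1, (seg["end"] - seg["start"]).to_numpy())
    return BinScheme("replication_timing", n_bins, segments=seg,
                     n_motif_per_bin=n_per, bp_per_bin=bp_per)


def make_expr_bins(expression: pd.Series, n_bins: int = 7) -> BinScheme:
    """Per-sample expression septiles on log(TPM), zeros floored into bin 1.

    Bin 7 is the highest-expression bin.  Equal values always share a bin;
    an all-constant sample is returned with ``degenerate=True`` and must be
    excluded from slope estimation.
    """
    if (expression < 0).any():
        raise ValueError("negative expression value")
    if (expression == 0).all():
        raise ValueError("all-zero expression")
    nz = expression[expression > 0]
    logv = np.log(nz.to_numpy(dtype=float))
    edges = np.quantile(logv, np.arange(1, n_bins) / n_bins)
    bins = pd.Series(1, index=expression.index, dtype=np.int8)
    bins.loc[nz.index] = 1 + np.searchsorted(edges, logv, side="left").astype(np.int8)
    degenerate = bins.nunique() == 1
    return BinScheme("expression", n_bins, gene_bins=bins, degenerate=degenerate)


def infer_fork_map(profile: pd.DataFrame, window_bp: int = 100_000,
                   derivative_threshold: float | None = None) -> pd.DataFrame:
    """Assign a replication-fork direction to every timing segment.

    The local timing derivative is the least-squares slope of segment values
    against segment midpoints over a sliding ±window/2 window.  Decreasing
    timing (early to late moving right) means a rightward-moving fork.
    Segments with |derivative| below the threshold (default: 20% of the
    cohort median absolute derivative) are left undetermined and excluded
    from strand analyses.
    """
    out = []
    for chrom, sub in profile.groupby("chrom", sort=False):
        sub = sub.sort_values("start", kind="stable").reset_index(drop=True)
        m = ((sub["start"] + sub["end"]) / 2.0).to_numpy()
        y = sub["value"].to_numpy(dtype=float)
        lo = np.searchsorted(m, m - window_bp / 2, side="left")
        hi = np.searchsorted(m, m + window_bp / 2, side="right")
        cx = np.concatenate(([0.0], np.cumsum(m)))
        cy = np.concatenate(([0.0], np.cumsum(y)))
        cxy = np.concatenate(([0.0], np.cumsum(m * y)))
        cxx = np.concatenate(([0.0], np.cumsum(m * m)))
        n = (hi - lo).astype(float)
        sx = cx[hi] - cx[lo]
        sy = cy[hi] - cy[lo]
        sxy = cxy[hi] - cxy[lo]
        sxx = cxx[hi] - cxx[lo]
        denom = n * sxx - sx * sx
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.where(denom > 0, (n * sxy - sx * sy) / denom, np.nan)
        out.append(sub.assign(slope=slope))
    fm = pd.concat(out, ignore_index=True)
    if derivative_threshold is None:
        derivative_threshold = 0.2 * float(np.nanmedian(np.abs(fm["slope"])))
    d = np.zeros(len(fm), dtype=np.int8)
    d[fm["slope"].to_numpy() <= -derivative_threshold] = RIGHTWARD
    d[fm["slope"].to_numpy() >= derivative_threshold] = LEFTWARD
    fm["direction"] = d
    fm.attrs["derivative_threshold"] = derivative_threshold
    return fm


# ---------------------------------------------------------------------------
# position-level annotation


class GenomeAnnotation:
    """Per-base lookup arrays tying positions to bins, forks and genes.

    ``rt[pos]`` is the timing bin (1..7, 0 = uncovered); ``fork[pos]`` is
    +1/-1/0; ``gene[pos]`` is the row index into ``genes`` (-1 intergenic,
    -2 covered by more than one gene, excluded as ambiguous).
    """

    def __init__(self, genome: GenomeContext, rt_bins: BinScheme,
                 fork_map: pd.DataFrame | None = None, genes: pd.DataFrame | None = None):
        self.genome = genome
        self.rt_bins = rt_bins
        self.n_bins = rt_bins.n_bins
        self.genes = genes.reset_index(drop=True) if genes is not None else None
        self._memo: dict = {}
        self.rt: dict[str, np.ndarray] = {}
        self.fork: dict[str, np.ndarray] = {}
        self.gene: dict[str, np.ndarray] = {}
        for chrom in genome.chrom_names:
            L = genome.length(chrom)
            self.rt[chrom] = np.zeros(L, dtype=np.int8)
            self.fork[chrom] = np.zeros(L, dtype=np.int8)
            self.gene[chrom] = np.full(L, -1, dtype=np.int32)
        for _, s in rt_bins.segments.groupby("chrom", sort=False):
            chrom = s["chrom"].iloc[0]
            arr = self.rt[chrom]
            for st, en, b in zip(s["start"], s["end"], s["bin"]):
                arr[st:en] = b
        if fork_map is not None:
            for chrom, s in fork_map.groupby("chrom", sort=False):
                arr = self.fork[chrom]
                for st, en, d in zip(s["start"], s["end"], s["direction"]):
                    arr[st:en] = d
        if genes is not None:
            cover: dict[str, np.ndarray] = {
                c: np.zeros(genome.length(c), dtype=np.uint8) for c in genome.chrom_names
            }
            for i, g in self.genes.iterrows():
                cover[g["chrom"]][g["start"]:g["end"]] += 1
                self.gene[g["chrom"]][g["start"]:g["end"]] = i
            for chrom in genome.chrom_names:
                self.gene[chrom][cover[chrom] > 1] = -2

    # -- exposures (memoized: tables are reused across samples) ------------

    def memo(self, key, fn):
        if key not in self._memo:
            self._memo[key] = fn()
        return self._memo[key]

    def _masks(self, chrom: str, motif_class: str):
        codes = self.genome.trimer_codes(chrom)
        plut, mlut = motif_luts(motif_class)
        valid = codes >= 0
        return valid & plut[np.where(valid, codes, 0)], valid & mlut[np.where(valid, codes, 0)]

    def rt_exposures(self, motif_class: str = "TCN") -> np.ndarray:
        """Motif count (both strands) per timing bin; index 0 = bin 1."""
        out = np.zeros(self.n_bins + 1, dtype=np.int64)
        for chrom in self.genome.chrom_names:
            p, m = self._masks(chrom, motif_class)
            w = p.astype(np.int64) + m
            out += np.bincount(self.rt[chrom], weights=w, minlength=self.n_bins + 1).astype(np.int64)
        return out[1:]

    def rep_strand_exposures(self, motif_class: str = "TCN") -> pd.DataFrame:
        """Per-bin motif exposure on the lagging and leading strands."""
        lag = np.zeros(self.n_bins + 1, dtype=np.int64)
        lead = np.zeros(self.n_bins + 1, dtype=np.int64)
        for chrom in self.genome.chrom_names:
            p, m = self._masks(chrom, motif_class)
            fork = self.fork[chrom]
            rt = self.rt[chrom]
            lag_mask = ((fork == RIGHTWARD) & p) | ((fork == LEFTWARD) & m)
            lead_mask = ((fork == RIGHTWARD) & m) | ((fork == LEFTWARD) & p)
            lag += np.bincount(rt[lag_mask], minlength=self.n_bins + 1)
            lead += np.bincount(rt[lead_mask], minlength=self.n_bins + 1)
        return pd.DataFrame({"bin": np.arange(1, self.n_bins + 1), "lagging": lag[1:], "leading": lead[1:]})

    def gene_strand_exposures(self, motif_class: str = "TCN") -> pd.DataFrame:
        """Per-gene motif exposure on the sense and antisense strands."""
        ng = len(self.genes)
        sense = np.zeros(ng, dtype=np.int64)
        anti = np.zeros(ng, dtype=np.int64)
        strand_plus = (self.genes["strand"] == "+").to_numpy()
        for chrom in self.genome.chrom_names:
            p, m = self._masks(chrom, motif_class)
            gi = self.gene[chrom]
            inside = gi >= 0
            for mask, on_plus in ((p, True), (m, False)):
                sel = inside & mask
                cnt = np.bincount(gi[sel], minlength=ng)
                # central pyrimidine on the coding strand => sense
                sense += np.where(strand_plus == on_plus, cnt, 0)
                anti += np.where(strand_plus == on_plus, 0, cnt)
        return pd.DataFrame({"gene_idx": np.arange(ng), "sense": sense, "antisense": anti})

    def gene_rt_exposures(self, motif_class: str = "TCN") -> np.ndarray:
        """(n_genes, n_bins) motif counts within each gene split by timing bin."""
        ng = len(self.genes)
        out = np.zeros(ng * (self.n_bins + 1), dtype=np.int64)
        for chrom in self.genome.chrom_names:
            p, m = self._masks(chrom, motif_class)
            gi = self.gene[chrom]
            sel = (gi >= 0) & (p | m)
            key = gi[sel].astype(np.int64) * (self.n_bins + 1) + self.rt[chrom][sel]
            w = (p.astype(np.int64) + m)[sel]
            out += np.bincount(key, weights=w, minlength=len(out)).astype(np.int64)
        return out.reshape(ng, self.n_bins + 1)[:, 1:]

    def gene_rt_bp(self) -> np.ndarray:
        """(n_genes, n_bins) base-pair content of each gene per timing bin."""
        ng = len(self.genes)
        out = np.zeros(ng * (self.n_bins + 1), dtype=np.int64)
        for chrom in self.genome.chrom_names:
            gi = self.gene[chrom]
            sel = gi >= 0
            key = gi[sel].astype(np.int64) * (self.n_bins + 1) + self.rt[chrom][sel]
            out += np.bincount(key, minlength=len(out))
        return out.reshape(ng, self.n_bins + 1)[:, 1:]

    def territory_exposures(self, motif_class: str = "TCN") -> dict[str, int]:
        """Motif counts in genic vs intergenic territory (ambiguous excluded)."""
        genic = inter = 0
        for chrom in self.genome.chrom_names:
            p, m = self._masks(chrom, motif_class)
            both = p.astype(np.int64) + m
            gi = self.gene[chrom]
            genic += int(both[gi >= 0].sum())
            inter += int(both[gi == -1].sum())
        return {"genic": genic, "intergenic": inter}


def label_mutations(catalog: pd.DataFrame, ann: GenomeAnnotation) -> pd.DataFrame:
    """Attach rt_bin, replication-strand and transcription-strand labels.

    rep_class: 'lagging' / 'leading' / 'undetermined';
    tx_class: 'sense' / 'antisense' / 'intergenic' / 'ambiguous'.
    """
    out = catalog.copy()
    rt = np.zeros(len(out), dtype=np.int8)
    fork = np.zeros(len(out), dtype=np.int8)
    gidx = np.full(len(out), -1, dtype=np.int64)
    for chrom, sub in out.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        rt[sub.index] = ann.rt[chrom][pos]
        fork[sub.index] = ann.fork[chrom][pos]
        if ann.genes is not None:
            gidx[sub.index] = ann.gene[chrom][pos]
    out["rt_bin"] = rt
    rc = replicative_class(out["pyr_strand"].to_numpy() == "+", fork)
    out["rep_class"] = np.select([rc == 1, rc == -1], ["lagging", "leading"], "undetermined")
    out["gene_idx"] = gidx
    if ann.genes is not None:
        strand_plus = (ann.genes["strand"] == "+").to_numpy()
        in_gene = gidx >= 0
        g = np.where(in_gene, gidx, 0)
        sense = strand_plus[g] == (out["pyr_strand"].to_numpy() == "+")
        out["tx_class"] = np.select(
            [gidx == -2, in_gene & sense, in_gene & ~sense],
            ["ambiguous", "sense", "antisense"],
            "intergenic",
        )
    else:
        out["tx_class"] = "intergenic"
    return out


def filter_expression_samples(labeled: pd.DataFrame, min_in_gene: int = 600) -> list[str]:
    """Samples retained for expression-axis analyses (>= 600 in-gene SBS)."""
    counts = labeled[labeled["gene_idx"] >= 0].groupby("sample").size()
    kept = [s for s in labeled["sample"].unique() if counts.get(s, 0) >= min_in_gene]
    dropped = set(labeled["sample"].unique()) - set(kept)
    if dropped:
        log.info("filter_expression_samples: excluded %d samples", len(dropped))
    return kept
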