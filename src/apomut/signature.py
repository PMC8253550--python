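"""APOBEC signature classification and per-sample fold enrichment.

The APOBEC signature used throughout is C→T / C→G at TCN (pyrimidine
oriented).  Sample-level APOBEC activity is summarized by the TCW fold
enrichment of Roberts et al.: signature-context mutation counts relative to
the availability of the signature context in the ±20 bp sequence around each
mutated cytosine.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .refio import GenomeContext, motif_luts

log = logging.getLogger(__name__)

APOBEC_TCN = "APOBEC_TCN"
OTHER_C = "OTHER_C"
NON_C = "NON_C"

_TCN = {"TCA", "TCC", "TCG", "TCT"}
_TCW = {"TCA", "TCT"}


def classify_sbs(pyr_context: str, pyr_alt: str) -> str:
    """Signature category of one SBS with defined pyrimidine context."""
    if not pyr_context:
        raise ValueError("undefined context; pre-filter records with context_ok")
    if pyr_context[1] == "T":
        return NON_C
    if pyr_context in _TCN and pyr_alt in "TG":
        return APOBEC_TCN
    return OTHER_C


def classify_catalog(df: pd.DataFrame) -> pd.DataFrame:
    """Add category / is_apobec / is_tcw columns to an annotated catalog.

    Records with undefined context get category "" and are excluded from all
    motif-normalized statistics (they still count toward raw load).
    """
    out = df.copy()
    ctx = out["pyr_context"].to_numpy()
    alt = out["pyr_alt"].to_numpy()
    ok = out["context_ok"].to_numpy()
    central_t = np.array([c[1] == "T" if c else False for c in ctx])
    in_tcn = np.isin(ctx, list(_TCN))
    apo = in_tcn & np.isin(alt, ["T", "G"])
    cat = np.where(~ok, "", np.where(central_t, NON_C, np.where(apo, APOBEC_TCN, OTHER_C)))
    out["category"] = cat
    out["is_apobec"] = apo & ok
    out["is_tcw"] = out["is_apobec"] & np.isin(ctx, list(_TCW))
    return out


def apobec_enrichment(sample_df: pd.DataFrame, genome: GenomeContext, window: int = 20) -> float:
    """TCW fold enrichment E of one sample's catalog.

    E = (m_TCW * c_C) / (m_C * c_TCW) with mutation counts m over C→T/C→G
    events and context counts c taken in ±``window`` bases around each
    mutated cytosine, on both strands, with per-mutation multiplicity.
    Returns NaN when the sample has no cytosine mutations.
    """
    ok = sample_df["context_ok"].to_numpy()
    ctx = sample_df["pyr_context"].to_numpy()
    alt = sample_df["pyr_alt"].to_numpy()
    at_c = ok & np.array([bool(c) and c[1] == "C" for c in ctx])
    cyt_mut = at_c & np.isin(alt, ["T", "G"])
    m_c = int(cyt_mut.sum())
    if m_c == 0:
        return float("nan")
    m_tcw = int((cyt_mut & np.isin(ctx, list(_TCW))).sum())
    tcw_plus, tcw_minus = motif_luts("TCW")
    c_tcw = 0
    c_c = 0
    muts = sample_df[cyt_mut]
    for chrom, sub in muts.groupby("chrom", sort=False):
        codes = genome.trimer_codes(chrom)
        enc = genome.encoded(chrom)
        tcw_mask = np.where(codes >= 0, tcw_plus[codes] | tcw_minus[codes], False)
        c_mask = (enc == 1) | (enc == 2)  # C on either strand
        ct = np.concatenate(([0], np.cumsum(tcw_mask, dtype=np.int32)))
        cc = np.concatenate(([0], np.cumsum(c_mask, dtype=np.int32)))
        pos = sub["pos"].to_numpy()
        lo = np.clip(pos - window, 0, len(enc))
        hi = np.clip(pos + window + 1, 0, len(enc))
        c_tcw += int((ct[hi] - ct[lo]).sum())
        c_c += int((cc[hi] - cc[lo]).sum())
    if c_tcw == 0:
        log.warning("apobec_enrichment: no TCW context around mutations; E undefined")
        return float("nan")
    if m_tcw == 0:
        return 0.0
    return (m_tcw * c_c) / (m_c * c_tcw)


def sample_summaries(catalog: pd.DataFrame, genome: GenomeContext, window: int = 20) -> pd.DataFrame:
    """Per-sample counts and enrichment for a classified catalog."""
    rows = []
    for sid, sub in catalog.groupby("sample", sort=True):
        rows.append(
            {
                "sample": sid,
                "n_sbs": len(sub),
                "n_apobec_tcn": int(sub["is_apobec"].sum()),
                "n_apobec_tcw": int(sub["is_tcw"].sum()),
                "enrichment": apobec_enrichment(sub, genome, window=window),
            }
        )
    return pd.DataFrame(rows)


def select_samples(summaries: pd.DataFrame, threshold: float = 2.0,
                   very_high: float = 2.5, very_low: float = 1.5) -> pd.DataFrame:
    """Partition samples by enrichment (strict > threshold for "enriched").

    Samples with undefined enrichment are dropped from enrichment-stratified
    analyses.
    """
    out = summaries.copy()
    e = out["enrichment"]
    out["apobec_enriched"] = e > threshold
    out["group"] = np.select([e > very_high, e < very_low], ["very_high", "very_low"], default="mid")
    out.loc[e.isna(), ["apobec_enriched", "group"]] = [False, "undefined"]
    return out
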