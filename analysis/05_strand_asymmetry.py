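"""Replicative and transcriptional strand asymmetry of APOBEC mutations.

Per enriched sample: lagging/leading density ratio per timing bin (with
low-enrichment non-TCN cytosine mutations as control), the pooled profile
with the curvature shuffle test for the mid-timing peak, sense/antisense
ratios over expression bins, Mann-Whitney group comparisons, and the
co-direction (replication vs transcription) contrast.
"""

import json
import os
import sys

import numpy as np
import pandas as pd

from _shared import RESULTS_DIR, annotate, load_selection, load_sim, save

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))
from apomut import asymmetry, binning  # noqa: E402


def main():
    genome, profile, genes, expression, catalog = load_sim()
    selection = load_selection()
    ann, labeled = annotate(genome, profile, genes, catalog)
    enriched = set(selection.loc[selection["apobec_enriched"], "sample"])

    rep_rows, tx_rows = [], []
    pooled_lag = np.zeros(7, dtype=np.int64)
    pooled_lead = np.zeros(7, dtype=np.int64)
    schemes = {}
    for sid, sub in labeled.groupby("sample"):
        sub = sub.reset_index(drop=True)
        apo = asymmetry.replication_strand_profile(sub, ann, "apobec")
        ctl = asymmetry.replication_strand_profile(sub, ann, "non_tcn_c")
        rep_rows.append({"sample": sid, "enriched": sid in enriched,
                         "ratio_apobec": asymmetry.mean_ratio(apo),
                         "ratio_control": asymmetry.mean_ratio(ctl)})
        if sid in enriched:
            pooled_lag += apo["n_lagging"].to_numpy()
            pooled_lead += apo["n_leading"].to_numpy()
        scheme = binning.make_expr_bins(expression[sid])
        schemes[sid] = scheme
        txa = asymmetry.transcription_strand_profile(sub, ann, scheme, "apobec")
        txc = asymmetry.transcription_strand_profile(sub, ann, scheme, "non_tcn_c")
        tx_rows.append({"sample": sid, "enriched": sid in enriched,
                        "ratio_apobec": asymmetry.mean_ratio(txa),
                        "ratio_control": asymmetry.mean_ratio(txc)})
    rep = pd.DataFrame(rep_rows)
    tx = pd.DataFrame(tx_rows)
    save(rep, "replication_ratios.tsv")
    save(tx, "transcription_ratios.tsv")

    exp = ann.rep_strand_exposures("TCN")
    pooled = pd.DataFrame({"bin": np.arange(1, 8), "n_lagging": pooled_lag,
                           "n_leading": pooled_lead,
                           "m_lagging": exp["lagging"], "m_leading": exp["leading"]})
    pooled["ratio"] = (pooled["n_lagging"] / pooled["m_lagging"]) / (
        pooled["n_leading"] / pooled["m_leading"])
    save(pooled, "lagging_profile_pooled.tsv")
    curv = asymmetry.curvature_shuffle_test(pooled, n_shuffles=10_000, seed=1)

    rep_cmp = asymmetry.group_ratio_comparison(
        rep.loc[rep["enriched"], "ratio_apobec"], rep.loc[~rep["enriched"], "ratio_control"])
    tx_cmp = asymmetry.group_ratio_comparison(
        tx.loc[tx["enriched"], "ratio_apobec"], tx.loc[~tx["enriched"], "ratio_control"])
    table, codir_p = asymmetry.codirection_contrast(labeled, ann, schemes)
    save(table, "codirection_slopes.tsv")

    out = {
        "lagging_leading": rep_cmp, "sense_antisense": tx_cmp,
        "peak_bin": int(pooled["ratio"].idxmax()) + 1,
        "curvature": {"observed": curv.observed, "null_mean": curv.null_mean,
                      "null_sd": curv.null_sd, "p_gaussian": curv.p_gaussian,
                      "p_empirical": curv.p_empirical, "n_shuffles": curv.n_shuffles},
        "codirection_wilcoxon_p": codir_p,
    }
    with open(os.path.join(RESULTS_DIR, "asymmetry.json"), "w") as fh:
        json.dump(out, fh, indent=1)
    print(f"lagging/leading mean ratio: {rep_cmp['mean_a']:.2f} (enriched) vs "
          f"{rep_cmp['mean_b']:.2f} (control), MWW p = {rep_cmp['p']:.1e}")
    print(f"pooled profile peaks at bin {out['peak_bin']} "
          f"(ratio {pooled['ratio'].max():.2f}); curvature p = {curv.p_gaussian:.1e}")
    print(f"sense/antisense mean ratio: {tx_cmp['mean_a']:.2f} vs {tx_cmp['mean_b']:.2f}, "
          f"MWW p = {tx_cmp['p']:.1e}")
    print(f"co-direction contrast Wilcoxon p = {codir_p:.3f}")


if __name__ == "__main__":
    main()
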