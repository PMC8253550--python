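"""Classify SBS by APOBEC signature and stratify samples by fold enrichment.

Writes results/sample_selection.tsv (per-sample counts, TCW fold enrichment
E, the E > 2.0 enrichment flag, and the very-high / very-low strata used by
the regression contrast).
"""

from _shared import load_sim, save

import sys, os
sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))
from apomut import signature  # noqa: E402


def main():
    genome, profile, genes, expression, catalog = load_sim()
    summaries = signature.sample_summaries(catalog, genome)
    selection = signature.select_samples(summaries)
    save(selection, "sample_selection.tsv")
    n = len(selection)
    print(f"{n} samples; enrichment {selection['enrichment'].min():.2f}"
          f"-{selection['enrichment'].max():.2f}")
    print(selection["group"].value_counts().to_string())
    print(f"APOBEC-enriched (E > 2.0): {int(selection['apobec_enriched'].sum())}/{n}")


if __name__ == "__main__":
    main()
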