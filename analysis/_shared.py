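"""Shared loading helpers for the numbered analysis drivers.

`01_simulate.py` writes the synthetic cohort under results/sim; the other
drivers read those files back through the standard-format readers, so the
whole chain exercises the same I/O paths a real dataset would use.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from apomut import binning, refio, signature  # noqa: E402
from apomut.pipeline import RunConfig, build_annotation  # noqa: E402

SIM_DIR = os.path.join(os.path.dirname(__file__), "..", "results", "sim")
RESULTS_DIR = os.path.join(os.path.dirname(__file__), "..", "results")


def load_sim(simdir: str = SIM_DIR):
    if not os.path.exists(os.path.join(simdir, "genome.fa")):
        raise SystemExit("run analysis/01_simulate.py first (no simulated cohort found)")
    genome = refio.read_fasta(os.path.join(simdir, "genome.fa"))
    profile = refio.read_bedgraph(os.path.join(simdir, "timing.bedgraph"))
    genes = refio.read_genes(os.path.join(simdir, "genes.bed"))
    expression = pd.read_csv(os.path.join(simdir, "expression.tsv"), sep="\t").drop(columns=["gene_id"])
    catalog, _ = refio.read_mutations(os.path.join(simdir, "mutations.tsv"), genome)
    catalog = signature.classify_catalog(catalog)
    return genome, profile, genes, expression, catalog


def annotate(genome, profile, genes, catalog, cfg: RunConfig | None = None):
    cfg = cfg or RunConfig()
    ann = build_annotation(genome, profile, genes, cfg)
    labeled = binning.label_mutations(catalog, ann)
    return ann, labeled


def load_selection():
    path = os.path.join(RESULTS_DIR, "sample_selection.tsv")
    if not os.path.exists(path):
        raise SystemExit("run analysis/02_classify_samples.py first")
    return pd.read_csv(path, sep="\t")


def save(df, name):
    os.makedirs(RESULTS_DIR, exist_ok=True)
    path = os.path.join(RESULTS_DIR, name)
    df.to_csv(path, sep="\t", index=False)
    print(f"wrote {path}")
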