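"""Shared fixtures: tiny handcrafted genomes and a small simulated cohort.

All fixture data are generated programmatically; the small cohort is sized
so the whole unit suite stays in the seconds range while every estimator
still has enough counts to be meaningfully exercised.
"""

import numpy as np
import pandas as pd
import pytest

from apomut import binning, pipeline, refio, signature
from apomut.synthetic_data import SimulationConfig, generate_reference, simulate_catalog


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(
        seed=11,
        genome_length=4_000_000,
        n_genes=800,
        gene_len_median=2_000,
        gene_len_max=8_000,
        n_samples=4,
        n_mutations=12_000,
        n_clusters=0,
    )


@pytest.fixture(scope="session")
def small_ref(small_cfg):
    return generate_reference(small_cfg)


@pytest.fixture(scope="session")
def small_catalog(small_cfg, small_ref):
    catalog, truth = simulate_catalog(small_cfg, small_ref)
    catalog = pipeline.prepare_catalog(catalog, small_ref.genome)
    return catalog


@pytest.fixture(scope="session")
def small_annotation(small_cfg, small_ref):
    cfg = pipeline.RunConfig()
    return pipeline.build_annotation(small_ref.genome, small_ref.profile, small_ref.genes, cfg)


@pytest.fixture(scope="session")
def small_labeled(small_catalog, small_annotation):
    return binning.label_mutations(small_catalog, small_annotation)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort simulated without any injected effect (flat rates, no biases)."""
    cfg = SimulationConfig(
        seed=23,
        genome_length=2_000_000,
        n_genes=300,
        n_samples=3,
        n_mutations=8_000,
        n_clusters=0,
        rt_gradient=0.0,
        lagging_bias_amplitude=0.0,
        sense_bias_amplitude=0.0,
        background_rt_gradient=0.0,
    )
    ref = generate_reference(cfg)
    catalog, _ = simulate_catalog(cfg, ref)
    catalog = pipeline.prepare_catalog(catalog, ref.genome)
    return cfg, ref, catalog


def random_genome(rng, length, gc=0.4, name="chr1"):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list("ACGT"), size=length, p=p))
    return refio.GenomeContext({name: seq})
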