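# apomut

Quantifying how DNA replication and transcription shape APOBEC mutagenesis
in cancer genomes.

APOBEC cytidine deaminases attack single-stranded DNA and leave a
characteristic somatic footprint: C→T and C→G substitutions at TpC
dinucleotides (the **TCN** trinucleotide signature, written on the
pyrimidine strand). Single-stranded DNA is exposed both behind replication
forks (preferentially on the lagging-strand template) and during
transcription (on the coding/sense strand), so the density of
APOBEC-induced mutations carries information about which cellular process
exposed the substrate. `apomut` implements the full quantitative toolkit
for reading that information out of a somatic SBS catalog:

- **Signature classification and sample selection.** Every SBS is oriented
  on its pyrimidine strand and classified (APOBEC `TCN` C→T/C→G, other
  cytosine SBS, thymine SBS). Per-sample APOBEC activity is summarized by
  the TCW fold enrichment
  `E = (m_TCW · c_C) / (m_C · c_TCW)`,
  with mutation counts `m` over C→T/C→G events and context counts `c`
  taken within ±20 bp of each mutated cytosine; samples with `E > 2.0`
  count as APOBEC-enriched.
- **Motif-normalized densities.** The genome is partitioned into seven
  replication-timing bins holding approximately equal numbers of TCN
  motifs (bin 1 = earliest), and genes into seven per-sample expression
  septiles (bin 7 = highest). Per bin,
  `D_APOBEC = N_APOBEC / N_TCN`, the background density `D_NCN` uses SBS at
  non-TCN cytosines over such sites, and the relative density is
  `RD = D_APOBEC − D_NCN`. Trends are OLS slopes of RD against bin index.
- **Strand asymmetry.** Fork direction is inferred from the local
  derivative of the timing profile (timing falling to the right ⇒
  rightward fork ⇒ plus-strand pyrimidines on the lagging template);
  lagging/leading and sense/antisense density ratios are computed per bin
  and per sample. The mid-timing peak of the lagging/leading profile is
  tested by shuffling mutations between strands within each timing bin and
  refitting a parabola — the quadratic coefficient's Gaussian tail over
  the shuffle null gives the p-value.
- **Kataegis-like clusters.** Runs of ≥ 2 mutations with neighbor gaps
  ≤ 10 kb are candidate clusters; under uniform random placement the span
  of k mutations follows a negative-binomial law
  `p = P(NB(k−1, n/G) ≤ d − (k−1))`, and candidates with `p ≤ 10⁻⁴` are
  kept. A cluster is APOBEC only if *all* members carry the signature.
- **Two-factor model.** Per sample, the normalized relative density
  `NRD(r,t) = RD(r,t) / Σ RD` over the 7×7 (timing × expression) grid is
  fitted as `NRD = β₀ + β₁ r + β₂ t + ε`; relative importance of the two
  drivers is decomposed by LMG and type II ANOVA.

Real cohorts (WGS mutation calls, Repli-Seq timing, RSEM expression) are
consumed through standard formats: FASTA, MAF-lite TSV / minimal VCF,
bedGraph, BED6/GFF3, TSV expression matrices. Because such data are bulky
and access-controlled, the package ships a first-class synthetic-data
module that generates genomes, timing waves, genes with expression and
mutation catalogs with *known* ground truth for every effect the pipeline
estimates — all tests and the acceptance script run on it.

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
30-sample cohort (20 Mb genome, 2 000 genes, ~40 000 SBS per sample):

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_classify_samples.py
python analysis/03_timing_density.py
```

which prints

```
cohort: 30 samples, 1205928 SBS (40186-40209 per sample) on a 20 Mb genome
30 samples; enrichment 0.55-2.97
APOBEC-enriched (E > 2.0): 20/30
RD slope over timing negative in 30/30 samples
slope-vs-enrichment trend: k = -7.622e-04 (p = 2.12e-16) over 30 samples
```

i.e. every sample shows the early-replication excess of APOBEC mutations,
and the excess steepens with APOBEC activity (negative trend of the RD
slope against enrichment). The remaining drivers continue the narrative —
`05_strand_asymmetry.py` reports

```
lagging/leading mean ratio: 1.26 (enriched) vs 1.00 (control), MWW p = 1.2e-05
pooled profile peaks at bin 3 (ratio 1.50); curvature p = 1.8e-240
sense/antisense mean ratio: 1.29 vs 1.00, MWW p = 1.2e-05
```

(the lagging-strand excess peaks in mid-replicating territory, exactly
where the generator put it), and `07_model.py` closes with the two-factor
regression:

```
30 samples fitted; mean b1 (timing) = -5.44e-03, mean b2 (expression) = 9.58e-04
very_high: expression coefficient significant in 13/13 samples (100%)
very_low: expression coefficient significant in 1/6 samples (17%)
```

The same pipeline is scriptable through the `apomut` CLI
(`apomut simulate`, `apomut run`, plus per-stage subcommands), which writes
the same TSV/JSON artifacts from files on disk.

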