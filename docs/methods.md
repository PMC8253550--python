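# Methods

## Coordinates, orientation and the signature

All internal coordinates are 0-based half-open; MAF-lite (1-based) and GFF3
inputs are converted at the boundary and indels are dropped at intake with
a counter. Every SBS is re-expressed on the strand whose mutated base is a
pyrimidine; the 3-mer context is taken from the reference around the
mutated base and reverse-complemented when the reference base is a purine.
Records whose 3-mer window leaves the chromosome or touches an N keep
their place in raw load counts but are excluded from all motif-normalized
statistics, so numerators and denominators always refer to the same site
universe. The APOBEC signature is C→T/C→G at TCN. The category
`OTHER_C` (all remaining cytosine SBS) is broader than the background
*density* control: `D_NCN` is site-based — SBS at non-TCN cytosines over
non-TCN cytosine sites — so C→A events at TCN sites enter neither its
numerator nor its denominator.

Sample-level APOBEC activity is the TCW fold enrichment
`E = (m_TCW·c_C)/(m_C·c_TCW)` with context counts taken in ±20 bp windows
around each mutated cytosine, both strands, windows counted per mutation
(overlaps with multiplicity). The window size is configurable; 20 bp is
the default. Enrichment stratification uses strict thresholds: enriched
`E > 2.0`, very high `E > 2.5`, very low `E < 1.5`. Samples without
cytosine mutations have undefined `E` and drop out of stratified analyses.

## Bins

**Replication timing.** Timing segments (bedGraph, higher = earlier) are
ordered by value descending and cut into seven consecutive groups whose
cumulative TCN counts are as equal as possible: each cut is rounded to the
segment boundary nearest k/7 of the total, followed by a local repair pass
that nudges boundaries by one segment while that shrinks the max−min
spread. On 1 kb segments this keeps the per-bin spread within one
segment's TCN count. Bins are intervals of the timing *value* axis, not
genomic order; bin 1 is earliest.

**Expression.** Per sample, genes with zero expression all go to bin 1 and
the remaining genes are split by value septiles of log expression
(equal values always share a bin; an all-constant sample is flagged
degenerate and excluded from slope estimation). Bin 7 is highest.

**Fork direction.** The local timing derivative is the least-squares slope
of segment values against midpoints in a sliding 100 kb window. Falling
timing (early → late moving right) means a rightward fork; |derivative|
below a threshold (default 20% of the cohort median absolute derivative —
scale-free, since Repli-Seq wavelet units are arbitrary) leaves the
segment undetermined, excluded from numerators and denominators alike.
The strand convention is fixed once: in a rightward-replicating region a
plus-strand central pyrimidine lies on the lagging-strand template. The
simulator encodes the same constant, so round-trip tests validate the
estimators, not the convention.

## Strand ratios and the curvature test

Ratios are density ratios — mutations per motif site on one strand class
over the other — computed per bin and per sample, then averaged across
samples; samples are never pooled for the headline means. Bins with a
zero count on either side are undefined and skipped. For the mid-timing
peak of the lagging/leading profile, mutations are pooled across enriched
samples into one profile; the test statistic is the quadratic coefficient
of an OLS parabola over the seven per-bin ratios. The null resamples each
mutation's strand within its timing bin (binomial, probability
proportional to strand exposure, preserving per-bin totals exactly);
shuffles that zero out a strand in some bin are dropped and counted. The
reported p-value is the Gaussian tail of the observed coefficient under
the null mean/sd — observed effects can fall far beyond any empirical
rank — with the empirical rank `(1+#{null ≤ obs})/(N+1)` always emitted
alongside (it is the calibrated quantity under the null and is what the
calibration test checks). Two-sided by default; the one-sided concave
version is also reported. Group contrasts (enriched APOBEC ratios vs
non-TCN-cytosine ratios in low-enrichment samples) use the two-sided
Mann-Whitney test.

## Clusters

Candidates are maximal runs of ≥ 2 same-chromosome mutations with neighbor
gaps ≤ 10 kb. Under uniform placement of the sample's n SBS over the
covered genome G, inter-mutation distances are geometric with per-base
rate π = n/G, so the span d of k mutations has
`p = P(NB(k−1, π) ≤ d−(k−1))`; two adjacent bases give p = π exactly. A
10⁶-replicate Monte-Carlo placement oracle doubles as the normative check
of this tail. Candidates pass at `p ≤ 10⁻⁴` and are classified strictly:
APOBEC only if all members carry the signature, non-APOBEC only if none
does, otherwise mixed (excluded from both tallies). Grid assignment uses
the cluster midpoint; densities normalize counts by cell bp.

These constants presume genome-scale sparsity (mean gap ≫ 10 kb). On the
package's compressed default simulation scale the catalog is ~2500× denser
than a real genome, consecutive gaps almost never exceed 10 kb, and the
grouping rule yields one chromosome-wide candidate with p ≈ 0.5 — no
clusters are detectable there, by construction rather than by defect.
Cluster analyses therefore run on a sparse cohort configuration (~250 SBS
per 8 Mb, mean gap ≈ 30 kb) where the constants are meaningful. Injected
clusters are kataegis-like strand-coordinated runs (k = 4 + Poisson(2)
within 300 bp).

## The NRD model

Per sample, `NRD(r,t) = RD(r,t)/ΣRD` over the 49 (timing × expression)
cells of genic territory; the normalization removes the sample's overall
load, and the grid sums to 1 by identity. Cells intersect timing bins
with the sample's expression bins exactly (genes may straddle timing
bins). A cell with zero motif sites invalidates the grid; |ΣRD| < 1e-12
makes the sample non-normalizable — both are excluded with a logged
warning, which at small simulation scales is the dominant reason a sample
drops out. OLS with intercept on uncentered bin indices is numerically
safe because the balanced 7×7 design makes r and t orthogonal; the same
balance means LMG shares reduce to marginal R² increments averaged over
the two orderings (they sum to R² to machine precision) and type II ANOVA
sums of squares equal type I. "Significance values" entering the cohort
Pearson correlation are −log10 of the coefficient p-values (raw p
available by flag). The clusters-excluded variant drops mutations inside
detected cluster footprints and refits.

## The synthetic cohort

The generator emulates the study conditions the estimators are built for:

- genome: one 20 Mb chromosome, i.i.d. bases at GC 0.41 (human-like);
- timing: cosine wave, period 2 Mb, amplitude 30 on an offset of 50
  (ENCODE wavelet-like units), 1 kb bedGraph segments; fork truth is the
  analytic derivative with a 2% dead zone at extrema;
- genes: 2 000 non-overlapping genes, log-normal lengths (median 3 kb),
  placed with weight `exp(z_timing)` so gene-dense regions associate with
  early replication; expression log-normal across genes (σ = 1.5) with
  per-sample noise and 10% zeros;
- cohort: 30 samples × 40 000 SBS; each sample's APOBEC fraction runs
  linearly over 0.05–0.90, which maps onto fold enrichment ≈ 0.5–3.3 and
  populates both the E < 1.5 and E > 2.5 strata;
- effects: APOBEC site weight `(1 + 0.12·(4−r))` (early gradient), times a
  lagging-strand factor `1 + 0.5·exp(−(r−3)²/4.5)` (peak ratio 1.5 at bin
  3, mirroring mid-replication maxima of ~1.35–1.55), times a sense-strand
  factor `1 + 0.5·(t−1)/6`; background SBS at non-TCN cytosines and
  thymines with a late gradient `1 + 0.08·(r−4)`; APOBEC alts C→T:C→G at
  2:1 (irrelevant to TCN statistics);
- clusters: strand-coordinated APOBEC runs biased toward early timing and
  high expression.

Mutations are drawn without replacement by Gumbel top-k over site weights;
all randomness flows from one root seed through `numpy` SeedSequence
spawning, and outputs are byte-identical across runs.

What the simulator does *not* emulate: real chromatin and mappability
structure, signature mixtures beyond one APOBEC plus one background
process, replication-origin geometry beyond a smooth wave, and realistic
inter-sample covariance of expression. Passing round-trip tests therefore
demonstrates that the estimators recover the effects they target under
known conditions — not that those effects take the same values in real
tumors. One known interaction is deliberate: because site weights
multiply, sense-strand sites in co-directionally replicated/transcribed
genes also carry the lagging factor, so the co-direction contrast is not
an exact null under the default effects and can reach nominal
significance at full cohort power.

## Problem sizes used by the test suite

Unit and acceptance tests run scaled-down instances chosen once for
minutes-scale runtimes: a 4 Mb / 800-gene / 4–5-sample session cohort;
50-seed parameter recovery at 4 Mb with 5 samples × 30 000 SBS; bin
construction checked at the full 20 Mb / 1 kb-segment scale; calibration
studies with 200 replicates and 999 shuffles; the Monte-Carlo cluster
oracle at 10⁶ replicates (G = 10⁶, n = 100, k ∈ {2,3}). Effect parameters
are never changed from the generator defaults in any of these. At scales
below ~800 genes the 49-cell grid can acquire empty cells (gene placement
is early-biased), which excludes samples exactly as the pipeline would;
the recovery suite counts a seed as failed if fewer than two samples
remain fitted.

## Numerical choices

- Motif counting uses per-position 3-mer codes with int32 prefix sums;
  motif instances are located by their central base, so interval
  assignment is unambiguous at boundaries.
- Overlapping input intervals are rejected rather than merged silently;
  positions covered by more than one gene are ambiguous and excluded from
  sense/antisense numerators and denominators.
- OLS slopes use bin indices 1..7 (configurable to bin-mean timing);
  slope p-values are two-sided t-tests.
- Ties in expression binning are resolved by value (equal values share a
  bin), keeping bins deterministic without ordering artifacts.
- The shuffle-null sd below 1e-15 raises rather than reporting a p-value.
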