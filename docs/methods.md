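# Methods

`lamingate` implements two quantitative analyses around germinal-centre-like
B-cell models: (i) quantification of somatic hypermutation (SHM) from
clonally sequenced immunoglobulin V-region amplicons, and (ii) detection of
Lamin B1 lamina-associated domains (LADs) from binned ChIP/input count
tracks, together with the differential "canyon/mesa" analysis that asks
whether binding drops over the immunoglobulin variable-gene clusters when
SHM is induced. A synthetic-data module generates every input the pipeline
consumes, so all guarantees are testable on a desk machine with no external
data.

## SHM quantification

**Model of the assay.** The assay clones a PCR-amplified V-region (a ~565 bp
fragment spanning a rearranged V–J segment) into bacteria and
Sanger-sequences independent colonies. Each clone is therefore an
independent draw from the mutated cell population; there is no clonal
phylogeny to model, and every clone is compared directly to the reference
amplicon.

**Alignment and calling.** Clones are globally aligned to the reference
(Needleman–Wunsch with affine gaps; defaults match=+1, mismatch=−1, gap
open=−4, gap extend=−1, where a length-k gap costs `open + (k−1)·extend`).
Full-length amplicons justify global rather than local alignment, and the
default scores rank a point mismatch above a spurious insertion/deletion
pair. Substitutions are called per mismatched base–base column in reference
coordinates; indel columns are excluded from the substitution count and
reported separately as indel events. Clones shorter than 80% of the
reference or with >10% mismatching columns are discarded as cloning
artifacts (both thresholds configurable and logged); duplicate sequences
are kept but flagged, with an option to collapse them.

**Statistic.** Mutations per base pair is the total substitution count
divided by total aligned base pairs across clones of a condition. A
condition passes QC only when at least 10,000 aligned base pairs were
assessed; failing conditions are still summarised but flagged.

**Hotspot classification.** The AID deamination hotspot is WRCY (W={A,T},
R={A,G}, Y={C,T}) with the mutated base being the C, and its reverse
complement RGYW with the mutated base being the G. A position is labelled
WRCY when it is a C and the window `[pos−2, pos+1]` matches W,R,C,Y; RGYW
when it is a G and `[pos−1, pos+2]` matches R,G,Y,W. Windows truncated by
either sequence end never match, and WRCY takes precedence if a position
could satisfy both readings (possible only through the shared central CG of
overlapping motifs; the tie-break is arbitrary but fixed).

**Condition contrast.** Conditions are compared by an exact conditional
binomial test: conditional on the combined substitution count N, under the
null of equal per-bp rates the count in condition B is Binomial(N,
bp_B/(bp_A+bp_B)). The two-sided p-value sums all outcomes no more likely
than the observed one, and the 95% CI inverts the Clopper–Pearson interval
onto the rate-ratio scale. This was chosen over a Wald/Poisson-regression
contrast because substitution counts per condition are small (tens), and
the conditional test is exact at those sizes with exposure built in.

## Synthetic clone sets

Each clone mutates independently: site i substitutes with probability μ
(the background per-bp rate) or h·μ at hotspot positions, where h ≥ 1 is
the hotspot multiplier. The substituted base is drawn from a configurable
4×4 spectrum (uniform over the three alternatives by default; an AID-like
preset upweights C→T/G→A). When the AID-null flag is set, all rates are
multiplied by a small attenuation factor (default 0.02), emulating the
near-complete loss of both background and induced mutation in AID-deficient
cells. Single-base indels can be enabled (default off, since the statistic
of interest counts substitutions).

Because conditional on a substitution occurring its position is
hotspot-distributed in proportion to the per-site rates, the expected
hotspot fraction has the closed form

    E[hotspot fraction] = n_h·h / (n_h·h + n − n_h)

for n_h hotspot positions among n sites, independent of μ. This is the
recovery target of the parameter-estimation tests. Default study
conditions: a 565 bp reference at GC 0.5 (for which n_h ≈ 35–40, so h=8
implies a hotspot fraction near 0.37), control μ = 8×10⁻⁴ per bp per clone,
a stimulated condition at 4.5× that rate, an AID-null condition at the
stimulated exposure, and 30 clones per condition (16,950 aligned bp,
satisfying the 10 kb QC rule). The hotspot multiplier default of 8 keeps
per-site probabilities far from saturation while separating hotspot and
background rates by almost an order of magnitude; pushing the observed
hotspot fraction toward the 70–85% seen in real V-gene data would require
h ≈ 40–90 on a random sequence, since real V regions concentrate many more
overlapping hotspots than a random 565-mer. The fixture emulates the
assay's sampling structure, not the sequence composition of a true V gene —
a passing recovery test shows the estimator tracks the closed form, not
that real loci have these rates.

## LAD calling

Inputs are integer read counts per fixed-size genomic bin for a ChIP track
and its input control (default bin 10 kb; the LAD literature uses 10–100 kb
and the smaller size keeps fixtures desk-scale). Calling follows the
enriched-domain-detector recipe for broad domains:

1. **Depth matching.** The deeper track is subsampled without replacement
   across bins (multivariate hypergeometric) so both totals are exactly
   equal; the shallower track is untouched. This preserves per-bin
   proportions in expectation and removes depth as a confounder before any
   ratio is formed.
2. **Log ratio.** Per bin, log2((chip+pc)/(input+pc)) with pseudocount
   pc=1; bins empty in both tracks are masked as undefined.
3. **Discretisation.** Bins score +1 when the ratio reaches a threshold —
   by default the genome-wide 66.7th percentile of unmasked ratios, i.e. an
   "enriched minority" assumption — and −g otherwise (gap penalty g=3).
   Masked bins score −g: they can be bridged by strong flanks but never
   seed a domain.
4. **Segmentation.** All maximal-scoring segments per chromosome via the
   linear-time Ruzzo–Tompa algorithm; these disjoint positive-score
   segments are the candidate domains.
5. **Significance.** Per chromosome, bin scores are permuted uniformly
   n_perm times; a domain's p-value is (1 + #{permutation max segment ≥
   observed score})/(n_perm+1), with Benjamini–Hochberg control across all
   domains. Permutation is scoped to the chromosome, not the genome,
   because chromosome-scale composition shifts are themselves biology of
   interest and must not leak into the null.

The default n_perm is 4000. This is a resolution requirement, not a power
knob: the achievable p floor is 1/(n_perm+1), and with the several hundred
candidate segments a 2,000-bin genome yields, BH multiplies that floor by
m/k ≈ 60–80; the floor must sit well below 0.05·k/m for any domain to be
declarable at q<0.05. At n_perm=1000 no domain can reach q<0.05 on these
fixtures regardless of its score.

## Synthetic binding tracks

Input counts are negative binomial around a background mean (default 20
reads/bin); ChIP bin means are multiplied by the planted enrichment inside
domains. The dispersion default is 100 (variance = mean + mean²/100, ~1.2×
Poisson at the default mean): the emulated upstream pipeline removes PCR
duplicates, after which 10 kb bin counts are near-Poisson, and heavier
overdispersion remains a config dial (`dispersion`) with Poisson as the
infinite limit. The default two-condition plan places five 20-bin LADs at
enrichment 4 on a 4×500-bin genome; in the induced condition the three
Ig-cluster LADs (IGHV/IGKV/IGLV) drop threefold (4 → 4/3) while adjacent
mesas rise so that both conditions carry the same expected total signal —
the canyon-inside-mesa geometry the differential analysis must resolve, and
a layout that keeps depth matching symmetric between conditions.

## Differential binding

Canyons and mesas are detected on the bin-level delta of the two
depth-matched log-ratio tracks (B − A): maximal runs of at least
`min_width` bins (default 3) with delta ≤ −δ (canyon) or ≥ +δ (mesa),
δ = 0.5 log2 units by default. Operating on ratios rather than domain calls
is deliberate: a canyon inside a mesa changes no domain boundary and is
invisible to set subtraction. Swapping the two conditions exchanges canyon
and mesa labels exactly.

Overlap of regions with an annotation (e.g. the Ig clusters) is reported in
bp with a Jaccard index; enrichment is observed overlap divided by its mean
under circular permutation — regions are rotated within their chromosome by
uniform random offsets, preserving lengths and spacings, which uniform
reshuffling would destroy. The locus fold change over an interval is
mean(2^ratio_A)/mean(2^ratio_B) across unmasked bins, reported as an
"x-fold reduction" when > 1. Because both conditions share the input count
distribution, the input's Jensen term cancels in this ratio of means; the
residual bias from pseudocounting and depth scaling is below 2% at the
default fixture depth, well inside the seed-to-seed spread.

## Numerical and degenerate-case policy

- All randomness flows through `numpy.random.SeedSequence(seed,
  spawn_key=…)`; every generator and every Monte-Carlo step is a pure
  function of (config, seed), and full pipeline runs are byte-identical per
  (config, seed).
- Percentile thresholds use linear interpolation (`numpy.percentile`).
- Hotspot fraction, CG fraction and spectrum fractions are undefined (None)
  when a condition has zero substitutions; the rate-ratio test returns
  p = 1 with an undefined ratio when both conditions have zero counts, and
  an infinite ratio when only the baseline does.
- Empirical p-values use the (1 + #extreme)/(n + 1) estimator and are never
  exactly zero; BH q-values are clipped to 1.
- Ties in segment maximality are resolved by the Ruzzo–Tompa list
  invariant (strict inequality on left cumulative scores), which prefers
  shorter, earlier segments over equal-scoring supersets.
- A fully masked locus yields a flagged, undefined fold change rather than
  NaN arithmetic downstream.

## Problem sizes used in the checks

Verification runs use a 565 bp reference with 30 clones per condition
(16,950 bp), 100 replicates for estimator-recovery checks, a 2,000-bin
(4×500) genome at 10 kb bins with background mean 20 and enrichment 4 for
domain recovery (20 seeds, plus 40 null seeds for false-positive
calibration), and 10–20 seeds for the differential analyses. These sizes
give Monte-Carlo standard errors a few times smaller than the effects being
recovered while keeping the full suite fast enough to run habitually.

## Limitations

- The clone simulator draws substitutions i.i.d. per site; real SHM shows
  strand bias, position-dependent targeting along the V region, and
  polymerase-η-driven A/T mutagenesis that the uniform-spectrum default
  does not emulate. Passing recovery tests validates the estimators, not
  the biological realism of the generator.
- The binding simulator plants rectangular domains with homogeneous
  enrichment; real LADs have ragged borders and nested sub-domain
  structure, so boundary-accuracy results here are optimistic.
- Canyon/mesa detection is a fixed-threshold run-length rule; a planted
  drop well below δ per bin, or fragmented by noise at low sequencing
  depth, is not recovered. The rule has no multiple-testing control of its
  own (the permutation machinery applies to domain calls and overlap
  enrichment, not to individual canyon calls).
- The permutation null for domains assumes exchangeable bins within a
  chromosome; long-range autocorrelation in real ChIP tracks would make it
  anti-conservative there.
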