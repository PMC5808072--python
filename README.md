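# lamingate

Quantification of somatic hypermutation (SHM) from clonal immunoglobulin
V-gene sequences, and Lamin B1 lamina-associated-domain (LAD) analysis from
binned ChIP/input tracks — including the differential "canyon/mesa" view
that asks whether nuclear-lamina binding drops over the immunoglobulin
variable clusters (IGHV, IGKV, IGLV) when SHM is induced.

It is written for groups studying the chromatin side of antibody
diversification: B cells mutate their rearranged V regions via
activation-induced cytidine deaminase (AID), whose hotspot motif is
**WRCY** (mutated C; W={A,T}, R={A,G}, Y={C,T}) and its reverse complement
**RGYW** (mutated G). The package takes Sanger-style clone sets of a
V-region amplicon plus binned ChIP-seq counts, and produces per-condition
mutation statistics, domain calls and differential-binding reports. A
synthetic-data module generates every input, so the whole pipeline is
verifiable offline.

## What it computes

**SHM.** Clones are globally aligned to the reference amplicon (affine-gap
Needleman–Wunsch); substitutions are called per mismatched column and
classified against the two-strand WRCY/RGYW hotspot. The headline statistic
is mutations per base pair

    m = n_subs / total aligned bp        (QC: ≥ 10,000 bp per condition)

and conditions are contrasted with an exact conditional binomial test of
the rate ratio: given N = n_A + n_B substitutions, under equal rates
n_B ~ Binomial(N, bp_B/(bp_A+bp_B)); the 95% CI inverts Clopper–Pearson
onto the ratio scale.

**LADs.** ChIP and input are depth-matched exactly (hypergeometric
subsampling of the deeper track), converted to per-bin log2(ChIP/input),
discretised to +1/−g against a genome-wide percentile threshold, and
segmented into all maximal-scoring segments (Ruzzo–Tompa). Domain
significance comes from per-chromosome score permutations with
Benjamini–Hochberg control.

**Differential binding.** Canyons (binding loss) and mesas (gain) are runs
of bins whose log-ratio delta crosses ±δ; overlap with the Ig clusters is
scored by Jaccard and circular-permutation enrichment; the locus fold
change over an interval is mean(2^ratio_A)/mean(2^ratio_B).

## Worked example

Generate the default synthetic study (three SHM conditions; two binding
conditions with threefold drops planted at the three Ig clusters) and run
the stages:

```sh
lamingate simulate --seed 1 --out fx
lamingate shm  --seed 1 --fixtures fx --out out
lamingate lads --seed 1 --fixtures fx --out out
lamingate diff --seed 1 --fixtures fx --out out
lamingate report --seed 1 --out out
```

`out/shm_summary.tsv` (seed 1):

```
condition	n_clones	aligned_bp	n_substitutions	mut_per_bp	n_hotspot	hotspot_fraction	...	qc_pass
aid_null	30	16950	2	1.179941e-04	1	0.5000	...	True
control	30	16950	27	1.592920e-03	11	0.4074	...	True
stimulated	30	16950	83	4.896755e-03	27	0.3253	...	True
```

Each condition clears the 10 kb QC rule (30 clones × 565 bp). The
stimulated condition mutates at ~4.9×10⁻³ per bp against a control of
~1.6×10⁻³, and the AID-null condition collapses to ~1.2×10⁻⁴ — mutation is
essentially abolished without AID. `out/shm_fold_changes.tsv` makes the
contrasts exact:

```
baseline	condition	rate_ratio	ci_low	ci_high	p_value
control	aid_null	0.0741	0.0085	0.2948	1.624e-06
control	stimulated	3.0741	1.9702	4.9380	8.31e-08
```

i.e. a significant ~3-fold induction in this single draw (the generating
ratio, 4.5, lies inside the CI) and a ~93% loss in the AID-null condition.
The LAD stage recovers the planted domains —

```
condition	n_segments	n_significant	threshold	lad_bins
control  	404	6	0.057	125
shm_induced	382	6	0.070	138
```

— and the differential stage reports, per Ig cluster
(`out/overlap_report.json`, `INFO` log):

```
IGHV: 3.09-fold reduction
IGKV: 2.80-fold reduction
IGLV: 2.99-fold reduction
canyon/Ig overlap enrichment 13.8, p = 2.5e-4
```

matching the planted threefold loss of Lamin B1 binding at all three
clusters. All outputs carry the tool version, config hash and seed; runs
with identical config and seed are byte-identical.

The same machinery is available as a library — see
`lamingate.shm.compare_conditions`, `lamingate.lads.call_lads`,
`lamingate.diff.detect_canyons_mesas` — and `docs/methods.md` documents the
models, defaults and limitations.

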