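# sitepin

Pinpointing transcription-factor binding sites (TFBSs) from ChIP-seq data at
single-base resolution — including multiple closely spaced sites inside one
enriched region, where summit-based peak callers typically report a single
position between the true sites.

`sitepin` is for anyone analysing transcription-factor ChIP-seq: it takes
uniquely mapped single-end reads ("tags", reduced to the fragment-proximal
5′ position and strand), finds statistically tag-enriched binding regions,
and then deconvolves each region into individual binding sites.

## Method

**Step 1 — binding regions.** Tags from both strands are pooled and
clustered: runs of tags whose successive positions differ by at most
*d* bp (default 30) form candidate regions; clusters with fewer than 10
tags or shorter than 100 nt are discarded. Each cluster with count *k* and
length *C* is tested against a Poisson null with a dynamic local rate,

λ_local = max(λ_BG, λ_5k, λ_10k)   (no control), or
λ_local = max(λ_BG, R·λ_control, R·λ_control_1k)   (with control),

where λ_BG is the genome-wide tag rate over the effective genome size
(default 2.4 Gbp), λ_5k/λ_10k/λ_control_1k are rates in windows centered on
the cluster, and R normalizes control depth to ChIP depth. *P* = P(X ≥ k),
X ~ Poisson(λ_local·C); Benjamini–Hochberg *Q*-values (Q = P·Count/Rank,
step-up monotonized) are thresholded at the chosen FDR (default 10%), and
region boundaries are trimmed to the bases whose smoothed tag density
exceeds λ_local.

**Step 2 — binding sites.** Fragment lengths *l* are modeled as
Gamma(α, β) with shape α = 10 and mean *L* = αβ estimated from the densest
regions (distance between forward and reverse stack centers). Because a
fragment straddles its site with two arms and gamma shapes add at a common
scale, one arm is Gamma(α/2, β) with mean L/2, which gives a discrete
single-site tag-density template f_tag(d), d = 0..D (for L = 120 the
template peaks 49 bp from the site). Per strand, per-base 5′-end counts
t_n are smoothed with a b = 20 bp moving average, and a window of width
W = 0.8·L slides base by base fitting s ≈ β·f_tag by no-intercept least
squares. Local maxima of the goodness-of-fit R² whose slope β is at least
half the region maximum become strand calls (β is reported as the relative
binding affinity); forward and reverse calls within 20 bp merge at their
midpoint, the rest are kept as single-strand evidence.

A built-in simulator draws tags from the same template (forward at
site − d, reverse at site + d) for benchmarking, and the evaluator reports
distances from detected sites to reference centers (simulated truth, or
motif centers on real data).

## Worked example

Simulate a 100-kb toy chromosome with three planted regions, each holding
two binding sites 60 bp apart (100 tags per site per strand, uniform
background), then call regions and sites and score them:

```sh
sitepin simulate --sites 500,560 --tags-per-site 100 \
    --genome-len 100000 --n-regions 3 --background-rate 1e-4 \
    --seed 7 --out-tags tags.bed --out-truth truth.bed
sitepin call --tags tags.bed --effective-genome 100000 \
    --out-regions regions.bed --out-sites sites.bed
sitepin evaluate --sites sites.bed --reference truth.bed
```

The `call` log reports `detected 3 enriched regions at FDR 0.10`,
`estimated mean fragment length L = 116.8 bp` (truth: 120) and
`pinpointed 7 binding sites in 3 regions`. `sites.bed` holds 1-bp
intervals whose name carries the source region and strand evidence and
whose score is the relative affinity, e.g.

```
sim1  62401  62402  region0_FR  114.429  .
sim1  62453  62454  region0_FR  118.3    .
```

for true sites at 62,396 and 62,456 — both adjacent sites recovered, 5 and
3 bp from truth. The evaluator prints the fraction of calls within 5, 10
and 20 bp of the nearest true site (0.857 at every threshold here: 6 of
the 7 calls are ≤5 bp from a true site; one region yielded an extra
between-sites call).

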