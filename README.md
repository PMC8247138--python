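# microdyn

Longitudinal microbiome resilience analysis: temporal beta-diversity
segmentation, persistence-based stable/transient clustering, and bipartite
host–ASV network dynamics for dense longitudinal 16S amplicon studies.

## The problem

A small cohort is sampled repeatedly over a long period (the motivating
design: six subjects confined together for 520 days plus a 200-day
follow-up, 15 timepoints, 88 salivary samples, ~2000 ASVs).  The questions
are about *resilience*: how much of each subject's microbiota turns over
with time, when the turnover regime changes, which taxa are stably resident
versus transiently passing through, and which taxa drive each subject's
temporal dynamics.

`microdyn` implements that analysis end to end:

1. **Preprocessing** — rare-ASV filtering (prevalence < 5% of samples *and*
   total abundance < 10), median-of-ratios size factors (positive-counts
   reference), Wisconsin double standardisation + square root.
2. **Diversity** — inverse Simpson (α = 1/Σp²), Good's coverage,
   rarefaction; Sørensen, Bray–Curtis (with the temporal gains/losses
   decomposition: d = (B+C)/(2A+B+C)), unweighted/weighted UniFrac;
   within-subject turnover series (consecutive-timepoint distances per
   subject) and between-subject divergence series (mean pairwise distance
   per timepoint).
3. **Community statistics** — non-metric MDS (Kruskal stress-1, isotonic
   regression), sequential (Type I) PERMANOVA on distance matrices,
   multivariate dispersion homogeneity (principal coordinates, spatial
   medians), one-way ANOVA, Benjamini–Hochberg correction.
4. **Temporal segmentation** — per-subject nonparametric PELT change-point
   detection (empirical-CDF cost at tail-weighted quantiles, MBIC penalty),
   genetic-algorithm refinement over candidate change-point sets with
   fitness 1/Σₖ RMSE(lmmₖ), and per-segment random-intercept mixed models
   (REML, Satterthwaite degrees of freedom) reporting slope *b*, SE, *t*,
   fractional df, *p*, and the cumulative effect *b* × segment span.
5. **Persistence dynamics** — the persistence matrix (subjects carrying
   each ASV per timepoint), dynamic-time-warping distances between
   row-standardised persistence trajectories clustered by partitioning
   around medoids into stable (cluster 2) vs. inconsistent (cluster 1)
   microbiota, persistence–abundance regression, per-timepoint bipartite
   subject–ASV networks, formed/destroyed edge series and their mixed
   models (day trend + post-isolation jump), degree centrality.
6. **Drivers & enrichment** — per-ASV linear models of standardised
   |consecutive differences| with segment-specific slopes selecting each
   subject's "drivers of diversity", and hypergeometric enrichment of
   stable-cluster membership among them.

A first-class synthetic-data generator (`microdyn.synthetic_data`) emulates
the full study design — planted change-points at days 123 and 480 with
segment slopes +0.00103 / −0.00064 / +0.00123 per day, stable and transient
ASV families, a +28 formed-edge jump at the end of isolation, uneven
sequencing depth — so every stage is testable without any sequencing data.

## Worked example

```python
from microdyn import *

design = SyntheticDesign(seed=0)          # the emulated study
table, tree = generate(design)            # 2000 ASVs x 88 samples

filtered = filter_rare(table)
norm = wisconsin_sqrt(scale_counts(filtered))
within = within_subject_series(norm, "bray_curtis")

seg, fits = segment_series(within, seed=0)   # PELT -> GA -> mixed models
print("change-points:", seg.changepoint_days)
print(segments_table(fits).round(5).to_string(index=False))
```

```
change-points: [114, 480]
 start_day  end_day        b      SE         t       df   p  cumulative_effect
        21      114  0.00099 0.00006  16.42146 17.00922 0.0            0.09224
       115      480 -0.00059 0.00002 -35.84366 35.00914 0.0           -0.21704
       481      716  0.00109 0.00004  27.69388 13.67400 0.0            0.25630
```

The pipeline recovers the planted change-points at the sampling days
adjacent to 123 and 480, and the per-segment slopes (per day, with
Satterthwaite fractional df): turnover rises during the outbound phase,
falls through the return phase, and rises again after isolation ends —
with cumulative effects (slope × segment span) close to the planted
+0.10 / −0.22 / +0.29.

```python
scaled = scale_counts(filtered)
pm = persistence_matrix(filtered)
clusters = dtw_cluster(pm, seed=0, abundance=scaled.values.mean(axis=1))
print(clusters.summary.round(2).to_string(index=False))

ed = edge_deltas(build_networks(filtered))
post = edge_models(ed)["formed"].coef("post_isolation")
print(f"post-isolation jump in formed edges: {post['b']:.1f} (SE {post['SE']:.1f})")
```

```
 cluster  size  mean_persistence  mean_abundance
       1   819              0.29            0.53
       2   815              5.65           78.63
post-isolation jump in formed edges: 24.5 (SE 8.2)
```

Cluster 2 is the stable microbiota (carried by ~5.7 of 6 subjects at every
timepoint, two orders of magnitude more abundant); cluster 1 the sporadic,
low-abundance transients.  The edge model estimates the planted +28 burst
of ASV acquisitions right after the isolation ends.

There is also a CLI: `microdyn all --synthetic --seed 0 --outdir out/`
runs every stage and writes TSVs plus a JSON run manifest;
`microdyn generate` writes just the synthetic study.

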