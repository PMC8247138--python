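# Methods

This note documents the models, algorithmic conventions, and design
decisions behind `microdyn`, and what the synthetic study does and does not
emulate.

## Data model and preprocessing

The unit of analysis is an ASV-by-sample integer count table joined to
per-sample metadata (subject, study day 1–720, diet ∈ {FV, TV, NR}, phase ∈
{outbound, return, followup}); isolation ends at day 520 and the normal
diet (NR) coincides exactly with follow-up.

*Rare-ASV filter.* An ASV is removed when it occurs in fewer than
⌈prevalence_fraction · n_samples⌉ samples (default 5%) **and** its total
count is below `min_abundance` (default 10).  The conjunction is
deliberate: the filter targets extremely rare taxa that distort
presence/absence indexes, not prevalent-but-shallow taxa.  The filter is
applied before beta-diversity computation; alpha diversity uses unfiltered
scaled counts (the filter's rationale is qualitative-index robustness, and
the inverse Simpson index is dominated by abundant taxa anyway).

*Depth normalisation.* Median-of-ratios size factors with a
positive-counts geometric-mean reference — zero-inflated amplicon tables
leave the classical all-counts reference undefined for most ASVs.  Factors
are rescaled to geometric mean 1.  Scale equivariance holds exactly on
all-positive tables and approximately otherwise.

*Variance stabilisation.* Scaled counts are Wisconsin double standardised
(row ÷ row-max, then column ÷ column-sum) and square-rooted before the
abundance-based dissimilarities.  Whether the phylogenetic distances
should also see transformed counts is genuinely open; UniFrac here uses
size-factor-scaled counts with the supplied rooted tree, which keeps the
quantitative variant interpretable in abundance units.

## Diversity

Alpha diversity is the inverse Simpson index 1/Σpᵢ².  Pairwise
dissimilarities: Sørensen (A+B−2J)/(A+B) on presence/absence; Bray–Curtis
Σ|x−y| / Σ(x+y), returned together with its temporal decomposition
A = Σ min(x,y) (unscaled similarity), B = Σ(x−y)₊ (losses), C = Σ(y−x)₊
(gains), for which (B+C)/(2A+B+C) is algebraically identical to the direct
formula; unweighted and (Lozupone-normalised) weighted UniFrac, so all four
indexes live on [0, 1].

The *within-subject* series holds, for every subject and every consecutive
pair of sampling days, the dissimilarity between the two samples, assigned
to the **later** day of the transition — this keeps the isolation-end
effect aligned with the first post-isolation transition.  The
*between-subjects* series holds, per sampling day, the arithmetic mean of
all pairwise dissimilarities among subjects sampled that day.

## Community statistics

PERMANOVA uses sequential (Type I) sums of squares on the Gower-centred
inner-product matrix, with projection hat matrices built in the given
factor order (headline order: subject, then diet, then day as a continuous
covariate — subject first is the conservative choice for repeated
measures).  p-values use unrestricted row permutations,
p = (#{F* ≥ F} + 1)/(n_perm + 1), 1000 permutations by default.  The
repeated-measures caveat applies: permutations are not restricted within
subjects.  The implementation reproduces the reference R implementation's
SS/R²/F decomposition to ~1e-9 on a fixture (see the test suite).

Dispersion homogeneity embeds samples by principal coordinates, keeps
negative-eigenvalue axes as imaginary parts (squared distances subtract),
measures each sample's distance to its group's spatial median (Weiszfeld),
and applies a one-way F test.  NMDS minimises Kruskal stress-1 by iterative
majorisation with isotonic regression of configuration distances on
dissimilarity ranks, best of n_starts random starts (default 300, k = 2).

## Mixed models

The inference engine is a Gaussian random-intercept model
y = Xb + Zu + e estimated by REML.  The variance ratio γ = σ²ᵤ/σ²ₑ is
profiled out (the criterion needs only per-group sufficient statistics, so
one fit costs microseconds) and minimised by bounded search on log γ with
an explicit γ = 0 boundary check.  Satterthwaite degrees of freedom come
from the delta method: dfⱼ = 2·Var(bⱼ)²/(gᵀAg), with g the central-difference
gradient of Var(bⱼ) with respect to (σ²ᵤ, σ²ₑ) and A twice the inverse of
the numerical Hessian of −2ℓ_REML.  Fractional df (e.g. 14.2, 424.2) are
the expected output; the df is clamped to at most the fixed-effect residual
df, with that value as the fallback when the information matrix is
degenerate (e.g. exactly at the γ = 0 boundary).  With one observation per
group the model refuses to fit rather than return arbitrary variances.
Fixed effects, standard errors, variance components, and the REML
log-likelihood agree with an independent reference implementation on
simulated fixtures.

Between-subjects series (one point per day, no grouping) are fitted by OLS
in the same result type.

## Temporal segmentation

*Detection.* Per-subject nonparametric PELT: the segment cost is the
empirical-CDF multinomial cost evaluated at K tail-weighted quantiles of
the full series (probabilities pₖ = [1 + (2n−1)·exp(−log(2n−1)·(2k−1)/K)]⁻¹,
K = ⌈4 log n⌉ by default), with weight log(2n−1)/K.  The MBIC penalty is
3 log n per change-point plus a log(segment length / n) correction folded
into each segment's cost; on this cost scale the constant calibrates the
null (i.i.d. series of length 100 essentially never segment, while planted
steps are found reliably).  PELT prunes with a log n slack because the
length correction is not exactly subadditive; on series up to n = 20 the
PELT solution attains the exact optimum of a full dynamic program without
pruning in 100/100 random cases.

*Refinement.* Detected change-points are only a starting point: the
genetic algorithm searches inclusion masks over **all** interior transition
days, with the pooled per-subject PELT mask, the empty mask (no
change-points is admissible), and random masks seeding the population.
The fitness of a mask is 1/Σₖ RMSE(lmmₖ), with lmmₖ the
subject-random-intercept model of segment k and RMSE computed from
conditional (BLUP-adjusted) residuals.  A mask creating a segment with
fewer than `min_segment_transitions` distinct transition days (default 3)
is infeasible (fitness 0) rather than an error — note that with the
follow-up design (3 transition days, two subjects missing the last one)
this guard is interpreted as distinct observed transition days per
segment; a stricter per-subject average of 3 would make the true
segmentation itself infeasible.  GA defaults: population 200, 100
generations, uniform crossover 0.8, per-bit mutation 0.1, 5% elitism,
early stop after 25 stagnant generations.  Fitness values are cached per
mask, so with ~13 candidate days the search effectively enumerates the
reachable masks, and the returned mask provably scores at least as well as
every seeded mask and the empty mask.

The Σ RMSE fitness penalises extra segments implicitly (each segment
contributes its own RMSE term), which is what lets the unstructured
between-subjects series remain unsegmented.  On short series (15 points)
the criterion still overfits occasionally — about one unstructured null
series in five acquires a spurious split — which is a property of the
criterion, not of the search.

*Inference.* Each segment is fitted as value ~ day (days, not timepoint
ranks, so slopes are per day) with subject random intercept, and the
cumulative effect is slope × (end_day − start_day).

## Drivers and enrichment

For one subject, each ASV's |consecutive abundance difference| series
(size-factor-scaled counts) is z-scored and fitted with segment-specific
intercepts and (centred) day slopes; the model F-test against the
intercept-only model gives p, BH-adjusted across the subject's ASVs.  A
*driver* must be significant (adjusted p < 0.05) **and** reproduce the
global within-subject slope-sign pattern in every segment.  Enrichment of
stable-cluster membership among a subject's drivers is the upper-tail
hypergeometric probability P(X ≥ k) with the filtered ASV universe as N
(the clustering universe — internally consistent, though a universe of all
pre-filter ASVs would also be defensible), BH-corrected across subjects.

## Persistence and networks

Persistence(a, t) = number of subjects whose sample at day t contains ≥ 1
read of ASV a (on the filtered table; the rare filter has already removed
sub-detection noise).  Rows are centred and scaled (constant rows map to
zeros), pairwise DTW distances (symmetric step pattern, unconstrained
window — 15 timepoints are short) feed partitioning around medoids with
k = 2, and the cluster with higher mean raw persistence is labelled 2
("stable").  Bipartite networks link subjects to detected ASVs per
timepoint; formed/destroyed edges per subject per transition obey
E_{t+1} = E_t + formed − destroyed exactly, and are modelled as
count ~ day + post_isolation with subject random intercept (Gaussian — the
counts are large enough that a Gaussian working model is reasonable, and
the reported effects are linear).

## The synthetic study

The generator emulates the study conditions: 6 subjects, sampling days
{1, 21, 52, 83, 114, 145, 176, 271, 302, 364, 425, 480, 540, 630, 716}
(7 outbound, 5 return, 3 follow-up; the final follow-up sample of the last
two subjects is dropped, leaving 42 + 30 + 16 = 88 samples), diet FV/TV/NR
by phase, sequencing depth uniform on [20000, 117000], 800 stable + 1200
transient ASVs (≈ the study's ~1900), negative-binomial counts
(size 100).

*Stable block.* Log-abundances are log 200 + 1.8·V(a, t) + subject offsets
(sd 0.6 per ASV × subject) + diet shifts (±0.125 log units on 20% of
stable ASVs, FV vs TV) + small independent per-subject wobble (sd 0.05),
clipped from below at log 50 — resident taxa stay above the detection
floor; that persistent detectability is what makes them "stable".  The
crew-shared pattern V(·, t) is always the same fixed standard-normal
quantile ladder, *reassigned to ASVs by rank* at each timepoint: taxa trade
places while the community's abundance distribution is exactly invariant,
so alpha diversity cannot drift by construction and the shared pattern
cancels from between-subject contrasts (which are driven by the constant
subject offsets, hence flat in time — as observed for the cohort).

*Turnover control.* The reassignment at each transition is a rotation
V_t = cos θ·V_{t−1} + sin θ·Z (Z fresh, orthonormalised) followed by the
rank map.  θ is solved per transition (Brent) so that a deterministic
proxy turnover — Bray–Curtis between the square-rooted shared expected
compositions — hits its target exactly; a frozen Monte-Carlo calibration
table (regenerable with `calibrate_turnover_link`) maps proxy targets to
the expected *measured* within-subject Bray–Curtis of the full pipeline.
Pinning the realised proxy removes realisation-to-realisation wander of
the day-level series, which would otherwise drown the first change-point.
Angles beyond 90° (anti-correlated consecutive patterns) are admissible
and carry turnover beyond full decorrelation — the follow-up segment's
+0.00123/day slope sustained over 240 days requires it.

The target path is piecewise linear in the study day with the planted
slopes (+0.00103, −0.00064, +0.00123 per day) around change-points 123 and
480, anchored at 0.339 at the first transition, with small level shifts at
the change-points (−0.05 entering the return segment, 0 at the isolation
end): regime changes are level-plus-trend shifts, consistent with the
isolation end acting as a shock in the edge dynamics.

*Transient block.* Per-subject two-state Markov switches (stationary
occupancy 0.035, stay probability 0.4) give independent gain/loss events;
the gain rate declines slowly with the day (5e-4 per day, floored).
Transient weights are anchored to ≈ 10 expected reads per presence at the
median depth, so gain/loss events stay visible to the rare-ASV filter
regardless of the stable block's total weight.  At each post-isolation
timepoint, a *shared* set of ≈ 29 cohort-seen taxa reactivates
(re-exposure to the common outside environment), which plants the +28
expected jump in formed edges per subject without inflating
between-subject divergence.

*Drivers.* Six designated stable ASVs form pairs sharing a high-quantile
centre and swinging in opposite phase in weight space, w = W(1 ± r) with
r ∝ (turnover path)² — each pair's total weight is invariant (no evenness
perturbation), the |consecutive difference| tracks the segmented pattern,
and the quadratic sharpening keeps the within-segment trend above the
counting noise.

*What passing tests do and do not show.* The generator reproduces the
statistical *structure* the analysis assumes — piecewise-linear
within-subject turnover with recoverable change-points, flat
between-subject divergence and alpha diversity, a stable/transient
persistence dichotomy, independent churn with a planted acquisition burst.
It does not reproduce taxonomy, phylogenetic signal (the tree is a random
coalescent), compositional correlations between taxa, or the sparsity of
real driver sets: because the temporal reordering is crew-shared across
the whole stable block, *many* stable ASVs qualify as drivers
(tens per subject rather than the handful seen in sparse real data), and
the variance explained by the diet/phase factor is inflated relative to
subject individuality.  Recovery results on this design therefore
demonstrate correctness of the methods under their assumptions, not
performance on any particular real dataset.

## Numerical conventions and degenerate inputs

- Change-point days label the last observation of the left segment.
- All stochastic stages derive independent substreams from a single master
  seed keyed by stage name (CRC-based, < 2³¹); reruns are bit-identical.
- Missing Newick branch lengths become 0 with a logged warning; the
  underscore-to-space Newick convention is disabled.
- The rare filter refuses to remove every ASV; size factors refuse samples
  with no positive counts; `inverse_simpson` refuses all-zero vectors;
  Good's coverage refuses non-integer (scaled) counts.
- One-way ANOVA returns F = 0, p = 1 when values have no spread at all
  (degenerate dispersion comparisons).
- DTW distances are computed with rolling dynamic-program rows, vectorised
  over pairs in memory-bounded chunks.

## Known limitations

- PERMANOVA permutations are unrestricted; with repeated measures the
  subject factor's p-value is anti-conservative (the R² decomposition is
  unaffected).
- The GA fitness can overfit very short series (see above); the empty-mask
  seed and the Σ RMSE penalty mitigate but do not eliminate this.
- Satterthwaite df rely on numerical second derivatives; exactly at the
  zero-variance boundary the residual-df fallback is used.
- Weighted UniFrac is only offered in the normalised ([0, 1]) variant.
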