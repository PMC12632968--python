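# Methods

## Model and procedure

The pipeline treats a developmental time course as a small ordered set
of stages t = 1..T (T = 3 in the motivating designs) sampled under two
conditions, with a handful of biological replicates per (stage,
condition) cell. Counts are assumed to be bulk RNA-seq-like:
non-negative integers whose biological replicate variability is
negative-binomial (variance μ + φμ²).

**Filtering.** A gene enters the analysis iff (a) its CPM reaches
`cpm_threshold` (default 1) in at least
`max(ceil(prevalence_fraction · n_samples), min_prevalent_samples)`
samples (defaults 0.20 and 2), and (b) it has a raw count > 0 in ≥ 1
sample of *every* stage. Criterion (b) deliberately uses raw detection,
not the CPM threshold: "reached CPM ≥ 1" and "was detected" are
different statements, and a gene silent at an entire stage has no
trajectory to estimate. CPM always uses library sizes computed over all
genes *before* filtering, so the filter cannot change the scale of the
values it filters on.

**Standardisation.** Retained genes are transformed to log2(CPM + 1)
and then Z-scored per gene across all samples (ddof = 1). The log step
matters: on the raw CPM scale a gene's peak stage dominates both its
mean and its variance, so standardised trajectories of genuinely
different shapes become nearly collinear, and — because count noise has
standard deviation roughly proportional to the mean — the within-
cluster noise collapses onto a single direction. In simulation this
makes clusters so elongated that one extra k-means cluster keeps
reclaiming > 5% of the WCSS and the elbow rule never fires; on the log
scale noise is approximately homoscedastic across stages, clusters are
round, and the elbow is sharp. `RunConfig(log_cpm=False)` restores
raw-CPM standardisation for strict compatibility with pipelines that
Z-score CPM directly.

Z-scores pool both conditions onto one scale by default, so reference
and comparison profiles are commensurable with a single set of
centroids. `RunConfig(zscore_within_condition=True)` switches to
per-condition standardisation; on simulated data the pooled variant is
noticeably more stable (per-condition Z halves the samples behind each
scale estimate), which is why pooled is the default.

Zero-variance genes cannot be Z-scored; they are dropped and reported
rather than being placed at an arbitrary origin.

**Stage profiles and clustering.** Each gene's trajectory is its mean Z
per stage over one condition's samples, columns in declared stage
order (stage order is always an explicit input — labels like "E18.5"
vs "12wk" do not sort lexically). K-means is Lloyd's algorithm with
squared-Euclidean distance, implemented directly so its determinism
contract is explicit:

- initial centres are k distinct data rows drawn uniformly (without
  replacement) from a seeded generator, per restart;
- nearest-centroid ties break toward the lowest centroid index;
- a cluster emptied during an iteration is reseeded with the point
  farthest from its currently assigned centroid, so returned models
  never contain empty clusters;
- the best of `n_restarts` (default 50, `max_iter` 1000) restarts by
  WCSS is returned, first-found on ties, and centroids are exactly the
  means of their members on return.

The sweep fits every k in `k_min..k_max` (default 2..15) with a per-k
sub-seed derived from `(seed, k)` via `numpy.random.SeedSequence`, so
extending the sweep range never perturbs existing k's results. Identical
seeds give bit-identical models.

**Elbow selection.** With gain(k) = (WCSS(k−1) − WCSS(k)) / WCSS(k−1),
the selected k is the smallest k with gain(k+1) < `gain_threshold`
(default 0.05); if no such k exists the sweep returns `k_max` with the
rationale "no-elbow". The full gain table is stored in the rationale
and the run manifest so the choice can be audited. A WCSS increase
beyond numerical tolerance aborts with an error — a non-monotone curve
means too few restarts to trust any elbow read off it. Note a
structural property of this relative-gain rule: splitting one of K
equal noise clusters reclaims a fixed fraction β of that cluster's
WCSS (β ≈ 0.5 for roughly Gaussian blobs), i.e. ≈ β/K of the total, so
the rule can only terminate once the planted cluster count is
comfortably above β/threshold (~9–10 at 5%). It is a good instrument
for the designs it was built for (k around 9) and a poor one for k ≤ 5.

**Cluster labels.** Fitted clusters are relabelled deterministically —
sorted by centroid value at the first stage, ties by size descending —
so repeated runs and permuted inputs yield identical labels.

**Cross-condition switching.** The comparison condition is *not*
re-clustered: its profiles are assigned to the nearest reference-
trained centroid (ties to the lowest label). This makes "switching"
well-defined without any cluster-matching step, and because converged
k-means is a fixed point of nearest-centroid assignment, projecting the
training profiles reproduces the training assignments exactly. The
k × k transition table counts genes from reference cluster i to
comparison cluster j; its grand total equals the shared gene universe
and row i sums to the size of reference cluster i. Genes present in
only one assignment (e.g. zero-variance in one condition) are excluded
and listed. Re-clustering the comparison condition independently and
matching clusters is a legitimate alternative design; projection was
chosen because it asks the sharper question ("did this gene leave its
reference program?") and needs no matching heuristic.

**Gene-set overlaps.** `intersect_gene_sets` enumerates the disjoint
membership regions of 2–3 named sets (case-sensitive, deduplicated),
the numbers behind a Venn diagram; region counts sum to the union size.

## Assay computations

**ΔΔCt.** Replicate Cts are averaged per (sample, target); per
mitochondrial target, ΔCt = Ct(mt) − Ct(nuclear); ΔΔCt centres ΔCt on
the arithmetic mean of the reference group (equivalently, the
geometric mean of reference ratios is 1 by construction); the relative
copy number is 2^(−ΔΔCt). Each mt target is normalised separately and a
combined `mt_mean` value (geometric mean across targets) is reported,
since whether multiple mt markers should be averaged is a per-study
choice. The estimator is invariant to machine offsets (adding a
constant to every Ct). Group comparisons use Welch's t-test — the
safe default when equal variances are not asserted. Cts outside (0, 45)
cycles are rejected as physically implausible.

**Targeted bisulfite.** Per CpG: percent = methylated / coverage × 100
where coverage ≥ `min_coverage` (default 10 reads, a common amplicon
floor), else flagged `low_coverage` and excluded. Per amplicon and
sample: the coverage-weighted mean over qualifying CpGs (always within
the range of its contributing CpG values); an amplicon with no
qualifying CpG is reported missing (NaN), never 0. Group means are
unweighted over samples. All percentages are invariant to multiplying
read counts by a constant.

## The synthetic-data generator

`simulate_counts` emulates the structure the pipeline assumes: T = 3
ordered stages, two conditions, `samples_per_stage_per_condition`
(default 6) replicates per cell, genes organised into trajectory
archetypes. For gene g (baseline b_g ~ Normal(`baseline_log_mean` 4.6,
sd 1.0), i.e. median ≈ 100 counts) in archetype a under condition c:

    mu[g,s] = exp(b_g + amplitude · archetype_{a(g,c)}[stage(s)]) · libscale_s
    counts[g,s] ~ NB(mean mu, variance mu + dispersion · mu²)

with `amplitude` 2, `dispersion` 0.1 (biological-replicate scale
variability, BCV ≈ 0.32) and library-size scales log-uniform over
(0.5e6, 2e6)/median — enough spread to exercise CPM normalisation. A
fraction `switch_fraction` (default 0.1) of genes uses a different,
uniformly chosen archetype in the comparison condition; the generator
returns the full planted truth. All generators are pure functions of
(design, seed).

The default archetype library is nine evenly spaced unit vectors in the
plane spanned by the orthonormalised linear and quadratic stage
contrasts (orthogonal to the flat trajectory): monotone up/down, early
and late peaks, transient spikes/dips, intermediate ramps. Because
trajectories are injected on the log-mean scale and the pipeline
standardises log CPM, the expected standardised profiles are the
archetypes themselves up to a common norm, so even angular spacing is
even spacing of what the clustering actually sees.

What the simulation does *not* model: litter/batch random effects,
gene–gene correlation, gene-specific dispersions, dropout, or genes
that belong to no program. Passing recovery tests therefore shows the
procedure is correct and well-calibrated under its own assumptions —
not that nine clusters is the right description of any particular real
tissue.

`simulate_ct` plants a copy-number effect as a +`effect_log2` shift of
the comparison group's ΔCt (true ratio 2^(−effect)), with Gaussian
per-replicate noise; `simulate_bisulfite` draws coverage ~
Poisson(`coverage_mean`) and methylated reads ~ Binomial(coverage, p)
per CpG.

## Problem sizes and numerical choices

The recovery benchmarks and the acceptance script use the two study
designs at full size — 1800 genes (9 × 200) by 36 (ovary) or 30
(germ-cell) samples, k swept over 2..15 with 50 restarts, ten seed
replicates per design — which runs in well under a minute per design on
one CPU. Floating-point tolerances: centroid/member-mean agreement
1e-8; Z-score mean/sd checks 1e-10; WCSS monotonicity slack 1e-9
relative. Ties (equidistant centroids, equal-WCSS restarts) always
resolve toward the lowest index/first occurrence, so every code path is
deterministic under a fixed seed.

## Known limitations

- The relative-gain elbow rule is unreliable for small true k (see
  above); users expecting < ~6 programs should inspect the WCSS curve
  rather than trust the automatic selection.
- CPM is the only normalisation (no TMM/median-of-ratios) and there is
  no batch or litter correction; differential expression is out of
  scope (DEG lists are consumed as plain inputs to the overlap
  utility).
- Switch detection inherits k-means' hard-assignment behaviour: a gene
  near a cluster boundary can switch by noise alone. On simulated data
  at the default separation this is rare (false-positive rate ≤ 0.005),
  but boundaries in real data are softer.
- ΔΔCt assumes equal amplification efficiency across targets; no
  efficiency correction is applied.
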