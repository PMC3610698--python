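# Methods

This note documents the statistical procedures implemented in `medipchip`,
their assumptions, the parameters that matter, the synthetic-data model used
to validate them, and the numerical choices made where the design was open.

## 1. Two-channel normalization

Input is a probe-level pair table: per probe (id, chromosome, 0-based
half-open interval, GC fraction) and per comparative hybridization two log2
channel intensities (experimental sample labeled Cy3, control Cy5).  MA
conversion is `M = Cy5 − Cy3`, `A = (Cy5 + Cy3)/2`; stages run strictly in
the order raw → loess → A-quantile → smoothed, enforced by a stage tag.

**GC-grouped loess** (`gc_group_loess`). Probes are split into GC-fraction
quantile groups (default 10 — deciles; the group count is a free choice, and
deciles give ~2,000 probes per group at the default desk scale).  Within each
group a loess curve of M on A (statsmodels `lowess`, span 0.4 by default,
two robustness iterations) is fitted and subtracted from M; A is unchanged.
Assumption: dye bias is a smooth function of intensity whose shape may differ
by GC content, and true differential signal is sparse enough not to bend the
curve (at the defaults, planted regions occupy <1% of probes).  Degenerate
cases: a group smaller than `min_group_size` (default 50) falls back to the
pooled all-probe curve; a group whose A values are all identical falls back
to subtracting its median M.

**A-quantile across arrays** (`aquantile_across_arrays`). Each probe's A is
replaced by the mean of the A values at its rank across arrays, so the
multiset of A values becomes identical on every array while each probe's M is
untouched (the limma "Aquantile" contract; the implementation is cross-checked
against limma's `normalizeBetweenArrays(method="Aquantile")` in the tests).
Ties are resolved by stable sort order; with continuous intensities ties have
measure zero.

**Windowed median smoothing** (`window_median_smooth`). Each probe's M is
replaced by the median of the M values of all probes whose midpoints lie
within ±300 bp of its midpoint (a 600 bp probe-centered window — the
symmetric, probe-centered anchoring is the standard tiling-array choice); the
same is done to A.  A window holding fewer than 3 **distinct probe
positions** yields no value and the probe is flagged invalid; positions, not
array-replicated measurements, are counted, so pooling arrays cannot rescue
an isolated probe.

*Pooling choice.* The smoothing step can pool M values across all arrays
(`pool_arrays=True`, the function default) or smooth within each array
(`pool_arrays=False`).  Pooled smoothing makes every array carry identical
smoothed M, which degenerates the per-hybridization Z-scores and makes the
paired-comparison intersection vacuous.  Because the downstream analysis
computes per-hybridization significance and intersects *pairs* of comparisons
(whose retained-site counts are expected to differ between pairs), the
pipeline and model default is per-array smoothing; pooled smoothing remains
available as an option.  Both readings of "median across all arrays within a
600 bp window" are implemented.

## 2. DMR calling

Per hybridization, probe significance is **empirical**: μ and σ are the mean
and standard deviation of all valid smoothed M values in that hybridization
(i.e. the observed M distribution is treated as the null, scaled normal);
`z = (M − μ)/σ`, `p = 2(1 − Φ(|z|))`, significance at `p < 10⁻⁵`.  Two-sided
p-values are used because regions are called in both directions.  μ, σ are
per-hybridization over valid probes only (a pooled variant is a flag);
invalid probes can never seed or join a region.

Probes significant in **every hybridization** (equivalently, in all unordered
pairs of comparisons — the identity is asserted by a property test) are
clustered: consecutive retained probes within 600 bases of each other whose
mean smoothed M (over hybridizations) agree in sign form a region; the region
interval spans the outermost probe extents (probes are the only observed
positions), its direction is the shared sign (exact-zero mean M tie-breaks to
+1 and is logged), and its p-value is the **maximum** member-probe p over
hybridizations — the most conservative choice for a region-level summary.

Regions are annotated with the promoter of largest overlap (ties to the
lexicographically smaller gene id), their CpG count over `[start, end)` and
density `100·n_cpg/(end − start)`, then filtered: kept iff mean A strictly
exceeds 9.5 **and** density ≥ 1 CpG/100 bp (boundary inclusive).  No
multiple-testing correction is applied beyond the fixed 10⁻⁵ threshold and
the all-pairs intersection, which is itself a strong reproducibility filter.

## 3. Differential-expression selection

Per gene, an additive fixed-effects linear model on log2 signals with
treatment (2 levels) and batch factors; the treatment effect is tested by the
extra-sum-of-squares F-test (computed by shared projection matrices — the
design is identical for all genes — and cross-checked against statsmodels
OLS + type-II ANOVA).  With a single batch the model degrades to a one-way
comparison.  A gene is selected iff `p < 0.05` AND fold change `> 1.2` AND
un-logged mean difference `> 10`.  The test runs on the log2 scale; the fold
(larger of the treated/control un-logged group-mean ratio and its reciprocal)
and the mean difference are computed on un-logged means, keeping the two
magnitude gates on one scale.  No multiple-testing correction is applied;
the fold and mean-difference gates, not the p-value, carry most of the
selectivity.  This is a deliberately plain estimator: variance-component
machinery (e.g. method-of-moments batch corrections in commercial suites) is
out of scope — the reusable computation is the selection rule.

## 4. ECR detection

Windows of 2 Mb at 50 kb steps tile each chromosome (a chromosome shorter
than the window yields one truncated, flagged window).  A gene belongs to a
window when its gene-body midpoint lies in `[start, end)` — half-open, so
each gene is counted once per window regardless of length.  Each window with
≥1 gene is tested one-sided for over-representation:
`z = (x/n − π₀)/√(π₀(1−π₀)/n)` with π₀ the genome-wide DE fraction (a
chromosome-wide reference is available via an option), flagged at `p < 0.05`.
Consecutive flagged windows (same chromosome, one stride apart) merge into
clusters; cluster DE genes are those with midpoints inside the merged
interval.  DMRs associate with a cluster at gap distance ≤ 2 Mb
(many-to-many).  DMR–expression correlation distinguishes **direct** pairs
(the DMR's promoter gene is itself DE) from **distal** pairs (DMR within 2 Mb
of a DE gene body, direct pairs excluded).

No correction is made for the 40-fold overlap of adjacent windows: member
windows are strongly dependent, so the realized fraction of flagged windows
under a Bernoulli null is somewhat above the nominal 0.05 in small genomes;
the validation suite bounds it at 0.08 and documents the inflation rather
than hiding it.

## 5. Synthetic-data model

The generator emulates the statistical structure the analysis assumes, at a
desk scale (~35× linear reduction of the real platform):

* **Geometry** — 2 chromosomes × 10 Mb, 400 promoters placed one per evenly
  sized slot with random jitter (non-overlapping by construction), each
  spanning −3,880/+970 bp around its TSS (strand-reflected), tiled with
  50–75 mer probes at 100 bp midpoint spacing (~48 probes/promoter, ~19,200
  total), 3 hybridization pairs.  Coordinates are 0-based half-open; strand
  affects only promoter construction.
* **CpG landscape** — each promoter draws a CpG/100 bp class from
  {1: 0.35, 2: 0.35, 3: 0.15, 5: 0.10, 8: 0.05} (mostly 1–2 CpG/100 bp with a
  thin tail — the low-density "CpG desert" composition reported for promoter
  DMRs) and places that many CpGs uniformly; intergenic background is
  0.3 CpG/100 bp.  Probe GC fraction mildly tracks the CpG class, which is
  what gives the GC grouping in normalization something to do.
* **Hybridizations** — per-probe abundance `A ≈ 10.5` log2 (promoter-level
  sd 0.3 + probe-level sd 0.3), placing typical region mean A above the 9.5
  intensity filter as on the real platform; probe noise on M is Gaussian,
  sd 0.3 per hybridization.  The scanner's raw-signal distribution is not
  publicly characterized; Gaussian-on-log2 is a stand-in, and conclusions
  that depend on heavy tails are outside what this validation shows.  Dye
  bias (amplitude configurable, default 1 log2 unit) is the minimal smooth
  intensity-and-GC structure that makes GC-grouped loess non-trivial: an
  intensity trend whose slope scales with GC plus an additive GC offset, so
  every GC group needs its own normalization curve and a local-linear loess
  can remove it exactly.  Planted DMRs shift E[M] by ±ΔM (default 4× noise
  sd) consistently across hybridizations.
* **Truth planting** — DMRs occupy runs of 6–10 consecutive probes in
  distinct promoters whose realized CpG density over the run is ≥ 1.2/100 bp:
  strictly above the downstream 1.0 filter, because a called region's
  interval is trimmed to its significant probes and truth planted exactly on
  the filter boundary would be censored about half the time by measurement
  jitter rather than by detection.  DE genes are Bernoulli(0.05) background
  plus Bernoulli(0.5) inside planted cluster intervals (10× enrichment,
  1 Mb default span); planted DE genes have treated/control group-mean ratio
  equal to their multiplier (default 2×).  Expression uses 3 replicate pairs
  (control + treated per batch), batch effects sd 0.25, residual sd 0.2 on
  log2; un-logged signals are stored because the mean-difference gate is
  un-logged.  Promoter sequences suppress spontaneous CG dinucleotides, then
  write in the annotated CpGs, then plant the motif at truth-specified
  offsets (a clearly synthetic 20-mer IUPAC placeholder ships for demos —
  the environmentally responsive methylation motifs studied on real data are
  not redistributed here).
* **Determinism** — every generator is a pure function of (parameters,
  seed); the pipeline derives one substream seed per stage from the root
  seed, and reruns are byte-identical.

**What passing validation does and does not show.** Recovery and calibration
on this generator demonstrate that the implementation computes the intended
statistics and that the pipeline's thresholds behave as designed under the
assumed noise model.  They do not establish performance on real arrays,
which additionally show spatial artifacts, probe cross-hybridization,
fragment-size effects and non-Gaussian tails — all deliberately out of the
generator's scope.

## 6. Numerical choices and validation sizes

* Loess: statsmodels `lowess` with `delta` interpolation (0.5% of the A
  range) for speed; fitted curves are linearly interpolated to probe A
  values.
* The per-gene F-test clips p-values to [1e-300, 1]; a zero residual sum of
  squares (noise-free input) maps to p → 0 rather than NaN.
* The residual-trend contract after GC-grouped loess is measured by refitting
  a **wide-span** loess (frac 0.8, no robustness iterations) of M on A per GC
  group and taking the sup-norm of its fitted values (tolerance 0.05, with
  per-group mean |M| < 0.02).  A narrow-span refit cannot measure this
  contract at desk scale: its own boundary estimation noise at ~2,000 probes
  per group is 0.05–0.25 even on perfectly normalized pure noise, while the
  wide-span refit keeps estimation noise well under the tolerance and still
  detects the planted bias (sup-norm ~1.3 before normalization).
* The Z-vs-binomial agreement check for window over-representation compares
  against the **mid-P** exact upper tail (`P(X > x) + ½P(X = x)`), the
  discreteness-respecting analog of a z statistic without continuity
  correction.
* Validation sizes: calibration and recovery suites run 10 seeds at the
  default 19,200-probe geometry; oracle-equivalence checks run exact
  brute-force re-computations on instances up to ~5,000 records.  These sizes
  make the whole suite run in a few minutes on one CPU while keeping the
  binomial arithmetic of every bound comfortably away from its threshold.

## 7. Known limitations

* The empirical-Z null treats the whole smoothed M distribution as noise; a
  genome with pervasive true differential methylation would inflate σ and
  cost sensitivity.
* Median smoothing correlates neighboring probes, so significant probes
  arrive in runs; the probe-level p-values are not independent and are used
  only through the region-level, intersection-filtered calls.
* The DE model assumes homoscedastic log2 signals and additive batch
  effects; no moderation/shrinkage across genes is attempted.
* ECR detection inherits the window Z-test's normal approximation; windows
  with very few genes are tested but carry little power, and no
  multiple-testing correction across windows is applied (by design).
* `pool_arrays=True` reproduces the literal pooled reading of the smoothing
  step but collapses per-hybridization variation; use it only with a single
  hybridization or when the downstream intersection is not of interest.
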