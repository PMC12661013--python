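# Methods

## Scope and data model

The package analyzes genus × sample abundance matrices of soil
metagenomes, restricted to plant-beneficial bacteria (PBB) through a
trait registry, under a pesticide-risk gradient. Abundances are reads
per million (RPM); the RPM denominator is the per-sample library size
from metadata, never the matrix column sum, because unassigned reads
exist. Kraken2-style reports are read at a single rank using the
directly-assigned read counts (column 3), not clade totals, so sibling
taxa never double-count. Alignment hits (DIAMOND/BLAST tabular) are
filtered at e-value ≤ 10⁻³, query coverage ≥ 60%, identity ≥ 70% — all
boundaries inclusive, since filter conventions in alignment tools are
inclusive and the thresholds' strictness is otherwise unspecified — then
reduced to one best hit per query by bit score.

## Statistical procedures

**Risk classification.** RI = Σ PEC/NEC with strict unit consistency per
pesticide (no conversions); classes low (RI ≤ 1), medium (1 < RI ≤ 3),
high (RI > 3), exactly as the upstream risk framework prints them. A
precomputed class column overrides a coexisting index with a logged
warning, because upstream class assignments may encode corrections the
index does not carry.

**Diversity.** Shannon uses the natural log by default (`base=2`
available); empty samples and singleton communities get H′ = 0.
Bray–Curtis assigns 0 to a pair of all-zero samples (identical
emptiness) rather than NaN.

**PERMANOVA.** Multi-factor, sequential (Type-I) sums of squares: the
Gower-centered inner-product matrix G = −½ J (D∘D) J is projected onto
the cumulative dummy design of the ordered factors via QR; pseudo-F per
factor uses the residual mean square; p-values permute whole samples
with the add-one estimator p = (1 + #{F* ≥ F}) / (1 + B). Permutation
counts and seeds are explicit everywhere. The default factor order in
the pipeline is (risk class, land use, coarse region), dropping factors
with a single level; region is a quadrant label about the median
coordinates — a deliberately crude surrogate for site grouping.

**Mantel / partial Mantel.** Pearson correlation over upper-triangle
entries; B is permuted by simultaneous row/column reordering. One-tailed
("greater") by default, matching the distance-decay hypothesis; the
partial statistic is the first-order partial correlation of the three
pairwise Mantel correlations. A control matrix perfectly collinear with
either argument is rejected as degenerate.

**PCNM.** Truncation distance t = longest edge of the minimum spanning
tree of the geographic distance matrix (the smallest t keeping the graph
connected); distances > t are replaced by 4t; the truncated matrix is
Gower-centered and eigendecomposed; positive-eigenvalue axes, scaled by
√eigenvalue, form the basis. No Moran's-I sub-selection — all positive
axes are kept, and the pipeline caps the axes passed to db-RDA at 20 to
preserve residual degrees of freedom at desk-scale sample sizes.

**db-RDA.** Principal-coordinate embedding of the distance matrix with
negative-eigenvalue axes dropped (no Lingoes/Cailliez correction — the
simplest defensible default; under a Euclidean distance the result is
exactly classical RDA, which a structural test pins to 1e-8). Covariates
are regressed out of both the embedding and the constraint; R² is the
constrained fraction of remaining inertia; significance permutes the
residuals of the reduced (covariates-only) model. Residual permutation
was chosen over raw-data permutation because the null of interest is
"no constraint effect given the spatial structure".

**Group tests.** Welch's t (two-sided) with Welch–Satterthwaite df;
degenerate zero-variance cases resolve to p = 1 (equal means) or p = 0
with a warning. Mann–Whitney U uses the exact distribution for combined
n ≤ 12 without ties, otherwise the tie-corrected normal approximation
with continuity correction. Kruskal–Wallis applies the tie correction
and resolves all-identical data to H = 0, p = 1. Dunn's post-hoc z uses
the pooled-rank variance with the Σ(t³−t)/(12(N−1)) tie term and
Holm–Šidák step-down adjustment. BH and Holm–Šidák go through
statsmodels.

**Differential screen.** Genera nonzero in ≥ 5% of retained samples are
tested (rarer genera are reported untested — prevalence filtering
stabilizes Welch variances); Welch per genus, high vs low class (medium
excluded: the contrast of interest is change with *increasing* risk); BH
across tested genera; direction up/down by the sign of the mean
difference at q < 0.05, with a flag to threshold raw p instead. The
screen operates on RPM, not relative abundance.

**Factorial interactions.** Cells: C (low risk, low covariate),
P (high risk, low covariate), F (low risk, high covariate), PF (both),
with the covariate split at its median within retained samples (ties to
the low side; the split is invariant to monotone rescaling). Pooled SD
over the four cells, df = N − 4, J = 1 − 3/(4df − 1); main effects use
the 2s denominator, the interaction d_I divides by s (a `"2s"` switch
exists; the /s default follows the standard factorial meta-analysis
parameterization). v_I = Σ 1/nᵢ + d_I²/(2N); 95% t-interval.
Classification: additive iff 0 ∈ CI; otherwise synergistic when d_I has
the sign of d_P + d_F, antagonistic otherwise; a zero main-effect sum is
resolved by sign(d_I) and flagged "undirected". The screen reports both
the interval half-width and the SD of d_I so either error-bar convention
can be plotted.

**Pathway completeness.** Steps are unordered requirements; alternatives
within a step are OR-semantics (KEGG-module-style granularity). A step
counts as covered at ≥ 1 hit contig by default (the presence threshold
is configurable because "presence" has no canonical definition at the
contig level). Completeness is exactly covered/total — tested as a
rational, not a float tolerance. Decreased biosynthesis requires both
BH-adjusted Kruskal–Wallis q < 0.05 across risk classes and
median(high) < median(low).

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume;
its defaults are the package's standard study conditions, at roughly
quarter scale of a large global survey so permutation batteries finish
in seconds on one CPU:

- 48/54/98 samples in the low/medium/high risk classes (preserving the
  strong class imbalance of agricultural surveys), 200 genera of which
  30% are PBB with trait probabilities 0.65/0.35/0.30 for
  PGP/biocontrol/stress resistance;
- log-normal abundances: between-genus baseline SD 1.5, within-genus
  per-sample noise SD 1.0; Poisson counts at ~2 M reads/library with 80%
  assignment, so integer profiles and RPM normalization are exercised;
- a spatially autocorrelated composition: 6 independent Gaussian fields
  with exponential covariance (range 800 km) over coordinates drawn in a
  continental box, with per-genus loadings scaled by 1/√6 so total
  spatial log-variance is exactly spatial_sd² = 1 regardless of the
  field count. Six smaller fields rather than one large one makes the
  induced distance decay stable across realizations (Mantel r ≈ 0.2);
- planted genus effects: 20 suppressed and 8 enriched PBB genera, log
  offsets in units of the noise SD, full effect in the high class and
  half in medium;
- planted diversity effects: an **evenness tilt**. A sample's PBB shares
  q are replaced by q^(1+γ), with γ solved by bisection so the
  sub-community Shannon index moves by exactly the requested multiple of
  its across-sample SD. This plants the risk-gradient Shannon decline
  (default 1 SD in the high class) and the factorial interaction (an
  extra −1.5 SD in the PF cell of one designated covariate,
  annual precipitation by default) with direct control of effect sizes;
- per-sample KO content: each pathway step of the demo growth-factor
  catalog is covered with probability 0.9, dropping to 0.5 in the high
  class for 5 randomly chosen "decreased" pathways (0.7 in medium);
  plus CNPS marker-gene counts with C/N markers declining and S markers
  rising along the gradient;
- a truth record lists every planted choice, and the same seed
  reproduces the bundle byte-for-byte.

What the generator does **not** emulate: real taxonomic correlation
structure (genera are conditionally independent given the spatial
fields), compositional interactions beyond renormalization, sequencing
batch effects, or spatially structured pesticide risk (risk class is
independent of geography by default, so the partial-Mantel confounding
scenario must be constructed explicitly, as in the tests). Passing tests
therefore demonstrate statistical correctness and recoverability under a
clean generative model, not performance on real surveys.

Two deliberate consequences of the generative model show up in
calibration numbers. First, suppressing 20 genera genuinely raises the
remaining genera's shares (closure), so the differential screen's
empirical "false" discovery rate against the planted list runs at ~0.08
rather than the nominal 0.05 — those extra calls are real compositional
changes. Second, the recovery simulations state planted effects on the
scale the test operates on: the 1.5-SD suppression condition uses a
log-noise SD of 0.5 with multiplier 0.4, which yields a standardized
mean difference of ≈1.5 on the RPM scale (under a log-noise SD of 1, a
1.5-SD raw-scale shift is unattainable — the lognormal's own skew caps
the standardized mean shift near 0.76).

## Known limitations

- With unadjusted per-covariate 95% intervals, screening 12 covariates
  yields ≈ 0.6 expected false non-additive calls under the null (half of
  them synergistic). A run of the screen should therefore be read
  rank-first: the planted/true interacting factor reliably tops the
  |d_I| ranking (≥ 90% of replicates), but the *set* of synergy calls
  includes a false positive in roughly a quarter of replicates. Demanding
  a clean synergy set would require adjusting the intervals across
  covariates, which the screen deliberately does not do (the effect-size
  framework it mirrors reports unadjusted intervals).
- The factorial cell construction (median split of a continuous
  covariate within low/high risk samples) is a declared convention;
  other dichotomizations will move d_I.
- PCNM axes are capped (default 20) before db-RDA; with hundreds of
  samples and fine spatial structure the cap is conservative.
- Haversine distances assume a spherical Earth (R = 6371.0088 km);
  errors vs. ellipsoidal geodesics are < 0.5%, irrelevant at the scales
  used.
- The bundled trait registry, growth-factor catalog, and CNPS map are
  small demonstration versions; real analyses should supply full curated
  catalogs in the same formats.
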