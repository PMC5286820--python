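# Methods

This note records the models, algorithms, parameter choices and known
limitations behind `rootskew`.

## Root morphometrics

A traced root is an ordered polyline `(x_i, y_i)` in millimetres, from the
position at gravistimulation to the tip, with y increasing with gravity on
the plate face. Derived statistics:

- **Arc length** `L = Σ ‖p_{i+1} − p_i‖`.
- **Horizontal / vertical growth index** `HGI = (x_tip − x_start)/L`,
  `VGI = (y_tip − y_start)/L`. For a straight root at angle θ from
  vertical, `HGI = sin θ` and `VGI = cos θ`. HGI is signed (positive to
  the viewer's right on the plate face); traces digitised from images
  taken through the media carry `view_flipped=True` and are negated so
  one sign convention holds throughout. Group tables report both signed
  and absolute HGI, because signed means can cancel across roots skewing
  in opposite directions while the magnitude is what distinguishes
  skewing ecotypes.
- **Straightness** `STR = ‖p_tip − p_start‖ / L ∈ (0, 1]`, 1 iff all
  points are collinear in order.
- **Wave count / wave density.** No standard algorithm exists for
  counting waves on a traced root, so the package defines one: the signed
  perpendicular deviation of each point from the start-to-tip chord is
  smoothed by a centred moving average (window = 5% of the points,
  minimum 3, configurable); maximal runs of constant sign whose peak
  |deviation| reaches an amplitude threshold (default 0.1 mm) are counted
  as half-waves, consecutive same-sign qualifying runs merge (this can
  happen when a sub-threshold dip between them is discarded), and
  `wave_count = half_waves // 2`, `WD = wave_count / L`. The threshold
  separates waving from digitisation jitter; 0.1 mm is well below typical
  wave amplitudes (~0.5 mm) and well above smoothed tracing noise.
  Wave counts are invariant under uniform rescaling of both axes as long
  as the amplitude stays above threshold; WD scales inversely.

Degenerate inputs: fewer than 2 points, repeated consecutive points,
non-finite coordinates and zero-length traces raise `InvalidTraceError`;
a trace whose start and tip coincide has no chord and is rejected by the
wave counter.

## Group statistics

Per (ecotype × angle) cell: mean and Student-t 95% CI (`mean ±
t_{0.975, n−1}·s/√n`); a single observation yields a mean with no CI, a
zero-variance cell collapses the CI onto the mean. The t CI was chosen
over a bootstrap because cell sizes are small and the trait distributions
approximately normal.

The two-way ANOVA uses Type-II sums of squares (each main effect adjusted
for the other; interaction from the full model), fitted through
statsmodels OLS / `anova_lm(typ=2)`. Rank-deficient designs (e.g. an
empty cell) raise `RankDeficientDesignError` rather than silently
dropping columns.

Post hoc comparisons use Scheffé's method: for groups i, j the contrast
statistic `F_c = (m_i − m_j)² / (MSE·(1/n_i + 1/n_j))` is referred to the
bound `p = P(F_{k−1, df_err} ≥ F_c/(k−1))`. Grouping follows the
interaction rule: the six cells when the interaction p < α (default
0.05), the marginal levels of each factor otherwise. Letters come from an
insert-and-absorb compact letter display processed in descending mean
order, which makes the output deterministic under ties.

## Differential expression

The pipeline consumes an already normalised log2 gene-level matrix.
`quantile_normalize` is provided as an optional stand-in for upstream
array summarisation (which is out of scope): every column is mapped onto
the mean of the columns' order statistics, ties receiving the average
reference value.

Every contrast is a two-group comparison on 3 replicates per cell:
within-ecotype tilted angles (45°, 135°) against the 90° vertical
control, and Col-0 against WS (WS the reference, so `log2fc` = Col-0 −
WS) at each angle. The statistic is the empirical-Bayes moderated t

    s̃² = (d0·s0² + d·s²)/(d0 + d),  t̃ = Δmean / (s̃·√(1/n₁+1/n₂)),

with d = n₁+n₂−2 and d0+d degrees of freedom. The prior (d0, s0²) is
moment-matched on log sample variances under the scaled-F model
`s² ~ s0²·F(d, d0)`: the sample mean and variance of `log s²` are equated
to their theoretical values (digamma/trigamma identities) and the
trigamma equation inverted by Newton iteration. When the spread of log
variances does not exceed `trigamma(d/2)` there is no detectable
gene-to-gene variance heterogeneity and the prior becomes a point mass
(d0 = ∞) at the **arithmetic** mean variance; this convention makes the
statistic reduce exactly to the pooled t when all genes share one sample
variance (a geometric-mean convention would not — at d = 4 it would
inflate s0² by a factor (d/2)/exp(ψ(d/2)) ≈ 1.31). Both conventions are
consistent estimators under the model; the finite-d0 branch is checked in
the tests against an independent numeric solver of the moment equations
and against Bioconductor limma. No mean-variance trend is fitted. With
moderation off (d0 = 0) the statistic is the ordinary pooled-variance t;
a zero-variance gene then gets p = 0 if its means differ and p = 1
otherwise. p-values are two-sided throughout.

Significance: `|log2fc| > 1` and `p < 0.05`, both strict; `q < 0.05`
under Benjamini–Hochberg step-up adjustment
(`q_(i) = min_{j≥i} m·p_(j)/j`, capped at 1) is carried as an additional
flag rather than a gate, trading some false positives for sensitivity at
n = 3.

## Candidate-gene inference

Seven contrasts form the comparison matrix. Processing order:

1. **Inherent filter.** A gene significant between ecotypes at all three
   angles whose three log2fc values share a sign and span at most 1 log2
   unit (max − min ≤ 1, i.e. "within ±1 of each other"; the span cut is
   configurable for the alternative span ≤ 2 reading) is a constitutive
   ecotype difference and is removed.
2. **Categories.** The remaining 2³ significance patterns over
   (45°, 90°, 135°) map to Categories I–VI (see `patterns` module
   docstring); two-angle categories (II, III, V) additionally require
   sign agreement between their two significant log2fc values —
   discordant genes become OTHER, as do (T,T,T) genes that survive the
   filter. OTHER is excluded from candidates (conservative: no pattern
   interpretation exists for it). Within-ecotype shared genes do *not*
   require sign agreement — an angle-responsive gene may flip direction
   between 45° and 135° and remain a candidate.
3. **Candidate sets.** Physiology = union of the two within-WS DE sets;
   genotype = IV ∪ V ∪ VI; overlap = their intersection; HPSGC = overlap
   genes in the WS-135°-vs-90° DE set with category V or VI — the
   135°-on-both-sides conjunction, since 135° elicits skewing with
   minimal waving and is therefore the condition that isolates skewing
   from the waving confound.

Invariants asserted in code: categories partition the universe; HPSGC ⊆
overlap ⊆ physiology ∩ genotype.

## Synthetic data

The trace generator draws, per (ecotype × angle) cell, roots whose
noiseless path is a straight axis tilted by a planted skew angle with a
sinusoidal lateral component of a planted integer number of full periods
(so the noiseless HGI equals sin(skew) exactly). Defaults encode the
study conditions: skew 20° for WS on tilted plates and 2° for Col-0, 0°
vertical; 4 waves at 45° for both ecotypes, 1 for WS at 135° (reduced
waving), 0 otherwise; amplitude 0.5 mm, root length 25 mm, 300 points.
Positional noise (default SD 0.05 mm) is applied as a *smooth* displacement
field (Gaussian draws at coarse knots, interpolated), mimicking tracing
error, which is correlated along a root; independent per-point jitter at
sub-pixel spacing would spuriously inflate polygonal arc length by tens
of percent and is not how digitised traces behave. Default 12 roots per
cell keeps the suite fast while leaving clear group separation; real
assays use more.

The expression generator plants, on top of gene baselines ~ U(6, 12)
log2 units and Gaussian residuals (σ = 0.25, the microarray-scale
convention; no gene–gene correlation, since the pipeline is gene-wise),
class-specific shifts of e = 2.0 log2 units: INHERENT (Col-0 shifted at
all angles), CAT_I..VI (Col-0 shifted at that category's angles),
WS_ANGLE_45/135 (WS shifted at the tilted angle relative to its
vertical control) and HPSGC_LIKE (a WS-specific 135° response). Because
shifting WS alone at a tilted angle already creates the between-ecotype
difference there, WS_ANGLE_135 and HPSGC_LIKE are mechanically identical
and WS_ANGLE_45 genes land in Category IV; the truth table records these
expectations explicitly. 3 replicates per cell matches the study design;
at these settings the per-contrast effect size is |t| ≈ e/(σ√(2/3)) ≈ 9.8,
so near-complete recovery is the correct expectation and the planted
recovery criteria (≥95% category recovery, ≤1% null contamination) test
calibration rather than power. An optional scaled-inverse-chi-square
variance mixture exercises the moderation path. What the generator does
*not* emulate: probe-level effects, array batch structure, correlated
gene modules, non-Gaussian tails — passing tests demonstrate the
algebra and calibration of the pipeline, not robustness to those
artefacts.

`study_scale_comparison_matrix` plants structure one level higher:
contrast tables are written directly (members |log2fc| = 2, p = 1e-4,
non-members null) with configurable set sizes whose defaults exercise
every path at realistic scale — six category blocks (61/24/43/38/26/64,
with up/down splits 19/42, 15/9, 20/23, 30/8, 20/6, 14/50), a 30-gene
inherent block, within-WS sets of 66 and 40 sharing 14 genes (one of
which flips sign between angles), an overlap of 16 of which 11 are
135°-anchored, and within-Col-0 sets of 22 (3 up/19 down) and 6 sharing
4. This fixture is synthetic; it pins down the exact expected output of
the set-algebra and classification stages.

## Problem sizes and numerics

The default test and acceptance runs use 2000 genes × 18 samples for the
simulation studies, 500 genes for the set-structure fixture, 20 random
instances for each statistical oracle comparison, and 72 simulated roots;
a full pipeline run at these sizes completes in a few seconds on one CPU.
Newton inversion of the trigamma function iterates to a relative step
below 1e-13 (matching the brute-force brentq solution to ~1e-8 or
better). Oracle comparisons use absolute tolerance 1e-8; geometric
identities 1e-6 or better.

## Known limitations

- Wave counting is definition-dependent; other deviation measures
  (curvature inflections, Fourier peaks) would give different counts on
  irregular roots. The chord-deviation rule matches the "waves per
  millimetre" definition and is robust to jitter, but is not validated
  against hand counts.
- The moderated t assumes independent genes and equal group variances
  within a gene; the between-ecotype contrasts are fit pairwise rather
  than within a single six-group model, so residual variance is estimated
  per contrast.
- The inherent filter's span rule is one reading of "within ±1 fold
  change"; the alternative (span ≤ 2) is available via configuration but
  changes removals.
- GEO series-matrix ingestion assumes gene-level rows; probe-to-gene
  collapsing is out of scope.
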