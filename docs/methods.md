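# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical decisions a user auditing results should know about.

## Coordinates and formats

All intervals are 0-based half-open (BED convention); touching intervals do
not overlap. Interval collections are pandas DataFrames; overlap queries use
interval trees. On-disk formats are plain text: BED3/BED6, BEDPE (header
optional), bedGraph at fixed bin size, gene models as TSV
(`chrom start end strand gene_id`), counts as features × samples TSV with a
sample sidecar (`sample condition spike_total`), and Hi-C as sparse
upper-triangle COO text with a `#chrom <name> <length> <resolution>` header.
BED records on unknown chromosomes are errors only when a genome is
supplied; promoter windows are strictly upstream of the TSS (default
3000 bp), clipped at chromosome bounds, and dropped only if clipping leaves
zero width.

## Count statistics

One NB framework serves ChIP peaks, RNA genes, and loop-pixel counts.

**Scale factors** are multiply-convention throughout: multiplying a sample's
counts by its factor puts samples on a common effective depth; factors are
rescaled to arithmetic mean 1. Spike-in factors are `∝ 1/spike_total`;
median-of-ratios factors (for data without spike-in) invert the per-sample
median ratio to the feature-wise geometric mean; total-count factors exist
as the deliberately-wrong contrast for the spike-in demonstration, since
they erase a genuine global shift by construction.

**Dispersions** are method-of-moments per feature,
`α̂ = max(10⁻⁸, (s² − m)/m²)` on normalized counts, with `s²` the pooled
within-group variance when condition labels are available (otherwise a real
between-group difference masquerades as dispersion and destroys power).
Each `α̂` is then pulled 90% of the way toward the 2%-trimmed ensemble mean.
The heavy pull is deliberate: with two replicates per group the per-feature
estimate has ~2 degrees of freedom, and weighting it strongly makes the
Wald test anti-conservative (measured null type-I ≈ 0.08–0.10 at a 50%
pull versus ≈ 0.06 at 90%); a 10% trim was also measured to bias the center
of this highly skewed distribution low. Both knobs remain arguments.

**Wald test.** `log2FC = log2(m₂ + ½) − log2(m₁ + ½)` on normalized group
means (pseudocount ½ guards zeros; it also makes exact scale-equivariance
approximate, at the ~1e-3 level for typical depths). The SE comes from the
delta method with per-sample NB variance `μ + αμ²` mapped through the
factors; two-sided p from the normal. BH adjustment is standard step-up.
Labels: `enhanced`/`weakened` at q < 0.05 (fold threshold optional); RNA
mode uses raw p < 0.05 with fold > 2, the conventional rule for that assay.

## Hi-C

Matrices are dense in memory (targets are chromosomes of a few hundred
bins) and symmetric by construction. **ICE**: bins with coverage more than
3 MADs below the median (or zero) are masked; biases iterate by the square
root of the relative row sums until the maximum relative deviation is
below 1e-5 (default), with the gauge fixed by unit geometric mean.
**Expected** is the per-diagonal mean of the balanced matrix over unmasked
pairs. **Contact probability** averages the expected profile within
log-spaced distance strata and normalizes the curve to sum 1.
**Compartments**: rebin to 250 kb, balance, O/E, Pearson correlation matrix
over unmasked bins, leading eigenvector scaled by √λ₁; the sign — arbitrary
from eigendecomposition — is oriented positive-A against a reference
activity track (promoter density per bin by default). This replaces the
likelihood-based compartment caller used in the original setting with a
deterministic, dependency-free eigenvector method with the same A/B
semantics. **SCC** smooths both raw matrices with a uniform filter
(half-width 1 by default), computes per-diagonal Pearson r up to 5 Mb, and
aggregates with weights `N_k σ_ak σ_bk`. Smoothing uses nearest-edge
padding and trims the filter half-width from each diagonal's ends: zero
padding would imprint an identical edge dip on both matrices and bias the
null correlation upward (measured ≈ +0.19 on independent flat matrices).

## Loops, domains, APA

**Loop calling** is single-resolution donut-filter enrichment. For every
unmasked pixel farther from the diagonal than the donut span (peak half-width
p = 1, donut half-width w = 5) and within 5 Mb: four local expected values
are computed by convolving the balanced matrix and the distance-expected
matrix with 0/1 kernels (donut annulus excluding the center row/column,
lower-left quadrant, horizontal and vertical stripes), each scaled by the
pixel's distance-expected; the most conservative, mapped back to raw scale
through the biases, parameterizes a Poisson upper-tail p-value for the raw
count. BH runs within log2 distance strata at FDR 0.1; surviving pixels
must also exceed fold thresholds 1.75 (donut, lower-left) and 1.5
(stripes) — the published defaults of the donut-filter family — and
8-connected clusters merge into one call at their maximum-observed pixel.
Multi-resolution merging is out of scope.

**Domains** come from the insulation score (log2 of the w-bin cross-diamond
mean over its chromosome-wide mean, w = 4 bins): boundaries are local minima
with prominence ≥ 0.3; domains fill the spans between boundaries. In a
sharp two-block fixture the two junction-adjacent bins both see a fully
cross-block diamond, so either may be the literal minimum. **Loop domains**
are domains with a loop anchor within 1 bin of each boundary; two
conditions' loop-domain sets merge when both boundary windows (± slack)
overlap, under transitive closure, keeping the union span and both
provenances. A merged loop domain inherits its supporting loops'
differential labels; whether the original analysis derived its differential
domain labels from loop-level or domain-level tests is ambiguous, and this
package states its choice here.

**Differential loops** sum raw counts in the (2·pad+1)² block around each
loop pixel per replicate (pad 1) and reuse the NB framework with
median-of-ratios factors; `strengthened`/`weakened` at q < 0.05. Note the
block sum dilutes a planted center ratio: a 2× center with a Gaussian 3×3
kernel yields a measured block ratio ≈ 1.6.

**APA** averages O/E submatrices (window w, default 5 in the pipeline where
planted loops start at 12 bins; 10 in the stand-alone fixtures) around loop
pixels, dropping loops within 2w+1 bins of the diagonal or clipped by the
matrix edge; the score is the center pixel over the mean of the
lower-left ⌈w/2⌉ × ⌈w/2⌉ corner block, per loop and in aggregate. Condition
comparison is a paired two-tailed t-test on per-loop scores.

## Integration

Anchor typing precedence is promoter > enhancer > insulator (any-overlap):
enhancers already exclude promoters by construction, and insulator overlap
is near-universal at CTCF anchors, which would otherwise swamp the E/P
classes. With 50 kb synthetic anchors and ~1 gene per 30 kb, most anchors
touch some promoter, so P-labeled classes dominate and I-I is rare — a
resolution artifact of the toy scale, not of the rule. The permutation
statistic is total peak signal overlapping targets (the quantity "level of
binding" suggests); the null re-places peaks uniformly within their own
chromosomes, overlap-permitting, carrying signals; both the normal-tail p
(per the stated normality assumption) and an empirical rank p are reported.
The overlap of strengthened E-P loops with enhanced peaks is anchor-based
by default (span mode available). Expression concordance reports both the
fraction of target genes with log2FC > 0 and the fraction passing the DE
up rule, plus a one-tailed chi-square (df 1, no continuity correction,
one-tailed p = p_two/2 when the sample association matches the
alternative). The stoichiometry helper is arithmetic on XIC peak areas,
reported as a percentage rounded to 2 decimals.

## Synthetic generator

Defaults define the study conditions: chr1 20 Mb + chr2 10 Mb at 50 kb
(600 bins total), 1000 genes, 2000 peaks, 600 enhancers, 60 loops (15%
strengthened at 2×, 15% weakened at 0.5× in MUT, base strength 3× over
background), 15% enhanced peaks at 2× on top of a 1.3× global MUT binding
factor, ChIP mean 200 with dispersion 0.05, RNA mean 500 with dispersion
0.02, compartment contrast a = 0.3 at 250 kb, domain boost 0.5, decay
`(1 + d/s₀)⁻¹` with s₀ = 100 kb, Hi-C base intensity 150 (chosen so the
planted long-range differential loops are identifiable at the generator's
stated recovery contract), and per-replicate depth factors near 1. Counts
are hierarchical gamma–Poisson: one latent level per feature (gamma with
the configured dispersion), Poisson replicates at depth — replicate noise
is Poisson, feature-to-feature variation is NB. Spike totals are exactly
proportional to depths with equal spike truth across conditions.

Structure is planted coherently: two-thirds of loops sit exactly on domain
boundaries (the loop-domain substrate); every loop anchor carries a peak;
strengthened loops carry a 12-gene promoter cluster on the left anchor
(Hox-like clustering; it also gives the concordance estimate ~100 genes
instead of ~9) and a forced enhancer on the promoter-free right anchor, so
they type as E-P; their anchor peaks are planted enhanced; cluster genes
are up-regulated at 3× with probability 0.65 (the configured concordance),
all other genes null. Because non-up target genes are null, the fraction
with log2FC > 0 converges to c + (1−c)/2, not c; the fraction passing the
DE rule converges to ≈ c·power ≈ c and is the recovery metric compared to
the configured value. Stage seeds are decoupled (changing the expression
seed cannot alter Hi-C output).

What the generator does *not* emulate: real-study-scale counts (thousands of
loops, tens of thousands of peaks — recovery is tested statistically, not
by matching real-data tallies), read-level data, restriction-fragment
geometry, inter-chromosomal contacts, exon structure, GC/mappability bias,
or batch effects. Passing tests therefore show the estimators recover the
planted statistical structure at realistic signal-to-noise, not that they
are robust to every artifact of real libraries.

## Pipeline and determinism

`run_pipeline` chains simulate → ChIP differential → Hi-C core →
loops/domains/APA → integration, pooling replicates within condition for
calling and using per-replicate raw matrices for quantification; the union
loop set dedups calls whose anchors agree within 2 bins, keeping the
strongest pixel. All randomness flows from one master seed through
`SeedSequence` spawns; reports are JSON with sorted keys and rounded
floats, byte-identical for identical config + seed. The acceptance script
replays every headline computation from scratch at sizes that keep the
whole run under a minute on one CPU.

## Known limitations

- The Wald test's residual anti-conservatism (~0.06 at nominal 0.05 with
  2+2 replicates) is inherent to plugging estimated dispersions into a
  normal reference; a t-reference or exact test would trade power.
- Compartment sign orientation needs a reference track; on a genome with no
  promoter-density contrast between compartments the sign is arbitrary.
- The loop caller is single-resolution and intra-chromosomal; calls within
  the donut span of the diagonal are impossible by construction.
- Anchor typing at coarse bins over-assigns promoters (see above); on real
  5–25 kb anchors the class balance would differ.
- `merge_loop_domains` applies transitive closure, so one permissive slack
  can chain distinct domains; slack defaults to 1 bin.
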