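# Methods

## Setting and model

The package analyses two-color hybridizations in which total community RNA
from a biofilm sample (Cy5, 635 nm) and a planktonic sample (Cy3, 532 nm)
compete on a genomic microarray of one organism.  Per spot the scanner
reports foreground and background medians per channel.  After background
subtraction (floored at zero) the working coordinates are

- M = log₂(biofilm / plankton) — the quantity of interest,
- A = (log₂ biofilm + log₂ plankton) / 2 — mean log intensity,

defined only where both corrected foregrounds are positive.

The expectation model for a probe of gene *g* in campaign *c* is

    E[M] = fc_gc + log2(r_c) + bias(A)

where `fc_gc` is the per-cell expression change (a shared gene effect plus
campaign-level jitter, since field campaigns are treated as experimental
replicates), `r_c` is the organism's biofilm/plankton abundance ratio in
the community RNA, and `bias(A)` is the intensity-dependent dye bias.  The
pipeline removes the last two terms; the selection rules then act on the
estimated `fc`.

## Normalization: two composable corrections

**LOWESS dye-bias correction.**  The trend of M on A is estimated by
locally weighted regression: tricube weights over the span-nearest
neighbors in A, local degree-1 fits, and bisquare robustifying passes
(statsmodels' smoother; defaults span = 0.4 and 3 iterations, conventional
values in the normalization literature; the robust passes matter because a
minority of genuinely regulated probes should not bend the trend).  At
least 10 finite (A, M) points are required; flagged spots never enter the
fit but are still reported, with the trend interpolated at their A.

**Two level conventions.**  `lowess_normalize` subtracts the *full* trend
by default ("centering"), the classic convention: it assumes the bulk of
genes is unchanged and the organism equally represented, and under that
assumption it absorbs any constant offset — including an abundance
confound — into the trend.  With `preserve_level=True` the mean of the
trend is added back, so only the A-dependent *shape* of the dye bias is
removed and the global level of M survives.  This is the mode used by
`normalize_array` when a phylochip reference ratio is supplied: the
externally measured abundance ratio, not the unchanged-majority assumption,
then anchors the scale through the abundance correction below.

**Abundance correction.**  M_corrected = M − log₂(r), a uniform,
rank-preserving shift.  *r* is measured on the phylochip (PAM) as the
background-subtracted biofilm/plankton signal ratio at the reference probe
of the profiled strain (`LEP439`), median over replicate spots, and is
only accepted when the probe is detected in both channels.  Applying a
centering LOWESS *and* the log₂(r) shift would double-correct; the package
therefore pairs the shift with the preserve-level smoother, and the
order of the two steps is immaterial (the shift is constant), which a test
asserts.

A constant dye bias cannot be distinguished from an abundance shift by the
expression array alone; in preserve-level mode whatever mean dye bias the
array carries over its intensity range remains confounded with *r*.  The
simulator's default bias is an odd cubic with near-zero mean over the
intensity distribution, which mirrors a scanner balanced on average but
curved at the extremes.

## Detection and tiered selection

A probe is **detected** when foreground > 3 × background in at least one
channel (strict inequality).  On the phylochip the same rule is applied per
channel, since each channel is an independent sample there.

Selection treats campaigns as replicates.  Technical replicates within a
campaign are averaged at the probe level (mean of M); genes aggregate their
redundant probes (1–4 per gene on a shotgun-library array) by the median
over detected probes.  Tiers, evaluated on normalized log₂ ratios
two-sidedly (down-regulation uses ratio ≤ 1/threshold):

| tier | rule |
|---|---|
| `robust_biofilm` / `robust_plankton` | \|ratio\| **>** 2 in *every* campaign, consistent direction |
| `candidate` | \|ratio\| **≥** 2 in ≥ 1 campaign |
| `pathway_relaxed` | flagged pathway member with ratio in [1.5, 2) in every campaign, consistent direction |
| `expressed_both` | detected, no fold criterion met |
| `not_detected` | no detected probe |

The one-campaign rule is inclusive (a *minimal* ratio of 2) while the
every-campaign rule is strict (a ratio *higher than* 2); this keeps the
robust set a subset of the candidates, and both thresholds are
configurable.  The procedure is deliberately threshold-based — no
p-values, no multiple-testing correction — reproducing the field practice
it formalizes; that limitation is inherited knowingly.

## qPCR arm

Standard curves are ordinary least squares of Ct on log₁₀(dilution) over
all wells (≥ 2 distinct dilution levels; slope ≥ 0 is rejected as
non-amplifying).  Efficiency is E = 10^(−1/slope) − 1, a fraction in
(0, ~1.1] with E = 1 meaning perfect doubling (slope ≈ −3.32).  Relative
expression against the 16S rRNA reference (which tracks organism abundance,
so the abundance confound cancels) is

    fold = (1 + E_t)^ΔCt_t / (1 + E_r)^ΔCt_r,
    ΔCt  = mean Ct(plankton) − mean Ct(biofilm)

so biofilm-induced genes give fold > 1 (a flag inverts the convention).
With E_t = E_r = 1 this is exactly the classic 2^ΔΔCt.  The SD propagates
the replicate Ct scatter to first order,
sd(fold) = fold · √(ln²(1+E_t)·Var(ΔCt_t) + ln²(1+E_r)·Var(ΔCt_r)),
treating the fitted efficiencies as fixed; a bootstrap over wells is
available behind `sd_method="bootstrap"`.

## What the simulator emulates — and what it does not

Defaults encode the study design the pipeline targets: two campaigns
("2004", "2005") with organism abundance ratios 1 and 2 respectively,
technical replicates in 2005 only, 2–3× redundant probe coverage
(1 + Binomial(3, ·) probes per gene, mean 2.5), 70% null genes and
symmetric effects uniform on ±[0.585, 2.5] log₂ (spanning the 1.5×–2×
selection regime), campaign jitter 0.2 log₂, per-channel multiplicative
noise 0.15 log₂, Gaussian background (120 ± 15), lognormal baselines
(log₂ ~ N(10, 1.5²)) with per-probe affinities (0.3 log₂), and the odd
cubic dye bias described above.  Intensities are floats in memory and
16-bit clipped integers in emitted GPR files, like a scanner.  qPCR wells
follow Ct = intercept − log₁₀(dilution)/log₁₀(1+E) + N(0, 0.1) with
triplicates at five 10-fold dilutions and E = 0.95.  Everything derives
from one seed through per-stage `SeedSequence` children, so identical
configs give byte-identical files.

Not emulated: sequence-level cross-hybridization (a scalar
cross-hybridization matrix stands in on the phylochip), hybridization
thermodynamics, spatial/print-tip artifacts, and the severe signal loss of
real environmental RNA — on field samples roughly half the probes can fail
the 3× background rule, whereas the default synthetic regime detects ~90%.
Passing tests therefore certify the *rules and corrections*, not
performance on degraded field RNA.  An optional per-gene amplification
factor models linear-amplification preference; it distorts intensities but
cancels in M, and its magnitude is not constrained by field data, so it
defaults to off.

## Numerical choices and degenerate inputs

Background subtraction floors at zero; zero-foreground spots get undefined
M/A and are excluded from fits without being dropped from output.  The
3× and fold thresholds use strict/inclusive comparisons exactly as
specified above; dominance classification on the phylochip (|log₂| ≥ 1
biofilm/plankton, else similar) is inclusive at the boundary, with the
threshold a documented convention rather than a measured constant.  A
taxon detected in only one sample is classed as dominant there even though
its finite ratio is undefined.  Probe maps must be functions (a probe
listed with two genes is an error); probes missing from the map flow
through normalization as "unassigned" but never enter gene calls.

## Validation conditions and known limitations

The test suite validates each stage against independent oracles
(brute-force filter scans, per-point weighted-normal-equation LOWESS
solves, closed-form zero-noise identities) and the whole chain against
simulated truth.  The heavier checks use these problem sizes, chosen to
estimate each quantity with comfortable statistical margin while keeping
the default suite fast: dye-bias removal on ~2000 spots (per-intensity-
decile residuals within ±0.05); abundance-confound correction on 500 genes
(raw bias ≈ +1 log₂ at r = 2, corrected bias ≤ 0.05, median |error| of
recovered fold changes < 0.15); selection performance pooled over three
replicate 500-gene studies with 30% effects at |log₂ fc| ≥ 1 (robust-tier
recall ≥ 0.8, false-positive rate on nulls ≤ 0.05, full PAM-calibrated
pipeline); 100 simulated standard curves (mean efficiency within 0.02 of
truth).

Two limitations are worth knowing.  First, the abundance/dye-bias
confounding above: the preserve-level pipeline leaves the mean dye bias in
the corrected ratios, which is zero only to the extent the bias averages
out over the intensity range.  Second, fold-change leakage into the trend:
a gene's own expression change moves its A by fc/2, so E[fc | A] ≠ 0
whenever many genes change, and *any* M-on-A smoother absorbs part of the
true signal (with the default simulation geometry, roughly a 0.19·(A −
center) shared error per gene, correlated across campaigns).  This — not
measurement noise — is what bounds robust-tier recall in the mid-80% range
for effects near the 2× threshold, and it would affect real arrays with a
large regulated fraction equally.
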