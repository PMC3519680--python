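# Methods

This note documents the models, estimators and conventions implemented in
`ampliquant`, the design choices made where several options were defensible,
and the limits of what the synthetic data can demonstrate.

## Curve preprocessing and efficiency estimation

A well's trace is baseline-corrected by subtracting the mean fluorescence of
cycles 1–5, then normalized to its maximum over the run (the plateau at the
final cycles).  Both thresholds are fractions of that maximum — 3% and 6% by
default — which makes every downstream quantity invariant to detector gain
and optical scale differences between instruments.

Threshold crossings are located at the first cycle pair that brackets the
threshold (searched only after the baseline window, so baseline noise cannot
register as an early crossing) and interpolated **log-linearly**: exponential
growth is linear in log fluorescence, so this is the interpolation consistent
with the growth model.  If noise drives the lower bracket non-positive, that
bracket falls back to linear interpolation.  The efficiency follows from the
crossing spacing, E = (frac_b/frac_a)^(1/(Ct_B − Ct_A)) − 1.  On any
noiseless exponential segment this is exact regardless of template amount,
gain, offset or amplicon length (property-tested).

Per-well estimates are combined into one efficiency per gene by arithmetic
mean over usable wells; wells are censored when a threshold is never crossed
and flagged when the estimate leaves (0, 1.1].  Flagged wells are excluded
from the gene mean by default.  A per-sample efficiency mode (each sample's
own wells instead of the gene mean) is available behind
`PipelineConfig.per_sample_efficiency` for sensitivity analyses; the gene
mean is the default because the Pfaffl calculation uses one efficiency per
gene.

**Noise sensitivity (known limitation).**  The two-threshold estimator reads
the curve at 3% and 6% of the plateau, where the signal-to-noise ratio is
lowest, and the two crossings are only ~1 cycle apart.  With additive
detector noise of 0.5% of the plateau the per-well estimate carries a
standard deviation of roughly 0.3 and a median absolute error near 0.15
(the estimator is also convex in ΔCt, so averaging noisy wells does not
remove the error: Jensen and range-truncation biases of order 0.1 remain).
Because downstream quantities contain (1+E)^Ct with Ct ≈ 30, an efficiency
error δE inflates inter-gene ratios by exp(Ct·δE/(1+E)) — at this noise
level about 30% even after averaging hundreds of wells per gene.  Multi-point
exponential-window regression would reduce this but is deliberately out of
scope; at noise levels an order of magnitude below the plateau percent range
(typical of well-maintained instruments) the effect is modest, and in the
noiseless limit recovery is exact to machine precision.

## Relative quantification

Targets are normalized to the housekeeping gene Eef1a1 and to the control
group, by default the pooled 0-hour (pre-treatment) samples; the control Ct
entering the ratio is the arithmetic mean Ct of that group.  Technical
triplicates are aggregated by arithmetic mean of their 6%-threshold Ct
before any ratio is formed; censored wells drop out of the mean, and a
sample missing its housekeeping Ct is excluded (and reported) rather than
imputed.  Samples sitting exactly at the control means give a ratio of
exactly 1 by construction.

## Inter-gene analysis

The inter-gene ratio assumes (i) fluorescence proportional to dsDNA mass,
i.e. to amplicon length × copies, with the same proportionality constant for
every amplicon (no sequence-composition correction), and (ii) that the
per-gene 6% thresholds correspond to the same absolute fluorescence.
Assumption (ii) is exact when all genes plateau at the same fluorescence —
which holds when the plateau is set by a shared reagent budget (total dsDNA
mass) rather than a per-gene copy number; this is how the simulator
constructs its plateaus, and approximately true of multiplexed plates run
under one master mix.  On instruments where per-gene plateaus differ, the
shared-threshold assumption adds a gene-wise scale error equal to the
plateau ratio.

Within a sample, each gene's relative starting-transcript value is computed
as 1/(Amp·(1+E)^Ct) on a common arbitrary scale; pairwise ratios,
composition shares (normalized to sum to one; anchor-gene choice provably
cancels) and the summed ECM/MMP balance all derive from it.  Default gene
sets: collagens {Col1a1, Col3a1, Col5a1, Col12a1}, proteoglycans {Bgn, Dcn,
Lum}, ECM = collagens ∪ {Fn1} ∪ proteoglycans, MMP {Mmp2, Mmp3, Mmp14,
Mmp16}.

Group-level summaries use two different aggregators deliberately:
composition **shares** are averaged arithmetically over samples (shares are
bounded and the mean share is the natural stacked-bar quantity), while
**ratios** are summarized by the geometric mean — per-sample ratios of
log-normally distributed quantities are themselves log-normal, and the
arithmetic mean of a log-normal overshoots its median by exp(σ²), ~4% at the
default biological CV.  Time-course normalization divides each group value
by the same gene/treatment value at 0 h; a zero reference propagates as
missing.

## Statistics

Group summaries report mean, SEM (sd/√n with the n−1 denominator; missing
for singleton groups) and n.  The two-way ANOVA (treatment × time, with
interaction) is fitted by OLS through statsmodels and decomposed with
type-II sums of squares, which tolerates the mild imbalance arising from
lost samples (n = 5 vs 6); on balanced data all decomposition types
coincide, which the test suite asserts.  Ratios are analysed untransformed
by default (matching how such data are usually plotted), with a
log-transform flag; at CV ≈ 0.2 the F-test's type-I error is calibrated on
either scale (checked against the exact binomial band over 1,000 simulated
null studies).  A table with zero variance is reported as "no effect"
(SS = 0, p = 1) rather than an exception; an empty design cell is an error
naming the cell.

Post tests compare every treatment pair within each timepoint using the
pooled residual variance from the full model (t statistic on the residual
df) and Bonferroni-correct within the timepoint's family of pairs (6 for
four doses); the family size is recorded in the output rather than assumed.
Gel contraction is the area of a gel at time t divided by the same gel's
0-hour area — unit-free, so pixel or mm² measurements are interchangeable.

## Synthetic data

The generator emulates the tenocyte study design: 17 genes with the packaged
primer panel's amplicon lengths, four doses (0/1/10/100 ng/mL), four
timepoints (0/6/24/48 h), 6 biological samples per group, triplicate wells
(4,896 wells in the default study).

*Curve mechanism.*  Product copies grow as D_c = min(t0·(1+e0)^c, d_max):
exactly exponential below a saturation capacity, flat at the plateau.  The
saturating-exponential form (rather than a logistic) keeps the 3%/6%
threshold region purely exponential, so the estimators' exactness can be
tested without model-mismatch bias; real curves bend earlier, which is one
reason real efficiency estimates run below the true amplification factor.
The capacity is a shared dsDNA *mass* budget: d_max = mass/amplicon length,
making every gene's plateau fluorescence equal (see inter-gene assumption
(ii)).  Fluorescence is baseline + α·Amp·D_c plus optional additive Gaussian
noise; signal below a detector resolution floor (10⁻⁶ of the plateau)
reads as pure baseline, as real thermocyclers report a flat baseline until
product is detectable — this also means the baseline window carries no
signal, as the baseline-correction step assumes.

*Defaults.*  Per-gene true efficiencies lie in [0.92, 1.0] and 0-hour copy
numbers span 25–2500 (a 100-fold range, so inter-gene ratios cover
10⁻²–10²), arranged so that the 0-hour composition echoes the tendon-cell
literature: ECM:MMP ≈ 2.7, MMP-14 ≈ 58% of MMP transcripts, biglycan ≈ 89%
of proteoglycan transcripts.  Copy numbers and capacity are jointly chosen
so every well saturates by cycle 40 (thresholds are defined relative to the
40-cycle maximum).  True fold changes per (gene, dose, time) follow the
qualitative dose/time structure of the emulated study — ECM genes up at
10–100 ng/mL by 24–48 h, the decorin rise in controls suppressed by dose,
MMP-16 down dose-dependently, PAI-1 up early, Scx/Mkx up strongly,
housekeeping flat.  Biological replicates multiply t0 by a mean-one
log-normal factor (CV 0.2 by default), drawn independently per gene and
sample; technical wells share their sample's t0 — additive well noise is
the only technical error source.  Gel areas start near 120 mm² and shrink
toward dose-specific mean trajectories ending at 83/57/49/47% of the
initial area with small log-normal measurement noise.

*What the simulator does not emulate* — and hence what passing tests do not
show about real data: primer-dimer and off-target amplification, melt-curve
behaviour, pipetting dropout or volume errors, plate-position and
inter-instrument effects, curve bending below the plateau, and
sequence-dependent dye binding.  Recovery results on synthetic data bound
the estimator error under the stated noise model only.

*Determinism.*  One study seed drives a master generator that draws
biological multipliers and per-well child seeds, so plates are byte-identical
across runs and wells could be generated in parallel without changing the
output.

## Numerical conventions and degenerate inputs

Fractional Ct uses log-linear interpolation with a linear fallback for
non-positive lower brackets; a curve whose baseline-corrected maximum is not
positive is censored (no amplification), not an error.  Censoring propagates
as missing values through ratios; a sample is dropped only for the genes
affected.  Efficiencies outside (0, 1.1] are flagged; ct_B ≤ ct_A is flagged
invalid.  Shares are renormalized sums of positive ratios, so they sum to 1
to machine precision.  All writers emit full-precision floats and readers
parse with round-trip precision, so write→read cycles are lossless.

## Problem sizes used in the test suite and acceptance script

Unit tests run on reduced designs (2–17 genes, 2 doses × 2 timepoints, 2
biological × 2 technical replicates).  The acceptance script runs the full
default study twice (noiseless and noisy, 4,896 wells each), a 10,000-point
reduction grid, and 1,000 null studies of 24 wells each for ANOVA
calibration — about one minute in total on a single CPU.
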