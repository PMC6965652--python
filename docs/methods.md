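# Methods

## Twitch waveform model

A single motor-unit twitch is modelled, with sarcomere displacement
standing in for force, as `F(t) = p t^m e^(-kt)` with time measured from
force development. The three physiological parameters are the contraction
time `T_c` (force development to peak, ms), the half-relaxation reference
`T_hr` (force development to half of peak during relaxation, ms) and the
peak amplitude `F_max` (pixels, convertible to µm through the pixel size).
The shape constants follow algebraically:

    k = ln 2 / (-T_c ln(T_hr/T_c) + T_hr - T_c)
    m = k T_c
    p = F_max exp(-k T_c (ln T_c - 1))

The denominator of `k` equals `T_c (u - 1 - ln u)` with `u = T_hr/T_c > 1`,
which is strictly positive, so `k > 0` and `m > 0` on the whole valid
domain. `p` itself can underflow to zero in floating point when
`T_hr/T_c → 1` (m grows without bound); evaluation therefore always uses
the normalized form `F_max (t/T_c)^m e^(-k(t - T_c))`, which is stable.
A latency `delay ≥ 0` from the electrical stimulus to force development
shifts the waveform; displacement is identically zero before it. Reported
constants: rise time `t_r = delay + T_c`, half-relaxation time
`t_hr = T_hr - T_c`.

### Fitting

`TwitchModel.fit()` runs bounded trust-region nonlinear least squares in
the parameterization `(T_c, Δ, F_max, delay)` with `T_hr = T_c + Δ`,
`Δ > 0`, which keeps `k` defined at every iterate. Bounds:
`T_c ∈ [0.5, 200]` ms, `Δ ∈ [0.1, 400]` ms, `delay ∈ [0, 20]` ms,
`F_max > 0`. Initialization is deterministic and data-driven: `F_max₀` and
the peak time from the trace maximum, `delay₀` from the first crossing of
10 % of peak, `T_c₀` = peak time − `delay₀`, `Δ₀` from the first half-peak
crossing after the peak. Standard errors come from the Gauss–Newton
approximation `s² (JᵀJ)⁻¹` at the optimum.

Identifiability: near onset the waveform rises as `(t - delay)^m` with
`m` typically 3–8, so `delay` and `T_c` trade off along a shallow
likelihood ridge. At 2 % amplitude noise this puts roughly 3 % relative
spread on `T_c` individually while the *reported* `t_r = delay + T_c`
stays several times tighter. Verified by restarting the optimizer at the
true parameters: the spread is a property of the least-squares optimum,
not of the optimizer.

### Sequential decomposition

Raising the stimulation voltage recruits motor units one quantal step at a
time. `subtract_and_fit` evaluates the previously fitted composite model
on the new trace's time grid, subtracts it (using the model rather than
the raw previous trace denoises the reference), and fits the residual as
the newly recruited unit. A residual whose post-stimulus peak is below 3×
the pre-stimulus displacement RMS is declared "no new unit" — the
operational form of a visual no-jump judgement. Joint multi-unit fitting
is deliberately out of scope; decomposition is strictly sequential, and
summation of unit displacements is assumed linear.

## Line-scan extraction

Recordings are space–time matrices `[space_pixel, time_line]` at a default
1.09 kHz line rate. Processing:

1. **Averaging.** All windows from 50 ms before each stimulus to 450 ms
   after (half-open, 500 ms total) that lie fully inside the recording are
   averaged element-wise.
2. **Resting reference.** The pre-stimulus columns are averaged into a
   single column representing the resting sarcomere pattern.
3. **Shift search.** For each time line, the vertical shift minimizing the
   sum of squared errors against the reference is found over ±20 px
   (configurable); only the overlapping pixel range is compared and the
   SSE is normalized by overlap length, so large shifts are not penalized
   spuriously. The integer minimum is refined by parabolic interpolation
   through its two neighbours (no data resampling).
4. **Continuity.** Sarcomere band patterns are near-periodic, so the SSE
   profile has aliased minima one band period apart. Tissue motion between
   successive kHz lines is far below one period, so each line's minimum is
   taken within ±5 px of the previous line's shift (the first line uses
   the global minimum). A consistently aliased branch is a constant offset
   and is removed with the baseline.
5. **Baseline and QC.** The pre-stimulus median is subtracted so resting
   displacement is zero. A trace passes QC only if its post-stimulus peak
   is ≥ 3× the pre-stimulus RMS (inclusive) *and* the peak is unique to
   within ±1 sample — the operational form of "clearly visible maximum".
   Failing units are excluded from all downstream tables.

Positive displacement is motion toward increasing space index; space index
0 is the top of the probe field. Manual tracing fallback is not
implemented: extraction is automatic for every voltage step, including the
higher-voltage composites that feed the subtraction.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not muscle biophysics. Motor units belong to three types — fast-fatigable
(FF), fast fatigue-resistant (FR), slow (S) — with log-normal rise and
half-relaxation time distributions and a uniform 1–5 ms latency. Default
medians (ms): t_r 13/20/35, t_hr 8/14/30, geometric SD 1.25 for all. These
are calibration knobs with no literature authority; they were chosen once
so that a fast-dominated healthy mixture sits near a composite twitch time
of 21 ms and the pure-type extremes span 20.7–64.2 ms, bracketing the
disease range. Peak amplitudes are log-normal with median 4.5 px (≈1.5 µm
at the default 0.33 µm/px), and the default band pattern period is 2.5 µm —
a plausible resting sarcomere spacing, configurable.

Disease progression is a single degree of freedom: mixture weights march
along the FF → FR → S axis (`λ ∈ [0, 2]`, `(1-λ, λ, 0)` then
`(0, 2-λ, λ-1)`), along which the expected composite twitch time is
monotone. `calibrate_preset` bisects this axis until a Monte-Carlo
estimate (10⁵ samples) of the expected CTT hits a requested target within
0.5 ms.

**Estimand choice.** The population CTT (harmonic mean + median over one
very large pooled sample) and the expectation of the *per-mouse* CTT
computed from ~7 units differ materially for bimodal mixtures: the 7-unit
sample median of half-relaxation times is biased upward by roughly 10 %
when the FR and S modes straddle the population median. Printed group
means are means over mice of small-sample statistics, so calibration
aimed at such a value should target the per-mouse estimand;
`expected_ctt(..., units_per_mouse=7)` selects it. The population
estimand remains the default.

Rendering places the band pattern — a raised sinusoid multiplied by a
smooth random envelope, which breaks exact periodicity and gives the SSE
registration a unique optimum — on the space–time raster, translates each
line vertically by the summed twitch displacement of the recruited units,
and adds i.i.d. Gaussian noise of amplitude (pattern contrast)/SNR.
Stimuli arrive at 1 Hz; 8 sweeps per recording by default. Not modelled:
photon shot noise, breathing/motion artifacts, site-level heterogeneity
within a mouse, fatigue, tetanic summation.

Cohorts follow the study design: groups × six time points (weeks 12–23),
3–19 units per mouse per time point, every random draw derived from a
single master seed through named seed-sequence spawns, so identical specs
reproduce byte-identical tables.

## Biomarker and ROC

Per mouse and time point, `CTT = harmonic mean(t_r) + median(t_hr)` (even
counts: mean of the central pair). Candidate summaries (means, type-7
quartiles, unbiased variance, adjusted Fisher–Pearson skewness) are
computed for both time constants. The AUC is the Mann–Whitney probability
with ties counted ½, which equals the trapezoidal area under the
threshold-sweep ROC exactly; confidence intervals are percentile
bootstrap, 1000 resamples drawn within each group independently
(resampling mice, not units), seeded. For multi-timepoint ROCs each
mouse–timepoint pair contributes one observation; repeated measures are
pooled without adjustment, a caveat inherited from the study design.

## Statistics

The longitudinal layout is a randomized block design (mice = blocks,
time points = treatments, motor units = replicates within a cell).

**Replicated-block rank test (`gore_test`).** All observations within a
block are mid-ranked jointly. For cell (i, j) with `c_ij` observations and
rank sum `R_ij`, the centred treatment totals `d_j = Σ_i R_ij − c_ij
(N_i+1)/2` have exact within-block permutation moments `Var(R_ij) = c_ij
s²_i (N_i − c_ij)/(N_i − 1)` and `Cov(R_ij, R_il) = −c_ij c_il s²_i/(N_i −
1)`, where `s²_i` is the population variance of the block's mid-ranks
(ties enter only here). The statistic is `dᵀ Σ⁺ d` (Moore–Penrose
inverse), asymptotically χ² with k−1 df. With equal replication `c` and no
ties this reduces to the closed form `12(k−1) Σ_j (T_j − nc(N+1)/2)² /
(k n c (N+1)(N−c))`, `N = kc`, and to Friedman's statistic at `c = 1`.
Unequal cell counts are handled by the per-cell moments. A seeded
within-block permutation mode provides a finite-sample cross-check; on
small designs the asymptotic p tracks the permutation p to well within
0.05.

**Missing-cell test (`skillings_mack_test`).** Same quadratic form with
one observation per cell and absent cells simply contributing nothing. On
complete data the statistic equals the tie-corrected Friedman statistic
exactly, for any tie structure. With missing cells and no ties it is a
valid χ² statistic that differs from the textbook formulation only in
block weighting (raw centred ranks instead of `sqrt(12/(k_i+1))`
weights); the realized-moment form was preferred because it degrades
exactly to Friedman and handles ties without a separate correction.

**Post hoc.** Dunn's z on pooled mid-ranks with the `Σ(t³−t)/(12(N−1))`
tie correction; Bonferroni multiplies by the number of pairs in the call
(15 for six time points), capped at 1. The family is the pairwise
comparisons of the call, not experiment-wide.

**Distribution comparisons.** Two-sample KS (asymptotic p; at the study's
per-cell sizes the exact method's discreteness is worse than the
asymptotic error) and Wilcoxon rank-sum via the normal approximation with
tie and continuity corrections.

**Density estimation.** KDE by linear diffusion: the binned empirical
measure (2¹² mesh) is damped in the DCT domain by the heat kernel, with
the diffusion time chosen by the fixed-point plug-in rule
`t = ξ γ^[7](t)`, which estimates the density functionals required by the
asymptotically optimal bandwidth from the data itself. If the fixed-point
root is not bracketed the Gaussian-reference time is used. The mesh
density is renormalized and linearly interpolated onto the caller's grid.

**Trend fits and model equivalence.** `y = A e^{Bx} + C` with `C` pinned
to the mean of the data at the first time point (the healthy baseline),
so only A and B are free and the reduced χ² uses n−2 df. The fit runs
Levenberg–Marquardt from eight deterministic starts over a bracket of
growth rates, each with the conditionally optimal linear amplitude, and
keeps the best. Note that `B` is only recovered accurately when `C` is
supplied from adequate baseline data: a noisy 5-point baseline mean
propagates into a substantial `B` bias. Equivalence of two datasets'
trends is assessed by a pair of F-tests: `F = red-χ²(cross-applied
model)/red-χ²(own fit)` against `F(n−2, n−2)`, two-sided
(`2·min(sf, cdf)`, capped at 1), so identical datasets give F = 1 and
p = 1. A fit with zero residual makes the ratio undefined and raises.

## Problem sizes and numerical choices

Monte-Carlo suites use 200 replicates for recovery rates, 500 for test
size calibration, and 2×10⁴ permutations for the permutation cross-check;
rendered-image suites use 64-pixel fields and 4–8 sweeps. Cohort-level
validations run 5–6 mice × 7 units per condition, the study's median
sampling depth, with three replicate cohorts averaged where a single
cohort mean is dominated by biological sampling spread (per-mouse CTT SD
≈ 2.4 ms at the late-stage mixture). Degenerate inputs fail loudly:
flat traces, zero-variance columns, windows outside the recording, empty
groups and single-treatment blocks all raise typed errors rather than
returning values.

## What passing tests do and do not show

The generator produces exactly the structure the analysis assumes
(log-normal type mixtures, linear summation, Gaussian noise, perfectly
periodic stimulation). Passing round trips therefore demonstrate the
correctness and calibration of the *analysis* — not robustness to
breathing artifacts, probe drift, non-Gaussian photon noise, or
within-mouse site heterogeneity, none of which are simulated. Headline
real-data quantities (AUC near 0.96, per-timepoint significances) depend
on the animal dataset and are not reproducible from synthetic data;
what is reproduced is the recovery of known cohort-level composite twitch
times through the full imaging chain.
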