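# Methods

This note documents the models, estimators and numerical choices behind
`neurocrit`, the assumptions they rest on, and what the synthetic-data tests
do and do not establish about real recordings.

## Point process

Continuous recordings are z-scored per channel (mean removed, divided by the
SD; tolerance 1e-6 on both). Events are defined on the absolute signal: for
every maximal excursion with |X(t)| ≥ σ, exactly one event is placed at the
excursion's global |X| maximum, earliest sample on ties (ties are measure-
zero in real data; the rule exists for determinism). The default σ = 4 SD is
a conservative choice: in calibration experiments with Gaussian background
plus ~0.1 % planted high-amplitude events, the divergence-based threshold
estimator lands in [3, 4.5].

The data-driven estimator (`fit_gaussian_threshold`) pools |X| over
channels, bins it in 0.25-SD steps over a candidate range (default 2–6 SD),
and reports the left edge of the first bin at which the empirical bin
probability exceeds the folded-Gaussian fit by more than a factor of 2 for
two consecutive bins. The factor-2/two-bin rule is our operationalization of
"where the distributions diverge"; on pure Gaussian data no bin qualifies
and the default 4 is returned.

Correlation propagation uses the *signed* Pearson ρ of the raw normalized
signal on the excursion window [t_min, t_max], threshold ρ ≥ 0.75; an
absolute-ρ variant is available behind `PointProcessParams.absolute_rho`.
Anticorrelated channels therefore do not co-fire under the default. Windows
shorter than 3 samples are skipped (correlation is degenerate there) and
counted in the log. Overlapping windows from different seed channels may
each propagate; duplicate (channel, bin) events merge so the raster stays
binary. No temporal rebinning is applied at this stage: one bin = one sample
(1 ms at 1 kHz), because significant rebinning of 10-minute recordings
leaves too few avalanches to fit.

## Avalanches

An avalanche is a maximal run of consecutive non-empty bins. Size S counts
*events*, not distinct channels — over multiple bins the same channel can
contribute repeatedly, so S may exceed the channel count (reference-table
size bounds reach 634 on a 128-channel array, which is only consistent with
event counting). Avalanches clipped by the record boundary are kept and
flagged; a switch drops them. Keeping them is the default because no
principled exclusion rule exists and they are a vanishing fraction of long
recordings.

## Doubly-truncated power-law inference

Sizes and durations are modelled by the discrete pmf p(x) ∝ x^−e on the
integer support [x_min, x_max]. The exponent is fit by bounded scalar
minimization of the negative mean log-likelihood
e·mean(log x) + log Z(e), with Z(e) summed directly over the enumerated
support (log-sum-exp for stability); search bounds [1.01, 8], tolerance
1e-6 (well inside the 1e-4 contract), estimates pinned at either bound are
flagged degenerate. Goodness of fit is the KS sup-distance between the
in-range empirical CDF and the model CDF, referenced against surrogate
datasets drawn from the fitted pmf and refit on the *same* bounds
(semi-parametric convention; re-scanning bounds per surrogate would be
hopelessly expensive and changes p by little). The p-value convention is
reversed relative to ordinary testing: high p means the power law is
plausible, and fits are retained iff p ≥ 0.2. Default surrogate count 500;
inside the range scan the surrogate loop stops early once the accept/reject
decision at 0.2 is settled, which leaves the decision exact and only the
reported p approximate.

`scan_range` searches candidate (x_min, x_max) pairs — x_min from the
smallest observed support values upward, x_max from the largest downward, at
most 16 candidates per bound (evenly thinned), each pair required to contain
≥ 5 unique support values and ≥ 10 samples — and returns the admissible
(p ≥ 0.2) pair maximizing log10(x_max/x_min), ties broken by larger x_max
then smaller x_min. Maximizing decades is our explicit choice of objective:
the scientific claims about range restriction are phrased in orders of
magnitude. If nothing is admissible the best-p fit is returned flagged
implausible.

Parameter recovery: |bias| < 0.05 at n = 10^4 across exponents 1.5–3.5, and
the surrogate p-value is approximately uniform under the null (mean p ≈ 0.48
over 20 repetitions at n = 2000).

## Scaling battery

1/σνz is estimated three ways and cross-checked by percentage differences
(|a−b| / mean(a,b) × 100):

- **Exponent relation**: (α−1)/(τ−1).
- **Regression**: OLS slope of log⟨S⟩ vs log T over durations inside the
  duration fit's [x_min, x_max]. ⟨S⟩(T) is not a probability distribution,
  so MLE machinery does not apply.
- **Shape collapse**: mean profiles (durations with ≥ `min_profile_count`
  avalanches, default 10) are linearly interpolated onto a common 100-point
  normalized-time grid and divided by T^γ; the collapse error is the
  across-duration variance averaged over the grid, normalized by the
  squared mean curve; γ is grid-searched (default step 0.01 on [−0.5, 2.5])
  and 1/σνz = γ + 1. On the exact self-similar family T^0.5·4u(1−u) the
  construction exponent is recovered to the grid step.

Finite-size scaling subsamples fractions (1, ½, ¼, ⅛) of channels, 10 draws
each, pools avalanches across draws into one distribution per fraction
(pooling stabilizes the sparse tails; this is an interpretation choice), and
measures the mean pairwise distance across fractions before and after
rebinning time by the inverse fraction. Rebinning is a per-channel logical
OR over coarse bins — the raster stays binary and event counts are
deliberately not conserved. The fold change (rebinned − raw)/raw is ≤ 0 when
renormalization collapses the distributions. KS distance is the default
metric (it is what the reference table's columns contain); the 1-Wasserstein
distance is also provided and is computed on log-transformed values so heavy
tails do not dominate the transport cost.

Two facts worth knowing when interpreting fold changes. First, on critical
branching simulations the *size* distributions collapse clearly
(fold ≈ −0.5) while duration folds can be near zero: coarse binning divides
durations by the rebin factor, which distorts the short-duration end more
than subsampling does. Second, a homogeneous independent-Poisson raster
collapses almost perfectly (fold ≈ −1): channel thinning is a p-thinning of
the pooled per-bin Poisson count, and inverse rebinning exactly restores the
per-coarse-bin intensity, so the renormalized distributions are identical in
law. A strong collapse is therefore *necessary* for criticality but not
specific to it; the discriminating evidence is the combination with
power-law ranges and exponent relations.

## TSE complexity

C_N(X) compares subset integration (multi-information, plug-in estimates in
bits) against the linear reference (k−1)/(N−1)·I(X), summed over subset
sizes k = 2..N and divided by N. Exact computation is intractable at
N = 128 (the subset count explodes combinatorially and plug-in joint
entropies need ~2^k states' worth of samples), so the estimator:

- restricts the state sample to bins with at least one event (the
  complexity of the avalanches themselves, which also controls for the
  spacing between avalanches);
- samples k on the grid {2, 4, 8, 12, 16, 20} with 20 random subsets per k
  (all subsets, when there are fewer than that); k is capped at 20 because
  the joint-entropy estimate needs on the order of 10·2^k event bins;
- corrects each subset's integration by subtracting its mean integration
  under 20 independent 30-second jitter-null rasters, flooring negative
  corrected values at 0 (estimator noise; floored counts are logged);
- extrapolates the whole-system integration I(X) from a power fit
  a·(k−1)^b of the corrected curve (b clipped to [0, 1]; integration cannot
  grow super-linearly in k for stationary channels), evaluated at k = N —
  this extrapolation is the largest approximation in the battery;
- reports C_N as the area between the linear reference and the corrected
  curve (linear interpolation across k, the fitted bridge beyond the grid),
  divided by N. Using the unsigned area keeps C_N ≥ 0 regardless of which
  side of the line the curve falls on.

The jitter null displaces each event uniformly within ±30 s (wrap-around at
the record boundary, per-channel counts preserved exactly; collisions are
re-drawn rather than merged). Sanity anchors: duplicated channels and
independent channels both give C_N ≈ 0; critical branching rasters score
well above subcritical ones.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
ECoG biophysics. A discrete-time branching process on n_channels units is
seeded by Poisson(drive_rate) spontaneous activations per bin on quiet
channels; each active unit produces Binomial(n_channels, br/n_channels)
descendants, and the pooled descendants occupy *distinct* random channels at
the next step, capped at n_channels. Placing descendants on distinct
channels keeps the realized offspring mean at the nominal branching ratio
until the cap bites; letting descendants collide and merge would make the
effective branching ratio decay with the momentary active count
(≈ br·(1 − (k−1)/2n)), i.e. the process would be subcritical well below the
array size and the mean-field exponents (τ = 3/2, α = 2, ⟨S⟩(T) ∝ T²) would
not be recoverable at any range. Defaults — 128 channels, 600 000 bins at
1 ms, drive 0.01 — give ≈ 10 % busy bins and a few thousand avalanches per
10-minute raster, comparable to awake-condition event rates.

Remaining gaps to the asymptotic mean-field values are expected and
quantified: a pure critical Galton–Watson reference simulation, fit on the
same practically admissible ranges, yields α ≈ 1.8–1.9 and regression
slopes ≈ 1.8 (slow convergence of the duration tail plus truncation), so
recovery is asserted at τ = 1.5 ± 0.2 and α, 1/σνz = 2.0 ± 0.3.

The truncated power-law sampler inverts the exact enumerated CDF, so
samples follow the discrete pmf exactly. The ECoG synthesizer adds a
deterministic 3-sample pulse (peak amplitude in background-SD units,
default 6) at each event on unit-variance white Gaussian noise; it contains
no 1/f spectrum, volume conduction, or electrode geometry, so passing the
recovery tests shows the point process is correct, not that real ECoG noise
is benign. All generators take explicit seeds; identical seeds give
identical output.

## Problem sizes in the test suite

The acceptance-style property tests run the branching simulator at
128 channels × 10^6 bins with 200-surrogate range scans, the calibration
test uses 20 repetitions of n = 2000 with 200 surrogates, and complexity
contrasts run on 64-channel, 10^5-bin rasters with 8 nulls — sizes chosen
so the full suite completes in about a minute on one CPU while leaving the
assertions' tolerances comfortably resolvable.

## Known limitations

- The whole-system integration extrapolation (power fit to k = N) has no
  published reference implementation to compare against; C_N values should
  be compared within an analysis, not across packages.
- `scan_range` thins bound candidates to 16 per side; in pathological
  supports the true widest admissible range can fall between candidates.
- Surrogate refits reuse the empirical bounds, which makes the p-value
  slightly conservative near sharp truncations.
- EDF input is not supported; recordings are read as delimited matrices
  with a sampling-rate header, rasters as sparse TSV event lists.
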