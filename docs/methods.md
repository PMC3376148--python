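# Methods

## Thermodegradation model

DNA held at 95 °C depurinates and fragments; the mode of a sample's
fragment-size distribution decays toward an asymptote. fragmatch models the
mode size after `t` minutes of heat (plus the fixed labeling-reaction heat
exposure, which is absorbed into the parameters rather than modeled
separately) as a shifted inverse power law

    f(t) = theta1 + theta2 * (t + theta3) ** (-theta4)

* `theta1` ≥ 0 bp — asymptotic minimum fragment size;
* `theta2` > 0 bp·min^theta4 — decay amplitude;
* `theta3` > 0 min — time offset keeping f finite at t = 0;
* `theta4` > 0 — decay exponent.

This is the standard four-parameter inverse power law that is finite at
t = 0, strictly decreasing, and floored; the specific algebraic arrangement
is an explicit modeling choice (several four-parameter power laws fit decay
series comparably), kept behind a single forward-model function
(`decay.fragment_size`) so alternates can be swapped.

**Fitting.** Bounded trust-region least squares (scipy `least_squares`,
method `trf`) on untransformed bp residuals, from five deterministic
multi-starts spanning exponents 0.3–2 and offsets 0.5–2 min. Unweighted
fitting in size space is assumed; log-space or weighted variants were not
needed at the 5–20 bp measurement noise typical of gel sizing. Bounds:
theta1 ∈ [0, min(sizes)], theta2 ∈ (0, 10·max(sizes)], theta3 ∈ (1e-3, 30]
min, theta4 ∈ (0.05, 5]. Four observations with distinct times are required
(three when the exponent is fixed); exactly-determined fits are permitted
but warn, since 4 points / 4 parameters is ill-conditioned. The suite
cross-checks fitted residual sums of squares against a brute-force grid
search over the same bounded box.

**Inversion.** Closed form, t\* = (theta2/(target − theta1))^(1/theta4) −
theta3, valid for theta1 < target ≤ f(0). Targets at or above f(0) need no
fragmentation (t = 0); targets at or below theta1 are infeasible and
reported as such rather than clamped. Recommendations longer than a
configurable maximum (default 15 min — beyond any practical protocol) are
clipped and flagged. The round-trip |f(t\*) − target| ≤ 1e-6·target is a
tested invariant.

**Target size.** Default 400 bp: matched-size hybridizations are flat in
quality at and above ~400 bp and degrade below it, so 400 bp is the
smallest size with optimal quality — preferred because overshooting wastes
degradable samples.

## Gel densitometry

A lane profile is a strictly increasing migration coordinate with
non-negative intensities. Processing:

1. optional rolling-minimum background subtraction (window in position
   units, clipped at zero) — off by default, as is a 5-sample
   moving-average smoother;
2. ladder bands as the `n` most prominent local maxima (scipy
   `find_peaks`), each apex refined by 3-point parabolic interpolation,
   which gives sub-sample localization without assuming a band shape;
3. calibration by piecewise-linear interpolation in (migration, log10 bp)
   through the band anchors. Only monotonicity is assumed of the gel;
   under the classic mobility law d = A − B·log10(bp) the interpolation is
   exact. Beyond the anchor range the end-segment slope is extended in
   log-size and values are flagged as extrapolated;
4. mode fragment size = calibration evaluated at the smear's
   maximum-intensity position (parabolically refined), i.e. the
   mass-weighted stain mode exactly as an ImageJ max-intensity readout —
   no mass-to-molarity conversion. An apex below a prominence floor raises
   a "no smear" error instead of sizing noise.

## dLRsd

No closed formula is published for the derivative log ratio spread as
vendor software reports it; fragmatch defines it as

    dLRsd = IQR(delta) / (1.349 * sqrt(2))

where delta are log2-ratio differences of genomically consecutive probes
pooled within chromosomes. For iid Gaussian probe noise of sd sigma the
differences have sd sigma·sqrt(2) and IQR 1.349 times that, so the
estimator converges to sigma (tested within 2% at 1e5 probes), while the
quartile basis keeps a handful of genuine copy-number step edges from
inflating it (tested: ≤ 5 step edges move it < 3%). It is computed before
GC correction by default. Scale equivariance dLRsd(c·x) = |c|·dLRsd(x) is
a tested property. The 0.3 pass threshold is the standard array-QC gate.

## GC-wave correction

Log2 ratios show a periodic "wave" correlated with probe GC content. The
correction subtracts a mean-centered trend: median log2 ratio per 1% GC
bin over the occupied GC range, moving-average smoothed over 5 bins with
linear-extension padding (edge replication would flatten a linear trend at
the range ends), then re-anchored so the overall median log2 ratio is
unchanged. Probes carry a precomputed `gc` fraction (annotated upstream
from a window around each probe; the simulator draws it uniform in
[0.3, 0.7]).

## Aberration calling (interval-score surrogate)

The production caller this stands in for (ADM-2) is proprietary. The
surrogate scores a probe interval i..j as

    score(i, j) = |mean(log2 ratio)| * sqrt(n) / sigma_hat

(sigma_hat defaulting to the table's dLRsd — the z-score interpretation of
interval scores) and, per chromosome, recursively extracts the
maximal-score interval while its score clears the threshold (default 6.0),
recursing into the flanks so calls never overlap. Extracted intervals are
then filtered to more than five probes (`min_probes = 6`) and
|mean log2| > 0.3. The variant used for low-input comparisons (threshold
7.0, ≥ 7 probes, |mean| ≥ 0.35) is expressible through the same
parameters. The argmax search is O(n²) per segment; fixtures are kept at
≤ 5,000 probes per chromosome, and the suite verifies the recursive
extraction equals an independent exhaustive interval scan on every
fixture. Calls are labelled "ADM2-surrogate" conceptually; output columns
are chrom, start, end, direction, n_probes, mean_log2, score. Coordinates
are 0-based half-open throughout; overlap means ≥ 1 shared base on an
exactly matching chromosome name.

## ROC and concordance

Probe-level ROC compares aberrant-region against copy-neutral probe
values: thresholds sweep all observed values (classify aberrant at or
beyond the threshold, sign-flipped for losses), AUC comes from the
tie-corrected Mann–Whitney rank construction (cross-checked against direct
pairwise comparison), and the reported operating point maximizes Youden's
J — chosen because "ROC-optimized threshold" does not by itself name a
criterion and Youden's J is the standard one. FPR is the proportion of
neutral probes called aberrant, FNR the proportion of aberrant probes
called neutral, both at that threshold. Concordance between call sets is
the fraction of *reference* calls overlapped by ≥ 1 bp by any query call;
an empty reference is an error, not 0/0 = 0.

## Synthetic data

The generators exist to exercise the pipeline under known ground truth;
all are bit-reproducible given a seed (numpy `default_rng`).

**Hybridization.** Probe log2 ratios are
`true_shift + gc_effect·(gc − mean gc) + eps`, eps iid Gaussian with sd

    sigma = sigma0 * (1 + a*Delta) * (1 + b*max(0, Lstar/min(mt, mr) - 1))

where mt, mr are the test/reference mode fragment sizes and Delta their
relative difference |mt − mr| / mean(mt, mr). Rationale: hybridization
efficiency falls with the length of the unbound fragment end, so mismatch
between the competing samples biases ratios probe-by-probe, and very short
fragments hybridize poorly outright; at array level the minimal sufficient
model is a size-dependent noise scale, not a per-fragment simulation. The
constants (sigma0 = 0.16, a = 0.8, b = 0.35, Lstar = 400 bp) are a
synthetic calibration chosen once so the simulator reproduces the observed
phenomenology — the matched 225/225 pairing passes the 0.3 gate while
525/225, 525/140 and 225/140 fail it; all matched sizes 225–680 bp pass,
with quality flat above Lstar; and mode size correlates with dLRsd near
r ≈ −0.85 across the matched sweep (the multiplicative form itself is a
minimal choice; no quantitative mismatch-to-dLRsd law exists to copy).
Probes tile chromosomes contiguously at 2.1 kb spacing (the median spacing
of the 1 M-feature array class this emulates), 60 bp probes, GC uniform in
[0.3, 0.7].

**Decay series.** `f(t; theta) + N(0, sd)`, truncated at 30 bp; default
grids are the FFPE {0, 0.5, 1, 2} and frozen {0, 2, 4, 6} minute series.

**Gel lanes.** Fragment sizes are log-normal with the mode at the requested
size; through d = A − B·log10(bp) (defaults A = 850, B = 250 over a
420-row render, placing the whole default ladder — 100–1517 bp, a
vendor-style 100 bp ladder whose exact sizes are configurable — inside the
image) the smear renders as a Gaussian bump in migration coordinate whose
apex sits exactly at the true mode. Ladder bands are narrow Gaussians with
deterministically varied amplitudes; seeded sensor noise is added and
clipped at zero; lanes are tiled into a two-lane grayscale image with a
gap, and the ground truth is carried in the render object.

**What the simulators do not model** — and hence what passing tests cannot
show about real data: dye bias, spatial and ozone artifacts, scanner
saturation, per-sequence hybridization thermodynamics, tumor purity and
ploidy, gel tilt or lane distortion, and any real relationship between
block age and degradation. Tests demonstrate internal correctness and that
the encoded size-quality phenomenology is reproduced, not that the noise
constants describe any particular instrument.

## Problem sizes and numerical choices

Simulated arrays use 50,000 probes (14 arrays for the matched sweep);
decay-recovery studies use 200 replicates of 6-point series with 10 bp
size noise, with true parameters drawn from priors chosen to emulate
frozen-tissue samples (theta1 ~ U(50, 150) bp, f(0) ~ U(500, 900) bp,
theta3 ~ U(0.5, 2) min, theta4 ~ U(0.5, 1.5)); gel validation uses 100
lanes with modes uniform in [120, 900] bp. Ties in peak detection resolve
to the more prominent peak; parabolic refinement is clipped to half a
sample; degenerate inputs (flat lanes, zero noise scale, empty reference
call sets, targets below the decay floor) raise typed errors rather than
returning sentinel values.

## Known limitations

* The decay law's algebraic form is an assumption; with ≤ 4 points several
  monotone decay families are indistinguishable, which is why the workflow
  treats the fit as sample-specific interpolation for inversion, not as
  mechanistic chemistry.
* dLRsd here is a defined estimator, not the vendor's implementation;
  absolute values can differ slightly from vendor QC reports even on
  identical data.
* The caller is a surrogate: thresholds are comparable in spirit but not
  numerically interchangeable with ADM-2 scores.
* Gel sizing assumes one dominant smear per lane and monotone migration;
  multimodal distributions report only the global mode.
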