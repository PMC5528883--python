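# Methods

## Signal model and T2 estimation

Each voxel's multi-echo magnitude signal is modelled as a mono-exponential
decay, `S(TE) = S0 · exp(−TE/T2)`, sampled at 14 echo times evenly spaced
over 9–127 ms (TR = 2 s is treated as fully relaxed, so T1 never enters the
model). The least-squares fit is solved by variable projection: for fixed
T2 the optimal amplitude is `S0(T2) = ⟨x, S⟩/⟨x, x⟩` with
`x = exp(−TE/T2)`, reducing the problem to one dimension. The profile
objective is minimised by

1. a global scan over 64 log-spaced T2 values spanning the admissible range
   [1, 2000] ms,
2. 24 golden-section steps in log T2 inside the bracketing grid interval,
3. 30 bisection steps on the analytic derivative d(RSS)/d(log T2).

The derivative polish matters for reproducibility, not accuracy: a
value-comparison search cannot localise a minimum beyond ~√ε relative
(comparisons become rounding noise), while the derivative's sign is reliable
to machine precision and is exactly invariant under uniform signal scaling.
The search is global (no data-dependent initialisation to fail), every voxel
executes the identical instruction sequence, and reductions avoid BLAS
kernels, so results are independent of voxel order, batch size and run —
fitting one voxel alone reproduces the volume fit bit for bit.

Estimates pinned at either bound (e.g. non-decaying signals run to
2000 ms), non-positive fitted amplitudes and all-non-positive inputs are
flagged non-converged; non-converged voxels are never classified as lipid.
The model is fitted to magnitudes as-is, with no Rician bias correction; at
the default SNR of 40 the Monte-Carlo median bias at T2 = 30 ms is about
+2% (characterised in the tests), which the tolerance analysis below
absorbs.

## Segmentation and quantification

A voxel is lipid iff it lies in the vessel-wall mask, its fit converged and
its T2 is strictly below 42 ms; a voxel at exactly 42 ms is fibrous. The
threshold is fixed (histologically validated elsewhere); no lower T2 cut is
applied, and intra-plaque haemorrhage characterisation is out of scope.
Areas and volumes are voxel counts times the voxel geometry
(0.33 × 0.33 × 2 mm by default). Per-slice lipid percentage uses the wall
mask as denominator. Vessel-level lipid and wall volumes are the *per-slice
means* over the studied slices (the study's unit of analysis), so a 5-slice
acquisition averages over 5 slices.

## Deposit morphometry

Deposits are 2-D connected components per slice (8-connectivity by default,
configurable to 4; labels assigned in raster order of each component's first
voxel; no merging across slices). Components whose area is ≤ 1% of the
slice's pre-exclusion lipid area are excluded as noise in a single pass —
the denominator is the pre-exclusion total, and survivors are not re-tested
after renormalisation. Retained percentages are taken over the retained
total, so they sum to 100.

On the slice with maximal lipid volume (ties broken toward the lowest slice
index): `LLD%` is the largest retained deposit's percentage,
`RLD% = 100·(1 − LLD%/100)/(n − 1)` the mean share of the others, and
`LAI = LLD%/RLD% = f·(n − 1)/(1 − f)` with `f = LLD%/100`. RLD% and LAI are
undefined (NaN) when fewer than two deposits survive; LLD% additionally
requires one.

## Statistics

Lipid metrics are skewed, so location is median (IQR), quantiles by linear
interpolation. Group comparisons use the two-sided Wilcoxon rank-sum test:
full enumeration of the U null distribution when the pooled sample has at
most 12 observations (midranks, so ties are exact too; identical groups give
p = 1), otherwise the normal approximation with tie and continuity
corrections — within 1e−3 of a 10⁵-resample permutation null on an 80-sample
fixture, with type-I error 4.5% at nominal 5% (16 vs 34, 2000 null
replicates). Correlations are Spearman (Pearson on midranks) or Pearson,
the latter optionally after a base-10 log transform of x and with a
t-based 95% confidence band for the fitted line. α = 0.05, two-sided
throughout. In the bundled cohort report the symptomatic group is by
default the culprit vessel only, contralateral vessels counting as
asymptomatic (switchable to patient-level grouping; the choice is recorded
in the report metadata).

## The synthetic cohort

### What it emulates

Each vessel is an annular wall cross-section (lumen radius 2.5 mm, outer
radius set by the wall area) constant over 10 slices of 2 mm, rendered on a
96² grid of 0.33 mm voxels. Proton density is uniform in the wall; the
lumen carries 2% residual blood signal (black-blood preparation); outside is
signal-free. Fibrous T2 is drawn per voxel from U(50, 90) ms (texture),
deposit T2 per deposit from U(20, 38) ms. Acquisition noise is Rician:
magnitudes `sqrt((S+g₁)² + g₂²)` with Gaussian σ set by the SNR (default
40) relative to the first-echo wall amplitude.

The lipid-support upper edge sits 4 ms below the 42 ms threshold — about
3 σ of the voxel-wise T2 estimate at SNR 40. This is a deliberate phantom
design choice: tissue whose T2 straddles the threshold within the
estimator's noise has no recoverable ground-truth deposit topology (warm
deposits lose ~13% of voxels at a 2 ms margin and fragment, inflating
deposit counts), so such a phantom would test fit noise rather than the
segmentation and morphometry chain. Real plaque tissue is under no such
constraint; this is one of the ways the phantom is cleaner than patient
data.

Deposits are capsules: all voxels within a radial half-thickness `d` of a
circular arc at mid-wall radius, with `d` and the arc half-angle solved per
slice from the deposit's target area (degenerating to a compact disc when
the area fits one). Capsules rasterise 8-connected at every size, unlike
thin full-thickness wedges, which develop sub-voxel radial gaps and
fragment. Deposits are separated by angular gaps of at least 0.26 rad
(shrinking to a 0.12 rad floor, then merging the smallest pair, in the rare
infeasible layouts). The longitudinal lipid profile is
`floor + (1 − floor)·exp(−d²/2τ²)` around the maximal slice (τ = 2 slices),
which sits at the designated bifurcation slice with probability 74.6% and
uniformly elsewhere otherwise.

Cohort structure: 50 patients (34 symptomatic, culprit side right-biased
2.7:1), two vessels each. Wall area and maximal-slice lipid fraction are
log-normal, sampled through Gaussian copulas whose per-patient latent
factors induce the bilateral correlations; the culprit vessel draws its
lipid fraction from the symptomatic family. Deposit count is
2 + Poisson (capped at 10); the largest deposit's share is logit-normal
(group-specific), the rest symmetric Dirichlet(2). Duplex stenosis is
group-wise normal, clipped to [50, 99]%.

### What it does not emulate

No pulse-sequence physics (DANTE preparation, fat saturation, stimulated
echoes), no coil profiles, no motion artefacts or scan rejection, no
partial-volume mixing (one tissue per voxel), no T1 weighting, no
anatomically shaped bifurcation (the bifurcation is "the slice configured
to carry maximal lipid"), no intra-plaque haemorrhage or calcification.
Passing end-to-end tests therefore demonstrates that the analysis chain
recovers known truth under idealised, noise-correct conditions — not that
it handles patient-data artefacts.

### Calibration

`calibrate_to_paper` matches the generator's parametric families to target
cohort statistics by deterministic root-finding (Brent) against a
fixed-seed sampler evaluation, with common random numbers across evaluations
(all base variates are drawn once and transformed, Poisson counts through
the quantile function, so every objective is smooth in its knob). Order:
lipid-fraction log-normals in closed form from median/IQR; profile floors
against the slice-averaged lipid medians; wall-area spread against the
wall-vs-log₁₀-lipid Pearson correlation; the two copula correlations
against the bilateral Spearman targets; deposit-share families and deposit
count alternately (twice) against the LLD% group medians and the cohort LAI
median, since the 1% exclusion couples them.

Because the published statistics come from a single 50-patient cohort,
calibration targets the *sampling expectation at that size*: the calibration
sample (30 000 patients) is split into 50-patient replicates, the statistic
computed per replicate and averaged. The distinction is material for the
bilateral Spearman correlation (expectation ≈ 0.48 at n = 50 when the
population value is 0.5) and for medians of skewed quantities such as LAI.
The group medians 49% and 42% for LLD% imply a cohort mixture median near
43.5%, not the separately printed 45%; the group values are calibrated and
the cohort median is left to follow.

### Tolerances and problem sizes

The end-to-end recovery check generates five independent 50-patient cohorts
(500 vessels, ≈ 2.4 million voxel fits), runs the full pipeline and averages
each recovered statistic over the five replicates — a few minutes on one
CPU, the same configuration the acceptance script uses. Medians are
required to land within 10% relative and correlations within 0.1 absolute of
their targets; with ~1–2% voxel-level segmentation bias (Rician fitting
bias plus rasterisation) and seed-averaged sampling noise (e.g. σ ≈ 0.065
for the five-seed mean of an n = 50 Spearman correlation), those bands are
the natural scale of the design, not a tuned quantity.

## Numerical and design choices

- **T2 bounds** [1, 2000] ms; bound-pinned fits flagged, never lipid.
- **Connectivity** 8 in-plane by default (a diagonal touch joins deposits);
  the original analysis used a commercial package whose convention is
  undocumented, so it is configurable.
- **1% rule** inclusive (≤ 1%), single pass, pre-exclusion denominator.
- **Max-slice ties** go to the lowest slice index; LLD% is tie-invariant.
- **Lipid % denominator** is the whole wall-mask area, stated explicitly
  because a plaque-only sub-region would give larger percentages.
- **Seeds**: one master seed per cohort; per-vessel generator and noise
  seeds are spawned deterministically (`SeedSequence`) and recorded, so any
  vessel can be regenerated in isolation.
- **Degenerate inputs**: empty masks, lipid-free vessels, slices without
  wall voxels and single-deposit slices all return well-defined objects
  with NaN/None where an index is undefined, rather than raising mid-cohort.

## Known limitations

- The mono-exponential model ignores multi-compartment decay and
  stimulated-echo contamination; fitted T2 is an effective value.
- No Rician bias correction: at SNR well below ~20 the upward T2 bias
  erodes the lipid/fibrous separation faster than the tests characterise.
- The phantom's wall is circularly annular and its deposits are capsules;
  morphometry on strongly non-convex real deposits is exercised only through
  the random-mask component-labeling tests.
- LAI is undefined on single-deposit slices by construction; cohort
  medians here simply omit such vessels.
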