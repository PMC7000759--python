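# Methods

This note documents the models, defaults and numerical choices behind
`vertchem`, and what the synthetic study does and does not establish.

## Signal model and reduction chain

An ablation record is a time-resolved matrix of ion counts per second
(cps), one column per monitored isotope mass. The forward model assumed by
both the generator and the reducer is

    cps(t, m) = B(m) + S(m) · d(order, m) · c(t, m) + noise,

where `B` is the gas-blank baseline, `S` the sensitivity (cps per ppm),
`d` a per-mass relative sensitivity that drifts over the acquisition run,
and `c` the concentration of the ablated material. The reduction chain
inverts this model step by step:

1. **Signal window.** The usable signal is the longest contiguous region
   where the internal standard (⁴³Ca) exceeds the blank mean by 10 blank
   SDs. Spot plateaus are trimmed by 2 s at each end (a deterministic
   stand-in for the manual screening of unstable signal portions);
   transect windows are not trimmed, so the record keeps its true focus
   and birthmark endpoints. Because a spiked blank point adjacent to the
   scan can pass the plateau threshold, transect edges are additionally
   trimmed by an ablation-yield criterion: leading/trailing points whose
   raw ⁴³Ca net signal is below half the window median are discarded
   before any despiking.
2. **Despiking.** Spot windows and blanks use an iterative two-sided
   Grubbs test (α = 0.05, critical value from the t-distribution closed
   form). The most extreme point is tested at the full series length,
   replaced by the mean of the non-spike points, and the modified series
   is re-tested; the procedure stops at a fixed point and is therefore
   idempotent. Transects carry genuine trend, which plain Grubbs would
   flag, so spikes there are detected on residuals from an 11-point
   running median (mirror padding, so edge spikes cannot dominate their
   own baseline) and must additionally exceed half the local signal level
   — a smooth noiseless trajectory is never modified, while the ×5–20
   single-point spikes the generator injects always are.
3. **Background.** The despiked means of the two bracketing gas blanks
   are subtracted per mass. Negative net cps are kept (not clamped) and
   surface as below-LOD flags, keeping the LOD bookkeeping unbiased.
4. **Drift.** NIST-612 is ablated in two-replicate brackets throughout
   the run. The drift factor of a mass at any acquisition order is the
   linear interpolation, on order, of that bracket's net cps relative to
   the first bracket (constant extrapolation outside). A linear synthetic
   drift is undone exactly at bracket positions; between brackets the
   interpolation is exact for linear drift, which is what the generator
   produces.
5. **Calibration and standardization.** Sensitivity comes from the first
   standard bracket (net cps / nominal concentration). Absolute ppm
   requires an internal-standard index for the sample matrix; vertebral
   bioapatite is assigned a fixed Ca mass fraction (default 0.399,
   configurable). Element:Ca molar ratios (µmol·mol⁻¹) are formed from
   drift-corrected cps ratios against the reference-bracket standard and
   do not depend on that assumption; Ca:Ca ≡ 10⁶ by construction.
6. **LOD and screening.** LOD(m) = 3·SD of the pooled despiked gas
   blanks, converted to ppm through `S·d`. Elements with ≥ 10 % (boundary
   inclusive) of replicate measurements below LOD are omitted from the
   analysis set; the internal standard is never dropped. Replicate spot
   scans are screened with Stahel–Donoho outlyingness: the maximum, over
   1000 seeded random unit projections, of the robust z-score of the
   projected point (median/normalized-MAD). Columns are
   robust-standardized first — random directions on raw ppm scales would
   otherwise be dominated by the few high-concentration elements — and
   replicates above 10 are excluded before averaging. Screening pools
   replicates per analysis set (all focus spots; all edge spots), which
   is the set within which the subsequent multivariate test operates.

## Multivariate tag statistics

* **PERMANOVA** (one-way): `SS_T = Σ_{i<j} d²_ij / N` over all pairs,
  `SS_W` summed per group, pseudo-F from the usual mean squares. On
  Euclidean distances of univariate data this equals the classical ANOVA
  F exactly, which the tests exploit as an oracle. p-values use the
  (b+1)/(B+1) convention with seeded label permutations, so they can
  never be 0 and are reproducible.
* **CAP**: principal coordinates of the distance matrix (centered Gower
  matrix, eigendecomposition, negative eigenvalues discarded — Euclidean
  input makes them numerically zero), the first m orthonormal axes, and
  the canonical correlations between those axes and the group indicator.
  The trace statistic is the sum of squared canonical correlations, with
  a permutation test. Leave-one-out classification re-runs the PCoA on
  the remaining N−1 samples, projects the held-out sample with the Gower
  formula, refits the canonical axes, and assigns to the nearest group
  centroid in canonical space (ties to the lowest group index).
  `m = auto` maximizes LOO accuracy over 1..N−2 with ties to the smallest
  m; a fixed m can be supplied instead. G_prop reports the share of
  positive eigenvalue mass captured by the m axes.
* **PCC**: chance accuracy Σ(nᵢ/N)²; significance is the exact binomial
  upper tail for the observed correct count at the chance rate — the
  permutation variant is unspecified in the source methods, and the
  binomial is exact and reproducible.

A caveat that shaped the test design: when m is chosen by maximizing LOO
accuracy, the reported accuracy is optimistically biased under the null
(selection and evaluation share the same folds). The null-calibration
simulation therefore fixes m (= 3 for N = 12, three groups); there the
mean LOO accuracy sits within a few points of the proportional-chance
rate, slightly *below* it, because a held-out sample's own centroid is
estimated from one fewer point and lies farther away on average.

## Profile classification and back-calculation

Sr:Ba and Pb:Ca are formed as raw (drift-corrected, background-subtracted)
cps ratios on the distance grid; points with nonpositive denominators are
flagged missing, never infinite. Smoothing is an 11-point centered running
average whose window shrinks symmetrically at the edges and skips missing
points. Ratios are formed first and smoothed second.

Thresholds come from the reported ranges: Pattern-2 profiles stay within
0–200; Pattern-1 peaks fall in 600–1200 and the nearshore band is 150–400.
Hence Pattern 2 ⇔ smoothed max ≤ T_low = 200; Pattern 1 ⇔ smoothed max ≥
T_peak = 600 and the terminal-segment mean ≤ T_return = 400; anything else
is reported as *undetermined* rather than forced into a binary call.
Initial/terminal segments are 10 % of the transect ("shortly prior to
birth" is not quantified in the source). The habitat shift R_t is the
first point after the global smoothed maximum below T_return. Pb
corroboration compares the terminal (Pattern 1) or initial (Pattern 2)
segment mean Pb:Ca against the 25–75 % mid-segment mean.

Fraser–Lee back-calculation uses `L_t = (R_t/R_V)(L_C − a) + a` with the
juvenile relation `L_C = 17.349·R_V + 14.516`. Transect distances are µm
and centrum radii mm, with one conversion point; the radius unit of the
relation is configurable because the underlying growth literature does not
state it unambiguously (mm assumed). The slope and intercept are
configuration, never re-fit: the specimen data behind them are not
available.

## Synthetic study

The generator emulates the study design: 4 pregnant females with litters
of 4, 3, 3 and 4 embryos (lengths 240–291 cm and 41–49 cm), and 15 YOY
(49.2–59.6 cm) of which 11 carry Pattern-1 and 4 Pattern-2 in utero
records. Acquisition order interleaves a gas blank before every ablation,
NIST-612 brackets (two replicates) before and after every fifth vertebral
section, and MACS-3 at each slide boundary. Spots are 60-s plateaus with
triplicate replicates; transects scan at 10 µm·s⁻¹; the acquisition rate
(not stated by the instrument description) defaults to 5 points/s.

Trajectories: Pattern 1 is a logistic rise from a nearshore baseline
(60–160) to a peak drawn in 650–1150, followed by a rapid logistic decline
(width 1.5 % of the transect) starting at the shift fraction (0.85 ± 0.02,
i.e. slightly before term) to a terminal value in 120–300; Pb rises
sigmoidally at the shift. Pattern 2 is a constant mean in 80–150 with
AR(1) jitter clipped inside 0–200 and Pb elevated at the focus, decaying
over the first ~7 % of the transect. Ba concentrations are set so the
drift-corrected cps ratio equals the environmental Sr:Ba index exactly;
Sr is modulated with the offshore index (so Sr:Ca and Ba:Ca are inversely
related, as observed) and scaled by a per-track lognormal uptake level
(σ = 0.15) that persists across a mother's spots and transects.

Noise: Gaussian with variance equal to the mean cps (counting statistics),
2 % multiplicative flicker, spikes with probability 0.01 per point scaled
by U(5, 20), and lognormal positional heterogeneity (σ = 0.08) between
replicate spot scans — real replicates ablate slightly different material,
and without this within-group spread the replicate-outlyingness screen
would see degenerate point clusters and flag whole litters. Litter
signatures apply a lognormal effect (σ = 0.25) per element to nominal
vertebral concentrations; a mother's edge-period environment vector is
identical to her embryos' by construction (the maternal tag). Seven
monitored trace elements (Sc, V, Cr, Ge, Au, Th, U) are configured below
their LODs so the ≥ 10 % omission rule is exercised; the NIST-612/MACS-3
concentrations, blanks and sensitivities are internal configuration
defaults shared by generator and reducer, not certificate values.

What passing tests show — and do not. The synthetic data are linear in
the forward model, drift is exactly linear, matrix effects are a single
scalar sensitivity, and there are no isobaric interferences, so exact
round-trips (1e-6 relative) demonstrate the *internal consistency* of the
reduction chain, not its robustness to real instrument pathologies.
Classification accuracies on synthetic litters depend on the chosen
between-litter (σ = 0.25) and within-replicate (σ = 0.08) variance scales;
they show the statistics behave correctly when groups are separated at
realistic signal-to-noise, not what accuracy real vertebrae would yield.

## Problem sizes and numerical choices

* Type-I calibration: 500 null data sets (N = 12, three groups of four,
  four features), 199 permutations each; the rejection rate at α = 0.05 is
  checked against the binomial 99 % CI. CAP null calibration: 200 data
  sets, m = 3 fixed.
* Pattern recovery: one 200-transect YOY cohort at default noise
  (≥ 90 % agreement required; observed 100 %), plus the deterministic
  limit for zero confusions and shift localization within 5 % of the true
  shift fraction (observed ≤ ~2.5 %).
* Eigenvalues below 1e-9 of the largest are treated as zero in PCoA;
  centroid ties in LOO are broken toward the lowest group index after
  rounding distances to 12 decimals; permutation p-values include the
  observed statistic.
* Degenerate inputs: series shorter than 3 points pass through despiking
  unchanged with a warning; records whose internal standard never clears
  the blank threshold are flagged failed ablations and excluded; an
  all-excluded spot yields a signature marked missing; profiles that never
  clear the return threshold cannot host a shift and raise.

## Known limitations

* The despiking of trending transects (running-median residuals with a
  relative floor) is a pragmatic rule, not a changepoint model; extended
  multi-point spikes would evade it.
* The "mean integrated transect data" used for the transect-based litter
  test is ambiguous in the source; both the full resampled profile
  (default feature matrix) and per-element transect means are produced.
* Printed chance rates for two of the source analyses (40 %, 26.4 %) are
  not reproducible from the printed group sizes; PCC is always computed
  from the actual analysis set instead of hard-coding those numbers.
* Back-calculation assumes linear proportionality between body length and
  centrum radius near term; early-gestation growth is faster and is out
  of scope here, as in the source analysis.
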