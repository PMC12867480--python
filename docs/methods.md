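# Methods

## The estimand

A chromatin-bound molecule disappears from a tracking experiment when it
dissociates, photobleaches, defocuses, or is missed by the detector. The
survival function of bound dwell times therefore decays at an *apparent*
rate. Fitting

S(t) = exp(−k_off_app · t)

to the Kaplan–Meier estimate of dwell times gives `k_off_app`, which is
an upper bound on the true dissociation rate. Rather than attempting to
subtract the nuisance contribution, the analysis bounds it: a fixed-cell
control (molecules chemically crosslinked, unable to dissociate) is
imaged under identical conditions, and the upper 95% confidence limit of
its fitted rate is the *photobleaching floor*. A live-cell rate at or
below the floor is bleaching-limited and uninterpretable as
dissociation; rates well above it are dominated by genuine unbinding.
Condition contrasts use disjointness of 99% bootstrap confidence
intervals (p < 0.01). This is why no censoring is applied in the
survival estimate — every track end, whatever its cause, is an event,
and the floor absorbs the non-dissociation causes.

## Analysis pipeline

1. **Precision filter.** Localizations are kept when their reported
   precision is strictly better than a threshold (25 nm for 2D data,
   40 nm as the looser initial 3D threshold). The strict inequality is a
   deliberate, documented reading of "better than"; the boundary
   behaviour is configurable.
2. **Linking.** Localizations in successive frames are connected when
   within 400 nm (planar distance). Candidate links per frame pair are
   accepted greedily in ascending distance, one link per localization
   per side; exact ties resolve by lowest row index. No gap closing: a
   missed detection ends the track. This inflates the apparent rate
   identically in live and fixed cells and is therefore absorbed by the
   floor.
3. **Segmentation.** A trajectory frame is chromatin-bound iff it lies
   in a window of W consecutive frames (default 5) whose maximum
   pairwise planar displacement is ≤ r_conf (default 220 nm ≈
   √2·4σ_loc + diffusion allowance). This sliding-window confinement
   classifier is deterministic and validated against simulator ground
   truth (≥ 95% per-frame agreement at the 20 ms regime with default
   noise). At the 500 ms regime motion blur removes free molecules
   before detection, so all localized molecules may be declared bound
   (`assume_bound`, the default for frame intervals ≥ 0.1 s).
4. **Dwells.** One dwell per maximal run of bound frames; duration =
   (run length − 1) × frame interval, i.e. time from first to last
   observation of the episode. Single-frame runs carry no duration and
   are discarded.
5. **Survival.** Dwells shorter than t_min = 1.5 s are discarded (noise
   floor); survivors are shifted by −t_min so S(0) = 1. For an
   exponential distribution this left truncation plus re-origin leaves
   the rate unchanged (memorylessness). The t_min filter is applied to
   dwell records; a flag applies it at whole-track level instead for
   the long-exposure case where they coincide. The Kaplan–Meier
   estimate is computed with lifelines; with zero censoring it equals
   the empirical survival function exactly (asserted by an oracle
   test). If a dwell equals t_min exactly, its event sits at the
   re-origin itself; the stored curve always carries an explicit (0, 1)
   origin point ahead of any such step.
6. **Fit.** Unweighted nonlinear least squares of exp(−k t) over the KM
   step points (the origin plus one point per distinct event time).
   Confidence intervals are percentile bootstrap over dwell records
   (default 1000 resamples, seeded); intervals are widened, if
   necessary, to contain the point estimate. The closed-form
   left-truncated exponential MLE, n / Σ(tᵢ − t_min), is exposed as an
   independent cross-check and agrees with the NLS fit within 5% at
   n ≥ 1000 in tests. The fit refuses curves with fewer than three
   distinct event times or no decay (e.g. a fixed-cell movie without
   bleaching).
7. **Pooling.** Replicates are pooled before fitting; per-replicate
   fits remain available for QC by running conditions separately.

## The simulator

Each molecule carries three independent exponential clocks —
dissociation (k_off), rebinding (k_on) and bleaching (k_bleach) — in a
continuous-time two-state chain, with the initial state drawn from the
equilibrium occupancy k_on/(k_on + k_off). Bound molecules are static
(D_bound = 0 by default); free molecules are Brownian with D_free
(default 2 µm²/s). Positions are evaluated at frame times; the state at
the frame-start time determines that frame's behaviour. A localization
is emitted iff the molecule is unbleached, within the ±2 µm axial slice,
and its state's RMS within-frame displacement √(4·D·Δt) does not exceed
`blur_max_nm`. Emitted coordinates add isotropic Gaussian noise of SD
σ_loc (default 25 nm); the reported precision is σ_loc perturbed by
±20% uniform noise (a nominal value of 1 nm is reported for noiseless
test tables, which need a positive precision).

Defaults and rationale:

- **blur_max_nm = 500.** √(4·2·0.02) µm = 400 nm at 20 ms and 2000 nm
  at 500 ms, so a 500 nm cut reproduces the experimental regime split:
  free molecules detectable at short exposures, motion-blurred out at
  long ones. The hard threshold stands in for PSF-level blur without
  image rendering.
- **Photoactivation** is modelled by staggering appearance frames
  uniformly over the movie, keeping per-frame density sparse for
  unambiguous linking (≥ 99.9% of links join the correct molecule at
  the defaults). Real activation schedules are user-configurable via
  n_molecules / n_frames; the experiment fixes neither.
- **Bleaching clock** runs from appearance (continuous illumination),
  the simplest model consistent with a single apparent exponential.
- **k_on = 0.5 s⁻¹** by default, i.e. a mean free-search time of 2 s,
  in the range reported for nuclear TF target search.
- **Axial behaviour.** Bound molecules never leave the slice; free
  molecules diffuse axially and are permanently lost once |z| exceeds
  the half-width, keeping bound-state loss attributable to bleaching
  only, as the fixed-cell floor assumes.

Ground truth records every molecule's state intervals, bleach time and
true positions. Observed bound-episode durations are the minimum of two
independent exponentials and hence Exponential(k_off + k_bleach) — the
analytic oracle behind `analytic_apparent_rate` and the recovery tests.

### What the simulator does not emulate

Camera noise, dye blinking/re-activation, PSF shape and 3D lobe
geometry, chromatin motion of the bound state, heterogeneous binding-site
classes (one k_off per condition), and detection dropout (detection is
perfect for unblurred in-slice molecules). Passing recovery tests
therefore show the estimator chain is correct under the model's
assumptions, not that real data are free of, e.g., multi-exponential
dwell mixtures — for real data the fixed-cell floor and the residual
structure of the fit must be inspected.

### Known estimation biases

**Defocus enrichment of the bound state.** Bound fractions are computed
over *detected* trajectory frames. Free molecules diffuse out of the
axial slice and are lost, so detected frames oversample the bound state
and the bound fraction exceeds the equilibrium occupancy
k_on/(k_on + k_off) — by roughly 0.1 at the short-exposure defaults.
This is a property of the measurement (shared with the real experiment),
not of the estimator: with the axial slice widened in simulation, the
estimate matches the equilibrium value.

### Known discretization bias

Free excursions shorter than one frame interval can escape detection,
merging two bound episodes into one dwell. At 500 ms frames with
k_on = 0.5 s⁻¹ about a fifth of excursions are at risk, giving an
apparent rate a few percent below k_off + k_bleach (0.065 vs 0.07 s⁻¹
in the reference scenario). The same effect exists in the real
experiment; it cancels in condition comparisons made at the same frame
interval.

## Genomic-region computations

Interval sets use BED conventions (0-based, half-open). An interval
overlaps another set if it shares ≥ 1 base with any member (configurable
minimum); counting is per query interval against the merged target set,
verified against a per-base brute-force oracle. Overlap shares are
reported as percentages to one decimal. A/T content is case-insensitive
with ambiguity codes counted in the denominator only. Spike-in scale
factors are each sample's uniquely mapped spike-in read count divided by
the smallest such count; whether downstream coverage is multiplied or
divided by the factor is a reporting choice (divide to normalise down to
the lowest sample) — the factors themselves are what the package emits.

## Numerical choices and problem sizes

- NLS initialisation at 1/mean(shifted durations); bootstrap refits fall
  back to that moment estimate on the rare non-convergence.
- Simulated tables are analysed with the 40 nm precision threshold: the
  simulator reports a nominal precision of σ_loc ± 20% (20–30 nm at the
  default 25 nm), so the strict 25 nm cut would discard half the rows
  and fragment tracks at random — a detector property the simulator
  does not model. The 25 nm default applies to real localizer output,
  whose precision distribution genuinely spans the threshold.
- The acceptance script and tests use 3000-molecule movies of 5000
  frames at 500 ms (per-frame density ≈ 40 emitters in a 20 × 20 µm
  field), 20 seeds for the floor-coverage and contrast-detection rates,
  and 300–500 bootstrap resamples — sizes chosen so each scenario's
  Monte-Carlo error is small relative to the 10% recovery tolerances.
- Reported seeds: every random draw (simulation, bootstrap) descends
  from an explicit integer seed; identical configurations are
  bit-reproducible.

## Open design points resolved here

- The segmentation algorithm behind published bound fractions is cited
  rather than restated in the experimental literature; the
  sliding-window classifier here is a standard, testable choice, with
  window and radius exposed.
- The published 1.5 s filter sentence ("tracks with a residence time
  shorter than…") is ambiguous between tracks and bound episodes; it is
  applied to dwell episodes, with a track-level flag available.
- The CI construction behind published error bars is unstated;
  percentile bootstrap over dwells was chosen for its lack of
  distributional assumptions.
- Whether the published spike-in divisor is the lowest sample's spike
  count or its total mapped reads is ambiguous; ratio-to-minimum-spike
  is implemented, with the alternative achievable by supplying those
  totals as the counts.
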