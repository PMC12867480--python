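# smresidence

Single-molecule residence-time analysis of transcription-factor (TF)
binding to chromatin, for labs doing live-cell single-particle tracking
(SPT/SMLM) of HALO-tagged nuclear proteins.

Chromatin remodellers such as CHD4/NuRD can actively limit how long a TF
stays bound to chromatin. The measurable signature is the dwell-time
distribution of individual chromatin-bound molecules: localizations are
linked into trajectories, trajectories are segmented into chromatin-bound
and freely diffusing states, and the survival function of bound dwell
times *t* (measured from first observation) is fitted with a single
exponential

```
S(t) = exp(−k_off_app · t)
```

where `k_off_app` is the **apparent** dissociation rate: it conflates true
dissociation with photobleaching and tracking loss. Those nuisance
processes are bounded by a **fixed-cell control** — formaldehyde-fixed
cells in which molecules cannot dissociate — whose fitted rate's upper
95% confidence limit is the photobleaching floor. Two conditions differ
significantly when their 99% bootstrap confidence intervals are disjoint
(p < 0.01).

The package provides:

- `simulate` — a two-state (bound ⇌ free) kinetic simulator with
  exponential dissociation (`k_off`), rebinding (`k_on`) and bleaching
  (`k_bleach`), Brownian free diffusion, a 4 µm axial capture slice, and
  motion blur that removes fast-diffusing molecules at long (500 ms)
  exposures — with full ground truth for validation.
- `locio` — localization-table IO and the precision filter
  (keep precision **better than** 25 nm, strict).
- `tracking` — frame-to-frame linking within 400 nm (greedy
  ascending-distance matching, no gap closing).
- `kinetics` — sliding-window bound-state segmentation, bound fractions,
  dwell extraction, Kaplan–Meier survival (dwells < 1.5 s discarded,
  re-origined), exponential fitting with percentile-bootstrap CIs, rate
  comparison and the bleaching floor. Also a closed-form truncated
  exponential MLE as an internal cross-check.
- `regions` — genomic-interval overlap counts/shares (BED, half-open),
  A/T base composition, and spike-in scale factors for sequencing
  normalization.
- `pipeline` — end-to-end orchestration with seeded determinism and
  per-stage artifacts.

Stage classes (`PrecisionFilter`, `TrajectoryLinker`,
`BoundStateClassifier`, `ResidenceTimeFitter`) follow scikit-learn
conventions (`fit`/`transform`, `get_params`, fitted attributes with a
trailing underscore).

## Worked example

```python
from smresidence import (SimConfig, simulate_condition, filter_precision,
                         link_trajectories, classify_states, extract_dwells,
                         km_survival, fit_koff, analytic_apparent_rate)

cfg = SimConfig(n_molecules=3000, seed=42, k_off=0.05, k_bleach=0.02,
                frame_interval=0.5, n_frames=5000, sigma_loc=25.0)
table, truth = simulate_condition(cfg)
trajs = link_trajectories(filter_precision(table, 40.0), max_link_nm=400.0)
# 500 ms frames: motion blur removes free molecules, so every
# localized molecule is treated as chromatin-bound
labels = [classify_states(t, assume_bound=True) for t in trajs]
dwells = extract_dwells(trajs, labels, cfg.frame_interval)
fit = fit_koff(km_survival(dwells, t_min=1.5), bootstrap_reps=1000, seed=1)
print(f"k_off_app = {fit.k_off_app:.4f} /s, 95% CI {fit.ci95}")
print(f"expected  = {analytic_apparent_rate(cfg):.2f} /s")
```

prints

```
k_off_app = 0.0653 /s, 95% CI (0.06311422343810102, 0.06767790839612967)
expected  = 0.07 /s
```

The fitted apparent rate recovers the sum of the dissociation and
bleaching rates (0.05 + 0.02 s⁻¹); the small downward offset comes from
sub-frame unbinding/rebinding excursions that merge adjacent bound
episodes, a discretization effect inherent to frame-based tracking (see
`docs/methods.md`).

The genomic worked example: of 26,510 sites gaining accessibility upon
depletion of one factor, 4,559 also gain upon depletion of the other —

```python
>>> from smresidence import overlap_share
>>> overlap_share(4559, 26510)
17.2
```

a 17.2% share.

## Command line

```bash
smresidence fixtures demo --seed 1      # small simulated 3-condition bundle
smresidence run demo/run.yaml           # full analysis + JSON report
smresidence track locs.csv --max-link-nm 400 --out trajs.csv
smresidence kinetics fit trajs.csv --frame-interval 0.5 --dwell-min 1.5
smresidence regions overlap a.bed b.bed
smresidence regions at-content sites.bed genome.fa
smresidence regions spike-factors counts.tsv
```

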