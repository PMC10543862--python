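# Methods

## Problem and coordinate model

A cochlear-implant electrode array is localized in post-operative imaging by
two polar coordinates per electrode contact, both defined relative to the
mid-modiolar axis (the central axis of the cochlear spiral):

* **EMD** — electrode-to-modiolar-axis distance, in mm;
* **aDOI** — angular depth of insertion, in degrees, measured from the
  round-window direction (0°); a deeply inserted array passes a full turn, so
  aDOI is a multi-turn angle that can exceed 360°.

With the axis at the origin and +x toward the round window, the planar
coordinates of electrode *i* are

    x_i = EMD_i · cos(aDOI_i),   y_i = EMD_i · sin(aDOI_i)

and the inverse transform is `EMD_i = √(x_i² + y_i²)`,
`aDOI_i = atan2(y_i, x_i)` followed by unwrapping. Degrees are used at every
interface and in files; radians only inside the trigonometric calls.

### Angle unwrapping

`atan2` returns angles in (−180°, 180°]; the multi-turn angle is recovered in
two steps applied to the basal-to-apical electrode sequence:

1. each angle is reduced modulo 360° into [0°, 360°) (a full modular
   reduction, so inputs that are already beyond one turn are also accepted);
2. a *wrap event* is a consecutive electrode pair whose first angle lies in
   [270°, 360°] and whose second lies in [0°, 90°] — the signature of the
   trajectory passing the 0° direction into the next turn. Each electrode
   gains 360° per wrap event preceding it.

Counting *per event* (rather than adding 360° once when any event exists) is
the natural generalization; the two rules coincide for arrays spanning less
than ~540°, which covers the 22-contact perimodiolar geometry modelled here.
The unwrap is reliable when consecutive measured electrodes are less than 90°
apart, which holds for 12 electrodes spanning ≈400°. Ascending electrode
number is taken as basal→apical (E22 most apical); a `basal_to_apical=False`
flag serves datasets with the reverse convention. Non-monotone inputs are not
rejected — the literal rule is applied.

## Axis collocation

Two raters (or a manual and an automatic method) select the mid-modiolar axis
independently, and the two selections are not expressible in a common image
frame. A between-method axis offset leaves a *partial periodic difference
pattern*: the radial projection of a fixed offset varies with insertion
angle, so per-electrode EMD/aDOI differences oscillate over the array.
Collocation removes this systematic component by translating one set's
coordinates uniformly:

    cost(shift_x, shift_y) = (1 − ρ(EMD_t, EMD_ref)) + (1 − ρ(aDOI_t, aDOI_ref))

where the moving set is transformed Cartesian → shift → polar (with
unwrapping) and ρ is the Pearson correlation across the electrodes of one
array. The cost lies in [0, 4] and vanishes when both parameter sequences
are perfectly linearly related; for a noise-free pure-offset pair it is
exactly zero at the restoring shift. Only translation is modelled — no
rotation (both methods share the round-window 0° reference) and no scaling.

Numerical choices:

* **Optimizer.** Nelder–Mead simplex (derivative-free; the cost is piecewise
  smooth but not differentiable where the unwrap pattern changes) within the
  square [−2, 2] mm — candidate axes are anatomically within ~2 mm of each
  other — from a deterministic 5-point multi-start lattice (origin plus the
  four quadrant points at half the bound). Starting at the origin guarantees
  the returned cost never exceeds the zero-shift cost; the extra starts guard
  against the cost's mild multimodality. Termination at 1e-4 on both cost
  and shift (mm). Identical inputs give identical results.
* **Degeneracies.** A probed shift that puts an electrode exactly on the axis
  makes its angle undefined; such points are treated as infinitely costly
  during search (and skipped, counted, in the grid oracle). Zero-variance
  parameter sequences make ρ undefined and are reported as errors, not
  patched.
* **Oracle.** An exhaustive grid search (ties broken by smaller shift norm,
  then lexicographically) provides an independent check of the optimizer in
  the tests; it is never the implementation path.
* **Pooling.** One shift per array (one axis selection per scan), applied to
  the designated moving set (by default the automatic method); electrode-level
  differences of all arrays are then pooled for the post-collocation
  statistics, exactly as for the pre-collocation ones.

## Agreement statistics

* **Bland–Altman**: bias = mean difference, limits of agreement =
  bias ± 1.96·SD with the sample (n−1) standard deviation — the conventional
  choice. Differences are pooled across arrays at the electrode level;
  within-array clustering is deliberately not modelled.
* **Percentage error** = 100 · (upper LoA − lower LoA) / mean of the
  reference (manual) method — scale-invariant by construction.
* **Pearson r** with a Fisher-z confidence interval (default 95%), via
  `scipy.stats.pearsonr`.
* **ICC**: two-way model, absolute agreement, computed from the ANOVA mean
  squares (rows = subjects, columns = raters):
  `ICC(A,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n)`; the single-measure form
  ICC(A,1) is exposed but not the default. An all-constant matrix (identical
  raters, zero variance everywhere) is defined as ICC = 1.
* **Normality**: Kolmogorov–Smirnov with mean and SD estimated from the
  sample, hence Lilliefors-corrected p-values (statsmodels). Constant data is
  flagged degenerate rather than tested.
* **Confounder screens**: Wilcoxon rank-sum for two groups, one-way ANOVA for
  more, on per-array bias; each group needs n ≥ 3. The report can flag
  whether the spread of group mean biases exceeds the interrater precision.
* No multiple-testing correction is applied anywhere in the battery.

The a-priori criteria are the interrater half-width LoA (1.96·SD of
interrater differences, computed globally rather than per electrode) and the
interrater ICC; a candidate method's bias is judged acceptable when its
magnitude does not exceed the interrater precision for that parameter.

## Synthetic cohort generator

The generator emulates the structure of a 50-patient electrode-localization
study so that every stage is testable without patient data:

* **Trajectory**: a planar log-spiral `r(θ) = r0 · exp(−decay·θ)` with
  `r0 = 2.8 mm` and decay `1.1046e-3 /deg` (so r ≈ 1.8 mm at 400°), sampled
  at E1 + even electrodes E2–E22 (12 contacts) evenly spaced over 20°–420°.
  These defaults are synthetic: they yield EMD magnitudes typical of a
  perimodiolar array, but no real electrode coordinates stand behind them.
  Small deterministic per-array jitter of span and size (±15°, ±5%) keeps
  cohort arrays from being clones; `array_jitter=False` disables it.
* **Axis offsets**: per array, magnitude |N(0.3 mm, 0.1 mm)| (folded normal),
  direction uniform on the circle. Real offset magnitudes are unknown; 0.3 mm
  is of the order of the voxel size and produces difference patterns of the
  magnitude the method comparison reports.
* **Noise**: independent Gaussian per electrode and parameter with
  σ_EMD = 0.0722 mm and σ_aDOI = 3.61°, the values for which two independent
  replicates give limits of agreement 1.96·√2·σ = ±0.2 mm and ±10° — the
  interrater precision the criteria are built on. EMD is floored at 1e-3 mm
  and aDOI at 0 (clips are logged; they do not occur at default settings).
* **Reproducibility**: all randomness derives from `(seed, array_index,
  stream)` seed sequences; regenerating a cohort with the same seed is
  byte-identical, and hidden offsets are written to a truth sidecar for
  parameter-recovery checks.

What the generator does **not** emulate: 3-D anatomy (axis tilt, scala
geometry), imaging (voxelization, artifacts, segmentation error), spatially
correlated or heteroskedastic measurement error, and rater-specific
round-window disagreement (a rotation, excluded by the shift-only model).
Passing tests therefore demonstrate the correctness of the algorithms under
the model's assumptions, not the performance of any imaging tool on real
scans.

## Problem sizes in the test suite

The validation suite runs cohorts of 5–50 arrays and up to 20 seeds per
property (e.g. the end-to-end LoA-shrinkage check uses 20 default 50-array
cohorts; noise calibration uses ~10,000 simulated pairs), sizes at which the
Monte-Carlo error of each checked quantity is well inside its asserted
tolerance. The noisy offset-recovery check uses 20 seeds of 5-array cohorts —
recovery is a per-array problem, so the cohort size only sets how many draws
enter the median.

## Known limitations

* Translation-only registration cannot absorb a rotational disagreement about
  the round-window direction; such a component would remain in the aDOI
  differences after collocation (consistent with the residual periodic aDOI
  pattern the method comparison leaves).
* The correlation cost is invariant to affine rescaling of the parameter
  sequences, so collocation aligns *patterns*, not absolute values; a global
  EMD bias survives collocation by design and is reported as bias.
* Pooled Bland–Altman statistics ignore the within-array correlation of
  electrode-level differences; confidence statements about the limits would
  need a clustered model, which is out of scope.
* The ICC is computed on the complete-matrix case only; missing cells are an
  error, not imputed.
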