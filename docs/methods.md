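# Methods

## Signal models

**Multi-echo GRE.** The magnitude signal of a voxel with baseline amplitude
S0 and effective transverse relaxation rate R2\* (1/s) is modelled as
mono-exponential, S(TE) = S0·exp(−R2\*·TE), sampled at the six echo times
4.92, 9.84, 14.7, 19.6, 24.6 and 29.51 ms.  Echo times are carried in ms
(scanner convention) and converted to seconds inside the fitters, so R2\* is
always in 1/s.

**Diffusion.** A single symmetric tensor D per voxel, with signal
S = S0·exp(−b·gᵀDg) over 30 approximately isotropically distributed
directions at b = 1000 s/mm² plus three b = 0 volumes.  White matter uses
an axially symmetric tensor (default eigenvalues 1.7, 0.3, 0.3 ×10⁻³ mm²/s)
aligned with the local fiber axis; other tissue is isotropic
(0.8 ×10⁻³ mm²/s).

**Noise.** Magnitude images carry Rician noise: independent zero-mean
Gaussian noise of SD `noise_sigma` (signal units, default 10 at S0 of
900–1000, i.e. SNR ≈ 90–100) is added to two quadrature channels and the
modulus is taken.  No noise-floor correction is applied in the fitters;
at the default SNR the Rician bias on a 6-echo fit is far below the
effect sizes studied, but this is a documented limitation at low SNR.

## The phantom

The anatomy is a stylised 48³ block layout (2 mm voxels): each hemisphere is
a cerebral-white-matter slab with four embedded deep-gray boxes (thalamus,
caudate, putamen, ventral diencephalon), labelled with FreeSurfer-style
integer ids and a TSV lookup table.  It makes no attempt at realistic
geometry; it exists so that every downstream estimate has a known truth.

* **Fiber field.** Inside each WM slab the fiber axis lies in the x–z plane
  and its angle to B0 (fixed to the third image axis, the scanner z
  convention) sweeps linearly from 0° to 90° along y.  This guarantees all
  eighteen 5° orientation bins are populated in both hemispheres (the
  smallest bin holds ≈ 1500 voxels).
* **R2\* truth.** Gray-matter regions carry per-(region, hemisphere,
  condition) values taken from the studied design's migraine-free means,
  with migraine-day shifts of +1.0 1/s (left caudate), −1.1 (right caudate),
  +1.3/−1.0 (ventral DC left/right) and smaller offsets elsewhere.  WM
  voxels follow R2\*(θ) = a + b·sin²θ with free-day (a, b) = (19.6, 2.5)
  left and (19.8, 2.1) right — chosen to match the profile endpoint means
  19.6→22.1 Hz and 19.8→21.9 Hz.  On migraine days the left isotropic term
  rises by 0.4 1/s (which alone lowers the left index by ≈ 1.9%) and the
  right anisotropic amplitude shrinks to b = 1.737, which lowers the
  generative right index b/(2a+b) by 16.6%.
* **Day schedule and jitter.** 21 days, migraine on days 12 and 16.  Real
  regional means fluctuate from day to day by far more than image noise can
  explain after averaging thousands of voxels, so the generator adds an
  explicit physiological term: an independent Gaussian offset per
  (region, hemisphere, day) with SD `day_jitter_sd` = 0.25 1/s.  This
  reproduces across-day regional SDs of ≈ 0.2–0.4 1/s, inside the reported
  0.2–1.0 band, and is what makes the 19-vs-2 day statistics meaningfully
  powered rather than degenerate.  The condition-level truth (without
  jitter) is kept separately so that contrast checks can be exact.
* **Determinism.** All randomness flows from the spec seed; per-day noise
  streams are derived from (seed, day), so regenerating a study is
  bit-identical.

What passing phantom tests does **not** show: robustness to motion, eddy
currents, field inhomogeneity, partial-volume mixing, registration error
across days, or realistic fiber-crossing geometry — none of which the
generator emulates (co-registration is assumed; crossing fibers are out of
scope of the single-tensor model).

## Estimators

**R2\* fitting.** Default is weighted linear least squares of ln S on TE
with weights S² (variance-stabilising for log-transformed Rician-ish data);
an optional Levenberg–Marquardt refinement of (S0, R2\*) on the raw signal
is vectorised over voxels with the 2×2 normal equations solved in closed
form (damping halved on success, ×4 on failure, ≤50 iterations, relative
cost tolerance 1e−12).  Voxels with a non-positive signal at any echo are
flagged invalid, never zeroed; negative fitted R2\* is retained but visible
to consumers via the value itself (transparency over clamping).  The default
foreground mask keeps voxels whose first-echo signal exceeds 5% of the
first echo's 99th percentile.

**Tensor fitting.** Ordinary least squares of −ln(S/S0) on the six design
components b·(gx², gy², gz², 2gxgy, 2gxgz, 2gygz), with S0 the geometric
mean of the b = 0 volumes, followed by a symmetric eigen-decomposition with
eigenvalues sorted descending.  Collinear direction sets are rejected
(design rank < 6).  bvecs are interpreted in image coordinates (FSL
convention).

**Fiber angle.** θ = arccos(|e1·B0|) in degrees, antipodally symmetric and
folded to [0°, 90°].  For near-isotropic tensors e1 is meaningless, so
voxels with FA < 0.1 are excluded from orientation pooling (threshold
exposed as `fa_threshold`); θ itself remains defined everywhere the fit is
valid.

**Orientation profile and anisotropy.** Voxel θ is assigned to bin
⌊θ/5⌋, half-open bins with θ = 90° joining the last bin.  Bins with fewer
than `min_count` = 50 voxels are undefined — the (max−min)/(max+min) index
amplifies unstable extremes, and 50 stabilises them at this grid size.  The
index is computed on raw bin means (the profiles are reported binned, and no
smoothing step is part of the procedure); a least-squares a + b·sin² fit is
available as a cross-check (`fit_sin2_model`).  Because bin means sit at
bin-interior angles, the binned index on the sin² model is biased low by
≈ 0.5% relative to b/(2a+b); tolerances in the tests account for this.
Anisotropy is computed **per day** and then compared across days (matching
the per-day grouping of the condition statistics); condition-pooled
profiles are also produced for plotting-style summaries.

## Statistics

The **day is the sampling unit** (19 migraine-free vs 2 migraine days):
voxels are averaged within a region first.  Route selection applies
Shapiro–Wilk per group at α = 0.05; any group with n < 3 (always true for
the migraine group) makes the test undefined and forces the nonparametric
route — a conservative, reproducible rule.  The nonparametric two-sample
test is a two-sided Mann–Whitney U with an **exact** null distribution by
complete enumeration of all C(n, n_b) rank assignments (mid-ranks for ties;
p = 2·min(P(U≤u), P(U≥u)) capped at 1).  With 19 vs 2 the enumeration is
210 assignments and the smallest attainable p is 2/210 ≈ 0.0095; a normal
approximation would be meaningless at n = 2, and exactness makes the value
independently checkable by brute force.  The parametric route is Welch's
t (unequal variances — the groups are severely unbalanced).  Multi-group
comparisons use one-way ANOVA or Kruskal–Wallis with pairwise post-hoc
tests Bonferroni-adjusted over the pair family.  The condition table's
Bonferroni family is **all rows of the table being reported**, stated in
the run log; p-values of the studied design itself are not reproducible
without the raw per-day data and are not targets of this package.

**Iron conversion** divides ΔR2\* by the gray-matter calibration slope
0.27 1/s per (mg iron/kg wet tissue); white-matter rows are not converted
by default because myelin confounds the calibration there (flag to
override).  **Hemispheric contrast** pairs left/right rows per region and
counts opposite-signed percent changes; midline structures are excluded.
The **sensitivity re-run** drops the migraine-free days immediately
following each attack (days 13 and 17 in the default schedule) and
recomputes the full table.

## Pipeline and reproducibility

`compute_maps` (per-day R2\*, θ, FA) uses no condition labels, supporting a
blinded workflow; `analyse_maps` consumes the labels afterwards.  All
intermediates are written to disk (NIfTI for maps, CSV for tables) and all
CSVs use a fixed float format, so a re-run with the same seed is
byte-identical.  Problem sizes used throughout (48³ grid, 21 days, 6
echoes, 33 DWI volumes) keep a full simulate-plus-analyse cycle at well
under a minute on one CPU while leaving ≈ 1500+ voxels per orientation bin
and ≈ 200+ voxels per gray-matter region.

## Known limitations

* Mono-exponential R2\* only: no multi-compartment or complex-valued
  fitting, no macroscopic-field-gradient correction, no QSM.
* Single-tensor diffusion: no crossing fibers, no robust (RESTORE-style)
  rejection.
* No noise-floor term in either fitter (bias grows at low SNR).
* The phantom's day-to-day jitter is independent across days and regions;
  real physiological fluctuation is likely autocorrelated and spatially
  structured, so the sensitivity re-run on the phantom is a consistency
  check, not a power analysis.
* The R2\*-to-iron slope is a gray-matter population calibration; converted
  values are approximations, not absolute concentrations.
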