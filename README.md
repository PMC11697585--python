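# qrelax

Longitudinal quantitative-MRI analysis of brain iron dynamics: voxel-wise
R2\* relaxometry, diffusion-tensor fiber-angle mapping, orientation-resolved
R2\* anisotropy, and region-of-interest condition statistics — exercised on a
synthetic phantom study with fully known ground truth.

## The scientific problem

The effective transverse relaxation rate R2\* (= 1/T2\*, in 1/s) is an
established in-vivo marker of brain iron: in gray matter R2\* rises linearly
with tissue iron concentration.  A single-subject design that scans a
migraine patient on 21 consecutive days — 19 migraine-free days and 2 days
with an acute attack — can ask whether iron content fluctuates on the time
scale of a migraine cycle.  In white matter, R2\* is confounded by myelin and
by the orientation of fibers (and fiber-parallel vessels) to the scanner's
main field B0; R2\* there is well described by

    R2*(θ) = a + b·sin²θ,

where θ is the fiber angle to B0 estimated from the diffusion tensor's
principal eigenvector.  Pooling white-matter voxels into eighteen 5° angle
bins and summarising the binned profile with the anisotropy index

    R2*_anisotropy = (R2*_max − R2*_min) / (R2*_max + R2*_min)

separates the isotropic (iron-sensitive) from the anisotropic
(vascular/myelin-sensitive) component; for the sin² model the index
converges to b/(2a + b) as noise vanishes.

This package implements that analysis chain for researchers in quantitative
neuroimaging, and — because raw patient MRI of this kind is not publicly
shareable — ships a phantom generator that emulates the acquisition
(6-echo GRE at TE = 4.92–29.51 ms; 30 diffusion directions at
b = 1000 s/mm² plus 3 b = 0 volumes; Rician magnitude noise; per-region
condition effects and day-to-day physiological jitter) so every step can be
validated against ground truth.

## What is in the box

| Module | Purpose |
| --- | --- |
| `qrelax.phantom` | synthetic study generator (anatomy, fiber fan, signals, manifest) |
| `qrelax.relaxometry` | weighted log-linear and NLLS mono-exponential R2\* fitting, map averaging, ΔR2\* maps |
| `qrelax.diffusion` | OLS diffusion-tensor fit, eigensystem, fiber angle to B0, FA |
| `qrelax.orientation` | 5°-bin orientation profiles, anisotropy index, condition averaging |
| `qrelax.regional` | label/LUT aggregation, condition table, hemispheric contrast, iron conversion, sensitivity re-run |
| `qrelax.stats` | Shapiro–Wilk gate, Welch t, exact (complete-enumeration) Mann–Whitney U, ANOVA/Kruskal–Wallis, Bonferroni |
| `qrelax.pipeline` / `qrelax.cli` | study orchestration (blind map stage + stats stage) and the `qrelax` command line |

The numbered scripts under `analysis/` run the study as a narrative:
`01_simulate_study.py` → `02_fit_maps.py` → `03_full_analysis.py` →
`04_worked_examples.py`, writing report tables to `results/` and imaging
intermediates to `scratch/`.

## Worked example

```sh
python analysis/01_simulate_study.py --seed 1
python analysis/03_full_analysis.py
```

prints (abridged):

```
               region hemisphere  mean_free  mean_migraine  delta_pct_report  p_value
              Caudate       left     20.532         21.472               4.6  0.009524
              Caudate      right     20.873         19.718              -5.5  0.009524
Cerebral-white-matter       left     20.982         21.375               1.9  0.038095
...
left WM anisotropy change during migraine: -1.9%
right WM anisotropy change during migraine: -14.9%
sensitivity re-run excluded days [13, 17] (free n 19 -> 17)
```

Reading this: the generator planted a +1.0 1/s migraine-day shift in the
left caudate (recovered as +0.94 1/s, i.e. +4.6%), −1.1 1/s in the right
caudate (−5.5%), a +0.4 1/s isotropic shift in left cerebral white matter
(+1.9%) and a 17% reduction of the right-hemisphere anisotropic amplitude b
(recovered as a −14.9% drop of the per-day anisotropy index; the generative
value is −16.6%).  With 19 vs 2 days the normality gate forces the exact
Mann–Whitney test, whose smallest attainable two-sided p is
2/C(21,2) = 2/210 ≈ 0.0095 — exactly what the strongly shifted regions
show.  A ΔR2\* of +1.0 1/s corresponds to ≈ +3.70 mg iron per kg wet tissue
at the gray-matter calibration slope of 0.27 1/s per mg/kg
(`python analysis/04_worked_examples.py`).

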