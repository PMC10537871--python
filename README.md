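# petseg

Semi-automated, training-free tumour delineation on FDG-PET volumes, with
the evaluation machinery to benchmark delineation methods against ground
truth on a cohort.

Contouring lesions on [¹⁸F]FDG PET/CT is a prerequisite for staging,
radiotherapy planning and radiomics, and doing it manually is slow.
`petseg` implements six widely used semi-automated alternatives and the
statistics needed to compare them:

**Draw-and-refine methods** (the operator sketches an enclosing sphere
volume; a threshold rule filters voxels inside it):

| method | rule |
|---|---|
| `suv2.5` | keep voxels with SUV ≥ 2.5 (fixed absolute threshold) |
| `rel40` / `rel50` | keep voxels with SUV ≥ 0.4 / 0.5 × SUVmax of the sketch |
| `nestle` | background-adaptive threshold *t*<sub>N</sub> = β·*I*₇₀ + *I*<sub>bgd</sub> |

where *I*₇₀ is the mean uptake of the voxels above 70 % of the region
maximum, *I*<sub>bgd</sub> the mean uptake of a 4 mm-thick background
shell offset 12 mm outward from that 70 % core (shell voxels with
SUV > 2.5 are excluded), and β = 0.30 by default.

**Click-and-draw methods** (the operator clicks one point near the lesion
centroid): a 3-D flood fill from the seed at threshold *t*·*I*(V<sub>s</sub>)
(*t* = 0.7 for `click`, 0.4 for `click40`) produces a first-pass region Ω
(an exception is raised if |Ω| > 500 cm³); the background-adaptive
threshold is recomputed on Ω and a second flood fill from Ω's
maximum-uptake voxel yields the final ROI.

**Evaluation** uses the Sørensen–Dice coefficient
DSC = 2|Ω<sub>e</sub> ∩ Ω<sub>gt</sub>| / (|Ω<sub>e</sub>| + |Ω<sub>gt</sub>|)
and the relative volume difference
RVD = (|Ω<sub>e</sub>| − |Ω<sub>gt</sub>|) / |Ω<sub>gt</sub>| (positive =
overestimation). Cohorts are aggregated as median ± SD per method and
compared pairwise with two-sided Mann–Whitney U tests under Bonferroni
correction (6 methods → 15 pairs → corrected α = 0.05/15 ≈ 0.003).

Because clinical scans are rarely shareable, the package ships a
**synthetic phantom generator**: ellipsoidal high-uptake lesions
(SUVmax ≈ 4–20) on a low background (SUV ≈ 1.5) on a clinical PET grid
(2.73 × 2.73 × 3.27 mm), convolved with a Gaussian point-spread function
and corrupted by additive Gaussian noise, with the pre-blur lesion support
as ground truth. Every pipeline stage is testable end to end without
patient data.

## Worked example

```python
from petseg import ImageGrid, rasterize_sketch, segment_nestle, evaluate_case
from petseg.phantom import Lesion, PhantomConfig, generate_phantom

grid = ImageGrid((41, 41, 41), (2.73, 2.73, 3.27))
centre = tuple((n - 1) / 2 * s for n, s in zip(grid.shape, grid.spacing))
cfg = PhantomConfig(
    grid=grid,
    lesions=(Lesion(centre, (15.0, 15.0, 15.0), 8.0),),
    background_suv=1.5, psf_fwhm_mm=6.0, noise_sd_suv=0.2, rng_seed=7,
)
case = generate_phantom(cfg, "demo")
sketch = rasterize_sketch(case.sketch, case.volume.grid)
mask, d = segment_nestle(case.volume, sketch, beta=0.30, with_details=True)
print(f"Imax={d.imax:.2f}  I70={d.i70:.2f}  Ibgd={d.ibgd:.2f}  tN={d.tn:.2f}")
ev = evaluate_case(mask, case.gt_mask, "demo", "nestle")
print(f"DSC={ev.dsc:.3f}  RVD={ev.rvd_percent:+.1f}%")
```

prints

```
Imax=8.44  I70=7.32  Ibgd=1.50  tN=3.70
DSC=0.950  RVD=+10.5%
```

The lesion was painted at SUV 8 on background 1.5; after 6 mm blur the
observed maximum is 8.44 (noise), the 70 %-core mean is 7.32, the
background shell correctly recovers 1.50, and the resulting threshold
0.30 × 7.32 + 1.50 = 3.70 delineates the sphere with Dice 0.95 and a
+10.5 % volume overshoot (spillover pulls the 3.7-SUV isocontour slightly
outside the true 21 mm-radius boundary).

The same pipeline runs from the shell:

```bash
petseg simulate  --n 10 --seed 0 --out cohort/
petseg segment   --method nestle --image cohort/case-000_suv.nii.gz \
                 --sketch sketch.yaml --out pred.nii.gz
petseg evaluate  --pred pred.nii.gz --truth cohort/case-000_gt.nii.gz --out eval.csv
petseg benchmark --n 30 --seed 0 --out bench/
petseg compare   --results bench/per_case.csv --metric dsc --out pairwise.csv
```

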