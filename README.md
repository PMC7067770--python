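# myotomo

3D quantification of nerve-injury damage in muscle from reconstructed
tomography stacks.

When a peripheral nerve (e.g. the sciatic nerve innervating the soleus) is
cut or crushed, the denervated muscle atrophies: fibres shrink, turn from
polygonal to round, and the interstitial **muscle fibre space** — fascia
shedding, edema, inflammatory infiltrate — widens. On high-resolution
tomography this space sits at the background grey level between bright
stained fibres, so its segmented volume is an objective per-specimen injury
metric, and the uninjured contralateral limb of the same animal provides the
within-subject reference.

`myotomo` implements the full analysis as a deterministic, scriptable
pipeline, for researchers quantifying muscle damage in small-animal imaging:

1. **simulate** — a ground-truthed synthetic phantom generator (Voronoi
   fibre packings with tunable atrophy, rounding and noise; section- and
   crush-type injury time courses; synthetic muscle weights), so every stage
   is testable without any raw data;
2. **preprocess** — median + non-local-means denoising;
3. **segment** — seeded region growing of the background/space class,
   inversion to fibres, island removal, closing + hole filling to the bundle
   contour `C`, subtraction `S = C ∧ ¬F`, and dark top-hat local-threshold
   refinement, with file-based manual-override masks and a full provenance
   record;
4. **quantify** — per-slice voxel sums `V = Σ_z |S_z|` (with the slice-wise
   standard deviation as an injury-distribution summary), area fractions
   `fiber% = 100·|F|/|C|`, `space% = 100 − fiber%`, day-1 baseline deltas and
   contralateral (injury − non-injury) differences;
5. **stats** — two-sided independent-sample t-tests (pooled or Welch) with
   significance tiers `‡ p<0.01, † p<0.05, * p<0.1`.

See `docs/methods.md` for the model, parameters and design choices.

## Worked example

```python
from myotomo.phantom import PhantomSpec, generate_phantom
from myotomo.preprocess import denoise
from myotomo.segment import segment_pipeline

spec = PhantomSpec(atrophy=0.5, noise_sigma=10, seed=42)   # 64x128x128 voxels
phantom = generate_phantom(spec)
result = segment_pipeline(denoise(phantom.intensity))

est = 100 * result.space.sum() / result.contour.sum()
print(f"estimated space fraction: {est:.1f}%")
print(f"true space fraction:      {100 * phantom.truth_space_fraction:.1f}%")
print(f"space volume: {result.space.sum()} voxels")
```

prints

```
estimated space fraction: 35.7%
true space fraction:      36.7%
space volume: 201630 voxels
```

i.e. on a half-atrophied phantom the pipeline recovers the interstitial
space fraction within about one percentage point of ground truth, and the
space volume is the voxel sum that tracks injury severity over time.

The same workflow from the shell, as a whole synthetic study:

```sh
myotomo pipeline --config examples/demo.yaml --out demo_out --seed 1
```

writes the stacks, masks, `report.csv` and `tests.csv`; the t-tests compare
the injured vs the uninjured side per model and day:

```
metric,group,day,n1,n2,t,df,p,flag
space_volume_vox,CRUSH,1,3,3,9.37447,4,0.0007213,‡
space_volume_vox,CRUSH,14,3,3,20.4549,4,3.37346e-05,‡
space_volume_vox,SECTION,1,3,3,7.8129,4,0.00144843,‡
space_volume_vox,SECTION,14,3,3,4.9936,4,0.00752444,‡
```

— the operated side carries significantly more fibre space in every cell
(`‡` = p < 0.01). Each stage is also available as its own subcommand
(`myotomo simulate|preprocess|segment|quantify|stats`, each with `--help`).

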