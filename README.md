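# octmac — retinal optical-intensity analysis of 3D macular OCT

OCT devices report layer *thickness*, but the backscatter *intensity* of each
retinal layer carries independent information: RNFL reflectivity falls in
glaucoma, the ellipsoid band dims in photoreceptor disease, and any normative
use of such measurements needs to know how healthy-eye intensity is
distributed across layers and macular regions, how reproducible it is between
operators, and which subject factors (age, image quality, biometry) drive it.
`octmac` is a tested, reusable implementation of that analysis for
ophthalmic-imaging researchers: it takes a 6×6 mm macular volume on the
16-bit export scale (0–65535 AU), segments eleven intraretinal surfaces,
maps the fovea-centered ETDRS grid, and reports the mean gray value of every
(layer × sector) cell, plus the cohort statistics on top (ICC, correlation
screen, stepwise regression, age-decade trends). A synthetic phantom/cohort
generator with exact ground truth stands in for clinical raw data, so every
stage is verifiable end to end.

## The core algorithm

Each surface is a height map z(x, y) over the A-scan grid, constrained by
hard smoothness bounds |z(x,y) − z(x′,y′)| ≤ Δ for 4-neighbors, minimizing a
per-voxel edge cost c(x, y, z) summed over the surface. This is solved
*exactly* as a minimum closed set in a vertex-weighted graph: assign node
weights w(x,y,z) = c(x,y,z) − c(x,y,z−1) so the weight of the set of voxels
below a surface telescopes to the surface's cost, add intra-column arcs
(closure) and inter-column arcs clamped at Δ (smoothness), and read the
optimal surface off the source side of a minimum s–t cut (Dinic max-flow).
The cost is the signed axial derivative of a curvature-anisotropic-diffusion
denoised copy of the volume, with per-surface polarity (e.g. dark→bright at
the ILM, bright→dark at the outer RPE edge); low-contrast boundaries
(GCL/IPL above all) additionally carry an anatomical position prior with a
dead zone so the prior never overrides a clean edge. Eleven surfaces are
found sequentially, each restricted to the band between its already-found
neighbors, yielding the eight layers RNFL, GCL, IPL, INL, OPL, ONL,
photoreceptor (ELM→inner RPE) and RPE. Intensity statistics are always
computed on the **raw** voxels; denoising only serves boundary detection.

Everything downstream is classical: ETDRS sectors by Euclidean mm distance
(1/3/6 mm circles, ±45° quadrant diagonals, laterality-aware nasal/temporal),
ICC(2,1) from the two-way ANOVA mean squares, Pearson/Spearman screens, and
forward-stepwise OLS with removal reporting standardized β.

## Worked example

Segment a synthetic macular volume and measure its layer/sector intensities:

```python
import octmac

spec = octmac.PhantomSpec()                      # 128x32x256, 6x6 mm, OD
vol, truth = octmac.generate_phantom(spec, seed=1)

surfaces = octmac.segment_retina(vol)            # 11 surfaces, exact solver
center   = octmac.locate_fovea(surfaces.z[0])    # deepest ILM point
grid     = octmac.build_etdrs_masks(center, vol.laterality,
                                    surfaces.z[0].shape, (vol.dx_mm, vol.dy_mm))
table    = octmac.layer_sector_intensity(vol, surfaces, grid)
print(table[table.sector == "AllETDRS"][["layer", "mean_au", "n_voxels"]])
```

```
   layer       mean_au  n_voxels
9   RNFL  30568.963354     37166
20   GCL  26433.820540     34041
31   IPL  26936.719992     30817
42   INL  23378.447171     28157
53   OPL  25021.417552     21741
64   ONL  21443.419502     62219
75    PR  31630.930225     52268
86   RPE  34116.020781     24253
```

The recovered profile shows the canonical brightness ordering
RPE > PR > RNFL > IPL > GCL > OPL > INL > ONL of healthy macular tissue on
the 16-bit AU scale. Against the generator's encoded truth, recovered
surfaces have median MAE ≤ 1 voxel per surface at default speckle (exactly 0
on a noiseless phantom), and layer means agree within ~2 %.

The numbered drivers under `analysis/` run the full study-shaped analyses
and write their tables to `results/`: `01` simulates the demo cohort, `02`
quantifies surface-recovery accuracy, `03` the two-operator reproducibility
(per-layer ICC 0.54–0.83 on re-scan phantom pairs at default jitter; the
estimator itself calibrated at true ICC 0.88 → median estimate 0.875 over
200 replicates), `04` the regional profile (nasal>temporal RNFL/GCL,
temporal>nasal ONL/PR/RPE, central depression except RPE), and `05` the
determinants on a 231-subject simulated cohort (stepwise selects age +
image quality for every layer; standardized β for age −0.53…−0.23 from RNFL
to PR and +0.32 for RPE, image-quality β +0.50…+0.87). There is also a thin
CLI (`octmac simulate|denoise|segment|intensity|stats|run`) over the same
functions.

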