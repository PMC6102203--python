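# microtem

Image-assisted analysis of cancer-cell transendothelial migration (TEM) in
microvessel-on-a-chip time-lapse recordings.

Microfluidic vessels let single breast-cancer cells be watched for hours as
they arrest on an endothelial wall and occasionally cross it into the
surrounding collagen matrix.  The raw data are two-channel confocal z-stack
time-lapses — brightfield plus GFP, a ~100 µm channel height at 1.5 µm
z-steps, one stack every 20 min over 15 h — and turning them into per-cell
statistics requires solving several image-analysis problems in sequence.
`microtem` implements that pipeline for experimentalists running such
assays, together with a synthetic-microscopy generator that makes every
stage testable against known ground truth.

## What the pipeline computes

1. **Focus stacking.**  Each pixel's vertical GFP intensity profile peaks at
   the z-level of the cell occupying it.  Selecting the brightfield pixel
   from that level builds an all-in-focus composite with sharp dark cell
   edges (parameters: lateral smoothing radius *R*, level correction ΔZ, 3D
   Gaussian scale Σ).
2. **Drift correction.**  Per-frame stage shifts are estimated by normalized
   cross-correlation of pillar-corner fiducials against frame 0.
3. **Segmentation.**  GFP projections are thresholded (Otsu), one marker is
   seeded per dark nucleus, and a watershed on the brightfield-composite
   gradient draws cell outlines; the per-cell z-coordinate is the slice
   maximizing the masked GFP sum.
4. **Tracking and regions.**  Nucleus centroids are linked greedily within a
   gate (default 30 µm/frame); each position is assigned to the *channel*
   (lumen), *barrier* (40 µm interface band) or *gel* region, with x = 0 at
   the barrier's gel face.
5. **Behaviour and statistics.**  Each trajectory is classified Type I
   (crossed into the gel), Type II (arrested at the barrier) or Type III
   (stayed in / returned to the lumen).  Time-averaged counts
   `N_av = (Σ_t n_t)/T` give the transmigration ratios
   `N_av-ext/N_av-tot` and `N_av-ext/N_av-barrier`; velocities are pooled
   across samples with the inverse-variance weighted mean

   ```
   mean = Σ_i w_i v̄_i / Σ_i w_i,   error = 1/√(Σ_i w_i),   w_i = n_i/σ_i²
   ```

   Occupancy maps (x–z scatter by eventual region) and crossing *hot spots*
   (KDE peaks tested against a uniform Monte-Carlo null on the accessible
   barrier plane) complete the per-sample bundle.
6. **Permeability.**  From a dye-perfusion intensity series,
   `P = (dI/dt)/(I₁ − I_b) · d/4` over the early-time window in which the
   gel still behaves as a perfect sink (default first 15 min).

## Worked example

```python
import microtem as mt

# a synthetic sample with complete ground truth (10-50 cells, 45 frames)
cfg = mt.SimulationConfig(n_cells=22, n_frames=45, seed=101,
                          p_cross_per_frame=0.06)
src = mt.SyntheticSource(cfg)                    # renders frames on demand
pc = mt.PipelineConfig(layout=mt.generate_layout(cfg), seed=101)
result = mt.run_pipeline(src, pc, out_dir="bundle")

s = result["sample_stats"]
print(f"N_av_tot={s.N_av_tot:.2f}  N_av_barrier={s.N_av_barrier:.2f}  "
      f"N_av_ext={s.N_av_ext:.2f}")
print(f"r_barrier={result['ratios'].r_barrier:.3f}")
```

prints (seed 101):

```
N_av_tot=18.20  N_av_barrier=3.80  N_av_ext=2.60
r_barrier=0.684
```

i.e. on average ~18 cells were present in the lumen+barrier per frame, ~4 of
them at the barrier, and the time-averaged cumulative crossings divided by
the barrier population gives the per-15 h transmigration propensity.  The
generator's ground truth for the same sample is `N_av_ext=2.60`,
`N_av_barrier=4.09` (`r_barrier=0.636`), so the full image→stats chain
recovers the crossing count exactly and the ratio to within ~8%.

The same stages are available from the shell:

```bash
microtem simulate --seed 3 --out sim/
microtem run sim/stack.ome.tif --config layout.yaml --out bundle/
microtem permeability series.csv --background 100 --diameter-um 100
```

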