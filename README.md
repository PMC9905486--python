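# vncorr

Spatial 3D correlation analysis of the segmentally periodic axonal
architecture of the *Drosophila* embryonic ventral nerve cord (VNC).

## The problem

The VNC's Fasciclin 2-positive longitudinal fascicles (medial,
intermediate, lateral, mirrored about the midline) compact once per
segment into a stereotyped transverse configuration — a **3D node** — and
disperse in between.  This package quantifies that architecture from
calibrated confocal stacks for developmental biologists studying VNC
patterning and condensation:

- **Self/cross correlation matrices** `M ∈ [0,1]^{n×n}`: `M_ij` is the
  Pearson correlation of transverse sections *i* and *j* after rigid
  registration (centre-of-mass prealignment, then Mattes
  mutual-information refinement with tolerance 1e-6 and ≤ 500 iterations),
  computed over AP bins of 1.65 μm, each a maximum-intensity projection of
  ~11 planes.
- **Node-anchored traces and architecture metrics**: nodes are detected as
  peaks of the mean off-diagonal row correlation; each node's trace is the
  mean correlation along its row ± 1 row (diagonal excluded); traces are
  aligned in the 25–57 μm window and averaged; the metrics are the
  internodal distance and the node → correlation-minimum posterior offset.
- **AP asymmetry statistic** with in-silico resampling (500 replicates of
  each trace position drawn from Normal(mean, SD), per-limb linear fits):

      r = (max(∇c) − |min(∇c)|) / ((max(∇c) + |min(∇c)|)/2),   |r| ≤ 2

  where ∇c is the spatial derivative of the correlation trace along AP,
  tested against 0 by a sign-flip randomized Mann–Whitney statistic.
- **Fluorescence quantification**: fixed-size ROI Average Integrated
  Density (Fiji IntDen convention) at nodes/internodes, whole-segment
  densities, and thresholded 3D binary-mask (inside/outside) readouts.
- **A synthetic phantom generator** emulating the fascicular architecture
  (periodic nodes, asymmetric internodal dispersion, node-enriched
  intensity, PSF blur, shot/read noise) with exact ground truth, so every
  stage is verifiable without raw microscopy data.

See `docs/methods.md` for the model, parameter choices and limitations.

## Worked example

```python
import numpy as np
import vncorr as v

params = v.preset("wildtype", n_segments=6, seed=1)   # 28 μm period planted
stack, truth = v.generate_phantom(params)             # calibrated 3D volume
result = v.architecture_pipeline(stack, bin_length=1.65)

print("nodes detected:", len(result.node_bins))
print("mean internodal distance (μm):",
      round(result.metrics.mean_internodal_distance, 2))
print("node -> minimum offset (μm):",
      round(float(np.mean(result.metrics.node_to_min_offsets)), 2))
```

prints (about one minute on one CPU):

```
nodes detected: 6
mean internodal distance (μm): 27.92
node -> minimum offset (μm): 9.62
```

Six nodes — one per segment — at a spacing of 27.9 μm against the planted
28 μm, with the internodal correlation minimum 9.6 μm posterior to the
node against the planted 9 μm; both within one AP bin (1.8 μm at this
pitch).  The same entry points exist on the command line
(`vncorr generate / correlate / nodes / asymmetry / density`).

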