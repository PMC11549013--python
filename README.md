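# delicate

Segmentation-driven enhancement of time-lapse 3D fluorescence movies of
labelled nuclei, for more accurate automated cell lineage tracing.

## The problem

Automated lineage tracing of developing embryos (the canonical case being
*C. elegans*, traced from the zygote to the ~550-cell stage) detects
fluorescently labelled nuclei in every 3D frame and links them over time.
Late-stage frames defeat the tracers: nuclei are small, densely packed and
fast-moving; photobleaching and depth-dependent light scattering dim the
signal; and some sublineages (D, E, and the germline progenitors, with
common histone-fusion markers) express the marker at a fraction of the
level of their neighbours. The result is an avalanche of segmentation and
tracking errors — spurious divisions, missed divisions, false deaths —
that must be corrected by hand.

`delicate` attacks the images rather than the tracer. Each time point is
reconstructed into an isotropic volume, nuclei are segmented as
**star-convex polyhedra** (a centre plus radial distances to the boundary
along 64 fixed rays), and the rasterized "pseudo-nuclei" are merged back
into the raw planes at uniform high intensity with the exact operator

```
Φ(I_raw, I_pseudo)(v) = I_raw(v)    if I_pseudo(v) = 0
                        max(I_raw)  otherwise
```

Every voxel outside a pseudo-nucleus keeps its raw value bit-for-bit, so
real signal survives wherever segmentation fails; every detected nucleus —
dim, deep or bleached — is raised to the brightest level of its time
point. The enhanced stacks keep the input geometry, dtype and naming, so
they drop straight into an existing tracing workflow.

Two interchangeable segmentation backends are provided: a light 3D U-Net
with residual blocks predicting objectness + 64 ray distances (implemented
on numpy, trainable on a CPU), and a deterministic classical detector
(multi-level distance-transform seeds, watershed, half-max refinement)
that needs no training. The package also contains a full evaluation layer
— MSE and SNR against rendered ground truth, detection
precision/recall/accuracy with no true negatives, a tracker, and a
five-class lineage-error taxonomy — plus a synthetic embryo generator that
reproduces the failure modes above with exact ground truth.

## Worked example

```python
import delicate as d
from delicate.segment import ClassicalDetector
from delicate.evaluation import SliceLinkTracer

# a synthetic embryo movie: 10 time points growing from 8 to 33 cells,
# with a dim sublineage, bleaching, depth attenuation, noise and debris
cfg = d.SimConfig(seed=0)
lineage, gt_volumes, raw_volumes = d.simulate(cfg)

# enhance the last (hardest) time point
t = 9
stack = d.ImageStack(time=t + 1,
                     planes=[raw_volumes[t].data[k]
                             for k in range(raw_volumes[t].shape[0])],
                     xy_spacing=0.36, z_spacing=0.72)
enhanced, result = d.enhance_timepoint(stack, ClassicalDetector().fit(),
                                       target_spacing=0.36)
print(result.n_instances, "pseudo-nuclei, fill =", result.fill_intensity)

# compare what a fixed slice-based detector sees before and after
tracer = SliceLinkTracer()
for name, stk in [("raw", stack), ("enhanced", enhanced)]:
    centers = tracer.detect_centers(stk)
    tp, fp, fn, _ = d.match_detections(centers, lineage.positions(t),
                                       gt_radii=lineage.radii(t))
    p, r, a = d.prf(tp, fp, fn)
    print(f"{name:9s} precision={p:.2f} recall={r:.2f} accuracy={a:.2f}")
```

prints (seed 0):

```
26 pseudo-nuclei, fill = 18126.0
raw       precision=0.86 recall=0.36 accuracy=0.34
enhanced  precision=0.88 recall=0.70 accuracy=0.64
```

At this late time point a third of the nuclei are too dim or too deep for
the fixed-threshold detector on the raw frame; on the enhanced frame they
are as bright as everything else and recall jumps accordingly, without any
loss of precision.

The same flow is available from a shell:

```bash
delicate simulate --out movie/ --name embryo --seed 0
delicate enhance  --input movie/ --output enhanced/ --name embryo \
                  --backend classical --target-spacing 0.36
delicate evaluate --input movie/ --output enhanced/ --name embryo \
                  --target-spacing 0.36 --gt movie/embryo_lineage.csv
delicate train    --data movie/ --name embryo --checkpoint model.npz  # DNN backend
```

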