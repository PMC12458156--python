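# fewpick

Few-shot particle picking for cryo-EM micrographs, built as a complete,
desk-scale implementation of the adapter-based segmentation approach:
a frozen hierarchical image encoder adapted with lightweight residual
bottleneck modules, a few-shot segmentation training loop, watershed-based
extraction of particle coordinates from masks, matching-based detection
metrics, and a paired nonparametric harness for comparing pickers.

## Who this is for

Cryo-EM practitioners and methods developers who want to study or extend
annotation-efficient particle picking: cryo-EM micrographs have extremely
low signal-to-noise ratios, and supervised pickers normally need large
annotated datasets. The few-shot strategy instead freezes a pretrained
hierarchical vision encoder and trains only tiny adapter modules and a
mask decoder from as few as 1–10 annotated micrographs.

## The model

The encoder has four sequential stages (embedding widths 144, 288, 576,
1152 with 2, 6, 36 and 4 blocks in the large preset; 1024 px input).
Before every block, a residual adapter modulates the features:

    feat_adapter = W_up · σ(W_down · feat),      σ = GELU
    feat_final   = feat + feat_adapter
    feat_next    = BLK(feat_final)

`W_down` is a per-block bottleneck down-projection; `W_up` is shared
across the blocks of a stage. Because the up-projection starts at zero,
training begins exactly at the pretrained encoder's function, and only
the adapters and the decoder receive gradients — the backbone is frozen
bitwise. Training minimizes class-balanced binary cross-entropy with
logits (foreground weighted by the background/foreground pixel ratio)
with Adam.

Predicted masks become coordinates through a structured pipeline:
thresholding, Euclidean distance transform, multi-scale peak detection,
marker-controlled watershed to split touching particles, geometric
filtering by area and circularity (4πA/P²), and a second, more permissive
pass that recovers closely packed particles, with final center
deduplication. Coordinates are written as RELION-dialect STAR files.

Evaluation matches predictions to ground truth one-to-one within half a
particle diameter and reports precision TP/(TP+FP), recall TP/(TP+FN),
their harmonic mean F1, and the pixel IoU of the rasterized particle
disks. Method comparison uses per-micrograph paired Wilcoxon signed-rank
tests (exact for N ≤ 15 without ties, otherwise a tie-corrected normal
approximation with continuity correction), rank-biserial-style effect
sizes reported both as z/N and z/√N, and Benjamini–Hochberg FDR
adjustment across each metric's family of tests.

The package runs everything on a miniature strided-convolution backbone
that reproduces the stage layout and freezing semantics at CPU scale; a
real pretrained encoder can be plugged in through the backbone contract.
A synthetic micrograph simulator with exact ground truth (configurable
diameter, SNR, overlap fraction, contrast jitter, and ice-like
contaminant blobs) makes the whole stack testable without external data.

## Worked example

Train a 5-shot model on synthetic high-SNR micrographs and evaluate on
held-out ones:

```python
import dataclasses
import fewpick as fp

sim = fp.SimParams(image_size=64, n_particles=6, particle_diameter=12,
                   snr=8.0, overlap_fraction=0.0, n_ice_blobs=0, seed=11)
shots = fp.make_fewshot_dataset(5, sim)
held = fp.make_fewshot_dataset(5, dataclasses.replace(sim, seed=1011))

model = fp.build_toy_model(input_size=64, seed=0)
trace = fp.train_few_shot([(m, g.mask) for m, g in shots], model,
                          fp.TrainConfig(input_size=64, seed=0))
print(f"loss: {trace[0]:.3f} -> {trace[-1]:.3f}")

pp = fp.PostprocParams(diameter=12)
rows = [fp.evaluate_picks(
            fp.extract_particles(fp.predict_mask(mic, model), pp),
            gt.particles, 64, 12)
        for mic, gt in held]
print(fp.aggregate_report(rows).round(3))
```

Output:

```
loss: 30.929 -> 0.255
precision    1.000
recall       1.000
f1           1.000
iou          0.865
```

The loss falls from its balanced-BCE starting point to near convergence;
on the held-out micrographs every particle is found within half a
diameter of its true center (precision = recall = 1), and the rasterized
predicted disks overlap the ground-truth disks with IoU 0.865.

The same pipeline is available from the shell:

```sh
fewpick simulate --out-dir sims --size 64 --n-particles 6 --diameter 12 \
    --snr 8 --overlap 0 --n-ice 0 --seed 11 --count 2
fewpick train --checkpoint-out toy.npz --shots 5 --size 64 --diameter 12 --snr 8
fewpick pick --checkpoint toy.npz --in sims/sim_000.mrc --diameter 12 \
    --out-star picks.star --size 64
fewpick evaluate --pred-star picks.star --gt-star sims/sim_000_gt.star \
    --diameter 12 --image-size 64
```

## Layout

- `fewpick.simulate` — synthetic micrographs with exact ground truth
- `fewpick.encoder` — stage specs, adapters, backbone contract, toy backbone
- `fewpick.model` / `fewpick.train` — assembled model, loss, Adam loop
- `fewpick.postprocess` — mask → coordinates pipeline
- `fewpick.io` — MRC/PNG/TIFF micrographs, STAR coordinates, frames
- `fewpick.evaluation` — matching, precision/recall/F1/IoU, aggregation
- `fewpick.stats` — Wilcoxon, effect sizes, FDR, success rates
- `docs/methods.md` — modeling choices, parameters, and limitations
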