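# gutseg

Segmentation toolkit for the gastrointestinal organs at risk in abdominal
MRI — **large bowel, small bowel, stomach** — the structures a radiation
oncologist must avoid when steering dose onto a GI tumour during MR-guided
radiotherapy. Delineating them by hand on every daily scan takes tens of
minutes; this package implements the full automatic pipeline: run-length
(RLE) mask I/O in the UW-Madison GI-tract CSV dialect, four-stage slice
preprocessing, a from-scratch U-Net with exact per-layer parameter
accounting, dice/IoU training and evaluation, and a synthetic abdominal
phantom generator so the whole chain runs and is verified without the
clinical data or a GPU.

## The model

A four-level U-Net for 160×160×1 slices. Encoder blocks are
(conv 3×3, conv 3×3, maxpool 2×2) with filters 64→128→256→512; the center
block holds two 1024-filter convs at the 10×10 bottleneck; decoder blocks
are (2×2 stride-2 transposed conv, skip concatenation, two 3×3 convs) with
filters 512→256→128→64; a 1×1 sigmoid conv emits the three class
probability maps. Parameters follow the biased-conv count
(k²·c_in + 1)·c_out — e.g. the first conv is (9·1+1)·64 = 640 and the
second center conv (9·1024+1)·1024 = 9,438,208. Training minimizes
BCE + (1 − soft dice) with Adam at lr 1e-4, batch 32, 20 epochs; scores are

    dice = (2|A∩B| + ε) / (|A|+|B| + ε),   IoU = (|A∩B| + ε) / (|A∪B| + ε)

averaged per class channel then per batch, predictions thresholded at 0.5.

The network itself is a self-contained numpy implementation (im2col
convolutions, manual backprop, Adam) — no deep-learning framework needed.

## Worked example

Generate phantoms, train a width-scaled U-Net for five epochs, and segment
a held-out slice:

```python
from gutseg import (PhantomConfig, generate_slices, train_val_split,
                    prepare_arrays, TrainConfig, ModelSpec, build_model,
                    train, predict_slice, dice)

cfg = PhantomConfig(n_cases=3, min_days=1, max_days=1, slices_per_scan=32,
                    image_size=64, seed=21)
slices = generate_slices(cfg)
train_cases, val_cases = train_val_split(slices, 1/3, seed=21)
x, y = prepare_arrays(slices, (64, 64))          # resize → blur → /255
tr = [i for i, s in enumerate(slices) if s.case in train_cases]
va = [i for i, s in enumerate(slices) if s.case in val_cases]

model = build_model(ModelSpec.scaled(base_filters=8, input_size=(64, 64)), seed=0)
report = train(model, (x[tr], y[tr]), (x[va], y[va]),
               TrainConfig(batch_size=4, epochs=5, learning_rate=1e-4,
                           seed=0, augment=False))
print(report[report.split == "val"].round(4).to_string(index=False))
```

```
 epoch split   loss   dice    iou
     1   val 1.1252 0.1875 0.1875
     2   val 1.1169 0.1875 0.1875
     3   val 1.0645 0.2734 0.2345
     4   val 0.9978 0.3278 0.2370
     5   val 0.9286 0.4027 0.3058
```

Epochs 1–2 sit at the all-background baseline (empty channels score 1 by
the ε convention, organ channels 0); from epoch 3 the organs start to be
recovered and both overlap scores climb. Segmenting a validation slice
returns the binary mask stack plus one RLE record per class:

```python
mask, records = predict_slice(model, x[va[16], :, :, 0], slices[va[16]].slice_id)
print(records[2].class_name, "->", records[2].rle[:40], "...")
print("dice vs truth:", round(dice(mask, y[va[16]]), 4))
```

```
stomach -> 1046 1 1050 1 1107 1 1109 5 1115 2 1171  ...
dice vs truth: 0.4445
```

A longer run — 200 training slices, base-24 filters, 10 epochs
(`gutseg.train.learning_smoke_run`) — reaches validation dice ≈ 0.84 in
about three minutes per seed on one core.

## Command line

```bash
gutseg simulate --seed 7 --out data/            # phantom dataset + train.csv
gutseg audit-params --out report.csv            # per-layer parameter audit
gutseg train --config pipeline.yaml --data data/ --out run/
gutseg evaluate --config pipeline.yaml --data data/
gutseg predict --config pipeline.yaml --image slice.png --out pred/
gutseg visualize --image slice.png --records data/train.csv \
       --slice-id case1_day1_slice_0002 --out overlay.png
```

Overlays use the standard colour convention: red stomach, green large
bowel, yellow small bowel. Every run writes its resolved config next to its
outputs; configuration errors exit 2, runtime failures 1.

`audit-params` prints each constructed layer's count, the implemented total
(31,030,723), the published per-layer summary's total (34,512,323), and a
row-level diff — the published decoder rows are internally inconsistent
with their own declared channel flow, and the audit flags exactly which
ones (see `docs/methods.md`).

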