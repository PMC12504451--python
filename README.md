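# slecg — single-lead ECG atrial-fibrillation screening

`slecg` is an end-to-end pipeline for classifying atrial fibrillation
(AFib) versus normal sinus rhythm on single-lead ECG recordings of the
kind produced by handheld and wearable devices (lead-I morphology,
~30 s at 300 Hz), using a compact 2-D convolutional network that can be
trained on clinical 12-lead data (10 s at 100/500 Hz).  The hard part of
that transfer is that the two worlds disagree on sampling rate,
amplitude scale, electrode polarity and record length; the pipeline
reconciles all four before the classifier ever sees a sample.

It is aimed at researchers prototyping cross-device ECG classification:
every stage is an importable, individually tested function, and a
synthetic ECG generator with analytic ground truth makes the whole
pipeline testable without downloading any clinical dataset.

## Pipeline

For a record `x` with sampling rate `fs`:

1. **Resample** to the common rate (default 100 Hz) by the Fourier
   method.
2. **Denoise** by a level-1 discrete wavelet transform (`bior3.1`,
   periodic boundary).  The noise scale is estimated from the finest
   detail band as `sigma = MAD/0.6745` and every detail coefficient is
   thresholded (hard, by default) at Donoho's universal threshold
   `T = sigma * sqrt(2 ln n)`.  At 100 Hz the approximation band covers
   0–25 Hz (the P-QRS-T energy) and the detail band 25–50 Hz.
3. **Normalize** amplitude to `[-1, 1]` by dividing by `max|x|`, and
   **correct polarity**: a zero-phase Butterworth high-pass isolates
   deflections, and the signal is inverted iff the sample of largest
   absolute amplitude is negative.
4. **Segment** into non-overlapping 10 s windows (optionally anchored at
   the first detected R peak; detection is Pan–Tompkins style).
5. **Rasterize** each segment into a deterministic 96×96 binary image
   (min–max envelope per column, +1 mV at the top row).
6. **Score** each image with a 4-conv-layer CNN
   (32/64/128/128 filters, kernels 3×3 then 3×1, max-pooling
   (2,2)×3 + (3,2), dense-96, sigmoid output; 375,520 core trainable
   parameters).  A score near 1 means normal, near 0 means AFib.
7. **Vote**: per-segment confidences (`score` for a norm call,
   `1 - score` for an AFib call) are summed per class; the larger sum
   decides the record label, so one confident segment can overrule two
   lukewarm ones.

Evaluation uses sensitivity `TP/(TP+FN)`, specificity `TN/(TN+FP)`
(AFib positive) and the trapezoidal AUROC
`sum_i (TPR_i + TPR_{i+1})(FPR_{i+1} - FPR_i)/2`.

## Worked example

Simulate a small cross-device study, train on clinical-profile records,
and classify smart-device records:

```sh
slecg simulate --n-per-class 100 --profile clinical_100 --seed 1 --outdir data/train
slecg train --data-dir data/train --epochs 30 --seed 1 --out model.npz
slecg simulate --n-per-class 2 --profile smart_300 --seed 9 --outdir data/test
slecg predict data/test/smart_300_*.csv --model model.npz --fs 300
```

which prints the training summary and, per record, the voted label and
the mean sigmoid score across its three 10-second segments:

```
trained 200 images, final val accuracy 0.825; saved model.npz
smart_300_afib_2063827471: afib (mean score 0.351)
smart_300_afib_615935265: afib (mean score 0.259)
smart_300_norm_1868845934: norm (mean score 0.771)
smart_300_norm_905266064: norm (mean score 0.940)
```

A mean score of 0.259 places the record well on the AFib side of the
0.5 decision boundary, 0.940 well on the normal side; the voted label
aggregates the three segment calls by summed confidence.  The same steps are available as
library functions (`slecg.synthetic.make_dataset`,
`slecg.model2d.train`, `slecg.app.classify_record`), and
`slecg.app.run_crossdevice_experiment()` runs the full
clinical-to-smart-device transfer (train 200/class at 10 s/100 Hz, test
50/class at 30 s/300 Hz) in one call, reporting accuracy, AUROC,
sensitivity and specificity.

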