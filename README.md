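# pyloruskit

Automatic localization of the stomach/small-intestine boundary (the pylorus)
in wireless capsule-endoscopy (WCE) frame sequences.

A swallowed capsule camera records the digestive tract as a sequence of tens
of thousands of frames; clinicians reviewing it, and lesion-detection
software running on it, both need to know where one organ ends and the next
begins. This package finds the pyloric boundary from the colour and texture
statistics of the frames themselves, touching as little of the video as
possible.

## Method

The pipeline has three stages:

1. **Valid-region extraction (CSD/VROF).** Each frame is converted to CIE
   Lab and a colour-saliency map is computed from the blurred chroma
   channels,

   `S(x, y) = (a(x, y) − a_u)^α + |b(x, y) − b_u|^β`

   with image means `a_u, b_u` and defaults `α = 3`, `β = 1.5`. Digestive
   tissue is redder (higher `a`) than bubbles, shadows, specular highlights
   or fluid, so the valid region of the frame (VROF) is the positive set
   `{S > 0}`; disturbances score strongly negative and drop out of every
   downstream colour statistic.

2. **Monitor.** The sequence is cut into windows of `m = 100` frames; every
   5th frame contributes its VROF-masked mean chroma `(M_a, M_b)`. The
   window-pair dissimilarity `DC_k = ‖(M_a, M_b)_k − (M_a, M_b)_{k+1}‖₂` is
   compared with the running mean MDC of previous pairs; the pair is
   suspicious when `DC_k / MDC > 0.2 + 0.3·t`, where the escalation counter
   `t` counts rejected inspections. Processing stops at the first accepted
   verdict, so frames past the boundary are never decoded.

3. **Judge.** Sampled frames of the suspicious pair plus its preceding
   window are classified stomach/intestine by an RBF-kernel SVM over the
   36-dimensional CTVP descriptor — GLCM contrast/correlation/energy/
   homogeneity of the phase-congruency maximum-moment map (texture) fused
   with 16-bin VROF-masked hue and saturation histograms in HSI space
   (colour). The label sequence is reduced to a boundary by the
   minimum-misclassification step split; a clean split is accepted as the
   pylorus estimate, a noisy or single-class one rejected (escalating the
   Monitor).

Clinical recordings are private, so the package ships a seeded synthetic
generator (`pyloruskit.synthetic`) that emulates the regime the method
relies on: reddish smooth stomach tissue, yellower villi-textured intestinal
tissue, an abrupt colour shift at a known boundary frame, and injected
disturbances with exact pixel footprints.

## Worked example

`examples/04_locate_boundary.py` trains the classifier on an independent
synthetic draw and runs the locator on a 2,000-frame sequence with the
boundary at frame 1234:

```
true boundary   : 1234
estimate        : 1235 (error 1 frames)
judge calls     : 7 (final escalation t=6)
frames decoded  : 260 of 2000 (stopped at index 1295)
```

The estimate lands within one frame of the truth (the sampling stride bounds
the resolution at 5 frames); the early ratio-1 triggers on the stationary
stomach stream are rejected and escalate the threshold, and only 13% of the
sequence is ever decoded. The other examples demonstrate the generator, the
valid-region mask, the descriptor and the evaluation metrics; each prints
the numbers it computes with a note on what they mean.

A thin CLI mirrors the library: `pyloruskit simulate | vrof | features |
train | locate | eval` (see `pyloruskit --help`).

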