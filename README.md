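# tumorcontrast

Tumor-to-tissue contrast analysis for T1, T2 and dual-action (T1/T2) MRI
contrast agents.

MRI contrast agents shorten the T1 and/or T2 relaxation times of the
tissue they accumulate in, making a tumor hyperintense on T1-weighted
(T1w) images and/or hypointense on T2-weighted (T2w) images.  For a
dual-action agent these two effects can be *combined in post-processing*:
subtracting the T2w image from the T1w image makes the tumor term grow
while the surrounding-tissue term shrinks, amplifying the visible
contrast well beyond either weighting alone.  This package implements
that analysis end to end:

* a **digital phantom** — two nested homogeneous ellipses (tumor inside
  normal adjacent tissue) rendered as co-registered T1w/T2w signal maps,
  with multiplicative agent-effect models and optional Gaussian or Rician
  magnitude noise;
* **image arithmetic** — pixelwise T1w − T2w and T1w + T2w in an analog
  (or lossless 16-bit) working representation, with 8-bit conversion kept
  strictly as a display export;
* **ROI statistics** — the tumor contrast

  ```
  TC = S_tu / S_ti
  ```

  where `S_tu` and `S_ti` are the mean signals over the tumor and
  adjacent-tissue ROI masks, reported per image variant (T1w, T2w,
  difference, sum) before and after injection;
* an optional **spin-echo physics layer**
  (`S = PD·(1 − e^(−TR/T1))·e^(−TE/T2)`, `1/T1' = 1/T1 + r1·C`) to derive
  plausible effect fractions from relaxivities and sequence settings;
* a **CLI** (`tumorcontrast simulate | combine | contrast | reproduce`)
  for file-based workflows on grayscale TIFF/PNG images and 0/255 masks.

It is aimed at researchers evaluating dual-mode contrast agents (e.g.
NaDyF4/NaGdF4 core/shell nanoparticles) who want a reproducible,
quantitative account of how much image subtraction buys them.

## Worked example

```python
import tumorcontrast as tc

dual = [e for e in tc.builtin_effects() if e.name == "dual"][0]
print(tc.phantom_report(dual))
```

prints

```
phase    variant   s_tu   s_ti   tc
  pre        t1w 100.00 100.00 1.00
  pre        t2w  70.00  70.00 1.00
  pre difference  30.00  30.00 1.00
  pre        sum 170.00 170.00 1.00
 post        t1w 150.00 100.00 1.50
 post        t2w  35.00  70.00 0.50
 post difference 115.00  30.00 3.83
 post        sum 185.00 170.00 1.09
```

Pre-injection, tumor and tissue share the same baselines (100 au on T1w,
70 au on T2w), so every variant has TC = 1.00.  A perfectly targeted
dual-action agent raises tumor T1w signal by 50% and halves tumor T2w
signal, giving TC = 1.50 (T1w) and 0.50 (T2w).  On the subtracted image
the tumor signal is 150 − 35 = 115 au against a tissue signal of only
100 − 70 = 30 au, so TC jumps to 3.83 — more than twice the best
single-weighting contrast — while addition (185/170 = 1.09) washes the
effect out.

The same arithmetic applied to published in vivo ROI means from a mouse
triple-negative breast tumor (non-targeted dual agent) is available as
`tc.invivo_worked_example()`, and from the shell:

```sh
tumorcontrast reproduce --out runs/
```

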