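# polyqhcs

Quantitative analysis pipeline for a human neural-stem-cell screening model
of polyglutamine (polyQ) aggregation and mitochondrial dysfunction:

* **`synthio`** — synthetic data generator with exhaustive ground truth:
  two/three-channel 16-bit microscopy fields (nuclei, intra-/extra-nuclear
  puncta, diffuse cytoplasm, optional neuronal marker), allelic-series
  plates whose planted inclusion burden rises with a per-line severity and
  day of differentiation, four-phase Mito Stress OCR traces, and
  linear / pseudo-first-order absorbance kinetics.
* **`nucseg`** — nuclear segmentation: 3-px disc median filter, global
  threshold (frozen DN or batch Otsu on the pooled histogram, exhaustive
  search with ties to the lowest cut), hole filling, distance-transform
  watershed to split touching nuclei, minimum-area filtering, per-nucleus
  geometry and channel-2 intensity maxima.
* **`incquant`** — inclusion-body metrics: prominence-based spot calling
  (a local maximum is accepted iff its height above the highest saddle to
  any higher region strictly exceeds the noise tolerance; 8-connectivity;
  plateaus give one topmost-leftmost call), aggregate-containing-nucleus
  (ACN) classification, nuclear/extra-nuclear/total aggregate counts,
  aggregate area fraction, diffuse background, perinuclear ring intensity
  and marker-positive fraction, and per-well pooling of the nine
  well-level statistics.
* **`respirometry`** — cell-density normalization of OCR traces and the
  six Mito Stress parameters (non-mitochondrial, basal, maximal, proton
  leak, ATP production, coupling efficiency) from phase-scoped extrema,
  plus control-relative percentages.
* **`enzymology`** — Beer–Lambert specific activities from absorbance
  slopes, inhibitor-sensitive rate differences, pseudo-first-order rate
  constants with non-enzymatic background subtraction, and citrate-synthase
  normalization (including CoQ10:CS ratios).
* **`mitomorph`** — volume-weighted small/medium/large mitochondrial
  volume fractions (medium bin closed: [100, 1000] µm³) and
  percent-of-control summaries.
* **`report`** — YAML-configurable pipeline driver, ANOVA + Bonferroni
  group comparisons, and the CLI.

## CLI

```sh
polyqhcs all --config study.yaml          # synthetic plate -> all tables
polyqhcs simulate --out demo              # write TIFF fields + ground truth
polyqhcs quantify --config study.yaml     # imaging branch only
polyqhcs respire ocr.csv --control 30CAG  # OCR -> respiratory parameters
polyqhcs mito volumes.csv                 # volume fraction classification
polyqhcs stats per_well.csv --value pct_acn --group line
```

Every analysis constant (nuclear threshold 144 or batch Otsu, ACN
threshold 2000, aggregate-area threshold 969, maxima tolerances 150/1000,
volume bounds 100/1000) is a `StudyConfig` field; there are no magic
numbers in the code paths. Exit codes: 0 ok, 1 input error, 2 internal
error.

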