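# cdktrace

Quantification, statistics and fate classification for in vivo
CDK-activity sensor (DHB) data.

A CDK biosensor built on a fragment of DNA helicase B translocates from
the nucleus to the cytoplasm as CDK activity rises, so the ratio of mean
cytoplasmic to mean nuclear sensor intensity (the **C:N** or **DHB
ratio**) is a live, dimensionless readout of CDK activity in single
cells.  After a mother cell divides, each daughter either ramps CDK
activity back up (CDK^inc — a cycling G1 cell) or settles into a
persistently low-activity state (CDK^low — quiescence/G0).  `cdktrace`
implements the downstream analysis of such recordings for researchers
studying proliferation–quiescence decisions in vivo (e.g. in *C. elegans*
larval lineages or zebrafish embryos):

* **Ratio quantification** — rolling-ball-style background subtraction
  (morphological opening, default radius 50 px) and mean-intensity
  measurement over a nuclear toroid (excluding the nucleolus, which does
  not localize the sensor) and a perinuclear cytoplasmic patch, giving
  the C:N ratio per cell per timepoint.
* **Trace conventions** — anaphase-aligned time (t = 0 at anaphase), the
  G1 snapshot at 25 min post-anaphase, and the fixed-threshold CDK^low
  call (ratio < 0.19 for ≥ 3 consecutive post-anaphase frames).
* **Permutation statistics** — for two groups of single-timepoint ratios,
  the observed statistic is |x̄₁ − x̄₂|; for two sets of traces it is the
  area between the per-timepoint mean trend lines, ‖x̄₁ − x̄₂‖₁ summed
  over the shared 5-min grid.  The null is built by randomly
  re-partitioning the data (whole traces for time courses) into groups of
  the original sizes; the empirical p-value is the fraction of replicates
  strictly exceeding the observed statistic, reported as p < 1/n_reps
  when no replicate exceeds it.  An exhaustive enumeration oracle is
  included for small inputs.
* **Fate classification** — at each post-anaphase timepoint, an ROC curve
  over the observed ratios (higher ratio ⇒ proliferative) with the
  operating threshold chosen to maximize √(sensitivity × specificity);
  a trace is classified by majority vote of its relevant timepoints (all
  samples after 60 min when the trace extends that far, where AUC > 0.9;
  otherwise its last three samples, where AUC > 0.8), ties broken by the
  latest vote.
* **Synthetic data** — generators for anaphase-aligned two-fate trace
  sets and for single-cell images with known ground-truth ratios, so the
  whole pipeline is testable without microscope data.

## Worked example

Simulate a labeled recording, train the classifier, evaluate it, and
test whether the two fates' time courses differ:

```sh
$ cdktrace simulate --seed 7 --n-per-class 50 --out traces.csv
wrote 100 traces to traces.csv
$ cdktrace train traces.csv --out classifier.json
trained 25 timepoints -> classifier.json
$ cdktrace evaluate classifier.json traces.csv --out eval.json
accuracy 100/100 = 100.0%
$ cdktrace permtest traces.csv --n-reps 100000 --seed 7 --out perm.json
p < 1e-05
```

`classifier.json` stores one operating point per trained timepoint; at
anaphase itself the fates already differ somewhat (AUC 0.94, threshold
0.214), and prediction becomes near-perfect within the first hour:

```json
{"time_min": 0.0, "threshold": 0.2139..., "gmean": 0.9287, "auc": 0.9364, ...}
```

The evaluation report counts predicted vs actual fates (here 50/50 + 50/50
correct), and the permutation test says that in 100 000 random
re-partitions of the traces no replicate produced an area between mean
trend lines as large as the observed one (p < 1e-05).

The same steps are available in Python (`simulate_traces`,
`fit_classifier`, `evaluate`, `permutation_test`, ...), and
`cdktrace run --config run.yaml` executes the whole pipeline
(simulate → qc → split → train → evaluate → permtest) with every artifact
stamped with the seed, config hash and package version.

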