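# karyodot

Quantitative cytology of dot-chromosome (Muller *F* element) behavior on
the *Drosophila* female Meiosis I spindle.

During Prometaphase I, nonexchange chromosomes — most reliably the small
"dot" fourth chromosome — move out of the main chromosome mass toward the
spindle poles before congressing back. In fixed, DAPI-stained oocytes
this behavior is quantified by three numbers per species:

* the **3D dot-dot separation**, combining the XY distance *d* between
  the two dots' outer edges in a maximum-intensity projection with the Z
  offset *z* (number of confocal sections between the dot "light cone"
  centers × section thickness) via `distance = √(d² + z²)`;
* the **proportion of oocytes out**: post-Prophase oocytes with one or
  more chromosomes out, over all scored oocytes — for fixed samples this
  is proportional to the time spent in the out configuration;
* the **dot cross-sectional area** (µm²), a proxy for chromosome size.

A chromosome counts as "out" when a background-subtracted intensity line
profile between it and the adjacent chromosome mass dips by **at least
50%** of the (lower) flanking peak. Oocytes with both dots on the same
side of the spindle, extra nonexchange chromosomes, or otherwise abnormal
figures are excluded from distance measurement but still count toward the
proportion out.

The package provides:

* `karyodot.synthetic` — a confocal-stack simulator (blurred solids over
  constant background plus Gaussian noise, 54 nm XY pixels) with full
  ground truth, and a sampler for per-oocyte species tables;
* `karyodot.measure` — the measurement protocol: projection,
  segmentation, the 50%-dip classifier, outer-edge XY / light-cone Z / 3D
  distances, areas, and configuration triage;
* `karyodot.stats` — the comparative layer: species summaries, pairwise
  contrasts between closely related species pairs differing in inversion
  polymorphism with a False Discovery Rate rule using cutoffs
  `(i/m)·Q`, `Q = 1/(2m)`, Welch group comparisons, Pearson correlations
  with regression-*t* significance, and phylogenetic pair-averaging;
* `karyodot.datasets` — the bundled 15-species summary table and the six
  close species pairs;
* a `karyodot` CLI (`generate`, `measure`, `stats`, `run`).

## Worked example

Run the full species-level analysis on the bundled table:

```sh
karyodot stats --summary-table builtin --out report/
```

prints

```
Group means (species means of dot-dot distance): polymorphic 7.15 um (n=7) vs monomorphic 6.81 um (n=7); Welch t-test P = 0.75
Pairwise contrasts (poly - mono):
  mel - sim: delta = 5.2 um, p = 2.2e-16, FDR cutoff = 0.014*
  yak - ere: delta = 1.6 um, p = 0.017, FDR cutoff = 0.028*
  car - sig: delta = -1.4 um, p = 0.018, FDR cutoff = 0.042*
  hyd - mea: delta = -0.7 um, p = 0.065, FDR cutoff = 0.056
  ame - vir: delta = -0.7 um, p = 0.0755, FDR cutoff = 0.069
  nic - mul: delta = 0.56 um, p = 0.1145, FDR cutoff = 0.083
Correlations (Pearson r, regression P):
  pct_heterochromatin vs mean_distance_um: r = 0.279 (n = 9, P = 0.467)
  mean_distance_um vs mean_dot_area_um2: r = 0.710 (n = 14, P = 0.00446)
  mean_distance_um vs proportion_out: r = 0.740 (n = 14, P = 0.00248)
  proportion_out vs mean_dot_area_um2: r = 0.794 (n = 14, P = 0.000705)
  proportion_out vs mean_dot_area_um2 excluding sig: r = 0.924 (n = 13, P = 6.64e-06)
  proportion_out vs mean_dot_area_um2, pair-averaged: r = 0.792 (n = 8, P = 0.0191)
```

Reading this: species tolerating common inversions do **not** separate
their dots farther (groups differ by ~0.3 µm, P = 0.75; half the close
pairs go the "wrong" way), genomic heterochromatin content does not
predict separation (r = 0.279, P = 0.47), but dot size, separation and
the proportion of oocytes out are mutually correlated — the strongest
link (r ≈ 0.8, P < 0.001) ties chromosome size to the fraction of time
spent out on the spindle, and it survives collapsing each close species
pair to its midpoint. An asterisk marks contrasts significant under the
step-up rule `p_i < i/(2m²)`.

Image-protocol round trip on synthetic data:

```sh
karyodot generate --mode stack --seed 2 --n 5 --out stacks/
karyodot measure --stack-dir stacks/ --out measurements.csv
```

Each generated stack carries a `*_truth.csv` sidecar; the measured 3D
distance lands within one voxel diagonal (≈ 0.5 µm at 54 nm pixels and
0.5 µm sections) of the ground-truth separation.

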