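# scith

Multi-region + single-cell intratumor-heterogeneity (ITH) analysis toolkit:

- **`scith.simulate`** — synthetic ground-truth generator: genome bin grids,
  clone trees with integer copy-number events, overdispersed single-cell bin
  depths calibrated to a target MAPD, bulk regions as clone mixtures with
  diploid contamination, dual-caller mutation tables with false negatives, and
  single-cell validation assays with allelic dropout.
- **`scith.profiles`** — control-normalized depth ratios, integer copy-number
  inference via a Gaussian-emission Viterbi HMM, MAPD quality control
  (strict pass below 0.25), per-bin median consensus profiles, and pairwise
  Pearson profile similarity.
- **`scith.mutations`** — dual-caller SNV consensus, base-quality (< 30) and
  spacing (< 15 bp, both members) filters, mandatory germline subtraction,
  VAF > 0.2 rescue of single-caller calls for variants confirmed elsewhere,
  indel merging, ubiquitous/shared/private categorization, pyrimidine-collapsed
  6-class mutation spectra with chi-square / Fisher contingency tests.
- **`scith.cells`** — rule-based cell identity: somatic diploid (no SCNAs, zero
  validated candidate mutations), mixture (diploid profile with > 3 candidate
  mutations), tumor (SCNAs and >= 4 of 14 tumor-panel mutations), otherwise
  ambiguous/excluded; cohort summaries by patient and region.
- **`scith.subclones`** — Ward/Euclidean hierarchical clustering, deterministic
  PAM with silhouette-based choice of k, variance (> 0.5) + PCA (PC1–PC6)
  selection of candidate subclonal bins, a >= 1.5 Mb contiguous-event filter,
  and subpopulation frequencies.
- **`scith.pipeline` / `scith.cli`** — end-to-end orchestration with a
  deterministic run manifest.

## CLI

```sh
scith all --seed 1 --out run/            # full synthetic end-to-end run
scith simulate --config sim.yaml --out run/
scith scna --out run/                    # profiles + MAPD QC
scith mutations --out run/               # dual-caller catalog + spectrum
scith cells --out run/                   # identity classification
scith subclones --out run/               # subclonal SCNA pipeline
```

`run/manifest.json` records per-file checksums; re-running with the same
config and seed reproduces them bit-for-bit.

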