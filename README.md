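# tauquant

Quantitative analysis of aggregated (sarkosyl-insoluble) Tau from targeted
proteomics, as a reusable pipeline:

* **tau_model** — Tau isoform sequences (2N4R/1N4R/0N4R/mouse, vendored
  FASTA), point mutations (P301S/P301L), in-silico tryptic digestion with
  canonical 2N4R-numbered coordinates, cross-isoform position mapping, and
  peptide specificity classification (shared / human-specific /
  mouse-specific / mutant-specific / flex-tag reporter).
* **srm_quant** — transition-level peak-area reports (Skyline-export-like
  CSV/TSV) to per-peptide L/H ratios (ratio of summed areas), reporter-
  peptide calibration of the heavy full-length standard, absolute Tau
  abundance (fmol/mg tissue), and per-peptide modification extent
  (1 − L/H normalized to the highest-L/H peptide of the same specificity
  class, clipped to [0, 1]).
* **ptm_consensus** — per-search-engine PTM site tables (registered column
  dialects) combined by union at the replicate level into canonical-numbered
  site × condition frequency matrices, thresholded (inclusive ≥ 0.5 by
  default) into binary presence matrices.
* **progression_stats** — hierarchical clustering (euclidean, complete
  linkage), temporal categories of PTM sites relative to a configured onset
  time point, fold changes vs the earliest time point, Welch t-tests, and
  Pearson correlation of per-peptide measures with log10 insoluble-Tau
  burden.
* **synthetic_data** — seeded ground-truth simulator (logistic burden
  trajectories, sigmoid stoichiometry–burden coupling, planted PTM detection
  schedules, lognormal area noise, 3–5 transitions per precursor) emitting
  the exact input formats the readers accept plus a JSON truth sidecar for
  recovery tests.
* **cli** — `tauquant` command with `simulate`, `quantify`, `consensus`,
  `stats`, `report` subcommands.

## CLI usage

```sh
# synthetic study with truth sidecar
tauquant simulate --seed 1 --out run/

# individual stages
tauquant quantify  --in run/ --out run/quant/
tauquant consensus --in run/ --out run/consensus/ --threshold 0.5
tauquant stats --quant run/quant/ --consensus run/consensus/ \
    --out run/stats/ --onset P301S 4 --onset P301L 4

# or everything at once
tauquant report --in run/ --out run/out/
```

All tables are TSV with documented headers; every output directory contains
the serialized run configuration (`run_config.yaml`) for provenance. Exit
codes: 0 success, 2 partial (per-sample failures listed in `failures.tsv`),
1 fatal. A YAML config (`--config`) can override the seed, the binary
threshold, the consensus grouping, the search-database isoform, and scenario
parameters for `simulate`.

## Notes

* The vendored mouse Tau record is a surrogate aligned 1:1 to canonical
  numbering (divergent N-terminus, conserved PRD/MTBD/C-terminus); see the
  FASTA header. Specificity classification accepts any user-supplied
  sequence set.
* Undefined ratios propagate as missing values, never zeros. Fractions
  exceeding the class reference are clipped to 1 with a logged event.
* p-values are uncorrected; clustering drops incomplete rows by default
  (mean imputation behind a flag).
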