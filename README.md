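# bctrace

Clonal lineage-tracing analysis for DNA-barcoded leukemia cells: from raw
barcode sequencing reads to chemoresistant-clone calls and
leukemia-initiating-cell statistics, with a ground-truth synthetic-data
generator for end-to-end validation.

## The problem

Cellular DNA barcoding tags every founding cell of an AML culture with a
unique heritable sequence, so the descendants of each cell — a *BC-clone* —
can be tracked quantitatively through drug treatment and relapse by deep
sequencing of the barcode locus. Two questions drive the analysis:

1. **Does chemotherapy select a pre-determined set of clones?** If relapse
   after treatment is driven by the same barcodes across independent
   experiments, resistance is an intrinsic, pre-existing clone property;
   if relapses are driven by different barcodes each time, survival is
   stochastic. This distinction matters for combination strategies (e.g.
   adding a low-dose DNA-methyltransferase inhibitor such as decitabine)
   that aim to suppress the resistant compartment.
2. **Are chemoresistant clones stem-like?** Leukemia-initiating capacity is
   measured by limiting-dilution xenotransplantation, and per-clone
   engraftment lets one ask whether the chemoresistant clones are also the
   ones that initiate leukemia in vivo.

`bctrace` implements the full quantitative pipeline for these questions:

- **barcode_io** — barcode-library handling, exact 15-nt-prefix read
  assignment after an anchor (common annealing region), count-matrix and
  sample-sheet I/O with cross-validation.
- **qc** — the three-gate QC used for barcoded-clone sequencing: drop a
  sample when the mean depth of its technical-replicate pair is `< 10^4`
  reads; zero "singleton" barcodes present in only one technical replicate;
  drop pairs whose technical replicates have Pearson `r < 0.8`; then
  normalize and average the pair into one clonal profile.
- **stats** — Shannon–Weaver diversity `H = −Σ xᵢ ln xᵢ`, architecture
  correlations, normalized barcode richness, per-clone fold variation
  `foldᵢ = xᵢ(T_relapse)/xᵢ(T0)`, *fitness* (mean fold under no treatment),
  *competitive index* `CI = fold(treatment)/fitness`, top-clone summaries
  and IC50 resistance ratios.
- **selection** — per-barcode Welch t-tests of log2 fold variations versus
  the untreated arm (`P < 0.05`); clones not significantly decreased are
  *resistant*; intersecting per-experiment resistant sets across
  independent experiments yields the reproducibly selected *core*.
- **stemness** — single-hit Poisson limiting-dilution analysis
  (`P(negative at dose d) = e^{−f·d}`) with maximum-likelihood `f̂` and
  profile-likelihood confidence bounds; per-lineage expected L-IC numbers
  `λᵢ` and establishment probabilities `pᵢ = 1 − e^{−λᵢ}`; exact binomial
  tail tests for lineages established in more mice than expected (HiL-IC).
- **simulate** — a generative model of the whole experiment (clone
  frequencies, binomial kill, exponential regrowth, multinomial
  sequencing, Poisson xenograft engraftment) with planted ground truth.

## Worked example

```python
from bctrace import (SimConfig, make_benchmark_dataset, analyze_counts,
                     fit_limiting_dilution, resistance_ratio)

# IC50 ratio relative to the untreated control (printed IC50s in uM)
resistance_ratio(1.40, 0.345)        # -> 4.06

# simulate a complete 3-experiment study and analyze it
cfg = SimConfig(seed=1, n_clones=250)
ds  = make_benchmark_dataset(cfg)
res = analyze_counts(ds.counts, ds.sheet)

sorted(ds.manifest["planted_resistant"])
# ['BC0339', 'BC0391', 'BC0712', 'BC1300', 'BC2585']
sorted(res.cores["Doxo"].barcodes)            # recovered exactly
# ['BC0339', 'BC0391', 'BC0712', 'BC1300', 'BC2585']
sorted(res.cores["Doxo+Cyta+DAC"].barcodes)   # DAC combination: no core
# []

lda = fit_limiting_dilution(ds.lda_design)
print(f"{lda.f_hat:.2e} ({lda.ci_lower:.2e}-{lda.ci_upper:.2e})")
# 3.10e-03 (1.12e-03-8.37e-03)   i.e. ~1 L-IC per 323 cells
```

The chemotherapy arms (Doxo, Doxo+Cyta) reproducibly select the five
planted resistant clones — the cross-experiment core equals the planted set
— while the decitabine-combination arm regrows through unpredictable
clones: its relapses have collapsed diversity (mean Shannon H 1.16 versus
5.21 in untreated cultures in this run) and an empty core. The
limiting-dilution fit brackets the simulated population's true L-IC
frequency (2.08e-03) inside its 95% interval.

The same steps are available from a shell:

```bash
bctrace simulate --seed 1 --out-dir data
bctrace qc --counts data/counts.tsv --sheet data/sample_sheet.tsv --out-dir qc
bctrace stats --profiles qc/profiles.tsv --out-dir stats
bctrace lda --design data/lda_design.tsv
```

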