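# Methods

This note documents the statistical procedures, the generative model behind
the synthetic benchmark, the default parameter choices with their rationale,
and the limitations of both.

## Barcode extraction

Reads are assigned by locating the first exact occurrence of a user-supplied
anchor sequence (the common annealing region) in each read and matching the
15 nt immediately downstream against the library's 15-nt barcode prefixes,
which are required to be pairwise distinct. Matching is exact by default; an
optional Hamming-distance-1 rescue assigns a prefix with a unique 1-mismatch
neighbour in the library and reports rescued reads separately. The anchor is
an input, not a constant, because its position within a read depends on the
amplicon design. Extraction is conservative (assigned + unassigned = total)
and order-independent.

## Quality control

Per biological replicate (a pair of technical replicates A/B from one
lysate), the gates run in this order:

1. **Depth**: drop when the mean of the two technical-replicate read totals
   is strictly below `min_depth` (default 10^4; the boundary keeps).
2. **Singleton masking**: a barcode with reads in exactly one technical
   replicate is zeroed in both — one-replicate detections are low
   confidence at these depths.
3. **Normalization** to proportions (the conventional "counts per 10^5"
   scale exists only in files).
4. **Concordance**: drop when the Pearson correlation of the two normalized
   replicates is strictly below `min_r` (default 0.8; computed on
   untransformed frequencies, with a log10(x+1) option).
5. **Averaging** the two replicate profiles, renormalized to sum to 1.

Masking before the concordance gate is a deliberate choice: the r gate then
measures reproducibility of the *confidently detected* barcodes rather than
being driven by one-replicate artifacts. Because the opposite convention is
also defensible, `QCConfig(order="concordance_first")` switches to it and
the order used is recorded in every report. Each excluded pair carries
exactly one primary exclusion reason, and the pipeline is deterministic and
invariant to barcode row order.

## Clonal statistics

Profiles are frequency vectors x over barcodes, Σxᵢ = 1.

- Shannon–Weaver `H = −Σ xᵢ ln xᵢ` (nats; 0·ln 0 = 0), 0 for a single
  clone, ln N for N uniform clones.
- Architecture correlation: Pearson r on the union barcode set (missing =
  0); undefined (NaN) under zero variance.
- Normalized richness: detected-barcode count divided by the mean count
  across untreated reference profiles.
- Fold variation `foldᵢ = xᵢ(T_relapse)/xᵢ(T0)` for barcodes detected at
  T0. Barcodes absent at T0 are excluded by default (a fold from zero is
  undefined); a half-minimum pseudocount policy exists for sensitivity
  analyses. When relapse mass stays on T0-detected clones,
  `Σ xᵢ(T0)·foldᵢ = 1` exactly — used as an internal consistency test.
- Fitness: a clone's mean fold across untreated replicates (arithmetic
  mean by default, geometric optional). Competitive index: mean treatment
  fold divided by fitness; CI = 1 means treatment did not change the
  clone's competitive behaviour. A zero fitness leaves CI undefined
  (flagged) rather than infinite.
- IC50 resistance ratio: treated-over-untreated IC50, rounded half-up to
  two decimals for reporting. Dose–response fitting itself is out of scope;
  only the ratio arithmetic is provided.

## Resistant-clone calling

For each barcode detected at T0, the treatment-arm fold variations are
compared with the untreated folds by Welch's unequal-variance t-test on
log2(fold + pseudocount), the pseudocount being half the smallest positive
fold in the comparison (this keeps eliminated clones, fold 0, testable).
With per-barcode `P < alpha` (default 0.05, uncorrected; Benjamini–Hochberg
optional) the clone is classed *decreased* or *increased* by the sign of
the mean difference, otherwise *equal*. Resistant = not decreased, with the
additional requirement that the clone was actually observed at relapse in
the treatment arm (otherwise never-seen barcodes would count as "equal").
The log2 transform stabilizes the variance of ratio data; a Student test on
raw folds is available for comparison. Degenerate zero-variance inputs are
resolved exactly (identical constants: p = 1; distinct constants: p = 0).

Per-experiment resistant sets are intersected across independent
experiments into the *core* — the reproducibly selected clones — and cores
of different regimens can be intersected again. The per-barcode test at
n = 3 replicates has limited power for clones near the sequencing noise
floor (tens of reads); the cross-experiment intersection is what removes
such false "equal" calls, since they rarely recur in all experiments.

## Leukemia-initiating-cell statistics

A mouse is scored positive when the human AML fraction exceeds 0.5%
(strictly) of mouse leukocytes in the injected tibia or the pooled bone
marrow. Under the single-hit Poisson model, a mouse receiving dose d from a
population with L-IC frequency f is negative with probability e^(−f·d); the
estimator maximizes the binomial log likelihood over dose groups (the
single-dose case reduces to the closed form −ln(1 − k/n)/d). Confidence
bounds invert the chi-square(1) likelihood-ratio threshold on the log-f
scale (brentq to high precision); a Wald interval on log f from the
numerical observed information is reported alongside. All-negative and
all-positive designs are flagged boundary cases with the appropriate
one-sided bound (the other bound 0 or infinite).

Given f̂, an injection dose and the injected clone frequencies, the
expected L-ICs of lineage i are λᵢ = f̂·d·freqᵢ in the default
`proportional` mode (L-ICs spread evenly among *cells*, so a lineage's
expectation scales with its size) or λᵢ = f̂·d/N in `even` mode (spread
evenly among *lineages*); pᵢ = 1 − e^(−λᵢ) is the per-mouse establishment
probability. The wording that motivated the even option is ambiguous, so
the mode is explicit in every call. A lineage established in kᵢ of M mice
is HiL-IC when the one-sided exact tail P(X ≥ kᵢ) < alpha with X ~
Binomial(M, pᵢ) (or the exact Poisson-binomial convolution when mice
received different doses), requiring kᵢ ≥ 1. The tail is monotone in both
kᵢ and pᵢ, and under a homogeneous null the HiL-IC rate is conservative
(≤ alpha) because the binomial is discrete.

## The synthetic benchmark

The generator emulates the barcoded-clone experiment end to end under one
master seed (all artifacts byte-reproducible).

**Population.** n clones (drawn uniformly in 210–330 by default, the
detected-barcode range of such sublines) with frequencies drawn lognormal
(σ = 0.8) and normalized. The population models the *detected* clone set:
barcodes counted in such experiments are by construction above the
sequencing detection floor, so the size spectrum is bounded away from zero;
a raw symmetric-Dirichlet option (`initial_distribution="dirichlet"`) is
provided for studying heavier tails, which places clones below the floor
and degrades per-clone testability. Growth rates are Normal(0.18, 0.01)
per day — the net recovery rate implied by regrowth of a >99%-depleted
culture to its starting size within ~30 days, which also matches the
30-day untreated harvest so that growth exposure is comparable between
arms. Five planted resistant clones (frequency ranks 12–16, i.e. sizeable
but not dominant) receive a 50× kill-survival multiplier and 0.85× growth
(slow, stem-like). Per-clone L-IC fractions are lognormal around 10⁻³;
thirty planted HiL-IC clones (four of them resistant, encoding the
chemoresistance–stemness correlation) carry an 8× L-IC multiplier.

**Treatment course.** One culture = stochastic kill + deterministic
regrowth. Kill: per-clone binomial survival with probabilities scaled so
the expected bulk kill matches the regimen target (Doxo 99.56%, Doxo+Cyta
99.96%, Doxo+Cyta+DAC 99.90% — the printed bulk-elimination levels; NT 0).
Regrowth: exponential at each clone's rate (times regimen modifiers) until
the culture returns to its starting cell number (10⁹ by default — a pooled
large-scale suspension culture, chosen so that even the smallest detected
clone keeps enough cells through a >99% kill for its fold variation to be
dominated by biology rather than by counting noise), or for a fixed 30
days in non-depleting arms. A course whose kill leaves nothing
able to regrow is flagged `relapsed=False`, not raised.

**DAC combination.** The hypomethylating-agent combination is modeled
phenomenologically: resistant clones keep their kill-survival advantage
(the drug's effect on elimination is mild) but their regrowth is strongly
suppressed (growth ×0.15), and — the essential ingredient — regrowth is
stochastically restricted for *all* clones: each clone in each culture
resumes proliferation only with probability 0.02 (`clone_regrowth_prob`).
Relapses are therefore founded by a few random clones, reproducing the
qualitative signature of this arm: collapsed richness and diversity,
uncorrelated replicate architectures, massive expansions of rare clones,
and an empty cross-experiment core. No methylation dynamics are modeled.

**Sequencing.** Each technical replicate is an independent multinomial of
`depth` reads (default 10⁵, the conventional normalization scale) over
clone frequencies; Dirichlet-multinomial overdispersion is available but
off by default so analytic sampling-error bounds hold in tests.

**Xenografts.** Each mouse at dose d receives Poisson(d·freqᵢ·ℓᵢ) L-ICs of
clone i; it is positive iff it received ≥ 1 (single-hit), and a clone is
present iff ≥ 1 of its L-ICs was injected. The default design is the
10⁴/10³/10²/10 ladder with 6 mice per dose, plus a 7-mouse single-dose
(10⁴) engraftment block for HiL-IC calling.

### Default parameters at a glance

| parameter | default | rationale |
|---|---|---|
| clones | 210–330 (drawn) | detected-barcode range of the sublines |
| clone-size law | lognormal σ=0.8 | detected clones, bounded off the noise floor |
| bulk kill | 99.56–99.96% | printed elimination levels per regimen |
| resistant survival | 50× | reproduces ~45–60% summed relapse share, 7–13× expansion |
| resistant growth | ×0.85 | slow stem-like phenotype |
| growth rate | 0.18 ± 0.01 /day | ~30-day regrowth of a >99%-depleted culture |
| culture size | 10⁹ cells | pooled large-scale suspension culture |
| depth | 10⁵ reads ×2 tech reps | conventional normalization scale |
| L-IC fraction | ~10⁻³ (lognormal) | limiting-dilution scale of such lines |
| HiL-IC multiplier | 8× on 30 clones | minority of high-initiating lineages |
| DAC regrowth prob | 0.02/clone/culture | few-founder, unpredictable relapses |

## Numerical choices

- Likelihood maximization for the dilution estimator runs on log f
  (bounded scalar minimization, xatol 10⁻¹²); profile bounds by brentq
  (xtol 10⁻¹⁴). The single-dose MLE agrees with the closed form to <10⁻⁹.
- Top-k clone selection breaks frequency ties lexicographically by barcode
  id, making reports deterministic.
- Frequency vectors are validated to sum to 1 within 10⁻⁶ at entry points;
  averaged profiles are renormalized to remove float drift.
- Resistance ratios round half-up (decimal arithmetic), matching reporting
  convention rather than banker's rounding.

## Limitations

- The simulator's technical noise is purely multinomial: no PCR jackpots,
  index hopping or overdispersion by default, so real technical replicates
  will be noisier than simulated ones and QC pass rates correspondingly
  lower. Passing benchmark tests therefore validates the pipeline's logic,
  not its behaviour under worst-case library-prep artifacts.
- Clones below the detection floor are not simulated; singleton masking is
  exercised by construction in tests rather than by a sub-floor clone tail.
- Chemotherapy arms deplete clone *frequencies* but rarely eliminate
  detected clones outright at the default culture size, so simulated
  richness drops less under Doxo than real relapses show.
- The per-barcode Welch test at 3 replicates has low power near the noise
  floor; single-experiment resistant sets should be read as candidate sets,
  with the cross-experiment core as the reliable output.
- Regrowth is deterministic-exponential after the stochastic kill (and
  lock, under DAC); no per-day branching noise. The DAC regrowth-lock is a
  phenomenological stand-in for stochastic epigenetic reprogramming.
- The profile-likelihood dilution intervals are asymptotic; with 24 mice
  their simulated coverage is ~94–96%, not exactly 95%.
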