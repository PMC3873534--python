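# Methods

`hhspike` re-implements, as a tested library, the single-unit analysis used
for intra-operative microwire recordings from human hypothalamic hamartoma
(HH): per-unit firing phenotypes, pairwise zero-delay synchrony with a
permutation null, and the population-level statistical battery.  Because no
raw clinical recordings are publicly available, the package ships a
synthetic-session generator that reproduces the reported population
structure and serves as ground truth for every stage.

## Data model

A *session* holds patients; each patient contributes two or three 5-minute
*epochs* recorded at successive microwire positions (up to 8 channels); each
epoch holds the spike times of its sorted single units, in seconds from
epoch start.  On disk: a long spike CSV plus a JSON sidecar (epoch
durations, unit roster, anesthesia covariates), or a single JSON document.
Spike times are serialized with 6 decimals so the 100 µs duplicate rule
survives a round trip.  Ingest sorts unsorted times but rejects NaN,
negative, or out-of-range values.  The default cohort layout (14 patients,
37 epochs, 222 units) mirrors the reference study and is fully configurable.

## Event detection and duplicate removal

Detection emulates the acquisition convention: samples at 29412 Hz, events
where |v| exceeds 2.8 SDs of the whole trace, 1.1 ms snippets.  A contiguous
suprathreshold excursion yields one event anchored at its extremum, so one
action potential is never counted twice.

The duplicate rule removes the same physical spike captured on two wires:
all spikes of an epoch are scanned once in global time order (ties broken
toward the lower-numbered channel), and a spike is deleted when any retained
spike on a *different* channel precedes it by < 100 µs.  Same-channel
intervals are untouched — the rule targets cross-channel copies, not genuine
short ISIs.  The scan is idempotent, order-independent, and verified in the
tests by exhaustive pair scanning.

A side effect worth knowing: on dense epochs the rule carves a genuine
zero-lag *deficit* into otherwise independent fast pairs (expected
2·λ₁·λ₂·100 µs·T coincidences are deleted), which the synchrony stage can
flag as significant negative peaks.  This is a property of the analyzed
method itself, not of this implementation; it plausibly contributes to the
negative peaks the original recordings show.

## Unit metrics

* **Mean rate** — spikes / epoch duration; units with rate < 2 sp/s are
  *slow*, ≥ 2 sp/s *fast*.
* **Burst index** `B_isi` — #(ISI < 10 ms) / #(ISI ≥ 10 ms); NaN below two
  spikes, +inf when no long interval exists (excluded from mixture fits).
  Note that a Poisson train is not burst-free by this criterion: its
  expected `B_isi` is e^(λ·10 ms) − 1 ≈ 0.16 at 15 sp/s, which lower-bounds
  what any near-renewal fast unit can realize.
* **Kernel rate** — sum of unit-mass Gaussians (SD = 1 s) at spike times on
  a 0.1 s grid, kernels truncated at ±5 SD (< 1e-5 mass lost).
* **Evolving discharges** — the phenomenon is reported without a published
  criterion, so the detector here is the package's own heuristic: maximal
  intervals where the kernel rate exceeds the epoch median by more than
  z = 4 robust SDs (1.4826·MAD, floored at 5% of the median) for ≥ 3 s *and*
  peaks ≥ 5 sp/s above the median.  The absolute peak-excess condition
  exists because sparse bursty trains clear a purely relative threshold
  without ever reaching discharge-like rates.  Calibration (in the tests):
  ≤ 5% false positives per epoch on stationary Poisson trains, ≥ 95%
  single-event recovery of an injected 1→30 sp/s ramp over 10 s.

## Synchrony

Each epoch is divided into 2-s segments; spikes are counted in 1/1024-s bins
on a grid fixed to the epoch (half-open bins; boundary spikes go to the
later bin; a trailing partial segment is dropped).  Per segment, the
cross-correlation of the two count sequences is computed spectrally and the
per-segment correlograms averaged; values are reported as coincidence rates
(counts per lag per segment / 2 s).  The transform-domain product implements
*circular* correlation within each segment; at |lag| ≤ 25 ms of a 2048-bin
segment the wrap-around bias is ≤ 1.3% of lags and the tests verify exact
integer agreement with brute-force lagged pair counting, so zero-padding
would change nothing material.

The **zero-delay peak** is the zero-lag bin minus the mean over the 1–25 ms
delay window (both signs pooled; bins whose delay lies inside the window,
i.e. lag bins 2–25 at the default bin width); the normalized peak divides by
the window SD.  The ±1-bin peak variant is available as a config option.

The **permutation test** shuffles the order of the second unit's 2-s
segments (200 draws, permutations without replacement, identity allowed),
recomputes the averaged correlogram and peak each time, and reports the
two-sided empirical p = (1 + #{|perm| ≥ |obs|}) / 201, so p ≥ 1/201 always.
The default statistic is the raw baseline-subtracted peak (shuffling
preserves the baseline); the normalized variant is an option.  Shuffling
leaves both units' firing rates untouched, which makes significance
independent of firing rate — verified by simulation at 0.5/5/20 sp/s.
Same-channel pairs are analyzed like any other; only sub-100 µs
coincidences are excluded, upstream.

Implementation note: per-segment FFTs are computed once per pair and reused
across all 200 shuffles (a shuffle only permutes rows of the second unit's
spectrum), which makes the 200-draw test ~150 ms per pair at 300 s epochs.

## Population statistics

* **Dip test** — Hartigan's dip computed by the classical iterative
  GCM/LCM construction, validated in the tests against a brute-force
  linear-programming oracle (the dip is the smallest sup-norm distance to a
  unimodal CDF — one LP per candidate mode).  The statistic is implemented
  in-package. P-values are Monte Carlo against uniform samples of equal size
  (2000 reference draws, cached per sample size, seeded).
* **Gaussian mixtures** — EM fits (10 restarts per component count, seeded)
  on the raw values, adding components until the AIC fails to improve (no
  slack), returning the best preceding fit with per-component medians.
  Non-finite burst indices are excluded; log-domain fitting is exposed as an
  option by pre-transforming inputs.
* **Binomial test** — two-sided exact (minimum-likelihood method) on the
  number of significant pairs at null probability p₀ = the synchrony α
  (0.05); "expected by chance" is read as the test's nominal false-positive
  rate, which the output flags.
* **Fisher exact test** — 2×2 (both-fast vs not) × (significant vs not).
* **Heterogeneity** — Pearson chi-square of patient × outcome over all
  pairs; the within-patient version sums per-patient chi-squares (and
  degrees of freedom) across each patient's epochs.
* **Anesthesia GLM** — per covariate, an F-ratio test of adding that
  covariate alone to the intercept-only linear model of firing rate
  (continuous covariates enter linearly; categorical ones through their
  dummy block, tested jointly); Benjamini–Hochberg FDR at q = 0.2 across
  the eight covariate p-values; incremental R² per variable; combined
  significant-covariate model for the total explained variance and the
  residuals, whose multimodality is re-tested with the dip test.

## The synthetic-data generator

The generator's defaults are the study conditions:

| aspect | default | rationale |
|---|---|---|
| cohort | 14 patients, 37×300 s epochs, 222 units | reported accounting |
| rate classes | slow 40% (log-normal, median 0.6 sp/s, σ_log 0.5, capped at 1.9), fast 60% (Gaussian, 15 ± 5 sp/s, floored at 2.2) | class medians 0.6/15.0, boundary 2 sp/s, overall mean ≈ 9.9 sp/s; Gaussian fast class so the raw-scale mixture has two components |
| burst classes | 35/35/30% at B_isi 0.015/0.18/0.39 (Gaussian scatter 0.008/0.045/0.08) | three reported burst classes |
| rate–burst coupling | shared latent Gaussian, ρ_latent = 0.9 | realizes raw Pearson ρ ≈ 0.7 (target 0.66) |
| synchrony | per-epoch master train (4 sp/s); units join their epoch's network with class-dependent probability; joined units carry jittered (SD 1 ms) copies of master spikes with copy probability min(0.35, 0.35·rate/4) | concentrates detectable synchrony among fast units while letting slow–fast pairs couple weakly |
| per-patient spread | ±50% on join probabilities | lesions differ in network synchrony (between-patient heterogeneity) |
| discharges | round(3.6% of units), triangular rate ramp +25 sp/s over 10 s | 8/222 reported units |
| traces | 29412 Hz, biphasic template, Gaussian noise | detection stage |

Bursty trains are a two-state renewal process: Poisson burst onsets, a
geometric number of spikes per burst (mean 4; mean 2 for near-Poisson
targets; truncated at 12 — untruncated geometric tails produce rare
mega-bursts that mimic discharges), gamma (shape 2) intra-burst intervals of
mean 4 ms, superimposed on a Poisson background.  The burst-onset rate for a
target `B_isi` is solved analytically from the expected short-interval
fraction (intra-burst gamma mass below 10 ms plus the exponential-gap tail)
by bisection; when the intrinsic Poisson short-interval fraction already
exceeds the target the train is left Poisson.  Realized `B_isi` at a target
of 0.39 is within ±0.1 over replicate medians.

Join probabilities are derived from the target fraction of synchronous
pairs: the mean join probability is √(target)/0.8 (the 0.8 is the assumed
average detectability of a network pair — weakly coupled slow units rarely
reach significance), split between classes by the fast-join bias (1.8).
Every generator consumes counter-derived substreams of one master seed, so a
unit's train does not depend on generation order.

Anesthesia covariates are generated as context (patient-level flags,
epoch-level continuous values) with **zero** default effect on rates:
injecting effects at the reported scale (e.g. −11 sp/s) into a population
whose class medians are 0.6 and 15 sp/s would produce negative rates or
distort the primary class structure.  The GLM stage is instead validated by
direct parameter recovery (a +11 sp/s flag effect recovered within
±2 sp/s; FDR ≤ 0.2 on pure-noise covariates).  `anesthesia_effects` in the
config injects additive effects for experiments.

### What the generator does not emulate

Waveform-shape diversity (single template), electrode drift between epochs,
non-stationary background rates, true inhibitory coupling (all injected
synchrony is excitatory; negative significant peaks arise only via the
duplicate-rule deficit), spike-sorting errors, and any clinical covariate
structure beyond random anesthesia context.  Passing tests therefore
demonstrate correctness and calibration of the *analysis* under a plausible
population model — not that real HH recordings would yield these exact
numbers.

## Numerical choices and degenerate inputs

* Spike exactly on a bin or segment boundary → later bin (half-open).
* Flat correlogram (e.g. an empty train) → normalized peak NaN, p = 1.
* `B_isi` sentinels: NaN (< 2 spikes), +inf (no long interval).
* Mixture fits: 10 EM restarts, reg_covar 1e-6, components sorted by mean;
  constant samples yield one component with a floored SD.
* Dip: ≥ 4 finite observations; samples with < 2 distinct values have dip 0.
* Exact duplicate-time ties across channels delete the higher-numbered
  channel's spike (deterministic).
* Problem sizes in the statistical suites: 500 independent pairs for the
  type-I check, 150 per rate for rate-invariance, 25 per level for power
  monotonicity, 10 generator seeds for mixture recovery, 2000 Monte Carlo
  reference samples for dip p-values — sizes chosen so each check has
  useful resolution at its stated tolerance.

## Known limitations

* The pair-count bookkeeping of the reference study (813 "all possible
  pairs" vs 840 = Σ C(n,2) over its table) cannot be reconciled from the
  published information; the pipeline reports the raw count.
* The discharge detector is a calibrated heuristic, not a published
  criterion; its sensitivity on high-rate units is < 100% by design of the
  robust threshold.
* Permutation p-values have 1/201 granularity; α = 0.05 corresponds to
  ≤ 9 of 200 exceedances.
* The dip test's uniform reference makes it conservative for peaked
  unimodal nulls.
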