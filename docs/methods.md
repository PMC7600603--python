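# Methods

This note records the models, conventions and numerical choices behind
`nrf2screen`, and what the synthetic generators do and do not emulate.

## Signature scoring

Expression input is an FPKM-like genes × samples matrix with tumour/normal
labels. Duplicate gene identifiers (multiple transcripts mapping to one
symbol) are collapsed to their per-sample **median** before scoring. Each
gene is z-scored across **all samples pooled** (tumour + normal) using the
sample standard deviation (ddof = 1); pooling is what makes the combined
score have zero mean across the whole cohort, which is the axis convention
the score is designed around. The per-sample signature score is the
**mean** (not sum) of the member genes' z-scores — mean and sum differ only
by a constant factor, and the mean keeps scores comparable across gene
sets of different sizes. Group differences use Welch's *t*-test
(unequal variances, Satterthwaite df, two-sided). Zero-variance genes are
an error (their z-score is undefined); gene sets with members missing from
the cohort are flagged `failed` in the panel output without aborting the
run. Externally published NRF2 signatures (e.g. the 32-gene multi-tumour
or 20-gene lung sets) are accepted as user-supplied gene lists and are not
hard-coded, since their membership is not part of this package's inputs.

Consequence of the conventions: the score is exactly invariant to any
gene-wise affine rescaling of the raw matrix, so FPKM-level normalisation
differences between cohorts do not move it.

## qPCR (comparative ΔΔCT)

Amplification efficiency is fixed at 2, the classical assumption; no
standard-curve calibration. Per replicate ΔCt = Ct(target) −
Ct(housekeeping); per condition ΔΔCt = mean ΔCt(condition) − mean
ΔCt(reference); fold = 2^(−ΔΔCt), so the reference fold is exactly 1. The
focused-array flag applies a per-gene Welch *t*-test on the replicate ΔCt
values (equivalent to testing log2 relative expression, where variance is
approximately stable): `up` iff fold > 2 and *p* < 0.05, `down` iff
fold < 1/2 and *p* < 0.05. No multiplicity correction enters the flag —
that is the rule being reproduced — but a Benjamini–Hochberg q-value
column is emitted alongside for transparency. Genes with fewer than two
replicates per condition are `untestable`.

## TMA histoscore and survival

Histoscore H = 0·u + 1·w + 2·m + 3·s, with percentages validated to lie in
[0, 100] and sum to 100 within a configurable tolerance (default 0.5
percentage points, absorbing rounding in hand-entered tables). H is linear
in the fractions and bounded in [0, 300].

Observer agreement: the ICC form is **ICC(2,1)** — two-way random effects,
absolute agreement, single rater — the standard choice for dual-observer
IHC scoring; the form is recorded in the report. Identical score vectors
are a legitimate perfect-agreement edge case and return ICC = 1 directly
(the ANOVA decomposition is degenerate there). Bland–Altman limits are
bias ± 1.96·SD of the paired differences. A pair is discordant when scores
differ by strictly more than 50 units; a difference of exactly 50 is
concordant. Observer 1 is the analysis score; observer 2 exists for QC
only.

High/low NRF2 dichotomization defaults to the cohort **median** of the
nuclear histoscore — the least-assuming convention, since no published
cutoff exists — with an explicit numeric override. Ties at the cutoff go
to `low`, documented and deterministic.

Survival uses the Kaplan–Meier product-limit estimator and the log-rank
test (lifelines). With zero events the log-rank statistic is undefined and
is reported as p = 1 with a warning rather than an error. The "mean
survival difference" between groups is implemented as the
**restricted-mean survival time (RMST) difference** up to the smallest
per-group maximum observed time (the common follow-up window); an
unrestricted mean is not identifiable under censoring. No Cox regression:
the analysis chain reproduced here is univariate KM/log-rank.

## Screen engine

**Normalization.** Percent effect = 100·(signal − neḡ)/(pos̄ − neḡ) per
plate, cell line and readout, where neg = DMSO wells and pos = 100 µM
benzethonium chloride wells. The same formula serves both readout
orientations: CTG (viability, high = alive, pos̄ < neḡ) yields percent
inhibition, CTX (cytotoxicity, high = dead, pos̄ > neḡ) yields percent
kill; in both, 0 = no effect and 100 = full kill. At least 3 control wells
of each kind are required; equal control means (dead plate) is an error.
Z′ = 1 − 3(σ₊ + σ₋)/|μ₊ − μ₋| is emitted per plate for QC.

**4PL fitting.** y(x) = b + (t − b)/(1 + 10^(s·(m − x))), x = log₁₀ dose,
m = log₁₀ EC50, fitted by bounded trust-region least squares with an
analytic Jacobian. Bounds stabilize 5-point fits: b ∈ [−10, 20] %,
t ∈ [0, 120] %, s ∈ [0.1, 10], m within two decades of the tested range.
Multi-start initialization (data-driven midpoint plus spread starts);
extra starts are skipped once a fit's residual SD falls under 1 % of the
response range. With fewer than four distinct doses, or when every full
fit fails, the bottom is fixed at 0 (3-parameter fallback, flagged via
`n_params`); if nothing converges a flat data-driven fit is returned with
`converged = False` and the DSS falls back to a trapezoid on the raw
responses. Tolerances 1e-11 with an iteration cap; noiseless curves are
recovered to better than 1e-6 relative.

**DSS.** Normalized area of the fitted curve above a 10 % activity
threshold θ, on the log₁₀-dose interval of the tested range, with the
response capped at 100 % inside the integral (so DSS ∈ [0, 100] by
construction):

    DSS = 100 · ∫ (min(y, 100) − θ)₊ dx / ((100 − θ)(x₂ − x₁))

The logistic integral has the closed form
∫ y dx = b·Δx + (t − b)·[log(1 + 10^{s(x−m)})]/(s·ln 10), evaluated with
`logaddexp` for stability; the threshold and cap crossings are solved
analytically, so no quadrature enters the production path. Tests validate
the closed form against dense trapezoid integration to 1e-6 relative. The
plain normalized AUC (∫y dx / (100·Δx)) is emitted alongside, and both
conventions are recorded in run metadata. A curve whose top stays at or
below θ scores 0.

**Hit calling.** ΔDSS = DSS(GOF) − DSS(WT) per readout; a compound is a
hit only when ΔDSS is **strictly greater than 5 in both** CTG and CTX
(a tie at 5 is not a hit). Hits are ranked by min(ΔDSS) over readouts —
the conservative key, since a hit is only as strong as its weaker readout.
Compounds present in only one cell line are excluded and logged.

**Follow-up.** IC50 is **absolute** (dose where the fitted curve crosses
50 % of control), matching the viability-assay convention, not the fitted
midpoint; a curve that never reaches 50 % yields a censored IC50 and an
undefined fold. TC50 is the same 50 % crossing computed on the CTX-readout
fit. Sensitization analysis normalizes each inducer arm to its own
no-AT9283 control (= 100 %) and Welch-tests each (inducer + AT9283) arm
against (DMSO + AT9283) at the same dose; the inducer-alone arms are
reported separately.

## Synthetic generators

All generators are pure functions of a frozen spec carrying one integer
seed; named sub-streams are derived deterministically from it, and ground
truth is always returned alongside the data.

- **Expression cohort** — log-normal FPKM: per-gene log2 baselines ~
  N(3, 1.5) drawn once per universe, i.i.d. N(0, noise_sd) log2 noise per
  cell, and a `log2_effect` shift added to signature genes in tumour
  samples. Defaults mirror the colon-cohort scale (478 tumour / 41
  normal). This emulates heavy-tailed FPKM marginals and a clean
  signature effect; it does **not** emulate gene–gene correlation, batch
  structure or compositional normalisation artefacts, so passing recovery
  tests demonstrate the scoring chain's correctness, not robustness to
  those real-data features.
- **Screen plates** — 528 compounds (158/285/85 by category) at 5
  log-spaced doses over a 10,000-fold range (consecutive ratio 10), with
  16 negative and 8 positive control wells per 384-well plate. Compounds
  fall into three ground-truth classes — inactive (top below the DSS
  threshold), shared-active (identical profile in both lines) and
  differential (GOF EC50 shifted 1.5–3 decades below WT, redrawn until
  true ΔDSS ≥ 8). The 70/24/6 % class mixture is a modelling choice: the
  real library's response distribution is unpublished. Both readouts share
  a compound's true effect profile per line; only the raw-signal
  orientation differs (CTG high = alive, CTX high = dead). Raw signals get
  multiplicative Gaussian noise with CV `noise_cv` (default 5 %), controls
  included. No spatial plate effects (edge, drift) are simulated, matching
  the per-plate-controls-only correction in scope.
- **TMA cohort** — staining fractions from group-specific Dirichlet
  distributions (high-NRF2 skewed toward strong staining); observer 2 is
  observer 1 perturbed by N(0, observer2_noise) per category, clipped and
  renormalized to 100. Here observer 2 scores every patient (the design
  being emulated re-scored 10 %); concordance runs on whatever pairs
  exist, so a subset works identically. Survival is exponential with a
  proportional hazard for the high group (baseline median 60 months) and
  independent censoring with probability `censor_rate` at a uniform
  fraction of the event time — a minimal mechanism whose expected censored
  fraction equals `censor_rate` exactly. Defaults: 356 patients, hazard
  ratio 2, 30 % censoring.
- **qPCR** — housekeeping Ct ≈ 20, per-gene baseline ΔCt ~ U(3, 8), target
  Ct = housekeeping + baseline − log2(true fold) + noise, so ΔΔCT
  recovers the folds exactly at zero noise and unbiasedly (in Ct space)
  otherwise.

## Problem sizes in tests

The default test run exercises the screen at full library size (528
compounds, both readouts, both lines, two seeded replicates), the TMA
null-calibration at 200 replicates of n = 120 with power checks at
n = 356, the signature type-I error at 200 replicate cohorts of 20 + 20
samples, and the DSS oracle at 1,000 random parameter draws against a
400,001-point trapezoid. These sizes give tight Monte-Carlo error on every
checked proportion while keeping the whole suite in the minutes range.

## Known limitations

- The DSS definition here (10 % threshold, log₁₀-dose integration,
  normalization by (100 − θ)·range, 100 % cap) is the single documented
  variant; other published DSS variants differ in threshold handling and
  normalization and are out of scope.
- Stage-specific p-values are not corrected across gene sets, genes or
  compounds except where the reproduced rule says so (the BH column on
  the array is informational).
- The generators' independence assumptions (genes, wells, patients) make
  recovery tests optimistic relative to correlated real data; they
  validate the estimators and rules, not cohort-level effect sizes.
- Patient-level quantities from the motivating study (survival p = 0.041,
  17-month mean survival difference, the real screen's hit list, IC50s of
  28/320 nM) depend on data that is not redistributable; the pipeline
  reproduces them as capabilities (same estimators, same rules), not as
  numbers.
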