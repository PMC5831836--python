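# Methods

This note records the models implemented in `srmquant`, the defaults and
their rationale, what the synthetic generator does and does not emulate,
and the numerical and design choices made where more than one reasonable
option existed.

## Experimental design

`DesignSpec` enumerates a serial-dilution validation layout: a serum
pool plus `n_dilutions` two-fold dilutions of a spiked parent solution
(sample k has theoretical dilution `dilution_base**k`), each sampled as
`aliquots_per_sample` aliquots assigned one-to-one to day-couples, with
`digestions_per_aliquot` separate digestions per aliquot and
`injections_per_digestion` injections per digestion. Defaults reproduce
the reference layout: 6 samples, 24 SRM aliquots, 16 readings per
sample, 4 day-couples. Daily QC vials of the 1/4 dilution
(`qc_vials_per_day` x `qc_injections_per_vial`, default 2 x 2) provide 4
digestion-yield calibrations per day; since the Bayesian quantifier
re-estimates every reading under each same-day calibration, its
bookkeeping gives 16 x 4 = 64 readings per sample. Two conventions are
ours: each digestion of an aliquot is read on the corresponding day of
its couple (digestion 1 on day 1, digestion 2 on day 2), and the QC
aliquots are labelled by vial = digestion. An `aliquots (= samples x
digestions x injections)` reading of the layout would conflate aliquots
with digestion-injection readings; the builder follows the aliquot-level
description (6 samples x 4 aliquots) and reproduces both headline counts
(24 aliquots, 16 readings/sample).

## Forward model of the acquisition chain

For each reading, peptide concentrations are
`kappa_i = H_i(y) + N(0, 1/gamma_kappa)` with
`H_i(y) = sum_p g_ip d_ip y_p`; the native transition signal is
`kappa_i * xi_il * C(tau_i, lam_i)(t_n)` plus i.i.d. Gaussian noise of
precision `gamma_n` per time point, and the labeled channel is
`kappa*_i * xi_il * phi*_il * C(...)` with precision `gamma*_n`.

Choices:

- **Peak shape.** The chromatographic response `C` is a Gaussian
  density in time, unit-normalised to integrate to 1 — symmetric,
  two-parameter, matching the position/width semantics of `tau`/`lam`.
  It is a pluggable callable (`peak_shape`) in both the generator and
  the sampler; real LC peaks are often tailed, which this default does
  not emulate.
- **Noise.** Additive Gaussian per time point, i.i.d. across points,
  transitions and channels, as the Gaussian trace likelihood implies.
  No heteroscedastic (shot-noise-like) component, no baseline drift.
- **Day effects.** Day-to-day technical variability enters through
  per-day-couple digestion-yield factors multiplying `g_ip` (the
  mechanism the Bayesian calibration targets; drawn uniformly in
  0.9–1.1 and mean-normalised in the default ground truth) and,
  optionally, per-day-couple gain multipliers.
- **Seeding.** One master seed; each reading draws from a substream
  keyed by a SHA-256 hash of its reading id, so adding or removing
  readings never perturbs the noise of the others (all derived seeds are
  kept below 2^31).
- **Pool sample.** The pool carries no theoretical spike dilution; its
  endogenous protein level is configurable (`pool_y`) and defaults to
  zero, so that the spiked dilution samples stay exactly on the
  two-fold line (an endogenous background would curve the low end of
  the log2-log2 relation). The pool is excluded from the regressions,
  where log2 of its undefined spike level does not exist.
- **Default panel.** Three proteins with 3, 2 and 1 proteotypic
  peptides (3 transitions each) — quantifier behaviour depends strongly
  on peptide multiplicity, and this panel spans the interesting range.
  Parent-solution concentrations ~10 (arbitrary amount units), AQUA
  spikes at a comparable scale, retention times in a 10.5–14.5 min
  window, widths ~0.1 min, trace noise SD 0.2 (peak heights of order
  30 at dilution 1, ~2 at 1/16).

The concentration-table generator (`simulate_concentrations`) is the
phenomenological counterpart: it draws log2 responses directly from the
full dilution-line model (sum-to-zero day-couple offsets on intercept
and slope, i.i.d. Gaussian residuals) and returns linear-scale values so
the analysis stage's log2 step is exercised.
`model1s_params_for_components` converts target variance shares
(e.g. 80/15/5) into generator parameters by anchoring the dilution SS at
the design's log2-x spread for the requested slope; the technical share
is placed entirely on the intercept offsets (evenly spaced, sum-to-zero)
and the noise share on the residual variance against the expected
corrected total. Censoring (`apply_missingness`) is independent
per-reading: missing rows are removed, zeroed rows stay as explicit
zeros and vanish later at the log2 step — the mechanism that makes real
datasets unbalanced.

## Classical (NLP) quantifier

Per transition, the native and labeled areas are trapezoidal integrals
(negatives clipped) over a window centred on the trace-product peak
position, +/- `window_k` (default 4) nominal widths. The log-ratio is
`t = ln(1 + I/I*)`; the protein estimate is the median of t pooled over
all the protein's transitions, zero-status transitions contributing
t = 0 and missing ones excluded.

Conventions where the original workflow is manual:

- **Peak windows** come from the same trace-product initialiser as the
  Bayesian sampler rather than from an operator or vendor software.
- **Censoring** replaces the operator's judgment by signal-to-noise
  thresholds: a channel's SNR is the in-window maximum over a robust
  baseline scale (1.4826 x MAD outside the window); labeled SNR below
  `min_labeled` (default 3) makes the transition missing, native SNR
  below `min_native` (default 3) assigns value 0. The area-threshold
  variant (`censor_transition`) exists for pre-integrated area tables.
- **Back-transform.** The median t is mapped to the concentration scale
  as `(exp(t_med) − 1) * kappa* / (g d)`. With several peptides the
  constant is averaged over the peptides that contributed valued
  transitions; this is a readability convention — the downstream
  analysis is slope/variance on the log2 scale, which a multiplicative
  constant cannot affect. Pooling the median across a protein's
  transitions (rather than per peptide first) is likewise a convention;
  both readings of "median over all transitions" coincide for the
  proteotypic single-peptide case.

## Bayesian (BHI) quantifier

The sampler targets the factorised posterior
`p(y) p(kappa|y) p(tau) p(lam) p(xi) p(phi*) p(gamma) p(gamma*)
p(I|...) p(I*|...)` and sweeps in the order kappa, tau, lam, xi, phi*,
gamma, gamma*, then the target block (y in quantification mode, g in
calibration mode). Point estimates are EAP — empirical means of the
post-warm-up draws; central 95% intervals and posterior SDs accompany
them, plus MH acceptance rates.

- **Conjugate updates.** The conditional mean/precision formulas are
  not given in closed form anywhere authoritative; they follow from the
  Gaussian-linear structure (`gaussian_linear_update`):
  `prec_post = prec_prior + sum a_k^2 gamma_k`,
  `mean_post = (prec_prior m + sum a_k gamma_k z_k)/prec_post`.
  kappa_i's conditional combines its prior around H_i(y) with the
  native traces only (the labeled channel involves the known kappa*,
  not kappa); xi_il is informed by both channels; phi*_il by the
  labeled channel. Identifiability: the labeled channel (known spike)
  identifies xi up to the tightly-prior-constrained phi*; the native
  channel then identifies kappa and hence y.
- **Gamma parameterisation.** The precision prior has density kernel
  `gamma^(alpha-1) exp(-gamma/beta)`, i.e. beta is a SCALE and the
  prior mean is alpha*beta; the conditional adds N/2 to the shape and
  ||residual||^2/2 to the rate 1/beta. This is stated explicitly
  because alpha/beta conventions are the classic trap here.
- **MH kernel.** Plain Gaussian random walk for tau and lam, uniform
  priors as hard bounds (out-of-bounds proposals rejected), no
  adaptation; default step = (bound range)/20.
- **Warm-up** defaults to half the iterations.
- **Initialisation.** tau from the argmax of the pointwise product of
  all the peptide's traces (only a peak present in every trace
  survives; ties break earliest, an all-zero product falls back to the
  window midpoint with a warning); lam from the product's second moment
  (rescaled by sqrt(#traces), since a product of K unimodal traces
  narrows by sqrt(K)); xi from labeled areas / kappa*; kappa from
  native areas / xi; y (or g) by least squares from the initial kappa —
  the kappa <-> target link has precision gamma_kappa and is
  deliberately tight, so a prior-mean start would make the pair mix
  pathologically slowly; the noise precisions start at their
  conditional means given that state.
- **Shared vs per-reading parameters.** tau and lam are shared between
  the native and labeled channels of a peptide (a single peak per
  peptide). When several readings are fitted jointly (the multi-QC
  generalisation of the calibration protocol), kappa, tau, lam get
  per-reading copies while xi, phi*, the noise precisions and the
  target block are shared; a single-reading fit reproduces the basic
  protocol.
- **Fixed hyperparameters.** gamma_kappa is a fixed hyperparameter
  (default 1e4), not estimated. Default priors are weakly informative:
  m_xi = 1 with precision 1e-2, phi* ~ N(1, 1/100), alpha = beta = 1,
  tau bounds the full grid, lam bounds [2 grid steps, span/4], vague
  y prior (precision 1e-6), g ~ N(0.7, 1/10). The (0,1] range of a
  yield is not enforced in the sampler — the model assigns g a plain
  Normal prior — but calibrated yields are clipped into (0,1] before
  re-use for quantification.
- **Implementation.** All conditionals depend on the data only through
  per-peptide projections (native @ C, labeled @ C, C·C and the
  constant sums of squares), so a sweep never forms residual matrices;
  the transitions of a peptide are conditionally independent and draw
  as vectors. Two precursor-chain concentration symbols of the model
  family (precursor-ion and fragment concentrations) never enter the
  signal equations and are not implemented.

## Variance-component analysis

`prepare_log2` drops zero/missing measurements and pool rows, log2s both
axes; `fit_linear_model` builds sum-to-zero-coded design matrices for
models 1S/2S/3S/4S (and the E-family, identical in structure with the
reading order as factor) and fits them by `statsmodels` OLS (QR/pinv
based; results match textbook OLS to well below 1e-9). Rank deficiency
raises an error naming the offending factor level (typically a level
observed at a single theoretical concentration, whose slope is not
estimable) rather than silently dropping terms.

The decomposition reports, as adjusted SS: dilution
(RSS(3S) − RSS(1S), df J), two-day (RSS(2S) − RSS(1S), df 2(J−1)),
interaction (RSS(4S) − RSS(1S), df J−1) and the full-model residual,
split into measurement error `sum (y_ijr − ybar_ij.)^2` over cells
(sample x factor level; the digestion-injection readings are the
replicates — digestion is deliberately not a separate stratum) and lack
of fit (residual − measurement error; the identity is exact because the
full model's fitted values are constant within a cell). On unbalanced
data the residual df is n − (free parameters of 1S) and the
measurement-error df is sum(n_cell − 1); the balanced formulas
(IJR − 2J, (R−1)IJ, IJ − 2J) are recovered on complete data. Tiny
negative adjusted SS from floating-point cancellation are clipped at 0
(the models are nested, so the true values cannot be negative).

Percentages divide by the **corrected** (mean-centred) total SS by
default — percentages then measure shares of variation and are bounded
by 100 — with an `uncorrected` switch since the alternative reading
cannot be excluded. On orthogonal (balanced) data
dilution% + two-day% − interaction% + residual% = 100 exactly; on
unbalanced data the signed discrepancy is reported
(`venn_discrepancy`), not assumed zero. The Bayesian quantifier's 4
same-day yield re-estimates of each reading are treated as additional
replicates within the same (sample, day-couple) cell.

## Method comparison

The correlation screen computes per-protein, per-method Pearson r
between log2 theoretical and log2 measured values; a protein is
retained if r >= 0.7 for at least one method, and zero-variance or
<3-pair series are flagged not-evaluable. The Wilcoxon signed-rank
test drops zero differences, midranks ties, and computes the exact
two-sided p by convolution over all 2^n sign assignments of the doubled
midranks for n <= 20 (the panel-scale regime where exactness matters),
with a continuity- and tie-corrected normal approximation above; both
variants are always computable and the pipeline reports which one it
used. The pipeline's two tests compare the dilution share (the
"theoretical concentration + interaction" percentage) and the technical
share (the "two-day + interaction" percentage plus the measurement-error
percentage — the aggregation matching the technical-variance footnote;
other aggregates can be formed from the component tables, since which
one underlies a published aggregate is ambiguous). No multiplicity
correction is applied; the two tests are not independent.

## Pipeline, problem sizes, determinism

`run_pipeline` wires simulate → quantify (NLP and/or BHI; BHI first
calibrates the 4 daily yields on the QC readings, then quantifies every
sample reading once per same-day yield) → per-protein decomposition →
correlation screen → Wilcoxon comparison, writing all intermediates
with `# seed=… # config=…` headers and a run manifest. The default
configuration runs 600-iteration chains (warm-up 300) for each of the
32 yield calibrations and 96 x 4 quantifications — about 3 minutes on
one CPU for the full reference design; the toy recovery studies in the
tests use 300–500 iterations on single readings. Chains are seeded
deterministically from the master seed, so a rerun is byte-identical;
estimates from chains this short carry Monte-Carlo noise of well under
a percent on the toys, which the recovery tolerances absorb.

## What passing tests do and do not show

The synthetic generator matches the model the quantifiers assume
(Gaussian peaks, additive i.i.d. noise, known digestion factors), so
recovery results demonstrate correctness of the inference machinery,
not robustness to real-data pathologies: retention-time drift between
days, tailed peaks, interfering transitions, matrix effects,
heteroscedastic noise and operator-level censoring are all outside the
generator. The variance-component stage, by contrast, makes no
distributional use of the trace model and its unbalanced-data
properties are tested directly on randomly censored datasets.
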