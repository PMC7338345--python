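# Methods

## The design and its statistics

The L9 orthogonal array assigns four three-level factors to nine runs such
that each level appears three times per column and each ordered level pair
appears exactly once per column pair. Under an additive main-effects model
this makes every level mean an unconfounded effect estimate. The canonical
row order used everywhere in this package is the run order of the bundled
esterification study (run 1 = all level 1; run 6 = levels 2,3,1,2), so
run-indexed outputs line up with that run sheet. Coded levels are 1-based
(1, 2, 3) to match the usual L1/L2/L3 notation. Categorical factors such as
the FFAs:alcohol molar ratio are carried as ordered labels ("1:1", "1:3",
"1:5"); the statistics only ever use the coded level.

`check_orthogonality` validates by exhaustive counting — no algebraic
shortcut — and reports every offending column and column pair; this is also
the test oracle for the design module.

### Signal-to-noise ratio

The larger-is-better statistic per run is

    S/N = −10 log10( (1/n) Σ_i 1/y_i² )   [dB],

defined for strictly positive responses and equal to 20 log10(y) for a
single observation (n = 1, the bundled study's case). Properties relied on
by the test suite: monotonicity in a single response, the Jensen bound
S/N ≤ 20 log10(max y) for replicates, and scale equivariance (multiplying
all responses by c adds 20 log10 c to every S/N, leaving deltas, ranks and
ANOVA F/p unchanged). S/N values are kept at full precision; 1-decimal
rounding is applied only in reports.

### Response table and ranking

Level means are arithmetic means of S/N over the three runs at each level;
delta = max − min; rank 1 = largest delta, ties broken by factor column
order (deterministic reports; the bundled data has no ties). The bundled
study has a documented near-tie in the temperature column: level 1 (29.84
dB) beats level 2 (29.71 dB) by ~0.1 dB, within the rounding of the
published table; the package follows the full-precision argmax.

### Optimum prediction

    S/N_pred = S̄/N + Σ_j ( S/N_j − S̄/N )

over the selected factors at their chosen (default: argmax) levels, with
the single-observation back-transform 10^(S/N_pred/20). The prediction is
additive on the dB scale and can exceed the 100% physical bound — for the
bundled study it does (43.6 dB ≈ 151%). Such values are reported unclipped
with an `exceeds_physical_bound` flag: clipping would hide the
extrapolation error, and no published headline figure is reproduced or
hard-coded in its place.

### ANOVA, pooling, contribution

For a complete single-replicate design, SS_f = Σ_k n_k (mean_k − grand)²;
for a saturated L9 the four factor SS sum exactly to the total SS (this
identity, at 1e−9 relative, is a standing regression check). Because the
design is saturated, F tests require pooling: the default "smallest-ss"
strategy folds factors in increasing-SS order into the residual until it
holds 2 degrees of freedom (for the bundled study this pools the time
factor). Then F_f = MS_f/MS_residual with p from the F(2, 2) survival
function, which analytically equals 1/(1+F) — used as an independent oracle
in the tests. Percent contribution is 100·SS_f over the sum of SS across
all factors, pooled included, which is the convention consistent with the
bundled study's published percentages. Degenerate input (constant S/N)
yields NaN F/p/contributions with a `degenerate` flag rather than division
errors. The table always reports df, SS and MS as separate columns.

## Bioprocess calculators

- **Acidity index** AI = MM·M·f·V/m (mg NaOH per g sample; V in mL).
  MM defaults to 40.00 g/mol and is overridable for other titrants.
- **FFA conversion** 100·(AI_blank − AI_sample)/AI_blank. Values outside
  [0, 100] are flagged (`negative`, `over-100`) instead of clamped, so
  titration faults surface in the output.
- **Hydrolytic activity** (p-NPB at 348 nm): Beer–Lambert converts the
  absorbance slope to a molar rate ΔA/(ε·ℓ); scaling by the cuvette volume
  and referring back to the enzyme dose gives U/mL with U = µmol/min.
  Defaults: ε = 5150 M⁻¹cm⁻¹, 1 cm path, 2.6 mL reaction volume (50 µL
  enzyme + 50 µL substrate + 2.5 mL buffer).
- **Immobilization**: yield IY = 100(A_i − A_f)/A_i from supernatant
  depletion (negative retention flagged, not raised); theoretical activity
  At_T = offered load × IY/100; recovered activity At_R = 100·At_B/At_T.
  The literature uses At_D and At_B interchangeably for the measured
  biocatalyst activity; this package standardizes on At_B.
- **Thermal deactivation**: single-exponential (first-order) decay is the
  simplest model consistent with reporting one half-life, t_1/2 = ln2/k.
  The fit is least squares of ln(activity) on time, by default weighted by
  activity: when measurement noise is additive on the activity scale the
  noise of ln A scales as 1/A, so weights ∝ A (variance weights ∝ A²) are
  the Gauss–Markov-consistent choice and stop the noisy late tail from
  dominating the slope. `weighted=False` gives the plain OLS fit. The R² of
  the (weighted) log-linear fit is reported so non-first-order decay is
  visible rather than silently averaged away. A fitted k ≤ 0 raises a
  no-decay error. Two points suffice for the definition-level fit; the
  synthetic generator requires at least three so the fit retains a residual
  degree of freedom.

## Synthetic data: what it emulates and what it does not

`simulate_doe` draws y(run) = µ + Σ_f offset_f[level] + N(0, σ) on the
conversion (%) scale — noise is additive on the measured quantity, not on
the dB scale — floored at 0.1% so the S/N transform stays defined. The
default "study-like" scenario (µ = 40%, σ = 1%, single replicate) plants a
biocatalyst-dominated effect structure with deltas ordered
Biocatalyst > Molar ratio > Temperature > Time, qualitatively matching the
bundled study's ranking; conversions span roughly 3–75%. Offset gaps are
wide enough that each factor's best level survives the concave dB
transform, so the noiseless pipeline recovers the planted optimum exactly —
a generator design constraint, since dB-level means of a %-additive model
can reorder levels whose offsets differ by less than the cross-factor
log-curvature.

`simulate_titration` back-solves the NaOH volume from a target acidity
index and quantizes it to burette resolution (default 0.05 mL), bounding
the recovery error by MM·M·f·res/(2m). `simulate_decay` is exponential
decay plus additive Gaussian noise, floored positive, with the t = 0 point
fixed at the initial activity (residual activity is defined relative to
it).

What the generators do **not** emulate: reaction mechanism (no Ping-Pong
Bi-Bi kinetics or equilibrium thermodynamics), factor interactions,
replicate heteroscedasticity, or titration endpoint bias. Passing tests
therefore demonstrate that the statistical chain is implemented correctly
under its own assumptions — not that those assumptions hold for any
particular wet-lab system.

Seeding: generators split a single integer seed through numpy's
`SeedSequence`, so identical seeds reproduce outputs bit-for-bit.

## Numerical choices and known limitations

- Problem sizes: every analysis is a 9-run design; Monte-Carlo checks use
  100 seeds (half-life recovery) and 200 seeds (effect-ordering recovery),
  which resolve the tested rates comfortably at negligible cost.
- The bundled study's published per-run S/N column is reproduced to 0.1 dB
  (the table's printed precision) for all nine runs, and exactly at one
  decimal for eight: the 5.4%-conversion run prints 14.7 dB where
  20·log10(5.4) = 14.648 — the source table evidently computed S/N from an
  unrounded conversion near 5.45%. The package computes from the inputs it
  is given and does not special-case this run.
- The published ANOVA's "Total" row (670.8) mixes three factor SS with the
  residual mean square; the self-consistent total SS of the nine dB values
  is 682.3 and that is what this package reports. All published F, p and
  contribution values are nevertheless reproduced under the residual
  convention described above (pooled-time residual: SS 20.4, df 2,
  MS 10.2).
- Only the larger-is-better S/N variant is implemented (no
  smaller-is-better or nominal-is-best), only three-level designs with the
  L9 catalogue entry, and no interaction columns — matching the scope of
  the analyses this package automates.
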