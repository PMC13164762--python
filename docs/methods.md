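# Methods

This note documents the models, conventions and design choices behind
the package, in the spirit of a statistical-methods appendix: what each
computation assumes, which knobs matter, and what the synthetic-data
tests do and do not demonstrate about real data.

## Calibration and validation statistics

Calibration is ordinary weighted least squares of the analyte-to-IS
peak-area ratio on nominal concentration. The default weighting is
1/x², which assumes the response error is proportional to
concentration — the empirically dominant error structure for LC-MS/MS
assays spanning three or more orders of magnitude. The reported r² is
the weighted coefficient of determination (1 − weighted SS_res /
weighted SS_tot about the weighted mean), the standard definition for
weighted bioanalytical fits. Back-calculation inverts the fitted line
and flags, but never clamps, results outside the calibrated range.

Accuracy is % bias of the replicate mean from nominal; precision is
% RSD using the sample (n−1) standard deviation, the small-n
convention. Inter-day statistics pool all replicates across runs rather
than averaging daily means: pooling matches batch-acceptance practice
and gives the SD the interpretation of total (within + between run)
variability. Acceptance limits default to ±20%/20% at the LLOQ and
±15%/15% elsewhere; carryover must stay within 20% of the LLOQ analyte
response and 5% of the IS response; storage stability within 85–115% of
fresh. All limits live in one `ThresholdSet` so every pass flag in a
report is a pure function of the stored statistics, re-derivable
without the raw data.

Blanks and zero-concentration samples are excluded from calibration
fitting; the curve is anchored on nine non-zero standards
(0.2–500 ng/mL by default). The module consumes back-calculated
concentrations and area ratios — peak integration is upstream and out
of scope.

## Microsomal stability and IVIVE

Substrate depletion is assumed first-order: the log response ratio is
fit by OLS against time, k = −slope, t½ = ln 2/k. A non-positive k
(stable compound, NADPH-free control) is a flagged outcome, not an
error, because "no measurable depletion" is a legitimate assay result.
Intrinsic clearance uses the fixed nominal incubation volume; the small
volume loss from serial sampling is ignored, consistent with how the
assay equation is conventionally applied.

Scaling constants are per species: 45 mg microsomal protein/g liver and
60 g liver/kg body weight for mouse, 32 and 25 for human; mouse hepatic
blood flow Q = 90 mL/min/kg and plasma fraction unbound 0.025. The
human entry deliberately carries no Q or fu,plasma, so the chain stops
at CL_H,int for human unless the caller supplies both — predicting
human in vivo clearance requires a deliberate parameter choice, not a
silent default.

Nonspecific microsomal binding is corrected with the lipophilicity
relationship fu_inc = 1/(1 + 10^(0.53·logP − 1.42)), valid for
basic/neutral drugs at 0.5 mg/mL protein; it is strictly decreasing in
logP with range (0, 1). The well-stirred model then gives
CL_H,pred = Q·fu_p·(CL_H,int/fu_inc) / (Q + fu_p·(CL_H,int/fu_inc)),
which is strictly increasing in intrinsic clearance and bounded above
by Q (flow-limited extraction); in the low-extraction limit it reduces
to fu_p·CL_H,int/fu_inc.

## Binding, partitioning, solubility, permeability

Protein binding from rapid equilibrium dialysis is
100·(donor − receiver)/donor; fu is the complement. The blood-to-plasma
ratio is a plain concentration quotient.

Kinetic solubility has no universally agreed formula when reported from
a dilution series; this package uses a plateau rule: a nominal level
counts as saturated when measured < 0.8·nominal (threshold
configurable), and the solubility is the mean measured value over
saturated levels. A fully soluble series returns the highest measured
value with an `unsaturated` flag.

PAMPA uses the closed-form two-chamber mass balance,
Papp = −ln(1 − Ca(t)/Ceq)/(A·(1/Vd + 1/Va)·t) with
Ceq = (Cd·Vd + Ca·Va)/(Vd + Va). The assay-sheet presentation of this
formula sometimes mixes the symbols for initial and equilibrium
concentrations; the mass-balance form implemented here is the one that
is exact for passive diffusion between two stirred chambers and
reproduces the standard plate geometry (0.3/0.2 mL, 0.3 cm², 5 h). An
acceptor at or above Ceq means the assay has equilibrated and Papp is
unidentifiable — that is an error, not a large number.

Caco-2 Papp is (dQ/dt)/(A·C0) with dQ/dt the least-squares slope of the
cumulative transported amount. Because each receiver sample physically
removes analyte (0.1 mL replaced by blank buffer), the cumulative
amount at sample n is C_n·V_receiver + Σ_{i<n} C_i·V_withdrawn; without
this correction the estimate is strictly biased low (about 13% low for
the default 4-sample, 1.5 mL design). The regression uses all sampled
points by default — the common 0–120 min design is within the linear
phase for moderate permeability — with an optional user window for
compounds that deviate. A recorded TEER below 400 Ω·cm² flags the
monolayer as failed; the value is still computed so the flag is
auditable.

Molar conversion uses ng/mL = µM × molar mass, default molar mass
483 g/mol (from the protonated precursor at m/z 484).

## Non-compartmental analysis

The default integration rule is the linear trapezoid, chosen for
determinism and because it is exact on piecewise-linear profiles;
linear-up/log-down is available by flag and is exact on
mono-exponential decline. The rule used is recorded in each result.

λz selection: candidate windows end at the last quantifiable positive
sample and grow backwards, excluding Cmax and anything earlier; among
windows of ≥3 points the highest adjusted r² wins, ties to the fewer
points. A profile in which no window yields a positive slope has no
identifiable terminal phase; extrapolated quantities are then absent
rather than fabricated. AUC∞ = AUC_last + C_last/λz, and CL and Vz are
computed from AUC∞ (Dose/AUC convention), as CL/F and Vz/F for oral
data with an explicit `normalize_oral_by_F` step rather than a hidden
correction.

BLQ convention: samples below the LLOQ before Tmax are set to zero
(absorption not yet started); embedded and trailing BLQ samples are
excluded. Units are fixed (h, ng/mL, mg/kg) so CL = 1000·Dose/AUC∞ in
L/h/kg. Group statistics are computed per subject and then summarised
as arithmetic mean ± sample SD.

## Synthetic data: what it emulates and what it does not

Generators use the study designs as defaults: the 8-point in vivo
sampling schedule (5 min–24 h) with LLOQ 0.2 ng/mL, the 7-point
microsomal schedule (0–60 min) at 0.5 mg/mL protein in 0.5 mL, the
9-level 0.2–500 ng/mL calibration series with QCs at 0.2/0.5/100/375
ng/mL, and the standard PAMPA/Caco-2 geometries. PK profiles are
one-compartment closed forms (IV bolus; first-order absorption oral),
with lognormal between-subject variability (median-preserving,
default CV 30% — sized so simulated group summaries show the 30–40%
SD/mean spread typical of small-n mouse PK) and proportional residual
error. All randomness flows through one seeded generator; a fixed seed
reproduces CSV output byte-for-byte.

What passing round-trip tests show: the estimators are correct
inverses of these generating models at the stated tolerances. What they
do not show: robustness to multi-compartment kinetics, enterohepatic
recirculation, absorption lag, correlated assay drift, or non-lognormal
outliers — none of which the generators produce. At the study's own
noise level, note that a single 7-point depletion curve with 5%
response noise carries a ~20% standard error on k; recovery claims at
that noise level are therefore tested on replicate means.

Problem sizes in the test suite and acceptance script are the study's
own (n = 4–6 subjects per arm, n = 100 only for the stochastic
clearance-recovery check), which keeps the full suite to a few seconds.

## Rounding policy for printed-table reproduction

Published disposition tables round each value before deriving ratios
from the printed cells. The `printed` policy reproduces that: two
significant figures below 10, nearest integer at or above 10, ratios to
two decimals, with ratios formed from the already-rounded numerator and
denominator. Full precision (`none`) is the computational default. One
known irreproducibility is retained deliberately: the 24 h unbound
brain-to-plasma ratio computes to 32.8 (full precision) or 32.5
(printed policy) from its own table entries, while the published cell
reads 33.3; the comparison utility flags such cells rather than
matching them.

## Pipeline determinism

`run_pipeline` output is a pure function of (inputs, config, seed):
reports carry no timestamps, JSON keys are sorted, and every operation
appends a provenance record with the parameters it used, so a report
can be audited line by line. Missing inputs skip their section; schema
violations abort with 1-based row numbers.

## Known limitations

* One-compartment NCA truth models only; sparse-sampling (naive-pooled)
  NCA is not implemented beyond group means.
* The fu_inc relationship is an empirical average; for acids or very
  high logP it can misestimate microsomal binding.
* Caco-2 supports the absorptive (A→B) direction as modelled; efflux
  ratio requires running the assay both ways and is left to the caller.
* The solubility plateau rule is a pragmatic default, not a pharmacopeial
  definition.
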