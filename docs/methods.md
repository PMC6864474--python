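# Methods

This note documents the models, conventions and design choices behind
`nirleaf`, in the order data flows through the package.

## Study structure and data model

The package models a leaf-survey design: 27 *Vaccinium* cultivars (24
*V. corymbosum*, 3 *V. ashei*), 35 plants, sampled in up to three Portuguese
regions (RA Northern Coast, RB Northern Inland, RC South Inland) and three
seasons (spring/May, fall/September, winter/December).  Region RA carries all
three seasons; RB and RC only spring.  A *sample* is a cultivar × region ×
season cell; each sample has three assay reference values (TPC, TFC, TAC,
reported as mean ± SD of quadruplicate assays) and five replicate NIR
diffuse-reflectance spectra on a shared 10000–4000 cm⁻¹ grid.

Spectra are stored on strictly descending wavenumber grids (instrument
convention); all spectral windows are closed intervals [low, high] in cm⁻¹,
inclusive at both ends.  The published reference tables are shipped as CSV
fixtures with missing cells absent, never imputed; the harvest-month column of
the plants fixture is derived from the seasons in which each cultivar has
printed assay values, and berry presence (printed as cell shading) is not
recoverable from the source text, so that column is present but empty.
Replicate spectra are kept as separate rows by default (averaging is
available via `average_replicates`), and the six data-set designs are: (1)
everything; (2) RA, all seasons; (3) spring, all regions; (4) spring RA;
(5) fall RA; (6) winter RA.

## Preprocessing

The chain is SNV → Savitzky-Golay first derivative → mean centering, in that
order (the order is configurable via `snv_first` since both orders are common
practice).

* **SNV** standardises each spectrum with the sample standard deviation
  (n−1).  A constant spectrum is an error, not a silent zero.
* **Savitzky-Golay** uses window 15, polynomial order 2, derivative order 1
  by default.  Edge points — the first and last (window−1)/2 = 7 — are
  *dropped* rather than extrapolated, so the default 751-point grid shrinks
  to 737 points and the grid bookkeeping is explicit.  The derivative is
  expressed per index step of the stored grid, not per cm⁻¹: on a
  constant-spacing grid the two differ by a constant factor that centering
  and PLS absorb, but reported regression vectors are on the index scale.
* **Mean centering** is always computed on calibration rows only and applied
  to whatever rows are being transformed; inside PLS the calibration means of
  X and y play this role.

## PLS1 calibration

NIPALS PLS1 with deflation of X only (for a single response, deflating y as
well provably yields the same weight sequence).  Components are extracted in
order; requesting more components than the data's rank truncates with a
warning.  The regression vector b = W(PᵀW)⁻¹q plus the stored centering
vectors let a model predict directly from preprocessed, uncentered spectra.

**Cross-validation unit.** LOOCV leaves one *sample* out: all replicate
spectra of a sample are held out together and the centering is recomputed on
each fold's training rows.  Leaving single spectra out while four sibling
replicates remain in training is leakage and gives optimistic RMSECV; the
spectrum-level variant is available behind `group_folds=False` for fidelity
experiments.

**Latent-variable choice.** The smallest k whose RMSECV is within 2% of the
curve minimum (tolerance configurable; 0 gives the global minimum).  A pure
minimum tends to overfit at these sample sizes; the parsimony rule is
deterministic and errs toward simpler models, capped at `max_lv = 10`.

**Region search.** Five base regions — 10000–7501, 7500–6316, 6315–5390,
5389–4926 and 4925–4073 cm⁻¹ — are combined exhaustively (all 31 non-empty
subsets, enumerated in binary-counting order; contiguous intervals merge).
For each combination the columns are masked, grouped LOOCV is run, the LV
count selected, and the winner is the combination with the lowest RMSECV at
its selected LV count; exact ties break toward fewer intervals, then fewer
LVs, then enumeration order.  The third and fifth base regions are the
phenolic windows of interest; the five boundaries are configurable.

## Evaluation

The 70/30 calibration/prediction split is drawn at the sample level
(replicates never straddle the split), stratified by reference-value quartile
so the prediction range sits roughly inside the calibration range, and is
deterministic given a seed (default 2017, the harvest year).  Region and LV
optimization sees calibration rows only.

Figures of merit follow the standard definitions: RMSE on the respective
rows; R² = 1 − SSres/SStot about the respective set's own mean; R²_CV
computed from RMSECV against the calibration set's variance; and
RER = Δy/RMSEP with Δy the prediction set's reference range by default
(calibration or pooled ranges are selectable, since the convention varies
between papers).  RMSEP = 0 reports RER = +∞ with a warning.  Quality labels:
RER < 10 insufficient, 10 ≤ RER < 15 quality control, RER ≥ 15
quantification.

**Transferability.** Entry (i, j) of the transferability matrix applies the
model trained under design i's calibration protocol to design j's prediction
samples; the diagonal reduces exactly to the single-design run.  Off-diagonal
entries share design i's RMSEC/RMSECV (properties of the trained model) and
report RMSEP/R²_P/RER against design j's prediction rows.  When designs
overlap (e.g. design 4 inside design 1), off-diagonal evaluation rows can
include samples the model calibrated on; the seasonal designs 4/5/6 are
disjoint and are the intended contrast.

## Synthetic data generator

The generator exists because no raw spectra were deposited; it reproduces the
statistical structure the pipeline relies on, not leaf physics.

**Reference values.** Each cultivar draws one uniform base value per
parameter inside the published ranges (TPC 39.6–272.8, TFC 41.2–269.1,
TAC 22.6–124.8); season and region offsets (defaults: fall −20, winter +40,
RA +10, matching the published qualitative ordering) shift it, and the result
is clipped back into the range.  Basing the draw on the cultivar makes
season contrasts consistent within a cultivar, as observed.  Assay SDs are a
uniform 1–4% fraction of the mean.

**Spectra.** Absorbance is a constant pedestal (0.5 AU) plus three large
fixed matrix bands (water analogues at 6900 and 5157 cm⁻¹, broad background
at 8500 cm⁻¹; peak 1.6–3.0 AU) plus per-parameter analyte signatures scaled
by concentration, all under per-replicate multiplicative scatter (SD 0.02),
baseline intercept/slope draws (SD 0.01/0.005) and white noise (SD 0.001 by
default).

Three structural choices matter and are deliberate:

1. **Analyte signatures are zero-net-area doublets** (a positive and an
   equal-area negative Gaussian lobe, all lobes inside 6315–5390 or
   4925–4073 cm⁻¹).  This encodes mass closure in a powdered mixture — more
   of one constituent displaces matrix absorbance — and it makes the
   per-spectrum SNV scale independent of composition.  Without it, the SNV
   normalisation factor carries a scalar summary of analyte load which, after
   the derivative, is linearly readable only from the large matrix bands in
   the *uninformative* regions, quietly making those regions predictive and
   the region search unable to prefer the true windows.
2. **Lobe sharing creates realistic collinearity**: the 6000 cm⁻¹ lobe is
   shared by TPC and TFC, the 4500 cm⁻¹ lobe by TPC and TAC.  Consequently
   TPC is not identifiable from either window alone and the exhaustive search
   genuinely needs the pair — mirroring why the real calibrations settled on
   both windows.  (TFC and TAC each have one private lobe, so their winning
   combinations are not forced.)
3. **Band positions jitter**: matrix-band centers drift per sample
   (SD 5 cm⁻¹, moisture-state analogue) and per replicate scan (SD 2 cm⁻¹),
   and analyte-band centers drift per sample (SD 2 cm⁻¹).  Position shifts
   leave the spectrum's variance — hence the SNV scale — essentially
   unchanged, so the matrix regions become *pure structured nuisance* that
   grouped LOOCV penalises, while the analyte jitter gives the noise-free
   limit a realistic error floor instead of machine-precision degeneracy.
   Setting the jitter and amplitude-variation SDs to zero recovers a plain
   fixed-band additive model.

Season-specific spectral shift bands (`season_shift_bands`, default none)
inject a per-season additive band for transferability experiments.

**What passing tests show — and don't.** The generator produces linear,
Gaussian-band spectra with mild, well-behaved nuisances.  Real leaf spectra
add non-linear scatter, correlated chemistry between the three parameters,
instrument drift and sparser designs; prediction metrics obtained here
(R²_P ≈ 0.99+, RER in the hundreds) characterise pipeline correctness, not
expected field performance, which the original study found in the
R² 0.84–0.99, RER 11–27 range.

## Assay arithmetic and statistics

Standard curves are ordinary least-squares lines (absorbance vs
concentration) for gallic acid, catechin and Trolox.  Contents convert as
content = concentration × dilution × solvent volume / leaf mass with the
protocol constants 50 mg leaf, 20 mL solvent and 50×/10×/50× dilution for
TPC/TFC/TAC (so 10 mg/L diluted TPC reads back as 200 mg GA/g).  Group
comparisons use Welch's t from summary statistics with Welch–Satterthwaite
degrees of freedom — the robust default when only quadruplicate mean ± SD
values are available and the original test is unspecified.  Zero-variance
degenerate inputs use the convention p = 1 (equal means) or p = 0 (unequal);
no multiple-testing correction is applied by default, with a Bonferroni
divisor available.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the default
study size (27 cultivars × 5 designs-cells × 5 replicates = 675 spectra) for
the headline recovery checks, and scaled-down configurations (10–12
cultivars, single region) for repeated-seed checks such as region-search
recovery, noise-response monotonicity and the transferability contrast —
sizes chosen to exercise every code path with comfortably repeatable runs.

## Known limitations

* JCAMP-DX support covers single-block `XYDATA=(X++(Y..Y))` AFFN files with a
  linear abscissa only; no compressed (SQZ/DIF) forms.
* No resampling between unequal grids: spectra must share one grid.
* The simulator is additive-Gaussian by construction: no radiative-transfer
  or instrument line-shape modelling, no simulation of 64-scan averaging.
* Exact boundaries of the five published base regions were not printed in
  the source; the defaults here contain the two known winning windows as
  exact base regions and are configurable.
* Off-diagonal transferability entries may evaluate on samples seen in
  training when designs overlap (documented above).
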