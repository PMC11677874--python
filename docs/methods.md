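# Methods

## Model overview

`dphpbpk` implements a whole-body, perfusion-limited physiologically based
pharmacokinetic (PBPK) model of diphenhydramine, a lipophilic first-generation
antihistamine (log P 3.27) that is a moderate-to-strong monoprotic base
(pKa 8.98), ~82 % bound to albumin, eliminated almost entirely by hepatic
CYP metabolism (CYP2D6 ≫ CYP2C19 ≈ CYP1A2 ≈ CYP2C9) with a small renal
component (0.01 L/h/kg).

The body is represented by fourteen perfusion-limited tissues (lung, brain,
heart, kidney, liver, gut, spleen, stomach, muscle, skin, adipose, bone,
gonads, and a lumped rest tissue) plus arterial and venous blood pools. Drug
is carried in plasma; each tissue equilibrates instantaneously with its
perfusing plasma according to a tissue:plasma partition coefficient, so organ
outflow concentration is C_tissue/Kp. Gut, spleen and stomach drain through
the portal vein into the liver, producing hepatic first pass for oral doses.
Amounts are tracked in µg and every elimination pathway accumulates into an
explicit ledger, so the mass balance `dose = Σ compartments + Σ eliminated`
is checked at every output time (tolerance 10⁻³ relative; the integrator is
run at rtol 10⁻⁸, atol 10⁻¹⁰ µg, so the realized error is ~10⁻¹⁵).

### Assumptions

* **Perfusion-limited distribution.** Diphenhydramine is a BCS class I
  compound with high Caco-2 permeability; membrane permeation is not rate
  limiting, so no permeability-limited sub-compartments are modeled. The
  printed "specific organ permeability" (0.19 cm/min) is stored as metadata
  only.
* **Plasma-borne transport.** The circulating pools carry the plasma
  concentration; the blood:plasma ratio enters only the partition-coefficient
  calibration (below), not the convective transport. For a compound with
  B:P near 1 the approximation is small against the 2-fold verification
  bands used throughout.
* **Hepatic-only CYP metabolism.** The four enzymes act in the liver;
  gut-wall metabolism is excluded. First-pass loss arises from portal
  routing alone.
* **Single-dose regimens.** No accumulation, enterohepatic recycling, or
  metabolite tracking.

## Tissue partitioning

Tissue:plasma partition coefficients use the Rodgers–Rowland scheme for
moderate-to-strong bases (pKa > 7), in which partitioning into lean tissue is
dominated by electrostatic association of the ionized species with acidic
phospholipids. With X = 1 + 10^(pKa−pH_iw), Y = 1 + 10^(pKa−pH_p):

    Kpu = f_EW + (X/Y)·f_IW + Ka_AP·[AP]·10^(pKa−pH_iw)/Y
          + (P·f_NL + (0.3P + 0.7)·f_NP)/Y
    Kp  = fu · Kpu

with intracellular pH 7.0, plasma pH 7.4 and erythrocyte pH 7.22. The
association constant Ka_AP is back-calculated from the erythrocyte partition
implied by the blood:plasma ratio and hematocrit. Adipose uses the
vegetable-oil convention for the neutral-lipid term
(log P_vo = 1.115·log P − 1.35). Tissue compositions (water, neutral lipid,
neutral phospholipid fractions; acidic phospholipid content) are packaged
literature values in `data/tissue_composition.csv`; stomach and the lumped
rest tissue are assigned gut-like and lean-average compositions.

**Blood:plasma ratio (sensitivity).** Kp for every lean tissue is steeply
sensitive to B:P because the erythrocyte residual calibrates Ka_AP. At
B:P = 0.8 the predicted steady-state volume is ~1.9 L/kg with a terminal
half-life of ~2 h; at B:P = 1.1 they are ~4.5 L/kg and ~4–5 h, matching the
literature consensus for diphenhydramine (Vss ~3–8 L/kg, t½ 4–9 h). The
packaged default is therefore 1.1, overridable in the drug config; users
fitting other compounds should treat this as a first-rank input.

## Absorption

Oral tablets follow the Lint80 convention: the dissolved fraction rises
linearly at 0.8/T80 per unit time, reaching 80 % at the stated dissolution
time (default 45 min) and completion at 1.25·T80. Dissolved drug empties
from the stomach with a first-order half-life of 0.5 h and is absorbed from
the intestinal lumen into gut tissue at

    ka = P_caco2 (cm/s) · 3600 · (2/r),  r = 1.75 cm

i.e. the smooth-cylinder surface-to-volume transform at the reference human
jejunal radius, giving ka = 2.23 h⁻¹ for the Table-value permeability. The
combination (dissolution 45 min, emptying 0.5 h, ka 2.23 h⁻¹) puts the adult
oral Tmax at ~2 h, consistent with clinical reports (2–3 h). Absorption is
complete (no lumenal loss); solubility never limits dissolution for the
studied doses (largest dose dissolves in ~29 mL; a guard rejects doses
needing ≥250 mL).

## Hepatic metabolism and IVIVE

Each CYP contributes a Michaelis–Menten sink driven by the unbound liver-exit
plasma concentration Cu (well-stirred liver):

    rate_e = CF · expr_e · abundance_e · MPPGL · m_liver · Vmax_e · Cu/(Km_e + Cu)

with Vmax in pmol/min/pmol recombinant enzyme and Km in µM (packaged values:
CYP1A2 14/295, CYP2C9 4.43/134, CYP2C19 11/55.7, CYP2D6 2.38/1.12). Enzyme
abundances (52, 73, 14, 8 pmol/mg microsomal protein) are literature-typical
hepatic means; with these, CYP2D6 carries ~69 % of intrinsic clearance, so
its knockout dominates single-enzyme effects. MPPGL follows the published
cubic-in-age log₁₀ polynomial (≈29 mg/g at age 4, 40 at 30 y, declining in
old age). Because absolute abundances and MPPGL are uncertain, a single
global calibration factor CF multiplies all four intrinsic clearances.

**Calibration.** CF is fitted once, by Brent root finding, so that the
simulated adult (33.5 y male) IV 50 mg plasma clearance equals the IV-route
reference clearance 59.44 L/h, and is then reused unchanged for every
population, dose, and scenario (stored in the drug config; CF = 5.80).
The observed IV clearance (88.34 L/h) is not an admissible target for a
flow-limited liver: with hepatic plasma flow ≈99 L/h it would force an
extraction ratio of ~0.89 and oral bioavailability ~0.11, while every
observed oral exposure in the same dataset implies F ≈ 0.7–0.9. The IV
reference value keeps the IV prediction within the 2-fold verification band
while preserving oral exposures; at it, the adult extraction ratio is ~0.53
and F ~0.47. Saturation of CYP2D6 (Km 1.12 µM) during first pass makes oral
exposure mildly superlinear in dose, which the observed high-dose rows also
show.

Renal elimination is linear: CL_R = 0.01 L/h/kg × body weight × GFR fraction,
driven by the arterial plasma concentration. For a linear (low-dose) run the
simulated NCA clearance reproduces the closed-form well-stirred + renal
clearance to <0.5 % (the IV mixing transient, time constant V_ven/CO ≈ 0.01 h,
must be resolved by the output grid for the quadrature to see this).

## Physiology and pediatric scaling

Virtual individuals (ages 2–100 y; neonates and infants are out of scope) are
built from packaged tables: growth-reference median weight/height by age and
sex; organ volume fractions of body weight on an age grid (2, 5, 10, 15,
30 y) anchored to ICRP-style reference anatomy (e.g. liver 0.43 kg at 12.5 kg,
0.83 kg at 32 kg, 1.8 kg at 73 kg); regional blood flow fractions of cardiac
output, with the lumped rest tissue taking the exact remainder so flow
conservation holds by construction; cardiac output scaling with body weight
to the 0.75 power and declining 0.45 %/y after age 35; an albumin-vs-age
ratio (near-adult from age ~2, mildly reduced in the elderly) that scales the
fraction unbound via fu' = 1/(1 + r·(1−fu)/fu); and Hill-type CYP ontogeny
curves (CYP2D6 and CYP2C9 near-adult in the first year, CYP2C19 intermediate,
CYP1A2 slowest). GFR maturation is ≈1 for all supported ages and exists so
renal-impairment scenarios can scale the same field.

The net pediatric effect on weight-normalized oral exposure is the product of
opposing factors: larger liver per kg (↑clearance), lower MPPGL and residual
ontogeny (↓), and slightly higher fu (↑). With the packaged tables, apparent
oral clearance per kg is ~3–10 % lower across the pediatric bands than in
adults, so dose-normalized AUC is modestly higher in children — the direction
the comparative age-band scenario reports.

## Virtual populations

Cohorts (default N = 1000) sample ages uniformly in the cohort range, assign
sex by exact rounding of the female fraction followed by a seeded shuffle,
take growth-table weights scaled by a lognormal body-size multiplier
(CV 20 %), and apply independent lognormal multipliers (natural-scale mean 1,
CV 35 %) to each CYP's expression. The CVs are typical virtual-population
magnitudes — the source material states that enzyme CVs were "maintained"
without printing them — and are editable per run. Summaries report the
arithmetic mean, 5th–95th centiles (linear interpolation on order statistics)
and min–max pointwise, plus a per-individual NCA table. Age-band comparisons
reuse the same seed across bands (common random numbers) so between-band
contrasts are paired draw-for-draw rather than masked by multiplier noise.

## NCA

AUC0–t uses the linear-up/log-down trapezoid; λz is the best adjusted-R²
log-linear fit over the last 3–6 points after Tmax; AUC0–∞ adds Clast/λz;
CL = dose/AUC0–∞, reported per kg when the dose was per kg (the pediatric
summary rows are only consistent with L/h/kg and are treated as such). For
IV-bolus curves whose first sample is post-dose, C0 is back-extrapolated
log-linearly from the first two samples. Curves with no positive terminal
decline report λz and AUC0–∞ as undefined with a reason rather than a number.

## Verification statistics

R = predicted/observed per parameter; AFE = 10^(mean log₁₀ R), the
sign-preserving geometric mean (the absolute-log variant AAFE is a separate
optional output); the acceptance screen flags ratios outside [1/2, 2].
Reports retain full precision and, where printed per-population AFEs exist,
show the recomputed value plus a deviation column — two printed values
(elderly Cmax 0.92, pediatric AUC 1.11) do not reproduce from the rounded
table entries and are reported as deviations, never forced. One transcribed
quotient (82.28/165.02 = 0.4986) prints as 0.50; screens quoted against the
printed table are judged at its 2-decimal precision.

## Impairment scenarios

Renal and hepatic impairment are multiplicative physiology modifiers applied
to sampled adults: CKD stages 3/4/5 scale GFR to 0.5/0.25/0.08 of normal,
with stage 5 (ESKD) adding dialysis-associated hypoalbuminemia (albumin
×0.8); Child–Pugh A/B/C reduce hepatic/splanchnic flow (×0.85/0.65/0.45,
redistributed to the rest tissue so cardiac output is conserved), CYP
expression (×0.70/0.45/0.25) and albumin (×0.90/0.75/0.60) while increasing
portosystemic shunt (0.10/0.25/0.45). Because renal clearance is ~1 % of
total, CKD 3/4 leave exposure essentially unchanged; in ESKD the
hypoalbuminemia-driven rise in fu (and hence hepatic clearance of this
low-extraction base) outweighs the lost renal pathway, so exposure falls —
this direction holds under the packaged albumin-dominant modifier and is a
documented sensitivity, not a universal invariant. Cirrhosis grades increase
exposure monotonically through reduced intrinsic clearance, reduced hepatic
flow and shunting. Only adult impaired cohorts are simulated.

## Synthetic observed data

The observed concentration–time datasets behind the published summaries are
digitized figures that cannot be redistributed; the synthetic-data module
emulates them instead: per-subject simulation under the twelve study designs
(cohort demographics and doses as printed; sampling schedule 0, 0.25, 0.5, 1,
1.5, 2, 3, 4, 6, 8, 12, 24 h, a conventional single-dose design not stated in
the source), multiplied by independent lognormal residual deviates
(natural-scale mean 1, default CV 15 %; no additive/LLOQ floor because no
assay limit is reported). Generating truth (individual states, seed, CV) is
retained for recovery tests. Passing self-consistency shows the pipeline
(generate → NCA → ratio/AFE) is unbiased under the model's own assumptions;
it does not validate the model against real digitization error, sparse
sampling, or assay noise structure.

## Numerical choices and problem sizes

LSODA with rtol 10⁻⁸/atol 10⁻¹⁰ µg; dissolution handled as an exact two-
segment integration (release window, then decay) to avoid discontinuity
error; output step 0.1 h by default, 0.05 h for verification runs, 0.005 h
where the IV mixing transient must be quadrature-resolved. Deterministic
scenario predictions use one reference individual per cohort (midpoint age,
table-midpoint weight). Test-suite population sizes (n = 60–150 per cohort,
n = 12 subjects per synthetic study) and the default N = 1000 for production
cohorts reflect, respectively, convergence of medians under common random
numbers and the published cohort size.

## Known limitations

* The PK-Sim internal physiology/ontogeny database is not public; all tables
  here are independent literature-informed stand-ins, so parameter-level
  agreement with the original model is not expected — verification is against
  the printed PK summaries at the 2-fold standard.
* Two observed rows are internally inconsistent with their sister rows
  (elderly-women 25 mg Cmax; children 1.25 mg/kg AUC) and fall outside the
  2-fold band for any single parameterization that fits the others.
* No transporter ontogeny, genotype-stratified (poor/extensive metabolizer)
  subpopulations, multiple dosing, pregnancy/obesity physiology, or pediatric
  impaired cohorts.
* Confidence intervals on predicted/observed ratios are not computed (no CI
  method or values exist to verify against).
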