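# Methods

## Equilibrium binding models

**Direct titration.** Protein P titrated into a fixed concentration of
fluorescent probe L\*. Observed anisotropy is a linear mix of the free
(r₀) and bound (r_b) endpoint anisotropies weighted by the probe bound
fraction, which for 1:1 binding with ligand depletion is the exact
quadratic root

    f_b = [(K_d + L_t + P_t) − √((K_d + L_t + P_t)² − 4 L_t P_t)] / (2 L_t).

**Competition titration.** Unlabeled competitor L titrated into a
preformed P·L\* mix (probe total L_st, protein total P_t, probe
affinity K_d1 fixed from a prior direct fit). Free protein p satisfies
the cubic p³ + d p² + e p + f = 0 with

    d = K_d1 + K_d2 + L_st + L_t − P_t
    e = (L_t − P_t) K_d1 + (L_st − P_t) K_d2 + K_d1 K_d2
    f = −K_d1 K_d2 P_t

whose physical root has the trigonometric form
p = [2√(d² − 3e) cos(θ/3) − d]/3,
θ = arccos[(−2d³ + 9de − 27f)/(2√((d² − 3e)³))]; bound probe fraction
is p/(K_d1 + p). The model assumes P_t > L_st (protein in excess of
probe), enforced at construction.

*Numerical hardening.* When K_d2 is many orders of magnitude from
K_d1 the arccos argument is a ratio of nearly cancelling ~1e39-scale
terms and the trigonometric root loses double precision entirely. The
cubic shares its non-negative roots with the (monotone) protein mass
balance, so it has exactly one root in [0, P_t]; the implementation
polishes the trigonometric root with safeguarded Newton (bisection
fallback) on that bracket. An independent oracle —
`solve_equilibrium_numeric`, a Brent root solve of the mass balance
P_t = p + L_st·p/(K_d1+p) + L_t·p/(K_d2+p) — certifies the closed form
to 1e-9 relative over 1000 log-uniform parameter draws (K_ds 1e-2 to
1e5 nM) in the test suite. Mass conservation in the oracle holds to
1e-10 relative. The arccos argument is clamped when within 1e-9 of
[−1, 1] and is an error beyond that.

**Fitting.** Trust-region nonlinear least squares
(`scipy.optimize.least_squares`); K_d parameterized as log K_d to
enforce positivity; anisotropy endpoints fit by default or fixable
when measured independently (free-probe wells, saturated direct
titration). Standard errors come from the Jacobian at the optimum via
the delta method. A curve whose signal swing is below 0.1% of its mean
is declared unidentifiable rather than fit. Validity flags mirror
assay practice: a competition baseline falling >3σ below the
free-probe anisotropy (`baseline_below_free_probe`), a direct-curve
start deviating from r₀ (`start_anisotropy_mismatch`), and reversals
beyond noise (`non_monotonic_beyond_noise`); σ defaults to a robust
successive-difference estimate.

Concentrations are nanomolar throughout the binding module; unit
conversion happens only at I/O boundaries.

## Dose–response and stability

Raw plate signals are normalized as 100·(raw − min)/(max − min)
against on-plate controls; values above 100% are legal (hyperactive
counterscreen wells). EC50s come from a four-parameter logistic with
bottom fixed at 0% and top free by default (top pinned to 100% for
%-inhibition proliferation curves); EC50 and Hill slope are fit on log
scale. When the fitted curve does not reach half of its fitted top
within the tested range — or the optimizer fails — the EC50 is
reported censored at the highest tested concentration with a `>`
bound, never extrapolated. The default concentration scheme is the
10-point, 3-fold serial dilution from a 10 mM DMSO stock (50 µM top
in-well).

Half-lives use log-linear least squares of ln(% remaining) vs time,
t½ = ln 2/k, chosen over nonlinear exponential fitting for robustness
at 4–5 timepoints. A slope not significantly negative (one-sided
p > 0.05) yields `> last timepoint`.

## Censored values

Assay tables report bounds (`>50`, `>>50`, `<1`) wherever a readout
saturated. `CensoredValue` carries the limit plus a direction, and the
ratio arithmetic used by every SAR index propagates them: a `>`
numerator (or `<` denominator) gives a `>` ratio, the mirror cases
give `<`, opposing directions are indeterminate and raise. `>>` is
arithmetically identical to `>` and differs only in display. For the
library filter, `>` entries are evaluated optimistically at their
bound.

## Peptide model

The residue registry (editable JSON shipped with the package) assigns
each token a chirality, side-chain formal charge at pH 7.4, polarity
class, hydrophobicity, helix-propensity class and staple-arm flag.
Charge model: Asp/Glu/α-methyl-Glu −1; Gla −2 (two carboxylates);
Lys/Arg/homo-Arg +1; His 0 (pKa ≈ 6 — His is grouped with charged
residues for substitution analysis but never contributes to net-charge
arithmetic); azido-Lys 0 (the azide removes the amine); free
N-terminus +1, acetyl 0; C-terminal amide 0, free acid −1. Side chains
at staple positions contribute 0: olefin/di-alkyne arms are apolar
hydrocarbons, and a lactam bridge consumes both the Lys amine and the
Glu carboxylate. Hydrophobicities are Eisenberg consensus values, with
non-naturals mapped to their nearest natural analog (Cba→Leu,
Aib→Ala, hS→Ser, hR→Arg, Gla→Glu, staple arms→Leu); only a consistent
polarity dichotomy matters for the amphipathicity analysis, not the
absolute scale. D-residues share their parent's charge and
hydrophobicity; chirality matters only to the tail classifier.

Sequence notation requires explicit caps (`Ac-`/`H-` and
`-NH2`/`-OH`) and brackets all non-natural tokens; unknown tokens are
errors, never skipped. Olefin and di-alkyne staples are inferred from
their arm residues (R8→S5 at i,i+7; S5→S5 at i,i+4; X→X at i,i+7);
lactam (i,i+4) and triazole (i,i+7) crosslinks reuse ordinary side
chains and are declared explicitly.

The helical wheel places residue k at (k−1)·100° mod 360° (ideal
α-helix, 3.6 residues/turn). The hydrophobic moment is the magnitude
of the per-residue-normalized vector sum of hydrophobicities at wheel
angles — near zero for hydrophobically uniform sequences, maximal for
face-segregated ones.

**Tail propensity classifier.** No quantitative predictor was
published for the High/Low aqueous-propensity labels of the
C-terminal-tail series; the rule here is reverse-engineered from the
printed labels and flagged as such: a tail is Low iff it contains a
canonical helix breaker (Gly, Pro, sarcosine) anywhere or a
D-configured residue at a non-C-terminal position. A single terminal
D-residue (a protease-resistance cap) leaves the tail High. The rule
reproduces all 19 printed labels; it is a label-faithful heuristic,
not a transferable propensity model.

## CD helicity

Mean residue ellipticity: MRE(λ) = θ_mdeg(λ)/(10 · l_cm · C_M ·
(n − 1)), using n − 1 peptide bonds (switchable to n). Fraction helix
from the 222 nm band by linear interpolation between θ_coil = +640 and
θ_helix(n) = −40000·(1 − 2.5/n) deg·cm²·dmol⁻¹ (standard chain-length
correction), clamped to [0, 100]%. This single-wavelength estimator
deliberately replaces full spectral deconvolution: published helicity
percentages from deconvolution software are therefore *not*
point-reproduced, only rank-order and round-trip behavior are tested.
Alternative reference constants can be passed as arguments.

## Synthetic data

Generators are deterministic under a fixed seed and write their
generating truth into curve/record metadata (`truth_*`), which no
analysis stage reads.

* Titrations: forward model plus i.i.d. Gaussian anisotropy noise;
  curves store means over `n_replicates` (default 3) replicate
  measurements, emulating the at-least-triplicate assay protocol.
  Default design: 12-point log protein grid 1–2000 nM at 50 nM probe
  (direct); competitor grid 1e-2–1e3 × K_d2 at 250 nM protein / 13 nM
  probe K_d1 (competition); endpoints r₀ = 0.05, r_b = 0.25; 2% of
  dynamic range as the default noise scale. The assay CV is not
  published; 2% Gaussian is an assumption.
* Dose–response: 4PL plus Gaussian noise in percentage points on the
  10-point, 3× dilution scheme.
* CD: linear mixing of analytic helix and coil basis spectra
  (Gaussian bands; helix basis anchored to θ_helix(n) at 222 nm, with
  the characteristic 208/222 double minimum), converted to measured
  millidegrees for the stated concentration/path.
* Library: LogD uniform on [0, 3.5]; K_D log-normal around 5 nM;
  log10(cell ratio) = 3.2 − 0.8·LogD + N(0, 0.3), encoding the
  observed lipophilicity–permeability trend; cellular EC50 = K_D ×
  ratio, censored at 50 µM; solubility log-normally anti-correlated
  with LogD; serum shift ~20× for records with solubility <10 µM and
  ~2× otherwise; exactly round(fraction_toxic · n) records (default
  10%) carry planted LDH/counterscreen potencies within 10× of their
  cellular EC50, emulating the cationic-peptide liability; all other
  records are clean at the censoring limit.

What passing these calibrations shows is that the estimators recover
the statistical structure they assume — Gaussian noise, 4PL-shaped
responses, log-linear trends. Real screening data add plate effects,
aggregation artifacts, correlated replicate errors and solubility-
driven censoring that the generators do not emulate; recovery rates
here are upper bounds on real-data performance.

## Library indices and filters

Cell ratio = cellular EC50 / binding K_D after exact µM→nM
harmonization (×10³); on-target index = off-target / on-target
proliferation EC50 (undefined when the on-target value is itself a
ceiling); serum shift = EC50(10% serum, 16 h)/EC50(0% serum, 4 h);
fold improvement = reference/improved. The clean-pharmacology filter
keeps records with K_D < 10 µM and cellular EC50 at least 10× more
potent than both counterscreen and LDH readouts; it is idempotent and
logs before/after counts to an append-only provenance trail.
Correlations default to Pearson on optionally log10-transformed
columns (Spearman available); censored entries are excluded and
counted, since a bound is not a measurement.

Tumor volume uses the study convention V = 4πabc/3 from three caliper
diameters, reproduced exactly as printed even though it is 8× the
ellipsoid-from-diameters volume πabc/6 (available via
`convention="ellipsoid"`). %TGI = 100·(1 − ΔT/ΔV) on baseline-to-
endpoint growth of group-mean volumes; the vehicle group must grow.

## Design choices and limitations

* The published 292×/80× proliferation-improvement figures derive from
  figure-level curve fits, not the printed table EC50s (which give
  ~179× and ~67×); they are not reproduced as point targets.
* Fitting quality limits: with free endpoints the 12-point competition
  design recovers a 5 nM K_d2 with ~6.7% median error at the default
  noise; fixing the independently measured endpoints brings this
  under 5%. Apparent K_ds are reported as-is; no depletion correction
  beyond the exact model is attempted.
* Out of scope: kinetic (non-equilibrium) binding, instrument
  polarization corrections, global multi-curve fits, plate-effect
  corrections, secondary-structure deconvolution, pKa prediction, 3D
  structure, and mixed-effects tumor-growth modeling.
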