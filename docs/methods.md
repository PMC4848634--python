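# Methods

## Scope and model

`anapept` implements a rule-based annotation procedure for anabaenopeptins
(APs) in centroided positive-mode MS/MS spectra, and an enzyme-inhibition
quantification stage for 96-well colorimetric assays. APs are modelled as a
five-residue ring with the conserved Lys in position 1 plus one exocyclic
residue joined through an ureido bond. Everything is monoisotopic and
singly charged: all reported AP species are [M + H]⁺, and the package does
not model isotope envelopes, multiple charging, or average-mass chemistry.

### Mass assembly

Neutral mass: `Σ(ring residues) + (exocyclic residue + H2O) + CO − H2`.
The ring term is a cyclic peptide (residue masses, no terminal water); the
exocyclic residue enters as a free amino acid bound through the ureido
carbonyl (+CO) with loss of two hydrogens forming the two N–C bonds.
This reproduces the literature nominal [M + H]⁺ values of AP A (844),
AP B (837), AP F (851) and oscillamide Y (858) exactly.

### Diagnostic ions

* Lys marker, m/z 84.0808 — the Lys immonium ion after NH₃ loss. The true
  Lys immonium lies at 101.107; the 84 ion is the species universally
  reported as the AP gate ion, and only the ammonia-loss reading reproduces
  the nominal 84.
* Phe immonium, 120.0808; protonated free Arg, 175.119.
* Carbamoyl-Arg-related ion, 201.1 — stored as an empirical constant. No
  single obvious elemental composition yields 201.1 (plausible readings
  give 185.1 or 203.1), so the observed value is carried as data, not
  derived.

### Exocyclic-loss rules

Collision-induced dissociation ejects the exocyclic residue from [M + H]⁺:

* Arg-style (default for all non-Tyr residues): neutral loss =
  free amino acid + CO − H2 (Δ 200.091 for Arg), leaving the bare
  protonated ring (637.371 for the AP A/B ring).
* Tyr: neutral loss = the free amino acid (Δ 181.074), leaving the ring
  still carrying the ureido carbonyl as an isocyanate-type ion
  (ring + CO − H2 + proton; 663.350 for AP A).

With the predicted "ring ion" defined as the loss *product*, mass
conservation `[M+H]⁺ = ring ion + loss` holds for every scaffold to
1e-4 Da, and is property-tested over random scaffolds.

### Fragment prediction

Predicted spectra contain the precursor, the loss-product ring ion, the
Lys marker, one immonium ion per distinct residue, the two Arg diagnostics
when Arg is present anywhere, and b2–b4 of one canonical ring
linearization (opened at the Lys α-amide in stored ring order). Only one
opening is generated: ring fragments from all five openings would inflate
the predicted set and are not needed for discrimination among the library
compounds; b1 (an acylium) and b5 (the full ring) are omitted as
uninformative or redundant.

## Screening parameters

* **Matching tolerance** — 0.5 Da absolute by default, reflecting
  nominal-integer reporting of unit-resolution ion-trap data; ppm mode is
  available for high-accuracy synthetic tests. Peak matching returns the
  most intense in-window peak; ties break toward lower m/z.
* **match_threshold** — 0.6: the minimum fraction of predicted fragments
  (precursor excluded) matched for a named library call. Noiseless
  self-matches score 1.0 and cross-compound scores are 0 (the precursor
  gate fails), so any threshold in (0, 1] separates the noiseless case;
  0.6 additionally tolerates moderate fragment dropout while keeping
  random noise matches far below threshold.
* **Tie-break** — equal scores resolve by smaller precursor error, then
  lexicographic name, making output deterministic.
* **CYP flags** — cyanopeptolin-like spectra are detected only through a
  configurable list of Ahp-related diagnostic m/z values (default 215.1,
  150.1, 134.1, commonly used Ahp-adjacent ions); no depsipeptide mass
  assembly is attempted because CYP annotation from these data is
  detection-level only.
* **Fragment rows** — spectra whose precursor matches a library ring ion
  within tolerance are reported as "AP fragment" rows in the fraction
  report. Fragment-like species that match no library ring (e.g. a 752
  ion) are simulated in the fixture but yield no report row; their
  structural origin is not modelled.

## Inhibition stage

* Percent inhibition `(A0 − AI)/A0` from mean absorbances; values outside
  [0, 1] are retained unclipped, since activation or assay drift must
  propagate into the error diagnostics honestly.
* Models: linear (inhibition on dose), loglinear (on log10 dose — log10
  chosen for dilution-series readability), quadratic (dose and dose²), all
  ordinary least squares. Model adequacy is the mean percent relative
  error (MRE) between measured and back-calculated inhibition; points with
  measured inhibition of exactly zero are excluded from the mean (relative
  error undefined at zero). Selection takes the minimal MRE with ties
  (within 1e-9) resolved toward the simpler model, so noiseless linear
  data select linear even though a quadratic also fits exactly.
* IC50 is the in-range dose where the fitted curve predicts 0.5;
  extrapolation is refused by default (a distinct undefined-IC50 error),
  with an explicit opt-in flag, so flat or negative dose–response curves
  fail gracefully. A quadratic with two in-range roots returns the
  smaller dose.
* Significance: a sample is flagged when its mean inhibition lies outside
  the 95% t-based confidence interval of the across-sample mean, built
  from the per-sample means within an enzyme. The reference population for
  this interval is a genuinely open design point; per-enzyme sample means
  were chosen as the most conservative construction that needs no
  replicate-variance pooling. Groups with fewer than two replicates, or a
  lone group, return an undefined flag rather than a guess.
* Relative potency defaults to `100 × IC50(standard) / IC50(fraction)`
  (a fraction needing more material than the standard scores < 100%); the
  reciprocal convention is available and the output header names the one
  in force, because a bare ratio-of-IC50s statistic is ambiguous about
  direction.

## Synthetic data

The simulator emulates unit-resolution product-ion scans over a
50–1000 Da window: predicted fragments survive independently with
probability 1 − dropout_p, get Gaussian m/z jitter (σ default 0.01 Da) and
lognormal intensities (arbitrary units — no instrument intensity model is
derivable or attempted), and uniform-random noise peaks are added. Decoys
are pure noise with the 84.081 ± 0.5 Da window cleared, so they fail the
gate by construction. The fraction fixture reproduces a published
detection layout (which compound in which methanol fraction, 24 spectra);
because the layout records ions that *were* observed, the fixture never
drops the gate ion or the exocyclic-loss ion and steers noise peaks clear
of all diagnostic windows — otherwise a fixture row would describe a
different experiment and the screening outcome would depend on the seed.

Plates are simulated as `A = A0(1 − inhibition(dose)) + N(0, σ)` with
duplicate sample wells, four zero-inhibitor wells, two negative controls,
a default six-point dose series (10–60 µg·mL⁻¹, mirroring a standard
trypsin/aprotinin design), A0 = 1 AU and σ = 0.02 AU. Absorbances are
floored at zero. All generators are pure functions of (parameters, seed).

What passing tests on these data do **not** show: robustness to
chromatographic co-elution, isobaric interference, real intensity
distributions, multiply charged precursors, or plate-position effects.
The fixture demonstrates that the decision rules reproduce a known layout
under the stated noise model, not that the rules are sufficient for
arbitrary real spectra.

## Problem sizes

The test suite simulates 10,000 decoy spectra for the gate property,
1,000 random scaffolds for mass conservation, and 3 × 200 seeded plates
for IC50 recovery (threshold: within 15% of truth in ≥ 90% of runs, met
at 100% for all three generating models). The full suite runs in a few
seconds on one CPU.

## Known limitations

* Ring compositions of the novel analogs (AP 802/809/827) are unknown;
  their fixtures carry only the gate ion and an Arg-style Δ200 loss and
  claim no structure.
* The 201.1 Arg-related ion is an empirical constant; spectra calibrated
  differently may need the CYP/diagnostic lists adjusted.
* Stereochemistry, ester-bond (depsipeptide) fragmentation and de novo
  ring sequencing are out of scope.
* MGF parse errors identify the offending block by index and title, not
  raw line number.
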