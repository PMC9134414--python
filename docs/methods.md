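# Methods

This note documents the physical model, the numerical choices, and the
limits of what the test suite demonstrates.

## Thermodynamic model

All energies are handled internally in eV per particle; ingested tables
may be in hartree, eV, kcal/mol or kJ/mol and are converted once with
CODATA 2018 factors. One pKa unit corresponds to RT·ln10 = 0.059159 eV at
the default temperature of 298.15 K. Temperature is a parameter of every
operation but is never varied by default: the intended comparisons are
between data obtained under standard conditions, and no temperature
extrapolation of solvation energies is attempted.

**Isodesmic route.** For a target acid AH and a reference acid BH with
experimental pKa `pKa_ref` in the same solvent,

```
ΔG_isodes = [G(A⁻) + G(BH)] − [G(AH) + G(B⁻)]
pKa(AH)   = pKa_ref + ΔG_isodes / (RT ln10)
```

The reaction is balanced (same number and charge of species on both
sides), so systematic errors of the solvation model largely cancel, and a
constant shift applied to every species energy in a solvent leaves the
prediction invariant (gauge invariance, property-tested).

**Effective proton energy and the direct route.** The reference couple
also fixes an effective total free energy for the solvated proton,
`G_eff(H⁺) = G(BH) − G(B⁻) + RT ln10 · pKa_ref`. Substituting it into the
direct dissociation expression `ΔG_diss = G(A⁻) + G_eff(H⁺) − G(AH)`
reproduces the isodesmic prediction identically; the package keeps both
routes and asserts their equivalence to 1e−9 pKa units as a standing
acceptance property. `G_eff(H⁺)` is deliberately an *effective* quantity:
it absorbs the method error of the chosen electronic-structure/solvation
setup, so it must be built with the same setup as the target energies
rather than taken from a more accurate calculation.

**Solvent transfer.** Absolute potentials of the standard hydrogen
electrode (consumed as tabulated inputs, never re-derived here) define
the water→solvent conversion factor
`ΔG_SolvX = F·(E_abs(X) − E_abs(water))`. Sign conventions are
centralized: reduction convention for potentials
(E_abs(SHE, water) ≈ +4 V), and

```
E_abs = (G_eff(H⁺) − ½G(H₂)) / F        G_eff(H⁺) = ½G(H₂) + F·E_abs
```

anchored on ½H₂ ⇌ H⁺ + e⁻ at 0 V. These choices satisfy every internal
identity the model demands — the proton's own pKa is 0, the factor gauge
is zero on water, antisymmetric and chain-additive, and the
factor-shift route and the E_abs route give the same `G_eff(H⁺, X)` to
1e−12 — and they reproduce the packaged worked magnitudes (−11.85 eV in
water from ≈4.05 V with ½G(H₂) = −15.90 eV). Inner (Galvani) versus outer
(Volta) potential conventions may be labelled in the solvent table;
mixing them is refused, and no surface-potential correction is ever
added, since it cancels for charge-neutral reactions treated
consistently.

**Gas-phase proton.** `G(H⁺, gas) = (5/2)RT − T·S` with the
Sackur–Tetrode entropy of a structureless particle of proton mass:
−0.272 eV (−6.27 kcal/mol) at 298.15 K and 1 atm. The 1 atm convention is
the default; the 1 atm → 1 mol/L standard-state correction
(+0.0821 eV at 298.15 K) is provided as an explicit opt-in and never
applied silently. Proton solvation energies are `G_eff(H⁺)` minus this
gas-phase value.

**PCET potential.** The oxidation B–H → B· + H⁺ + e⁻ against the
computational SHE is included because it closes the thermodynamic cycle
behind the conversion factors; it is not on the pKa critical path. Its
Nernst term uses the standard 59 mV/decade form, (RT·ln10/F)·pH.

## Data hygiene

* Replicate experimental pKa values for the same (species, solvent) are
  merged by unweighted arithmetic mean — no judgement of source quality —
  with all sources retained. Even irreconcilable literature values (e.g.
  13.7 vs 45 for picric acid in 1,2-dichloroethane) are averaged, because
  choosing between them would presuppose the answer.
* Structures whose lowest imaginary frequency is below −100 cm⁻¹ fail the
  convergence screen. The screen *flags* records and warns; it never
  silently drops user-supplied data. Records without frequency metadata
  pass with a notice.
* Solvent and species names are matched case-insensitively after
  whitespace normalization, with no synonym registry: "DMSO" and
  "dimethyl sulfoxide" are distinct unless the user aliases them,
  avoiding silent mis-joins.

## Regression choices

* **LAD solver.** Minimization of Σ|residual| uses iteratively reweighted
  least squares (weights 1/max(|r|, ε), ε = 1e−8; convergence 1e−10 on
  parameters; ≤500 iterations) followed by an exact polish: an L1 optimum
  of a p-parameter linear model interpolates at least p sample points, so
  candidate solutions through 2-point (line) or 4-point (Kamlet–Taft)
  subsets of the lowest-residual points are enumerated in a fixed order
  and adopted when at least as good. This makes the solver deterministic,
  exact on (mostly) collinear data, and verifiable against an exhaustive
  grid-search oracle in the tests; statsmodels' median regression serves
  as an independent cross-check there, never as the implementation.
* **Dispersion convention.** Residual σ and fold dispersions use the
  sample (n−1) denominator throughout.
* **Cross-validation.** k = 5 folds × 3 runs by default; fold sizes
  differ by at most one; run r shuffles with seed + r, so a single seed
  fixes the whole experiment bit-for-bit. Fits use the k−1 training
  folds; held-out MAE is reported alongside. Variance always equals sd².
  The run flagged for discussion is the one with the largest
  sd(slope) + sd(intercept) — a worst-case reading chosen because slope
  and intercept dispersion need not agree; the ranking scalar is
  documented here and trivially replaceable. Data sets with fewer than
  14 points proceed with a prominent applicability warning.
* **Scaling relations.** Scopes are `universal`, `protic`, `aprotic`,
  `group:<label>`, `solvent:<name>`; application precedence is solvent >
  group > class > universal. Shipped registries contain no numeric
  defaults: a relation is usable only after being fitted or explicitly
  configured, and `apply_scaling` refuses placeholders. Outliers are
  never removed; robustness comes from the L1 criterion alone.
* **Kamlet–Taft.** ΔG_solv(H⁺) ≈ c0 + c_π·π* + c_α·α + c_β·β by the same
  LAD criterion; the molar-volume term is neglected. At least four
  solvents with complete (π*, α, β) are required, and designs in which a
  parameter is constant (or the columns are linearly dependent) are
  rejected naming the deficient parameter.

## Synthetic fixtures: what they emulate and what they do not

The generator inverts the forward model. In water, the reference base
energy is placed so the reference acid reproduces pKa 3.77 with
G_eff(H⁺, water) = −11.85 eV; each target anion is placed so its acid hits
a prescribed "true" aqueous pKa (drawn uniformly on [−2, 20] unless
given). Moving to solvent X adds a shift to the proton energy only, so
the true pKa rises by shift/(RT·ln10) while species energies stay
solvent-independent. The default solvent panel and shifts mirror the
packaged printed solvation-energy table (methanol +0.29, acetonitrile
+0.63, DMSO +0.66, acetic acid +0.64, dimethylamine +0.97 eV vs water);
½G(H₂) = −15.90 eV anchors E_abs(water) = 4.05 V. Species energies are
given loosely realistic magnitudes (10²–10³ eV) so that floating-point
cancellation in the isodesmic differences is exercised.

Noise, when requested, is Gaussian on the *energies* (eV) of the target
species, independently per record, so error propagation through the
dissociation algebra is tested; 0.0296 eV corresponds to half a pKa unit.
The reference couple is kept noise-free: it defines the energy gauge, and
perturbing it would only add a global shift common to all predictions
rather than probing per-species error propagation.

What passing these tests shows: the thermodynamic algebra, the solvent
transfer, the statistical machinery, and their composition are
implemented correctly and deterministically. What it does **not** show:
accuracy on real molecules. The fixtures contain no conformer or
protonation-site ambiguity, no systematic method-vs-method shifts between
solvation models, no ion pairing, and no inconsistent experimental
anchoring — the very effects that make real nonaqueous pKa data hard.
Benchmark-scale error statistics on real DFT data are out of scope here
because they require the upstream quantum-chemistry dataset; the MAE/σ
and cross-validation machinery itself is verified on synthetic data with
known ground truth.

## Interfaces and provenance

The CLI takes four tables (energies, solvents, conjugate pairs,
experimental pKa); the pairs table is this package's own schema, since
acid/base pairing is not derivable from an energy table alone. Result
files are CSV with a JSON twin carrying full provenance (reference
compound, relation used, temperature, gas-phase proton convention) and a
hash of the run configuration; identical configurations produce
byte-identical files. Logs go to stderr, results never to stdout except
in explicit tabular mode.

## Known limitations

* Protonation-site and conformer selection, multi-site deprotonation
  sequencing, and ion-pairing corrections are upstream concerns and out
  of scope.
* Per-solvent absolute SHE potentials are inputs; the package does not
  re-derive them from radical-couple energetics.
* The problem sizes used in the automated checks (up to 100 species × 6
  solvents, 50-point regression sets, 20-solvent solvatochromic designs)
  are chosen as the package's own desk-scale verification conditions.
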