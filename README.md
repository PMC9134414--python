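# solvpka

Predict acid dissociation constants (pKa) of any compound in any solvent
from upstream quantum-chemical free energies plus a **single** experimental
aqueous reference pKa.

`solvpka` is aimed at computational chemists who already have implicit- or
explicit-solvent Gibbs free energies for their acids and conjugate bases
(from DFT, MP2, semiempirical methods, …) and need absolute pKa values in
solvents where no reliable experimental reference exists — the common
situation in nonaqueous electrochemistry, synthesis planning, and drug
discovery. The package does not run quantum chemistry; it consumes energy
tables and handles the thermodynamics, the solvent transfer, and the
statistics.

## The model

**Isodesmic (indirect) route.** With a reference acid B–H of known pKa in
the same solvent, the proton exchange AH + B⁻ → A⁻ + BH is balanced, so
systematic solvation errors largely cancel:

    pKa(AH) = pKa(BH) + ΔG_isodes / (RT·ln10)
    ΔG_isodes = [G(A⁻) + G(BH)] − [G(AH) + G(B⁻)]

**Effective proton energy.** The same reference defines an effective total
free energy of the solvated proton,

    G_eff(H⁺) = G(B–H) − G(B⁻) + RT·ln10 · pKa_ref

which makes the **direct** route, ΔG_diss = G(A⁻) + G_eff(H⁺) − G(AH),
algebraically identical to the isodesmic one.

**Any solvent.** Where no reference pKa exists, the aqueous G_eff(H⁺) is
transferred with a conversion factor built from absolute potentials of the
standard hydrogen electrode (SHE),

    ΔG_SolvX = F·(E_abs(SHE, X) − E_abs(SHE, water)),
    G_eff(H⁺, X) = G_eff(H⁺, water) + ΔG_SolvX,

with the computational SHE anchor ½H₂ ⇌ H⁺ + e⁻ at 0 V interconverting
G_eff(H⁺) and E_abs. Subtracting the Sackur–Tetrode gas-phase proton
(−0.27 eV at 298.15 K, 1 atm) yields the conventional proton solvation
energy ΔG_solv(H⁺).

**Scaling and statistics.** Raw pKa values from implicit solvation models
deviate from experiment by roughly linear maps. The package fits linear
free-energy scaling relations pKa(exp) ≈ slope·pKa(calc) + intercept by
least absolute deviation (LAD, robust to the gross outliers that plague
nonaqueous experimental data), universally or per solvent / solvent class
(protic vs aprotic) / functional group, validates them by repeated 5-fold
cross-validation (3 runs, worst run flagged), and regresses proton
solvation energies on the Kamlet–Taft solvatochromic parameters
(π*, α, β).

## Worked example

Generate a synthetic benchmark whose ground truth is known exactly, then
predict every acid in every solvent from the aqueous formic-acid reference
(pKa 3.77) alone:

```bash
solvpka simulate --n-species 4 --seed 42 --out demo/fix
solvpka pka --energies demo/fix/energies.csv --solvents demo/fix/solvents.csv \
    --pairs demo/fix/pairs.csv --reference formic_acid --ref-pka 3.77 \
    --out demo/out
head -4 demo/out/predictions.csv
```

```
species_id,solvent,pka_raw,pka_scaled,relation_used,reference_id,dg_diss_ev,temperature_k
formic_acid,water,3.7699999999966334,,,formic_acid,0.22303074831143022,298.15
acid_01,water,15.02703306822475,,,formic_acid,0.8889895040078954,298.15
acid_02,water,7.655325674538857,,,formic_acid,0.4528840885309364,298.15
```

The reference reproduces its own pKa (3.77) to machine precision — the
isodesmic self-consistency check. Joining against the fixture's ground
truth shows the solvent transfer at work for one acid: each solvent's
proton-energy shift (e.g. +0.64 eV for acetic acid) raises the pKa by
shift/(RT·ln10) ≈ 10.8 units, and the noiseless predictions match the
truth exactly:

```
species_id       solvent   pka_raw  pka_true
   acid_01         water 15.027033 15.027033
   acid_01      methanol 19.929048 19.929048
   acid_01  acetonitrile 25.676237 25.676237
   acid_01          DMSO 26.183342 26.183342
   acid_01   acetic acid 25.845272 25.845272
   acid_01 dimethylamine 31.423427 31.423427
```

Per-solvent proton energetics (the packaged consistency table of printed
solvation energies) are one command away:

```bash
solvpka proton-energy --packaged
```

```
solvent,class,g_eff_ev,dg_solv_ev,conversion_factor_ev
water,protic,-11.85208432159719,-11.58,0.0
methanol,protic,-11.562084321597188,-11.29,0.2900000000000009
acetonitrile,aprotic,-11.222084321597189,-10.95,0.6300000000000008
DMSO,aprotic,-11.19208432159719,-10.92,0.6600000000000001
acetic acid,protic,-11.212084321597189,-10.94,0.6400000000000006
dimethylamine,protic,-10.882084321597189,-10.61,0.9700000000000006
```

Water is the most negative entry — no common solvent matches its combined
polarizability and hydrogen bonding, so it stabilizes protons best. The
remaining subcommands (`fit-scaling`, `crossval`, `kamlet-taft`,
`simulate --scaling-slope …`) cover the statistical workflow; every result
file carries a configuration hash and full provenance, and identical
inputs give byte-identical outputs.

## Layout

| module | contents |
| --- | --- |
| `solvpka.core_units` | CODATA constants, unit conversion, RT·ln10, Sackur–Tetrode proton, standard-state correction |
| `solvpka.data_io` | energy / solvent / experimental-pKa table IO, frequency QC screen, replicate averaging, results writer |
| `solvpka.thermo_engine` | isodesmic and direct pKa, effective proton energies, PCET potential, absolute-SHE interconversion, conversion factors |
| `solvpka.regression_stats` | LAD fitting, scaling-relation registry, MAE/σ, repeated k-fold CV, Kamlet–Taft fit |
| `solvpka.synthetic_fixtures` | forward-model-inverting fixture generator, scaling scatter generator, packaged printed solvent table |
| `solvpka.cli` | `solvpka` command with the subcommands above |
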