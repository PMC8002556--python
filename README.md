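# cassanet

Molecular networking and diagnostic neutral-loss annotation of
**cassaine-type diterpenoids** from positive-mode LC-MS/MS data.

*Erythrophleum* trees (e.g. *E. suaveolens* and *E. ivorense*) produce
cassane-type diterpenes carrying a nitrogen-containing side chain ("arm")
at C-13 — long known as *Erythrophleum* alkaloids.  Untargeted
metabolomics of such plants yields hundreds of MS/MS features with almost
no database coverage, so annotation has to be done from first principles:
exact masses, characteristic neutral losses, and spectral similarity
between structural analogs.  `cassanet` implements that workflow as a
tested library for analysts working on diterpenoid alkaloid dereplication:

- **Formula assignment** — exhaustive CHNO(S,P) enumeration against an
  [M+H]⁺ m/z with a ppm tolerance and an RDBE plausibility window; the
  deviation is reported as δ (ppm) = 10⁶ · (m/z_obs − m/z_theo) / m/z_theo.
- **Molecular networking** — modified cosine similarity (√-intensity
  weighting, L2 normalization, direct or precursor-shifted peak matching
  with an *optimal* one-to-one assignment), with GNPS/MetGem-style edge
  filtering: CS > 0.55, ≥ 4 matched peaks, top-K = 10, component cap 1000.
- **Arm classification** — the C-13 arm type is read off diagnostic
  neutral losses from the precursor: CH₃NH₂ (31.0422 Da) for
  *N*-methylethanolamine esters, (CH₃)₂NH (45.0578) for *N,N*-dimethyl
  esters, NH₃/C₂H₇NO for primary-amine arms, H₂O + CH₃OH (18.0106 +
  32.0262) for *N*-methyl amides; the full arm cut C₃H₉NO (75.0684) is
  common to esters and amides and defines the cascade **anchor ion**.
- **Substituent inference** — mass differences below the anchor are
  decomposed over a loss alphabet (acetate/methyl ester 60.0211, CO, H₂O,
  tigloyl 100.0524, dihydro-/hydroxy-tigloyl, glucosyl 162.0528) to
  recover the scaffold substituent multiset.
- **Library matching** — a bundled machine-readable library of 28
  annotated cassane features (19 of them new structures) with formulas,
  observed m/z, retention times, arm classes, substituent multisets and
  four-way subgroup abundance profiles.
- **Group profiling** — per-subgroup mean intensities turned into integer
  percentage profiles (largest-remainder rounding, summing to exactly
  100), the pie-chart attributes of the network export.
- **Simulation** — an in-silico fragmentation simulator plus noise model
  (ppm jitter, lognormal intensity noise, spurious peaks) that emits
  ground-truthed MGF + quantification datasets for validation.

## Worked example

Simulate the bundled compound library into a dataset and annotate it back:

```bash
cassanet simulate --seed 3 --out demo
cassanet annotate demo/features.mgf --quant demo/quant.csv \
    --groups demo/groups.tsv --report demo/report.tsv --graphml demo/net.graphml
```

which prints

```
wrote 28 features to demo
annotated 28 spectra (28 arm-positive), 1 network components; report at demo/report.tsv
```

All 28 features fall into a single network component — the simulated
compounds share the cassane scaffold and its loss cascade, so the
modified cosine links them into one cluster, exactly the behaviour that
makes molecular networks useful for this compound class.  The report
starts:

```
node  arm  substituents                 best_formula  delta_ppm  library_match  confidence  heavy
A1    NME  ester60:1;oxo:1;hydroxy:1    C27H35N2O2    0.07       A1             high        no
A2    PAE  ester60:1                    C23H35NO5     0.49       A2             high        no
A3    NME  ester60:1;oxo:1;hydroxy:1    C24H35NO6     2.73       A3             high        no
```

Reading row A1: the spectrum lost methylamine and the full C₃H₉NO arm
(→ *N*-methyl ester, `NME`), its sub-anchor ladder decomposes into one
acetate-type loss, one CO and one H₂O, and formula + arm + substituents
together match library record A1 (*nor*-cassamine) even though, at this
noise level, a different formula happens to sit marginally closer in pure
mass terms — which is precisely why the neutral-loss evidence, and not
the mass deviation alone, drives the match.

The same steps are available as library calls (`simulate_fragments`,
`apply_noise`, `build_network`, `annotate_node`, `proportion_profile`, …);
see the module docstrings.

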