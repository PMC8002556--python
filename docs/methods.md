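# Methods

## Mass arithmetic

All masses derive from one constants table of monoisotopic atomic masses
(C 12 exactly, H 1.00782503207, N 14.0030740048, O 15.9949146196,
S 31.97207100, P 30.97376163) and the proton mass 1.007276467 Da.  Only
the [M+H]⁺ adduct at charge +1 is modelled; isotope envelopes, other
adducts and multiply charged species are out of scope.  Under these
constants the printed mass deviations of the bundled library reproduce to
within 0.05 ppm for every record not flagged otherwise (see "Annotation
library" below).

Formula assignment enumerates the element box C 5–40, H 5–70, N 0–2,
O 0–14 (S and P off by default) by sweeping the non-hydrogen elements and
solving the hydrogen count from the residual mass, then filters by the
ppm tolerance and an RDBE window of [0, 20] (RDBE = C − H/2 + (N+P)/2 + 1).
Candidates are ranked by |δ|, then fewer heteroatoms, then Hill string —
the ranking rule is a package convention, chosen so that ties are
deterministic.  The box covers every formula in the bundled library
without combinatorial blow-up; widen it explicitly for exotic chemistry.

## Spectra and tables

MGF reading goes through pyteomics; writing emits the MZmine/GNPS-export
dialect (TITLE = feature id, PEPMASS, RTINSECONDS, CHARGE=1+, m/z to
4 decimals).  Retention times are stored in minutes.  `clean_spectrum`
merges peaks within 0.005 Da (intensity-weighted mean; the merge radius
is deliberately below the 0.02 Da matching tolerance) and drops peaks
under a noise floor; it is idempotent, and a spectrum emptied by cleaning
is retained but flagged.  Whether MS/MS intensities should additionally
be normalized before networking is an open practice question; the scorer
is scale-invariant, so no normalization is applied.

## Modified cosine and networks

Intensities are square-root transformed and L2-normalized; no m/z
weighting.  Candidate peak pairs match directly within the fragment
tolerance (default 0.02 Da) or shifted by the precursor mass difference
(modified matching, on by default).  The one-to-one assignment maximizing
the weighted dot product is computed exactly by linear sum assignment:
greedy matching by descending pair product is usually identical but can
be suboptimal when direct and shifted candidates conflict, and the tests
hold the implementation to the exhaustive-search optimum.

Edges require CS > 0.55 and at least `min_matched` matched peaks.  The
default `min_matched` is 4, the MetGem import convention; a stricter
reading of "shared fragment ions" sometimes uses 10, and both are
reachable through the parameter.  The top-K rule (default 10) keeps an
edge only if **both** endpoints rank it among their K best.  The
component size cap (default 1000) is enforced by repeatedly deleting the
lowest-scoring edge of any oversized component (ties: fewer matched
peaks, then lexicographic node ids); whether the reference tools prune
edges or split clusters is undocumented, so this GNPS-style convention is
a documented package choice.

## Arm classification

The decision rule, applied to precursor-to-fragment mass differences
within 0.01 Da (configurable; observed fragment m/z routinely sit a few
mDa off the exact arithmetic):

1. loss of CH₃NH₂ (31.0422) → NME (*N*-methylethanolamine ester);
2. else loss of (CH₃)₂NH (45.0578) or C₄H₁₁NO (89.0841) → DME;
3. else loss of NH₃ (17.0265) or C₂H₇NO (61.0528) → PAE;
4. else losses of **both** H₂O (18.0106) and CH₃OH (32.0262) → AMD;
5. else a bare full-arm loss C₃H₉NO (75.0684) → NME;
6. else NONE.

Two deliberate conflations: PAE covers both a primary-amine ester and an
amide-alcohol (their fragmentation cannot distinguish them), and the
C₃H₉NO cut is treated as common to ester and amide arms — it therefore
does not veto an AMD call, whereas any amine-containing ester diagnostic
does.  The precedence NME > DME > PAE resolves mixed evidence.

## Substituent inference

The anchor A is the full-arm-loss ion (observed within tolerance, or
synthesised at precursor − arm mass).  Each fragment below A defines a
mass difference that is decomposed over the loss alphabet {ester60
60.0211 (acetic acid, isobaric with CH₃OH+CO — indistinguishable and not
distinguished), CO 27.9949, H₂O 18.0106, tigloyl 100.0524 (≡
3-methylcrotonyl), dihydrotigloyl 102.0681, hydroxytigloyl 118.0630,
glucosyl 162.0528 or 161.0450} with per-symbol caps (acyls and glucosyl
1, ester60 3, H₂O/CO 4 including generic dehydrations/decarbonylations)
and a tolerance that accumulates by 0.01 Da per loss.

Ambiguity is real: hydroxytigloyl is exactly tigloyl + H₂O.  The
resolver therefore picks, among the decompositions of the deepest
explainable fragment, the one that explains the most intermediate
fragments as sub-multisets (ties: fewest losses, then alphabet order),
and unions in minimal decompositions of any fragment left over.  A lone
118.0630 difference thus reads as one hydroxytigloyl, but the same
difference alongside separate tigloyl and water steps reads as
tigloyl + H₂O.  The output is a multiset only — positional isomerism
(e.g. a 3β- vs 4-acetoxy) is not modelled.

## Library matching and confidence

A match requires (i) the record's formula among the assigned candidates,
(ii) the same arm class, (iii) exact agreement on the acyl/ester/glucosyl
substituent counts, and (iv) hydroxy/CO counts within the record's count
plus a generic slack of 2 each (cascades routinely shed extra water/CO
beyond the named substituents).  Remaining ambiguity is resolved by
closest hydroxy/CO totals, then retention time, then record id.
Confidence tiers follow the best formula candidate's |δ|: high ≤ 5 ppm,
medium ≤ 15 ppm, flagged above.  The report writer also flags neutral
masses ≥ 488 Da as "heavy" — an operational marker for the larger
3β-acyl compounds, not a formal class.

Family propagation floods "cassane-type candidate" over every network
component containing at least one arm-positive annotation; annotated
nodes keep their specific label.

## Annotation library

`data/cassane_library.tsv` encodes 28 annotated features (19 new
structures): formula, observed m/z, RT, printed δ, arm class, substituent
multiset, generic losses, literature status, dominant subgroup and the
four-way abundance profile in the fixed subgroup order Ouesso-Sua /
Sua * / ivo-Libr 1 / ivo-Libr 2.  Substituent multisets are authored from
the reported substitution patterns and fragment cascades.  Six records
(B3, B4, B5, B8, B16, BS1) are flagged `unverifiable-as-printed`: their
printed formula/m-z/δ triples are internally inconsistent under any
constant set, so the values are retained as annotations and excluded from
reproduction checks.  One record (B11) is stored with the neutral
formula C₃₀H₄₇NO₉; its printed composition corresponds to the protonated
cation (half-integer RDBE) and the narrative identifies it as an isomer
of B8.  Records B9 and BS3 describe the same compound (identical
formula, RT, arm, substituents) and are mutually indistinguishable by
construction.

## Simulator and noise model

`simulate_fragments` emits the precursor (intensity 100), the
arm-diagnostic ions and anchor (80), and one fragment per non-empty
sub-multiset of the losses at 60 × 0.8^(number of losses).  The geometric
decay is an arbitrary fixed choice — no fragmentation energetics are
claimed — and all m/z are exact-mass arithmetic.  A guard rejects specs
whose losses would leave less than 150 Da of scaffold.  The noise model
applies Gaussian ppm jitter to every m/z (precursor included),
mean-preserving lognormal intensity noise of a given CV, and
Poisson-many spurious uniform peaks; it is bit-reproducible under its
seed (streams are keyed by spectrum id, so datasets are order-independent).

`emit_dataset` draws per-sample intensities lognormally around group
means given by a profile matrix (scaled by a base intensity of 10⁶ / 100
per profile unit) and writes MGF + quantification CSV + group map TSV +
ground-truth JSON.  Defaults emulate the study conditions the pipeline
assumes: four sample subgroups, three samples per group, 5 ppm jitter,
20 % intensity CV, a couple of spurious peaks per spectrum, and group
weights taken from the library's printed abundance profiles.

What the simulator does **not** emulate — co-eluting chimeric spectra,
retention-time drift, isotope envelopes, detector saturation, and real
fragmentation intensity patterns — bounds what passing tests show: they
validate the inference logic and its noise tolerance, not performance on
raw instrument files.

## Validation surface

The dataset-scale figures reported for the original field study (1186
detected features, the 262-node cassane cluster and its 137/125 species
split, PCA variance fractions, the measured abundance profiles) depend on
raw data available only behind a platform login and are not reproducible
here; the property suite substitutes for them.  The tests pin instead:
δ reproduction on the verifiable library rows (±0.05 ppm), the diagnostic
loss masses, the 28/19 library composition, exact agreement of the
similarity score with an exhaustive matching oracle (1000 random pairs of
≤ 8-peak spectra), the noiseless simulate→annotate identity on all 28
records, ≥ 95 % arm recovery at 5 ppm / 20 % CV over 200 spectra, the
top-K/size-cap/monotonicity network invariants on seeded synthetic
families, and largest-remainder profiles against a brute-force oracle
(1000 random mean vectors).  Problem sizes were chosen so the whole suite
runs in well under a minute on one core.
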