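# Methods

`biosurfkit` implements the computational side of characterizing a
surfactin-family lipopeptide biosurfactant: assigning ESI-MS spectra of a
homologue mixture, interpreting GC-MS spectra of its hydroxy fatty acids,
reading MIC/MBC endpoints off replicate microdilution plates, locating the
critical micelle concentration on a tension–dilution curve, and deriving
acid–base surface energetics of conditioned surfaces from contact angles.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic-data generators do and do not emulate.

## Chemical mass model (`chem`)

The molecule is modelled as a heptapeptide (canonically
Glu-Leu-Leu-Val-Asp-Leu-Leu, one-letter `ELLVDLL`) whose N-terminus is
acylated by a β-hydroxy fatty acid CnH2nO3 (saturated; double bonds reduce
the hydrogen count) and whose C-terminal carboxyl closes a lactone with the
β-hydroxyl. Monoisotopic masses are the internal currency: residue masses
come from the standard amino-acid residue table, fatty-acid masses from an
elemental formula sum, and the neutral cyclic mass is

    M = Σ residues + (fatty acid) − H2O.

Charge carriers are protons (1.00728 Da), singly charged only; metal
adducts, multiple charging and isotope patterns are out of scope. Leu/Ile
share one code, stereochemistry is ignored, and iso/anteiso branching is
carried as metadata because it never changes mass — which is exactly why
branched variants appear in GC as doublets rather than as separate masses.

Unit-resolution instruments print integer m/z. Those integers are
reproduced by rounding the monoisotopic m/z half-up. This convention is an
inference (printed spectra do not state it), but it reproduces every
printed molecular ion (1007/1021/1035/1049 deprotonated, 1009/1023/1037/1051
protonated for C13–C16) and fragment (685, 441, 370/352, 384/366)
simultaneously, which no alternative rounding tried does.

Fragment enumeration first ring-opens the lactone at the ester bond, giving
the canonical linear acyl-peptide FA–E–L–L–V–D–L–L; alternative ring-opening
sites are not enumerated. Standard series follow: b ions (acyl side,
Σ residues + acyl + proton), y ions (C-terminal side, Σ residues + H2O +
proton), internal b-type ions for interior spans of length ≥ 2
(Σ residues + proton), and −H2O satellites of acyl-bearing (b-series) ions
from the β-hydroxyl. Only the water loss is modelled; further satellite
losses (NH3, CO) are not. The b/y complementarity identity
b_k + y_(N−k) = [M+H]+ + proton holds to 1e−6 Da and is property-tested.

## MS annotation (`annotate`)

Peak matching assigns each theoretical ion to its nearest observed peak
within a tolerance (default 0.5 Da, appropriate for a unit-resolution
triple quadrupole; a ppm mode would suit high-resolution data and can be
emulated by passing a proportional tolerance). Ties break toward higher
intensity; output is sorted canonically so peak-list order never matters.

Homologue-ladder detection extracts maximal arithmetic chains with common
difference ≈ 14.0157 Da (CH2). The literature gives no algorithm, so a
deterministic greedy one is used: grow the best chain from every unused
start peak (nearest-in-tolerance stepping), keep the longest (ties: lowest
starting m/z), remove its peaks, repeat. Each peak joins at most one
ladder. Ladder members are then labelled with the fatty-acid carbon count
whose theoretical adduct is nearest, unlabelled if beyond tolerance.

## FAME diagnostics (`fames`)

β-hydroxy FAMEs give an α-cleavage fragment at m/z 103; α-hydroxy FAMEs
give a McLafferty fragment at m/z 90. The classifier normalizes the
spectrum to its base peak (making the call invariant to uniform intensity
rescaling), then requires the diagnostic within ±0.5 Da to reach 10%
relative intensity; both-present and neither-present spectra are returned
unclassified with a reason rather than forced. The windows and threshold
are defaults of this package, since only the diagnostic ions themselves
are established.

Chain length uses the classic linear retention model: carbons = 16 +
round(Δrt / increment) against a 3-OH-C16:0 methyl ester standard. The
per-carbon increment is a calibration input (default 1.0 min); the model is
exact on noiseless synthetic series and tolerates rt noise below half an
increment. Near-co-eluting peaks (default window 0.2 min) with identical
hydroxyl class are flagged as possible iso/anteiso doublets. TLC Rf is the
migration/front ratio reported to two decimals.

## Susceptibility endpoints (`susceptibility`)

Growth is boolean per well (for sulfate-reducing indicator bacteria,
medium blackening by FeS). The endpoint rule is the conservative
all-replicates convention: MIC = lowest concentration c such that every
replicate at every concentration ≥ c is growth-free. Skipped-well plates
(clear below a growth well) therefore raise the MIC and are flagged
non-monotone. All-growth and all-clear plates return `>max` / `<=min`
sentinels. The MBC applies the same rule to the subculture matrix and is
checked for MBC ≥ MIC. The rule is verified exhaustively against a literal
brute-force evaluation on all 2^21 seven-concentration × three-replicate
plates.

Serial dilutions are generated by repeated division (default twofold from
80 μg/ml), keeping values while they remain ≥ the stated lowest
concentration with 5% slack — so a nominal "1.2" endpoint admits the exact
twofold value 1.25, and the ladder 80, 40, 20, 10, 5, 2.5, 1.25 results.

## CMC estimation (`cmc`)

Surface tension versus log10 concentration is modelled as a continuous
two-segment line; the knot is the CMC. The fit is linear least squares in
the basis [1, x, max(x − c, 0)] with the knot c grid-searched over the
interior data abscissae plus 200 equally spaced candidates, requiring at
least two points on each side; RSS ties break toward the lower
concentration. Data that a single line already fits (relative RSS below
1e−10) are reported as "no breakpoint" rather than an error. The search is
batched over candidates with normal equations, so a fit costs a fraction
of a millisecond.

Uncertainty comes from a seeded residual bootstrap: the concentration grid
is a fixed design, so residuals of the fitted model are resampled onto the
fitted values and the knot search repeated (default 100 replicates, 95%
percentile interval). Pairs resampling was rejected as the design choice
here because deleting knot-adjacent points makes the knot non-identifiable
over a whole interval, which both biases the estimate toward the
lower-concentration tie-break and gives noiseless data a spuriously wide
interval; the residual bootstrap keeps the noiseless interval degenerate,
as it should be.

The estimator is scale-equivariant (scaling concentrations by k scales the
CMC by k) and recovers a planted knot exactly on noiseless curves, within
15% under 5% tension noise at 20 points, with ≥ 90% bootstrap coverage
over 100 seeded repetitions — measured properties, since published CMC
values come without their underlying tension curves.

## Surface energetics (`surface`)

The van Oss–Chaudhury–Good decomposition writes the solid surface energy
as γTOT = γLW + γAB with γAB = 2√(γ+γ−), and links it to probe-liquid
contact angles by the Young–Dupré relation

    (1 + cos θ) γl_TOT = 2(√(γs_LW γl_LW) + √(γs+ γl−) + √(γs− γl+)).

Probe liquids default to the standard 20 °C set — water 72.8/21.8/25.5/25.5,
formamide 58/39/2.28/39.6, ethylene glycol 48/29/1.92/47.0 mJ/m² — loaded
from an overridable table, since published applications name the liquids
but rarely their constants. With three liquids the relation is a 3×3
linear system in the square roots of the solid components; the system is
rejected if its condition number exceeds 1e8 (e.g. duplicated liquids), and
negative roots — routine with noisy angles — are clamped to zero and
flagged in diagnostics rather than rejected. Replicate angles (≥ 10 drops
in standard practice) are averaged arithmetically before inversion;
first-order propagation of the angle s.d. is deliberately not the default.

Hydrophobicity is ΔGiwi, the free energy of self-interaction immersed in
water; ΔGiwi < 0 is hydrophobic, > 0 hydrophilic, exactly 0 reported as
hydrophilic with a boundary flag. Forward model and inversion round-trip
to 1e−6 on admissible component triples (all three predicted angles
physical); ΔGiwi of a water-like surface is exactly zero; ΔGiwi is
monotone in the electron-donor component under water immersion. These
properties, not published energy tables, are the accuracy contract:
published tables of this kind are frequently internally inconsistent
(signed γAB by convention, totals that do not equal γLW + γAB), so they are
treated as qualitative context — their classification signs are honoured,
their numbers are not targets. γAB is always computed non-negative per the
theory.

The module is presented statsmodels-style — `ContactAngleModel(df).fit()`
returns `ContactAngleResults` with `.summary()` and control-vs-treatment
verdicts (`less/more hydrophobic` by ΔGiwi ordering, electron-donor
verdicts by γ− ordering, sign changes flagged) — because the inversion is
a genuine fit to data. The same shape is used for `CmcModel`/`CmcResults`.
The remaining stages are rule evaluations and stay functional.

## Synthetic data (`simulate`)

Every generator is seeded (`numpy` Generator), returns a `(data, truth)`
pair, and is deterministic: same config ⇒ identical output; a different
seed changes noise realizations only, never the truth labels. Noise models
are minimal standard choices: Gaussian m/z jitter (default 0.1 Da,
instrument-readout scale), truncated-Gaussian contact angles (default
0.5°, 10 replicates), Bernoulli well growth, Gaussian tension noise
(default 0.5 mN/m). Defaults mirror the study conditions the package
implements: a C13–C16 ladder in negative mode with 5 off-grid (≥ 3 Da)
decoys; MS2 of the C15 species with ≥ 1 Da off-grid noise peaks; twofold
plates from 80 μg/ml with five replicates and a planted MIC of 5 μg/ml
(the MIC/2 well optionally partial-growth with its first replicate forced,
so the planted endpoint stays identifiable); tension curves with a true
CMC of 27.6 mg/L and plateau 27.1 mN/m, 20 points over ±1.5 decades, the
knot concentration always on-grid; FAME series anchored at a C16 standard
at 20 min with a C15 iso/anteiso doublet 0.05 min apart.

What the generators do **not** emulate: isotope envelopes, peak shapes and
detector saturation in MS; chromatographic drift and co-elution beyond the
planted doublet; contamination, carry-over and edge effects in plates;
surface heterogeneity, hysteresis and drop-volume effects in contact
angles; temperature dependence of tension. Passing tests therefore show
the algorithms are correct under their stated statistical assumptions, not
that those assumptions hold on any particular instrument.

## Problem sizes and degenerate inputs

The test suite runs the exhaustive 2^21 plate-rule check, a 200-triple
surface round-trip, and a 100-repetition × 100-replicate bootstrap coverage
study; these sizes keep the full suite around half a minute on one core
while still being exhaustive where exhaustiveness is the point. Degenerate
inputs are first-class: empty spectra match nothing, single-peak spectra
form ladders only when a minimum of one member is requested, collinear
tension curves report "no breakpoint", all-clear/all-growth plates return
sentinels, and ill-conditioned liquid sets are rejected by name.

## Known limitations

* Printed integer m/z are matched via the half-up convention; instruments
  calibrated differently may print ±1 at the integer boundary.
* Only −H2O satellites are enumerated; spectra rich in NH3/CO losses will
  leave peaks unassigned.
* The retention model is linear in carbon number with a user-supplied
  increment; strongly temperature-programmed gradients may need a
  per-dataset calibration.
* The two-segment CMC model assumes a flat post-CMC plateau; slowly
  declining plateaus bias the knot upward.
* The contact-angle inversion propagates no angle uncertainty by default;
  component error bars require the (off) first-order option or the
  generators' simulation route.
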