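# Methods

This note documents the models, conventions and parameter choices behind
each `nodmet` module, what the synthetic-data generators do and do not
emulate, and the known limits of the methods.

## Mass arithmetic

All masses are monoisotopic, built from the IUPAC/CODATA atomic masses
shipped with pyteomics (`nist_mass`).  The proton mass is derived as
m(H) − m(e) = 1.007276 Da and asserted for consistency.  Charged-species
arithmetic always carries the electron mass explicitly:

* formula cation with k electrons removed: m/z = (Σ counts·m_atom − k·m_e)/z;
* adduct [M + nH + mNa]^(n+m)+: m/z = (M + n·m_p + m·(m_Na − m_e))/(n+m).

At Orbitrap accuracy this matters: the electron is 0.55 mDa, ~0.5 ppm at
m/z 1000, comparable to the instrument's own error.

Peptide neutral masses follow residue-additivity: linear free-termini
M = Σ residues + H₂O; an N-formyl cap adds CO; a C-terminal ethanolamide
replaces the acid –OH with –NH–C₂H₄–OH (net +C₂H₅N = +43.0422 Da);
head-to-tail cyclic peptides are Σ residues with no water and no caps.
The residue table (`data/residues.tsv`) holds elemental formulas for the
20 proteinogenic residues plus ornithine; residue masses are always
computed from the formulas, never stored.  D-residues are labels only —
mass spectrometry cannot distinguish them.

Printed-value conventions: 4-decimal literature values are compared at
2 ppm (they are measured ions carrying instrument error); 1–2-decimal
values after rounding.  One reference adduct, the doubly sodiated
[M+2Na]²⁺ at 1,044.0746, deviates 2.4 ppm from the computed theoretical
(1,044.0771) — the largest disagreement among the five adducts and the
reason it is excluded from the tight-tolerance comparisons.  Where the
same ion is reported in two places with different values (1,033.0829 vs
1,033.0848), the adduct-list value 1,033.0848 is used.

## Fragment ions

For a linear peptide of n residues, product ions are defined (1+ forms;
higher charges add protons and divide):

* b_i = Σ residues(1..i) + N-terminal cap + m_p (acylium),
* a_i = b_i − CO (27.99491 Da),
* y_i = Σ residues(n−i+1..n) + H₂O + C-terminal cap + m_p,
* Y_i: the y-type ion retaining an ethanolamide cap (the capital-Y
  convention used for gramicidin-family peptides),
* x_i = y_i + CO.

The identity b_i + y_{n−i} = M + 2·m_p is exposed as
`complementarity_check`.  One annotation question is left open rather
than adjudicated: the low-mass companion ion at 142.08 of the
N-formyl-Ile terminus is computed here as b₁ (formyl-acylium,
142.0863), although it has also been labelled x₁ in the literature; the
package computes both series so either reading can be inspected.
Cyclic-peptide fragmentation is out of scope: tyrocidines are handled at
intact-mass level only, matching how they are verified against authentic
standards in practice.

## Charge states and adduct grouping

Charge is inferred from isotope-envelope spacing, z = round(1.00335/Δ)
with the residual reported and a 0.01 Da consistency gate.  Adduct
grouping considers the five positive-mode species [M+H]⁺, [M+2H]²⁺,
[M+H+Na]²⁺, [M+2Na]²⁺, [M+Na]⁺, computes the neutral mass implied by
every (ion, adduct) assignment, single-linkage clusters implied masses at
5 ppm, and emits hypotheses supported by ≥ 2 distinct ions.

Because the H→Na substitution shifts every implied mass by exactly
(m_Na − m_e) − m_p = 21.981943 Da, any ion set can also be explained by a
mass-shifted "shadow" assignment.  Two consequences:

1. Claim order matters: hypotheses explaining more ions are preferred
   before mean-|ppm| score, since a shadow over a subset of the ions can
   be internally tighter than the true all-ion hypothesis.
2. Ion sets drawn entirely from the sodiated species ({M+Na, M+H+Na,
   M+2Na}) are *mathematically indistinguishable* from their protonated
   shadow at M+21.98.  The package adopts the standard
   protonated-species-first prior, which resolves every mixed subset
   correctly and deterministically maps pure-sodiated subsets to the
   protonated reading.  This is an identifiability limit of the data, not
   of the implementation; with all five adducts present the true mass
   always wins on supporter count.

## Ladder sequencing

The sequencer walks a singly charged b- or y-ion ladder: a step is
accepted when a peak-to-peak difference matches a residue mass within
tolerance (default 10 ppm with a 0.002 Da floor protecting low-mass
fragments; MS1 grouping uses 5 ppm).  The walk is depth-first with
deterministic ordering (lowest |ppm| first, then alphabetical residue)
and a 50-branch cap — the manual literature procedure is unbounded, but a
bound is required for adversarial spectra.  If the precursor [M+H]⁺ is
known, the final residue is closed out against it.

Ambiguity handling is deliberately conservative.  {Leu, Ile} are exactly
isobaric and always reported as a class.  {Gln, Lys} (Δ = 36 mDa,
separable on Orbitrap data) are *also* kept as a fixed class: the cost of
a silent misassignment exceeds the value of the extra call, and the
classical low-resolution ambiguity is what practitioners expect to
resolve with orthogonal evidence.  Classes collapse only via explicit
evidence flags — globally (`{"Ile/Leu": "Ile"}`) or position-scoped
(`{"Ile/Leu": {1: "Ile"}}`), the way a ¹³C-labelled feeding experiment
settles one position without touching the rest.  When no single-residue
step fits, a two-residue jump is reported as an unresolved gap with its
candidate pairs, never silently filled.  Note the exact sum degeneracies
Gly+Ala = Gln and Gly+Gly = Asn: a ladder with a missing peak over such a
stretch admits a legitimate shorter reading; full-length readings outrank
it, but both are reported.

## Nested Venn attribution

Cross-run feature identity is single-linkage clustering under joint
tolerances (default 10 ppm m/z, 0.2 min RT, both configurable): two
observations link when both differences are within tolerance, and linked
components become canonical features.  The alignment parameters of the
original processing software are not recorded anywhere, so these defaults
are declared rather than inherited, and the same RT tolerance is applied
across in-vitro and in-planta samples (one LC method served all
extracts).  Single-linkage chaining is accepted and flagged: clusters
whose m/z span exceeds 2× tolerance are marked `chained` in the report.

A feature is "present" in a treatment when detected in ≥ 50% of that
treatment's replicates (inclusive).  Replicate counts per treatment are
not published; the 50% rule is this package's explicit default, robust to
a single dropout at quadruplicate depth.

The three stages, per microbe m:

1. stage1(m) = in_vitro(m) ∩ single_inoculation(m) ∩ full_community −
   baseline,
2. stage2(m) = stage1(m) − ⋃ stage1(others)  (pairwise disjoint by
   construction),
3. stage3(m) = stage2(m) − ⋃ presence(exclusion communities lacking m).

The baseline is the symbiont-only nodule treatment.  The symbiont itself
needs a different baseline — its features are, by definition, present in
symbiont-only nodules, and subtracting them would force its feature count
to zero, contradicting the design's intent of attributing features to
every community member.  The design therefore supports per-microbe
baseline overrides, and the bundled study preset gives the symbiont a
plant-only control.  Stage nesting (stage3 ⊆ stage2 ⊆ stage1) and stage-2
disjointness are asserted on every pipeline run.

## Stachelhaus-code comparison

Code identity is the fraction of matching positions among the 10
binding-pocket residues ('-' never matches).  Substrate prediction is
nearest-neighbour against a reference table with ties reported and calls
below 0.8 identity refused.  Cluster architectures are matched by global
(Needleman–Wunsch) alignment of the ordered module lists, scoring matches
by code identity with a linear 0.4 gap penalty — low enough to admit a
genuine two-module insertion flanked by high-identity modules, high
enough to suppress spurious gaps; scoring runs in integer tenths so ties
are exact.  Tied optima place query gaps as late as possible, matching
the convention of numbering inserted chemistry at the downstream
positions.  The module consumes code strings; domain detection from
sequence is out of scope.

The bundled code tables (`data/synthetic_stachelhaus_codes.tsv`) are
synthetic: the true code strings live in a figure panel not available as
text, so the fixture provides constructed codes consistent with the
documented architecture — a 17-module query whose two extra modules
(chemical positions 7/8, in the second gene) predict Ala and Val, a
strongly divergent code at position 11 predicting Tyr where the
15-module reference carries Trp, and slightly divergent (0.9-identity)
codes on the inserted modules, as novel domains show in practice.  The
structure-concordance test asserts that predictions from this fixture
concatenate to the exact residue sequence the mass engine uses.

## Recovery statistics

Recovery of a strain from a nodule means ≥ 1 CFU on the isolation plate
(threshold configurable).  Mean CFU averages over all nodules of a
treatment including zero-count ones, matching the "average CFU per
nodule" convention; fold changes report both means and return "undefined"
on a zero denominator.  Relative recovery subtracts the strain's
single-accessory baseline rate and classifies the sign with a ±1
percentage-point zero band (the published heat map has a "zero change"
category with no stated tolerance).  Pair treatments are labelled
cooperation (both members above the band), competition (either below),
neutral, or mixed — recovery gains accompanied by a CFU decline relative
to the single-accessory mean, the signature of partners that help each
other colonize but compete once established.  Trio records flag members
whose rate in a trio falls below their pair rate, attributing the drop to
the third member.

## Synthetic-data generators

One integer seed expands into independent child streams via SHA-256 of
"seed:stream-name" (kept below 2³¹), so adding a generator never perturbs
existing outputs; identical spec + seed reproduces byte-identical tables.

* **Feature tables**: each planted feature gets a true (m/z, RT) drawn
  uniformly from m/z 200–2000 (the acquisition scan range) and RT 0.5–14
  min, placed with ≥ 4× the matching tolerance between distinct features
  so planted identity is unambiguous; each detecting sample receives a
  jittered copy (uniform ±5 ppm, ±0.05 min — half the matching
  tolerances; generation refuses jitter ≥ tolerance).  Four replicates
  per treatment, optional per-replicate dropout.  The study preset plants
  stage-2 unique counts of 37/4/16/0/5 for the five community members,
  two small shared-feature sets to exercise stage-2 subtraction, a
  25-feature plant/medium background, and leaks 3 of the focal microbe's
  16 unique features into the two exclusion communities, so stage 3
  yields 13.  The manifest records every feature's category, treatments
  and expected stage membership.
* **MS2 ladders**: true ions from the fragment engine, uniform ppm
  jitter, peak dropout, and decoy peaks rejected within 3× tolerance of
  any true ion, so decoys distract but cannot fake a ladder step.
* **Nodule tables**: per-nodule Bernoulli colonization with log-normal
  CFU when present (σ = 0.8; μ set so the arithmetic mean hits the
  documented values — 280 and 69 CFU/nodule for the focal pair).  The
  study preset encodes the reported rates (40%, 64%, 0% of 15, 83%/83%
  for the cooperative pair, the trio collapse) with 12–15 nodules per
  treatment; the one unpublished single-accessory rate is set to 0.33 as
  a neutral choice.

What the generators do *not* emulate: chromatographic peak shapes,
isotope envelopes (beyond spacing), intensity structure, correlated
dropout, retention-time drift, or real biological variance in feature
content.  Passing tests therefore demonstrate the *logic* of the pipeline
— set algebra, matching, ranking, statistics — under controlled noise,
not robustness to raw instrument data.

## Problem sizes

The default test suite and the acceptance script run the full synthetic
designs: 56 LC-MS sample tables (~2,600 feature observations) per Venn
run, 100 random peptides for ladder-recovery properties, 500–1,000-nodule
tables for binomial consistency, and exhaustive alignment enumeration up
to 6 modules.  The complete suite runs in well under a minute.

## Known limitations

* Cyclic-peptide MS2 prediction and sequencing are unsupported.
* Adduct grouping of pure-sodiated ion sets is resolved by prior, not by
  mass (see above).
* The ladder walker reads singly charged ladders only; multiply charged
  fragments must be deconvolved first.
* Venn attribution is presence/absence: no intensity normalisation, gap
  filling or statistics on abundances.
* The Stachelhaus fixture is synthetic; conclusions about real clusters
  require real code strings from annotation tools.
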