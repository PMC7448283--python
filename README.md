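# nodmet

Nonribosomal-peptide mass spectrometry arithmetic and community analysis
for a simplified legume root-nodule microbiome.

Root nodules of *Medicago sativa* host, besides the nitrogen-fixing
symbiont *Sinorhizobium meliloti*, a small accessory microbiome whose
members (a *Brevibacillus*, a *Paenibacillus*, a *Pseudomonas*, a
*Pantoea*) produce specialized metabolites in planta — including
tyrocidines and britacidins, gramicidin-family antimicrobial peptides made
by *B. brevis*. `nodmet` implements, as a tested Python library, the
computational workflow around such a system:

* **Exact-mass engine** (`nodmet.masses`, `nodmet.peptide`) — monoisotopic
  arithmetic for elemental formulas, ESI adducts and nonribosomal peptides
  with N-formyl / C-ethanolamide caps, ornithine and macrocycles.  For a
  neutral mass *M*, an adduct [M + *n*H + *m*Na]^(n+m)+ has
  m/z = (M + n·m_p + m·(m_Na − m_e)) / (n + m); the electron mass m_e is
  carried explicitly, since dropping it already costs ~0.5 ppm at m/z 1000.
* **Fragment engine** (`nodmet.fragments`) — a/b/x/y product-ion series for
  linear peptides, with capital-Y ions retaining the ethanolamide cap
  (b_i = Σresidues(1..i) + cap + proton; a_i = b_i − CO; y_i = Σresidues
  (last i) + H₂O + cap + proton).
* **Adduct grouping and charge calls** (`nodmet.spectra`) — infer charge
  from isotope spacing (z = round(1.00335/Δ)) and cluster MS1 ions into
  neutral-mass hypotheses supported by ≥ 2 adduct-consistent ions.
* **Ladder sequencing** (`nodmet.ladder`) — de novo sequence reading from
  successive residue-mass differences in a b- or y-ion ladder, with
  explicit ambiguity classes ({Leu, Ile}, {Gln, Lys}), evidence flags to
  collapse them, and unresolved-gap reporting.
* **Nested Venn attribution** (`nodmet.venn`) — single-linkage feature
  matching across LC-MS runs (ppm × RT tolerances) and the three-stage
  subtractive analysis that assigns features to microbes: treatment-triple
  intersection minus baseline → cross-microbe uniqueness →
  exclusion-community filtering.
* **Stachelhaus codes** (`nodmet.stachelhaus`) — NRPS adenylation-domain
  specificity-code identity, nearest-neighbour substrate prediction, and
  global alignment of module architectures (reports inserted domains).
* **Recovery statistics** (`nodmet.recovery`) — nodule recovery rates,
  baselines-relative recovery, co-occurrence partitions, CFU fold changes,
  cooperation/competition/mixed interaction calls.
* **Synthetic data** (`nodmet.simulate`) — seeded generators for all of
  the above: planted Venn designs, noisy MS2 ladders, Bernoulli
  colonization tables.  Everything runs with no downloads.

## Worked example

Grouping five co-eluting MS1 features into one neutral-mass hypothesis
(`python examples/adduct_grouping.py`):

```
neutral mass 2042.1748 Da (mean |error| 1.14 ppm)
  m/z 1022.0960  as [M+2H]2+     (+1.28 ppm)
  m/z 1033.0848  as [M+H+Na]2+   (-0.85 ppm)
  m/z 1044.0746  as [M+2Na]2+    (-2.00 ppm)
  m/z 2043.1830  as [M+H]+       (+0.43 ppm)
  m/z 2065.1664  as [M+Na]+      (+1.14 ppm)
```

All five measured ions are explained as adducts of a single molecule of
~2042.175 Da — britacidin A, whose 17-residue structure
(formyl-Ile-Gly-Ala-Leu-Ala-Val-Ala-Val-Val-Val-Tyr-Leu-Trp-Leu-Trp-Leu-
Trp-ethanolamide) the mass engine prices at 2042.1757 Da, within 1.3 ppm
of every supporter.  The Venn pipeline on the planted five-microbe design
(`python examples/venn_attribution.py`) prints:

```
                    stage1  stage2_unique  stage3_final
S_meliloti              37             37            37
P_agglomerans_Ag15       7              4             4
B_brevis_Ag35           18             16            13
Paenibacillus_Ag47       2              0             0
Pseudomonas_Ag54         8              5             5
```

i.e. 16 features unique to *B. brevis*, of which 13 survive the
exclusion-community filter — the shortlist of candidate *B. brevis*
metabolites in planta.

## Layout

```
src/nodmet/        library (one module per pipeline stage)
src/nodmet/data/   residue table; synthetic Stachelhaus-code fixture
examples/          one narrative script per capability
tests/             pytest suite (unit, property and end-to-end tests)
docs/methods.md    models, conventions, parameter choices, limitations
```
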