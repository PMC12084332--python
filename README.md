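# gsl4d

A Python toolkit for **4D glycosphingolipidomics**: profiling and
semi-quantifying glycosphingolipids (GSLs) measured by reversed-phase
LC coupled to trapped ion mobility mass spectrometry, where every species
is described by four dimensions — m/z, retention time (RT), collisional
cross section (CCS), and its MS/MS spectrum.

It is written for analytical and clinical lipidomics groups who profile
serum GSLs from two-fraction extracts (fraction 1: neutral GSLs and
sulfatides; fraction 2: sialylated ganglio- and neolacto-series) and need
reproducible, scriptable versions of the computations that normally live
in vendor software and spreadsheets.

## What it computes

**Mass engine.** Shorthand names such as `GD1 18:1;O2/18:0` are parsed
into a glycan composition (from a class registry covering ganglio-,
neolacto-, neutral, and sulfatide series) joined to a ceramide
(sphingoid base + N-linked fatty acyl, optional deuterium label). The
elemental formula is assembled additively from anhydro residue formulas
(Hex C6H10O5, HexNAc C8H13NO5, dHex C6H10O4, Neu5Ac C11H17NO8, Neu5Gc
C11H17NO9; +SO3 for sulfation, +C2H2O for O-acetylation) and the ion m/z
uses a proton mass of 1.007276 Da per charge:

    m/z = (M + Δ_neutral ± z·1.007276) / z

**Diagnostic fragmentation.** B/Y glycosidic fragments are generated on
the rooted glycan tree of each class; the screening catalog reproduces
the nominal diagnostics used to filter candidate precursors: m/z 290
(deprotonated Neu5Ac B ion) and 274 (dehydrated Neu5Ac oxonium) for
sialylation, 581 for the disialo element characteristic of b-series GD1,
332 for O-acetylated and 306 for N-glycolyl sialic acid, 264/262 for the
18:1;O2 / 18:2;O2 sphingoid base, and the 162/342 hexose/lactose neutral
losses for neutral GSLs.

**4D annotation.** Features are matched against a library within
configurable windows (m/z in mDa, RT in min, CCS in %, MS/MS cosine
score on a 0–1000 scale) and ranked by a composite score; CCS resolves
isobaric glycan-chain isomers such as GM1 vs Neu5Ac-nLc4Cer at m/z
794.93. A packaged 376-entry serum fixture reproduces the published
human-serum inventory (129 ganglioside, 30 sialylated neolacto, 145
neutral, 72 sulfatide entries).

**Partition-corrected semi-quantification.** For an internal standard
(ISTD) spiked at a known amount, its fraction-2 partition is
A = 100·area_f2/(area_f1+area_f2); the ISTD amount in fraction 2 is
B = spiked_nmol·A/100 and each analyte amount is
C = (area_analyte/area_ISTD)·B. Strategy I uses the cohort-average
partition Ā of reference extracts, Strategy II each sample's own A, and
the combined strategy corrects partition outliers (median/MAD rule) with
the alternate strategy. CV tables, calibration linearity with
LLOD = 3.3σ/s and LLOQ = 10σ/s, carry-over, and Mann–Whitney/BH
differential tables complete the pipeline. A seeded synthetic module
generates two-fraction cohorts, diagnostic spectra, and calibration
series with known ground truth.

## Worked example

```sh
$ gsl4d mass "GD1 18:1;O2/18:0" --ion "[M-2H]2-"
species    GD1 18:1;O2/18:0
formula    C84H148N4O39
M          1836.9721
[M-2H]2-   917.4788

$ gsl4d mass "GM1 18:1;O2/18:0"
species    GM1 18:1;O2/18:0
formula    C73H131N3O31
M          1545.8767
[M+HCOOH-2H]2- 794.9338
```

The first call assembles the GD1 formula (two Neu5Ac, three Hex, one
HexNAc on a d18:1/18:0 ceramide), giving a neutral monoisotopic mass of
1836.9721 Da and a doubly deprotonated ion at m/z 917.48 — the value an
instrument operator would extract an ion chromatogram at. The second
shows GM1's predominant negative ion, the formate adduct
[M+HCOOH−2H]²⁻ at m/z 794.93, which is isobaric with Neu5Ac-nLc4Cer and
is resolved by CCS during annotation.

The same things are available from Python:

```python
from gsl4d import chem, library4d, quantify, synthetic

species = chem.parse_species_name("GD1 18:1;O2/18:0")
print(round(chem.ion_mz(species, "[M-2H]2-"), 2))   # 917.48

lib = library4d.serum_fixture()
print(len(lib), lib.series_counts())
# 376 {'ganglio': 129, 'neolacto': 30, 'neutral': 145, 'sulfatide': 72}

cohort = synthetic.simulate_cohort(synthetic.SimConfig(seed=1, n_samples=6))
conc = quantify.quantify_strategy_II(cohort["areas"], quantify.QuantConfig())
```

## Layout

- `src/gsl4d/chem.py` — nomenclature, registry, formulas, ion m/z
- `src/gsl4d/fragments.py` — in-silico B/Y fragmentation, diagnostics
- `src/gsl4d/spectra.py` — MGF/MSP readers and writers
- `src/gsl4d/library4d.py` — 4D library model, builder, serum fixture
- `src/gsl4d/annotate.py` — tolerance-window matching and scoring
- `src/gsl4d/quantify.py` — partition correction, Strategies I/II/combined
- `src/gsl4d/validate.py` — calibration, LLOD/LLOQ, carry-over
- `src/gsl4d/stats.py` — Mann–Whitney/BH differential tables
- `src/gsl4d/synthetic.py` — seeded cohort/spectra/calibration generators

See `docs/methods.md` for the modelling assumptions and design choices.
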