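# Methods

This note documents the models, conventions, and design choices behind
`gsl4d`, and what the synthetic-data tests do and do not demonstrate.

## Mass and ion model

Species are treated as a glycan (composition + rooted topology taken
from the class registry) condensed onto a ceramide. Formulas are
assembled additively: free sphingoid base C_c H_(2c−2d+3) N O_n plus
free fatty acid C_x H_(2x−2y) O_(2+h) minus H2O for the amide bond, plus
one anhydro residue formula per monosaccharide, plus SO3 per sulfate and
C2H2O per O-acetyl. Deuterium labels (d3/d5/d9 internal standards)
substitute K hydrogens by H[2], raising the mass by K × 1.006277 Da.
Elemental arithmetic and monoisotopic masses are delegated to
`pyteomics.mass`.

Ion m/z uses a **proton mass of 1.007276 Da per charge** (electron mass
included). This convention reproduces the two-decimal reference values
for the doubly deprotonated GD1 ion (917.48) and the GM1 formate adduct
(794.93); a bare-H convention would miss both by ~0.5 mDa per charge.
Adducts are parsed from bracket notation (`[M+HCOOH-2H]2-`), splitting
the z transferred protons from the neutral gain/loss. Default negative
ion types per class: [M−H]⁻ for GM3/GM2 and neutrals, [M+HCOOH−2H]²⁻
for GM1 and mono-sialylated neolacto species, [M−2H]²⁻ for GD/GT/GQ,
[M−H2O−2H]²⁻ for GP1.

Isomer roots (GD1 vs GD1a/GD1b) share one composition; the a/b suffix
selects a topology only (identical mass) and is resolved downstream by
CCS and the 581 diagnostic. The GD1 root defaults to the a-type
topology for fragment generation; this choice affects no mass.

## Fragmentation model

B and Y ions are generated at every glycosidic bond of the topology
tree (a branch cleavage yields the branch as the B ion); modifications
ride with the residue that carries them. All fragments are singly
charged, matching the singly charged nominal diagnostics. Three
secondary emissions reflect well-known gas-phase behaviour and are
required for the diagnostics to appear in simulated spectra:

- every positive-mode B (oxonium) ion also sheds water — the dehydrated
  Neu5Ac oxonium is the nominal-274 sialylation diagnostic;
- O-acetyl groups are labile, so OAc-bearing B ions also appear
  de-acetylated (giving O-acetylated species their 290/581 ions);
- sulfatides emit an SO3 neutral loss, and a root-attached unmodified
  Hex-Hex chain emits a free-lactose loss (342.1162 — the published
  screening value; the anhydro-Hex2 loss of 324.1057 also exists but is
  not diagnostic).

Nominal mass is round-half-away-from-zero of the fragment m/z. C/Z ions
(±H2O) can be generated but participate in no diagnostic rule. The
default fragment matching tolerance is 10 mDa — looser than the 2–5 mDa
precursor windows because fragment statistics are poorer — and is
configurable everywhere it is used.

## 4D library and the serum fixture

Library entries carry theoretical m/z, mean RT/CCS over replicate runs,
fraction, and an optional reference spectrum; the builder averages
descriptors arithmetically and refuses mixed polarities per species.

The packaged serum fixture reproduces the published human-serum
inventory (376 species; 129 ganglio / 30 sialylated neolacto / 145
neutral / 72 sulfatide, with 14 count-only placeholder rows whose
ceramide is unidentified). The inventory prints acyl-carbon ranges and
counts, not explicit chain lists, so membership is filled
deterministically: even acyl carbons ascending first, then odd, then
higher double-bond/hydroxylation variants. Counts — not membership —
are the tested contract.

Fixture RT/CCS values come from a deterministic monotone surrogate:
RT increases with total chain carbons and decreases with unsaturation,
hydroxylation, and glycan size (sialylation/glycosylation shortens
elution on RP); CCS increases with glycan size, chain length, and chain
*extension* (maximum topology depth), so linear neolacto glycans get
larger CCS than branched ganglio isomers of the same composition —
the behaviour that lets ion mobility split GM1 from Neu5Ac-nLc4Cer.
Measured anchors (GD1b-type CCS 456.4 Å²) override the surrogate.
These descriptors exist to exercise matching logic; they are not
scientific reference values.

## Annotation

A candidate must pass every *active* window: m/z always; RT and CCS
when present on both sides (features missing one are annotated with a
partial-evidence flag); the MS/MS cosine score when both spectra exist.
Ranking uses 0.4·(1−|Δmz|/tol) + 0.2·(1−|Δrt|/tol) + 0.2·(1−|Δccs|/tol)
+ 0.2·(score/1000), renormalized over available terms — mass is the
strongest evidence. Ties break by smaller |ΔCCS|, then |Δmz|, then
name, so output is deterministic. The spectral score is 1000 × cosine
over greedily tolerance-matched peak pairs (unmatched peaks count in
the norms); it is symmetric, scale-invariant, and cross-checked against
matchms' CosineGreedy in the test suite. A vendor-style isotope-pattern
(mSigma) term is accepted in configuration for compatibility but not
implemented.

## Semi-quantification

The partition A = 100·area_f2/(area_f1+area_f2) is one function used by
both strategies. Strategy I: B = spiked_nmol·Ā/100 with Ā the
cohort-average over reference extracts; Strategy II: per-sample A.
In both, C = (analyte area / ISTD area)·B with **fraction-2 areas** in
the ratio — only the partition itself needs both fractions. The shipped
default ISTD map is the validated cross-class "sub-strategy 3"
(GM1→GM1-d5, GM2→GM2-d9, GM3→GM3-d5, GD3/GD2/GD1/GT1b/GQ1b→GD3-d3);
any map is configurable. Spiked amounts default to 12.5 µL × 20 µg/mL
= 0.25 µg per ISTD, converted to nmol by each ISTD's monoisotopic mass.

The combined strategy's base defaults to Strategy I with Strategy II
correcting outliers; the published description of which strategy is the
base differs between sections, so both orderings are selectable
(`combined_base`). Outlier rule (the source criterion is unstated): a
sample is flagged when any ISTD's A deviates from the cohort median by
more than k·MAD (k = 3.5) **or** by more than 15 percentage points;
cohorts under 3 samples skip flagging with a warning. Concentration
read-out is ng/µL serum via the species' monoisotopic mass and a
300 µL serum volume (both configurable). CVs use the sample standard
deviation (n−1); the compliance summary reports the share of species
with CV below a 35 % threshold. Fraction-1 neutral GSLs and sulfatides
are normalized to the GM3-d5 ISTD area as unitless ratios.

## Calibration and validation

Calibration fits response ratio on concentration ratio by OLS.
"Standard deviation of responses" in LLOD = 3.3σ/s and LLOQ = 10σ/s is
ambiguous; the default σ is the residual standard error of the
regression (the common ICH reading), with the intercept standard error
or an external blank SD selectable. LLOQ/LLOD is exactly 10/3.3 whenever
the slope is positive; non-positive slopes return the fit with limits
undefined and a flag. Linearity acceptance defaults to R² ≥ 0.95. The
dilution-series helper reproduces the 8-point two-fold design from
5 pmol/µL down to 0.039.

## Statistics

Per-species two-sided Mann–Whitney U with BH adjustment across species
(within each sex stratum when stratified). The exact null distribution
is used when both groups have ≤ 8 samples and no ties; otherwise the
tie-corrected normal approximation (scipy). Stars (*, **, ***) follow
the 0.05/0.01/0.001 thresholds on the raw p value. Covariate-adjusted
empirical-Bayes modelling is deliberately out of scope; this module
implements only the nonparametric layer.

## Synthetic data: what it emulates, and what it does not

The cohort generator reproduces the study design: ISTD partitions drawn
normal (truncated to (0,100)) at the reference-serum means/CVs
(78.70/5.59, 80.40/2.94, 75.99/3.95, 70.35/7.40 for GD3-d3, GM1-d5,
GM2-d9, GM3-d5; the published replicate count is ambiguous between 4
and 6, so n is a parameter); lognormal species abundances (default
median 0.05 nmol, CV 50 % across samples — a realistic spread for
low-abundance serum GSLs); multiplicative lognormal area noise
(default CV 7 %); response factors of 1 per class (the
semi-quantification assumption that analytes respond like their ISTD),
configurable to probe mis-calibration. Feature descriptors are fixture
values plus Gaussian jitter. For the annotation-recovery property,
"half-tolerance" noise is defined as jitter whose 2σ span equals half
of each matching window (σ = tol/4 per dimension).

Not emulated: chromatographic peak shapes, isotopologue interference,
in-source decay, matrix effects, inter-batch drift, or correlated
noise between fractions. Passing tests therefore demonstrate the
correctness of the computational pipeline under its stated noise model,
not instrument-level performance; cohort-level empirical findings
(differential species lists, empirical CV-compliance percentages,
per-analyte LLOD/LLOQ values) depend on instrument data and are covered
only by simulation analogues and properties (e.g. outlier correction
improving CV compliance, injected ≥4× fold changes detected at
adjusted p < 0.05 with 10 samples/group).

## Numerical conventions and problem sizes

Ion m/z is carried at full precision and compared to printed values at
2 d.p.; fragment and library m/z comparisons use absolute tolerances
(1e−4 Da in tests). Degenerate inputs are explicit: empty spectra score
0 with a warning and set no flags; zero two-fraction ISTD sums give an
undefined (nan) partition and flagged records; zero-mean species are
excluded (and counted) from CV tables. Simulations in the test suite
and acceptance script use 1000 replicates for partition recovery and
200 × 100-species null cohorts for the type-I-error check — sizes at
which Monte-Carlo error is comfortably inside the asserted bounds.

## Known limitations

- Linkage types (α2-3 vs α2-6), anomericity, and GalNAc/GlcNAc isomer
  discrimination are not represented; a/b-series assignment rests on
  the presence-based 581 diagnostic and CCS, with abundance-ratio
  discrimination left to the caller.
- Fixture membership inside printed carbon ranges is an enumeration
  convention, and fixture RT/CCS are surrogate values.
- The MSP dialect is the plain NIST text form (Name / PrecursorMZ /
  Num Peaks); vendor extensions are preserved only as opaque metadata.
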