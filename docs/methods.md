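# Methods

## Scope and model

`lipidflux` computes, end to end, the statistics of a serial-sampling
reperfusion lipidomics study: per-injection MRM peak areas are converted to
semi-quantitative concentrations against class-specific internal standards
(ISTDs), corrected for drift and batch effects with pooled-QC anchoring,
filtered for reproducibility, and analyzed with repeated-measures and
covariate-adjusted regression models.  Raw chromatographic peak integration
is out of scope (areas are the input), as are lipid identification,
absolute calibration-curve quantitation, and survival modeling.

## Nomenclature and panel

Species are identified at sum composition — class plus total acyl
carbons:double bonds (`PC 34:2`), with ether `PC(O-36:3)` and plasmalogen
`PE(P-38:4)` subclasses, chain-resolved names for DG/TG
(`TG 16:0_17:0_18:0`), and trivial names for the six oxidized-PC species
(POVPC, PONPC, PGPC, PAzPC, KOdiAPC, KDdiAPC).  Chain-resolved names retain
their chains in the identity so an odd-chain ISTD (TG 17:0_17:0_17:0) stays
distinct from an analyte with the same sum composition (TG 51:0).

The packaged default panel is a *representative reconstruction*: 322
species over the 25 classes/subclasses, with the printed odd-chain or
deuterated ISTDs per class.  The full deposited transition list is not
public in text form, so class membership counts and m/z values (from an
additive mass model in a dev script) are plausible config data, not
measured values.  Classes without a printed ISTD (PI, GM3) borrow the
nearest class standard (PG 17:0_17:0, Hex3Cer 17:0); the panel CSV is
ordinary config and can be replaced wholesale.

## Quantitation

* **Deisotoping.** Within a class, the M+2 isotopologue of the species with
  one more double bond overlaps the monoisotopic transition of its
  neighbour.  Species are processed in decreasing double-bond order:
  `corrected(S) = observed(S) − p2 · corrected(S′)` with
  `p2(C) = C(C−1)/2 · a²`, `a = 0.0107`, and `C` the molecular carbon count
  (acyl total + a per-class backbone-carbon table).  `p2` is the linearized
  two-heavy-atom term; the exact binomial ratio is ≈2% larger at natural
  abundance, a documented approximation.  Negative corrected areas clip to
  zero and are flagged.
* **ISTD ratio.** `conc = area/area_ISTD × spiked ISTD concentration`.
  Missing or zero ISTD areas make that sample/class missing and flagged —
  never silently dropped, never imputed at this stage.
* **Correction factors (DG/TG).** A species whose fragment signal splits
  over k equally likely acyl-loss channels retains 1/k of it in the
  monitored transition, while identical-chain ISTDs retain everything, so
  the measured ratio is **divided** by the CF (0.5 / 0.33 / 0.66 rules).
  The source method only says the factors were "applied"; division makes
  CF = 1 the no-op and is the default, with a `--cf-convention multiply`
  escape hatch.  This is the most consequential sign/convention choice in
  the quantitation stage.
* **CE response factors.** The saturation-specific calibration lines are
  evaluated exactly as printed and also divide the ratio.  The
  polyunsaturated line `y = −0.07x + 1.54` is non-positive for chain
  length ≥ 22, so CE 22:5 / CE 22:6 cannot be quantified under it; they are
  flagged `rf_nonpositive` and fall out at QC.  (The monounsaturated line
  dominating the saturated one at equal x is suspicious — possibly a
  transcription artifact in the source — but is implemented as printed.)
* **FA qualifier.** Fatty acids carry a second, higher-collision-energy
  transition with the same masses; a qualifier/quantifier ratio deviating
  more than ±50% (relative) from the PQC-established reference flags the
  measurement.

## Drift normalization and QC filter

The pooled QC (PQC) has constant composition, so any structure in its
signal is systematic error.  The SERRF-style normalizer fits, per species,
a random forest of the PQC log-intensity on injection order, batch index,
and the k = 10 most PQC-correlated other species, predicts the systematic
component for every injection and rescales
(`raw × median(PQC)/predicted`); forest size defaults to 500 trees,
seeded.  Companion features are standardized group-wise — PQC rows by PQC
statistics, study rows by study-row statistics — so that training and
prediction features share a scale and bulk biological differences between
study samples and the pool are not mistaken for systematic error; with
QC-only standardization the correction visibly attenuates broad biological
shifts (most classes move together at 2 h), which the group-wise scaling
prevents.  The per-species PQC median is preserved exactly (enforced
by a final rescale; contract-tested at 1%).  Batches with fewer than 5
PQCs fall back to a deterministic per-batch loess of PQC intensity on
injection order, which is also exposed directly as `loess_normalize`.

Normalization runs on quantified concentrations (post-ISTD); under the
multiplicative error model the ISTD ratio and the drift correction commute
to first order.  After correction, a species is retained iff its PQC
CoV (sample sd / mean × 100) is **below 20%** and its highest sample-type
mean is not in the blanks ("highest" = strictly greatest).  CoV is computed
post-normalization (config-switchable), since the filter follows batch
correction in the method's order of operations.  A 2-component PCA report
quantifies QC-replicate tightness (within-type dispersion relative to the
overall score dispersion).

## Statistics

* Lipid values are natural-log transformed before testing, with
  half-minimum imputation for zeros; percent differences and fold changes
  are computed on the raw scale.  Complete-case handling per species; no
  mixed-model imputation.
* **RM-ANOVA.** Standard within-subject decomposition;
  Greenhouse–Geisser ε̂ from the double-centered sample covariance of the
  timepoint measures, clipped to [1/(k−1), 1]; p from
  F(ε̂(k−1), ε̂(k−1)(n−1)).  At k = 2 this reduces exactly to the paired
  t-test (F = t²).  Constant data returns F = 0, p = 1 by convention;
  n < 3 complete subjects flags `insufficient_n`.
* **Pairwise contrasts.** Paired t-tests with Bonferroni correction.  The
  correction family defaults to the pairwise comparisons *within a species*
  (m = 3 for t0/t1/t2) — the reading most consistent with pairing the
  correction with "pairwise comparisons" — with a study-wide option
  (× number of species) available in config.  This family choice is the
  most consequential ambiguity in the statistics stage.
* **Percent differences** use a seeded nonparametric bootstrap over
  subjects (2000 draws by default) for the SEM.
* **Compositional view.** Within-class shares (species / class total per
  sample) with log₂ ratios of mean shares vs baseline; base 2 chosen where
  the source only says "log ratio".
* **Heatmap.** Complete-linkage Euclidean hierarchical clustering of
  log-transformed species profiles (the cited tool's defaults), emitting
  linkage and leaf order only (no figure rendering).
* **Injury association.** Delta cTnT = peak − baseline over all provided
  draws (optionally windowed, e.g. 72 h); OLS of delta on log lipid plus
  age, sex (0/1), BMI, smoking (0/1), diabetes (0/1) and ischemic time in
  minutes, untransformed; t-based 95% CIs; design condition number > 1e8
  flags collinearity.  No multiple-testing correction across species in
  this screen (raw p < 0.05), deliberately contrasting with the corrected
  ANOVA — stated loudly here.  Tertile split: top ⌈n/3⌉ values vs the
  rest, boundary ties to the lower group (n = 80 → 27 vs 53).  Group
  comparisons are unpaired t-tests on logs with raw-scale log2 fold
  changes; both groups need n ≥ 3.  An HDL-adjustment sensitivity analysis
  is available by passing extra covariate columns.

## Synthetic study generator

The generator emulates the acquisition design: default cohort 80 STEMI
(t0/t1/t2) + 30-subject late subset (t3/t4) + 50 controls; batches of 60
study samples with 20 PQC, 6 TQC, 4 SRM and 12 blank injections (102 per
batch), PQCs at a strict 10:1 cadence inside the study-sample span.  All
randomness flows from one seed through named sub-streams (CRC-keyed
`SeedSequence`), so fixed seed ⇒ bit-identical tables and stages can be
regenerated independently.

Planted biology (defaults are the study conditions, not tuning knobs):

* class abundance rank CE > PC > PC(O) > LPC > SM at the top and
  acylcarnitine < Hex3Cer < LPC(O) < GM3 < PE(P) at the bottom;
* temporal folds vs t0 — DG ×0.70 at t1 then ×1.64 to t2, TG ×0.76 then
  ×1.59, FA down to ×0.26 by t2, OxPL ×1.30 at t1, acylcarnitines
  declining to a 48-h nadir, most phospholipid classes ×0.80–0.90 at t1;
  remaining classes unchanged;
* troponin associations by construction: delta cTnT = 2500 + Σᵢ βᵢ·δᵢ +
  ischemic-time term + N(0, 500), with δᵢ the subject's latent lognormal
  deviation (σ = 0.294, i.e. ~30% between-subject CV — a config-exposed
  assumption, not a reported value) and β = +2000 (acylcarnitine 18:2),
  −1000 (TG 51:0), −900 (LPC 17:1), −600 (PI 34:1) ng/L per log-unit;
  β magnitudes were sized so the planted effects are detectable at n = 80
  through the attenuation added by within-subject and measurement noise;
* STEMI-vs-control elevation of the acylcarnitine and LPC classes;
* MACE sampled with probability increasing logistically in delta cTnT
  (~16% event rate).

Nuisance structure: smooth logistic injection-order drift with
class-correlated amplitudes (mean 0.35), lognormal batch offsets (σ 0.15),
8% multiplicative measurement noise, ~10 planted high-noise species
(σ 0.45) and 4 blank-dominant contaminants so the QC filter has real work;
M+2 interference is injected with the same `p2` model the deisotoper
inverts; blanks carry 1% carryover.  The troponin series is a fixed shape
peaking at 12–24 h whose maximum equals baseline + delta exactly.

What the generator does **not** emulate: chromatographic peak shapes,
retention-time drift, missingness mechanisms other than non-positive
responses, correlated covariate–lipid confounding (off by default), or
realistic troponin release kinetics.  Passing recovery tests therefore
shows the pipeline inverts its own error model faithfully — it does not
validate the biology of any real cohort.

## Numerical and testing choices

Tests compare the deisotoper against an independent linear-system-solve
oracle (1e-6) and the linearized `p2` against the exact binomial (3%);
RM-ANOVA against pingouin and a paired-t closed form; clustering against a
brute-force agglomeration; regressions against normal equations and null /
coverage simulations (2000 and 500 replicates).  The 20-seed recovery
sweep uses the deterministic loess normalizer so the replicates stay cheap;
the random-forest path is exercised on the single full-scale default run
(100 trees there; library default 500 — the drift signal has far lower
complexity than either).  Problem sizes in the test suite (null suite
n = 20, k = 3, 1000 reps; coverage 500 reps at n = 80) are the package's
own choices for a deterministic, tractable suite.

## Known limitations

* The panel is representative, not the deposited transition list; absolute
  concentrations are semi-quantitative (ISTD-relative) only.
* SERRF details (features, forest size, correlation set) are this
  package's operationalization of a briefly described method; all knobs
  are exposed in config.
* The CF/RF "divide" convention and the Bonferroni family are documented
  interpretations of ambiguous prose; both have config escape hatches.
* Deposited-cohort headline numbers are only checkable against a local
  MetaboLights MTBLS3839 download (`lipidflux.reference`).
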