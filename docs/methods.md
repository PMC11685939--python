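# Methods

`liquidmet` implements the computational layer of a liquid-biopsy metabolic
profiling workflow for acute myeloid leukemia (AML): single-cell redox
cytometry of circulating CD34⁺ blasts, SCENITH-derived energetic parameters,
Mito-Stress bioenergetics, multiplex extracellular-vesicle (EV) surface-marker
panels, and EV lipidomics. Because patient-level raw data for these layers are
not publicly deposited, the package ships a synthetic-cohort generator with
known ground truth; every analysis stage is validated by parameter recovery
and by independent oracles, not by reproducing any patient cohort.

## Redox cytometry

Each sample is an event table (cells × channels) with ROS (CellROX-type),
GSH (thiol-reactive) and MITO (mitochondrial-potential) channels, and
population labels {CD3, CD34, CD34_CD38low, other}. Classification is
quadrant gating on a channel pair: a cell is *hi* on a channel iff its
intensity strictly exceeds the cutpoint; a cell exactly at the cutpoint is
*lo*. Cutpoints are anchored on the CD3⁺ lymphocytes of the same sample — an
internal reference present in every blood draw that cancels batch and
instrument shifts. The anchoring population is part of the assay design; the
exact cut rule is not published, so we use a configurable quantile of the
CD3⁺ intensity distribution (default 0.5, linear interpolation between order
statistics). This default is a modelling choice, not a claim about the
original gates; the quadrant machinery is invariant to it.

Geometric-mean MFI (gMFI) is taken over strictly positive intensities.
Nonpositive values (possible after compensation upstream) are excluded and
counted rather than shifted — any additive offset would distort ratios of
gMFIs, which are the quantities of interest.

## SCENITH energetic parameters

Protein synthesis (puromycin incorporation, anti-puromycin gMFI) is measured
under vehicle (Co), 2-deoxy-D-glucose (2DG), oligomycin (O) and both (DGO):

    gluco_dep = 100·(Co − 2DG)/(Co − DGO)
    mito_dep  = 100·(Co − O)/(Co − DGO)
    glyco_cap = 100 − mito_dep
    faao_cap  = 100 − gluco_dep

Choices where the published description is silent:

* **Out-of-range values.** Noise can push the ratios outside [0, 100]. Raw
  values are always retained; the reported values are clamped by default and
  flagged when clamping occurred.
* **Harringtonine.** A full translation arrest estimates staining
  background. The formulas above do not reference it, so the default is
  `background="none"`; `background="subtract_H"` subtracts the H gMFI from
  all four conditions first. Both behaviours are available because the
  original choice is not recoverable from the text.
* **Degenerate denominator.** Co − DGO ≤ 0 means no inhibitor-sensitive
  translation signal; the computation fails loudly, naming the sample.

Uncertainty: a percentile bootstrap resamples cells with replacement
*independently within each condition* (conditions are separate tubes; no
cell pairing exists), recomputes the gMFI set and profile B times, and
reports 2.5/97.5 percentiles. Replicates with degenerate denominators are
dropped; more than 50% degenerate aborts with a diagnostic.

The synthetic generator uses an additive two-pathway model: translation
signal S on background b, with a glucose-driven share (gluco_dep_true%)
removed by 2DG and a mitochondrial share (mito_dep_true%) removed by
oligomycin; DGO and H leave only b. The formulas are exact inverses of this
model at zero noise, which makes parameter recovery a well-posed test:
recovery is exact at CV 0, and the mean recovered parameter over 200
replicates at 5% gMFI CV sits well within 2 percentage points of truth. A
single replicate's mitochondrial dependence is noisier (Co − O is a small
difference of large numbers), which is the realistic behaviour of the assay.

## Mito-Stress extraction

An oxygen-consumption trace with oligomycin → FCCP → rotenone/antimycin A
injections is reduced with the standard phase conventions: non-mitochondrial
OCR = minimum after Rot/AA; basal = last pre-oligomycin point − non-mito;
ATP-linked = basal − (post-oligomycin minimum − non-mito); maximal =
post-FCCP maximum − non-mito; spare respiratory capacity (SRC) = maximal −
basal. SRC may be negative (FCCP response below basal); it is flagged, never
clamped. Each of the four phases must contain at least one measurement.

## EV bead panels

The panel is the standard 37-epitope multiplex bead kit plus two isotype
controls (mIgG1, REA) and a buffer blank; the marker vocabulary is validated
on load. Correction subtracts the blank MFI from every marker. Negative
corrected values are clamped to 0 by default and flagged (the published
handling is unstated); isotype controls are reported but not subtracted —
an optional isotype gate (detected iff corrected MFI > mean corrected
isotype MFI) is provided, off by default.

Group comparison is a per-marker two-sided Mann–Whitney rank-sum test
(exact for small tie-free samples, asymptotic otherwise, via scipy's
`method="auto"`), with an optional Holm-adjusted column clearly labelled as
an analysis-layer addition. Discrimination uses the empirical ROC: AUC via
the rank (Mann–Whitney) formulation with ties counted half, operating
cutoff by Youden's J (the published "best cutoff" names no rule), and a
stratified percentile bootstrap CI (seeded). Particle-size samples are
summarized by mean, histogram-mode (configurable bin width, default 5 nm)
and D10/D50/D90 percentiles with linear interpolation.

## Lipidomics

Shorthand names follow `CLASS [O-|P-] chain ((_|/) chain)*` with
`chain = C:D[;ox]`. The sphingoid extra-oxygen token after `;` accepts `O`,
`nO`, a plain number ≤ 3, and the digit-zero spelling `20` (printed tables
often render `2O` this way); the last is read as 2 oxygens and flagged
ambiguous. Chains keep their source spelling so `format(parse(x)) == x`
byte-for-byte, while equality compares the semantic fields only. FA and LPC
carry exactly one chain; unknown class codes are rejected with the character
position.

The class registry is the nine classes observed in the dataset — PC, LPC,
ether-PC (`PC-O`), PE, PI, DG, FA, Cer, SM. Ether species are a distinct
class by default (keeping the nine-class count); a single flag folds them
into the diacyl class instead, never both. Class totals therefore conserve
the species sum exactly.

* **Composition**: class total / grand total × 100, per sample, per group
  and overall.
* **Odd/even ratio**: the published definition is implicit; here it is the
  percentage of total concentration carried by species with ≥ 1 odd-carbon
  chain (species-count weighting available). Neither variant is claimed to
  reproduce the published 3.28%/3.94%.
* **Annotation QC**: accept iff |observed − theoretical|/theoretical × 10⁶
  < 25 ppm **and** score > 80% (both strict; a record at exactly 80.0 is
  rejected — the boundary choice is ours). The mean |ppm| over accepted
  records is reported.
* **Normalization**: each sample divided by its own median, then each
  species row centered and scaled to unit SD (ddof = 1); zero-variance rows
  are flagged and left centered-only.
* **Transformation network**: for each directed class conversion (default
  SM→Cer, PC→DG, PC→LPC, PC→FA, PI→FA, taken from the precursor/product
  relations the study describes), per-sample r = log(product total /
  reactant total), scored by z = (mean_A r − mean_B r)/(s_p·√(1/n_A+1/n_B))
  with pooled SD — simple, sign-interpretable, antisymmetric under group
  swap, and invariant to per-sample rescaling (the original "arbitrary
  scale" z is not fully specified). Samples with a zero class total are
  excluded per edge with a log; an edge whose group drops below 2 usable
  samples errors.

## Synthetic cohorts

Defaults emulate the study's shape: 40 AML vs 12 HD samples, ELN risk split
favorable/intermediate/adverse = 0.25/0.40/0.35 allocated deterministically,
2000 events per sample, between-sample CV 0.20. All intensities are
log-normal; group effects are log2-scale shifts applied to the AML group
only. Defaults encode the reported directions: GSH +1 / MITO +1 / ROS −0.5
in AML CD34⁺ cells; CD44 +1.5 and other stem/immune markers up, platelet
markers down on AML EVs; DG +0.8 and FA +0.6 among lipid classes. The
default lipid composition uses the five published class percentages
(PC 44.69, FA 15.85, DG 11.61, Cer 11.37, SM 10.62); the remaining 5.86% is
split across LPC/ether-PC/PE/PI (2.00/1.50/1.50/0.86) as an illustrative
choice. Magnitudes are configurable throughout — the source reports group
summaries, not generative parameters, so recovery of *our own* ground truth,
not cohort reproduction, is the test.

Seeding: one global seed fans out through
`SeedSequence(seed, spawn_key=(domain, sample_index))`, so outputs are
byte-identical under a fixed seed and adding samples never perturbs
existing ones.

What the generator does **not** emulate: spectral spillover/compensation,
doublets, bead barcode deconvolution, particle-tracking physics, MS peak
picking, missing data, or patient covariate structure beyond group labels.
Passing tests therefore demonstrate correctness of the estimators and
calibration of the statistics under a clean generative model, not robustness
to instrument artifacts.

## Calibration and problem sizes

With all effects zero, the per-marker rank-sum rejection rate at α = 0.05
across 200 cohorts (20 vs 12; 7,400 tests) lies inside the 99% binomial band
around 5% — the pipeline's testing layer is honest at its nominal level.
Oracle checks run the quadrant classifier against a per-cell double loop
(1,000 fixtures ≤ 20 cells) and the rank-formulation AUC against all-pairs
counting (10,000 fixtures ≤ 50 samples, ties counted half). Simulation sizes
throughout (200 replicates for recovery and calibration, 2,000-replicate
bootstraps in examples) were chosen to keep the full suite fast on a single
CPU while leaving Monte-Carlo error well below the asserted margins.

## Known limitations

* The CD3-anchored threshold quantile is a stand-in for unpublished gates;
  quadrant percentages depend on it even though the classifier does not.
* Spearman p-values are exact only for tie-free n ≤ 9 (full enumeration);
  larger samples use the large-sample approximation.
* The odd/even ratio and network z definitions are fixed by this package,
  not by the source assays.
* No survival modelling, gene-expression integration, multivariate
  (PLS-DA/VIP) statistics, or instrument raw-file parsing.
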